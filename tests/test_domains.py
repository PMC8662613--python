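import numpy as np
import pytest

from conftest import random_protein
from oracles import pssm_brute

from ogmapper.domains import (
    DomainHit,
    clan_disambiguate,
    denovo_scan,
    map_coordinates,
    pssm_score,
    realign_refine,
    transfer_domains,
)
from ogmapper.refdb import DomainModel
from ogmapper.search import smith_waterman


def _model(motif, clan="CLx", match=5, mismatch=-2, ga_frac=0.6):
    alpha = "ACDEFGHIKLMNPQRSTVWY"
    pssm = np.full((len(motif), 20), mismatch, dtype=np.int64)
    for i, aa in enumerate(motif):
        pssm[i, alpha.index(aa)] = match
    return DomainModel("M_" + motif[:4], clan, len(motif), pssm,
                       ga_frac * match * len(motif))


class TestMapCoordinates:
    def test_identity_mapping_on_identical_sequences(self):
        seq = random_protein(np.random.default_rng(0), 50)
        hit = smith_waterman(seq, seq)
        assert map_coordinates(hit, (10, 20)) == (10, 20)

    def test_interval_outside_alignment_is_none(self):
        seq = random_protein(np.random.default_rng(1), 30)
        hit = smith_waterman(seq, "MMMM" + seq)  # alignment starts at t=5
        assert map_coordinates(hit, (1, 3)) is None

    def test_matches_column_walk_oracle(self, rng):
        for _ in range(25):
            a = random_protein(rng, 60)
            b = random_protein(rng, 60)
            hit = smith_waterman(a, b)
            if not hit.aligned_pairs:
                continue
            t_by_col = dict((t, q) for q, t in hit.aligned_pairs)
            ts = int(rng.integers(1, 60))
            te = int(rng.integers(ts, 61))
            qs = [t_by_col[t] for t in range(ts, te + 1) if t in t_by_col]
            expect = (min(qs), max(qs)) if qs else None
            assert map_coordinates(hit, (ts, te)) == expect


class TestTransfer:
    def test_identical_query_identical_coordinates(self, tiny_db):
        seq = tiny_db.proteins["pA"].sequence
        hit = smith_waterman(seq, seq, query_id="q", target_id="pA")
        hits = transfer_domains(tiny_db, "q", hit)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].mode) == (5, 12, "transferred")
        assert hits[0].clan_id == "CL1"

    def test_domain_outside_aligned_region_not_transferred(self, tiny_db):
        seq = tiny_db.proteins["pA"].sequence
        # query covers only the tail of pA; the 5..12 domain cannot map
        hit = smith_waterman(seq[19:], seq, query_id="q", target_id="pA")
        assert hit.target_start > 12
        assert transfer_domains(tiny_db, "q", hit) == []


class TestPssmScore:
    def test_exact_motif_scores_self_score(self):
        motif = "WWHHKKRRDD"
        model = _model(motif)
        window = "AAAA" + motif + "CCCC"
        score, iv = pssm_score(window, model)
        assert score == 5 * len(motif)
        assert iv == (5, 14)

    def test_negative_everywhere(self):
        model = _model("WWWW")
        score, _ = pssm_score("AAAA", model)
        assert score <= 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            motif = random_protein(rng, int(rng.integers(4, 12)))
            model = _model(motif)
            window = random_protein(rng, int(rng.integers(3, 40)))
            assert pssm_score(window, model) == pssm_brute(window, model)

    def test_x_residues_score_unknown_penalty(self):
        model = _model("KK")
        # best placement overhangs the window: a single position at the
        # unknown-residue score of -1 beats the full overlap at -2
        score, _ = pssm_score("XX", model)
        assert score == -1


class TestRefine:
    def test_pad_zero_exact_coordinates_unchanged(self, tiny_db):
        seq = tiny_db.proteins["pA"].sequence
        t = DomainHit("q", "DM1", "CL1", 5, 12, 40.0, "transferred")
        r = realign_refine(seq, t, tiny_db, pad=0)
        assert r is not None
        assert (r.start, r.end) == (5, 12)
        assert r.score >= tiny_db.domain_models["DM1"].ga_threshold
        assert r.mode == "refined"

    def test_spurious_transfer_below_ga_dropped(self, tiny_db, rng):
        noise = random_protein(rng, 40)
        t = DomainHit("q", "DM1", "CL1", 5, 12, 40.0, "transferred")
        # random sequence essentially never reaches GA = 24 over 8 positions
        assert realign_refine(noise, t, tiny_db, pad=4) is None

    def test_missing_model_is_error(self, tiny_db):
        t = DomainHit("q", "nope", "", 5, 12, 40.0, "transferred")
        with pytest.raises(ValueError, match="model"):
            realign_refine("AAAA", t, tiny_db)


class TestDenovo:
    def test_two_planted_motifs_both_found(self, tiny_db, rng):
        m1 = _model("WWHHKKRRDD", clan="A")
        m2 = _model("CCEEFFGGLL", clan="B")
        tiny_db.domain_models = {m1.model_id: m1, m2.model_id: m2}
        seq = "AAAA" + "WWHHKKRRDD" + "AAAA" + "CCEEFFGGLL" + "AAAA"
        hits = denovo_scan(seq, tiny_db, "q")
        assert [(h.model_id, h.start, h.end) for h in hits] == [
            ("M_WWHH", 5, 14),
            ("M_CCEE", 19, 28),
        ]
        assert all(h.mode == "denovo" for h in hits)

    def test_empty_model_set(self, tiny_db):
        tiny_db.domain_models = {}
        assert denovo_scan("AAAA", tiny_db, "q") == []

    def test_all_hits_clear_ga(self, small_benchmark):
        db = small_benchmark.db
        for qid, seq in small_benchmark.queries[:5]:
            for h in denovo_scan(seq, db, qid):
                assert h.score >= db.domain_models[h.model_id].ga_threshold


class TestClanDisambiguate:
    def _hit(self, model, clan, start, end, score):
        return DomainHit("q", model, clan, start, end, score, "denovo")

    def test_same_clan_identical_interval_best_wins(self):
        a = self._hit("m1", "C", 10, 20, 50)
        b = self._hit("m2", "C", 10, 20, 40)
        assert clan_disambiguate([a, b]) == [a]

    def test_different_clans_both_kept(self):
        a = self._hit("m1", "C1", 10, 20, 50)
        b = self._hit("m2", "C2", 10, 20, 40)
        assert set(clan_disambiguate([a, b])) == {a, b}

    def test_clanless_hits_never_compete(self):
        a = self._hit("m1", "", 10, 20, 50)
        b = self._hit("m2", "", 10, 20, 40)
        assert set(clan_disambiguate([a, b])) == {a, b}

    def test_small_overlap_tolerated(self):
        a = self._hit("m1", "C", 10, 20, 50)
        b = self._hit("m2", "C", 18, 30, 40)  # 3/11 of the shorter
        assert set(clan_disambiguate([a, b])) == {a, b}

    def test_idempotent(self, rng):
        for _ in range(20):
            hits = [
                self._hit(
                    f"m{i}", rng.choice(["C1", "C2", ""]),
                    int(rng.integers(1, 50)), 0, float(rng.integers(10, 90)),
                )
                for i in range(8)
            ]
            hits = [
                DomainHit(h.query_id, h.model_id, h.clan_id, h.start,
                          h.start + int(rng.integers(5, 25)), h.score, h.mode)
                for h in hits
            ]
            once = clan_disambiguate(hits)
            assert clan_disambiguate(once) == once

    def test_greedy_vs_exhaustive_subset_oracle(self, rng):
        """Greedy is the contract; compare against the best conflict-free
        subset to measure (and bound) its gap on small instances."""
        def conflict(a, b, frac=0.5):
            if not a.clan_id or a.clan_id != b.clan_id:
                return False
            ov = max(0, min(a.end, b.end) - max(a.start, b.start) + 1)
            shorter = min(a.end - a.start + 1, b.end - b.start + 1)
            return ov > frac * shorter

        from itertools import combinations

        gaps = []
        for _ in range(15):
            hits = []
            for i in range(7):
                s = int(rng.integers(1, 40))
                hits.append(
                    self._hit(
                        f"m{i}", str(rng.choice(["C1", "C2"])), s,
                        s + int(rng.integers(5, 20)), float(rng.integers(10, 99)),
                    )
                )
            greedy = clan_disambiguate(hits)
            # greedy output must itself be conflict-free and maximal
            assert not any(
                conflict(a, b) for a, b in combinations(greedy, 2)
            )
            for h in hits:
                if h not in greedy:
                    assert any(conflict(h, k) for k in greedy)
            best = 0
            for r in range(len(hits) + 1):
                for subset in combinations(hits, r):
                    if not any(conflict(a, b) for a, b in combinations(subset, 2)):
                        best = max(best, sum(h.score for h in subset))
            gaps.append(best - sum(h.score for h in greedy))
        assert all(g >= 0 for g in gaps)

    def test_refinement_never_increases_hit_count(self, tiny_db, rng):
        seq = tiny_db.proteins["pA"].sequence
        hit = smith_waterman(seq, seq, query_id="q", target_id="pA")
        transferred = transfer_domains(tiny_db, "q", hit)
        refined = [
            r
            for t in transferred
            if (r := realign_refine(seq, t, tiny_db)) is not None
        ]
        assert len(refined) <= len(transferred)
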