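import numpy as np
import pytest

from oracles import gene_tree_orthologs_oracle

from ogmapper import simdata
from ogmapper.refdb import validate
from ogmapper.simdata import (
    SimParams,
    assign_functions,
    emit_benchmark,
    evolve_sequences,
    simulate_family,
    simulate_taxonomy,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestTaxonomySim:
    def test_two_species_is_cherry(self):
        tree, root = simulate_taxonomy(2, 4, _rng())
        assert len(tree.nodes) == 3
        assert tree.leaves() == set(tree.children(tree.root_id))

    def test_leaf_count_conserved(self):
        for n in (2, 5, 9, 16):
            tree, _ = simulate_taxonomy(n, 8, _rng(n))
            assert len(tree.leaves()) == n

    def test_same_seed_identical(self):
        t1, r1 = simulate_taxonomy(12, 6, _rng(42))
        t2, r2 = simulate_taxonomy(12, 6, _rng(42))
        assert t1.nodes == t2.nodes
        assert [n.blen for n in r1.walk()] == [n.blen for n in r2.walk()]

    def test_depth_bound_respected(self):
        tree, root = simulate_taxonomy(8, 3, _rng(1))
        assert all(tree.depth(t) <= 3 for t in tree.nodes)

    def test_too_many_species_for_depth(self):
        with pytest.raises(ValueError):
            simulate_taxonomy(9, 3, _rng())


class TestFamilySim:
    def test_no_dup_no_loss_one_leaf_per_species(self):
        tree, root = simulate_taxonomy(8, 6, _rng(5))
        params = SimParams(n_species=8, duplication_rate=0.0, loss_rate=0.0)
        fam = simulate_family(root, params, _rng(5))
        assert len(fam.leaves) == 8
        assert len({lf.species for lf in fam.leaves}) == 8
        assert all(t == "one2one" for t in fam.true_types.values())
        # with no duplications every pair is orthologous
        n = len(fam.leaves)
        assert len(fam.true_pairs) == n * (n - 1) // 2

    def test_forced_root_duplication_splits_clades(self):
        # high duplication on a 2-species tree: cross-clade pairs whose LCA
        # is a duplication are never orthologs
        tree, root = simulate_taxonomy(4, 4, _rng(2))
        params = SimParams(n_species=4, duplication_rate=1.5, loss_rate=0.0)
        fam = simulate_family(root, params, _rng(7))
        for x in fam.leaves:
            for y in fam.leaves:
                if x.name >= y.name:
                    continue
                is_pair = fam.is_true_pair(x.name, y.name)
                oracle = y.name in gene_tree_orthologs_oracle(fam, x.name)
                assert is_pair == oracle

    def test_types_match_brute_force_counting(self):
        tree, root = simulate_taxonomy(6, 5, _rng(3))
        params = SimParams(n_species=6, duplication_rate=0.6, loss_rate=0.1)
        for seed in range(5):
            fam = simulate_family(root, params, _rng(seed))
            ortho = {lf.name: gene_tree_orthologs_oracle(fam, lf.name)
                     for lf in fam.leaves}
            for (x, y), t in fam.true_types.items():
                sp_x = fam.leaf_species[x]
                sp_y = fam.leaf_species[y]
                a = sum(
                    1 for z in fam.leaves
                    if z.species == sp_x and y in ortho[z.name]
                )
                b = sum(
                    1 for z in fam.leaves
                    if z.species == sp_y and z.name in ortho[x]
                )
                expect = ("many" if a > 1 else "one") + "2" + (
                    "many" if b > 1 else "one"
                )
                assert t == expect

    def test_hopeless_parameter_regime_raises(self):
        tree, root = simulate_taxonomy(4, 4, _rng(2))
        params = SimParams(n_species=4, duplication_rate=0.0, loss_rate=1.0)
        with pytest.raises(Exception, match="rejection|loss"):
            simulate_family(root, params, _rng(0))


class TestSequences:
    def _family(self, seed=11):
        tree, root = simulate_taxonomy(6, 5, _rng(seed))
        params = SimParams(n_species=6, duplication_rate=0.2, loss_rate=0.0)
        return simulate_family(root, params, _rng(seed))

    def test_rate_zero_all_leaves_equal_root(self):
        fam = self._family()
        evolve_sequences(fam, 100, 0.0, _rng(1))
        assert all(s == fam.root_sequence for s in fam.sequences.values())

    def test_same_seed_identical_sequences(self):
        f1, f2 = self._family(), self._family()
        evolve_sequences(f1, 80, 1.0, _rng(9))
        evolve_sequences(f2, 80, 1.0, _rng(9))
        assert f1.sequences == f2.sequences

    def test_divergence_matches_closed_form(self):
        # two leaves at total path distance T differ per site with
        # probability (1 - e^(-rT)) * 19/20; check within 3 sigma at n=1000
        tree, root = simulate_taxonomy(2, 2, _rng(21))
        params = SimParams(n_species=2, duplication_rate=0.0, loss_rate=0.0)
        fam = simulate_family(root, params, _rng(21))
        rate = 1.0
        evolve_sequences(fam, 1000, rate, _rng(3))
        a, b = fam.leaves
        T = a.blen + b.blen
        expect = (1 - np.exp(-rate * T)) * 19 / 20
        diff = sum(
            x != y for x, y in zip(fam.sequences[a.name], fam.sequences[b.name])
        ) / 1000
        sigma = np.sqrt(expect * (1 - expect) / 1000)
        assert abs(diff - expect) <= 3 * sigma


class TestFunctions:
    def _family(self, seed=13, dup=0.8):
        tree, root = simulate_taxonomy(6, 5, _rng(seed))
        params = SimParams(n_species=6, duplication_rate=dup, loss_rate=0.0)
        return simulate_family(root, params, _rng(seed))

    def test_p_zero_everyone_has_base_terms(self):
        fam = self._family()
        base = frozenset({"GO:a", "GO:b", "GO:c", "GO:d"})
        assign_functions(fam, base, 0.0, _rng(1))
        assert all(t == base for t in fam.terms.values())

    def test_p_one_swaps_exactly_half(self):
        # find a family with at least one duplication
        fam = self._family(seed=17)
        has_dup = any(n.label == "D" for n in fam.root.walk())
        assert has_dup
        base = frozenset({"GO:a", "GO:b", "GO:c", "GO:d"})
        assign_functions(fam, base, 1.0, _rng(2), swap_fraction=0.5)
        for terms in fam.terms.values():
            assert len(terms) == 4  # swaps replace, never grow or shrink

    def test_orthologs_share_more_terms_than_paralogs(self):
        # averaged over families: Jaccard(true ortholog pairs) must exceed
        # Jaccard(paralog pairs) when divergence hits duplications only
        o_scores, p_scores = [], []
        rng = _rng(99)
        tree, root = simulate_taxonomy(8, 6, rng)
        params = SimParams(n_species=8, duplication_rate=0.6, loss_rate=0.0)
        for _ in range(25):
            fam = simulate_family(root, params, rng)
            base = frozenset(f"GO:{i}" for i in range(6))
            assign_functions(fam, base, 0.8, rng)
            for x in fam.leaves:
                for y in fam.leaves:
                    if x.name >= y.name or x.species == y.species:
                        continue
                    a, b = fam.terms[x.name], fam.terms[y.name]
                    j = len(a & b) / len(a | b)
                    (o_scores if fam.is_true_pair(x.name, y.name) else p_scores
                     ).append(j)
        assert p_scores, "simulation produced no paralog pairs"
        assert np.mean(o_scores) > np.mean(p_scores)


class TestBenchmark:
    def test_database_validates_and_key_is_consistent(self):
        params = SimParams(n_species=8, n_families=8, root_protein_length=80,
                           random_seed=31)
        bench = emit_benchmark(params)
        validate(bench.db)
        for qid, _ in bench.queries:
            assert qid not in bench.db.proteins
            assert bench.key.true_orthologs[qid] <= set(bench.db.proteins)

    def test_no_loss_every_query_has_an_ortholog(self):
        params = SimParams(n_species=6, n_families=6, loss_rate=0.0,
                           root_protein_length=60, random_seed=8)
        bench = emit_benchmark(params)
        assert bench.queries
        for qid, _ in bench.queries:
            assert bench.key.true_orthologs[qid]

    def test_byte_identical_under_same_seed(self, tmp_path):
        from ogmapper.refdb import save_database

        params = SimParams(n_species=6, n_families=4, root_protein_length=60,
                           random_seed=12)
        b1 = emit_benchmark(params)
        b2 = emit_benchmark(params)
        save_database(b1.db, tmp_path / "d1")
        save_database(b2.db, tmp_path / "d2")
        for f in sorted(p.name for p in (tmp_path / "d1").iterdir()):
            assert (tmp_path / "d1" / f).read_bytes() == (
                tmp_path / "d2" / f
            ).read_bytes()
        assert b1.queries == b2.queries

    def test_negative_control_scores_below_ga(self):
        params = SimParams(n_species=6, n_families=6, domain_prob=1.0,
                           root_protein_length=80, random_seed=5)
        bench = emit_benchmark(params)
        from ogmapper.domains import pssm_score

        rng = _rng(1)
        made = 0
        for qid, _ in bench.queries:
            control = simdata.make_negative_control(bench, qid, rng)
            if control is None:
                continue
            made += 1
            fam = bench.families[bench.key.family_of[qid]]
            score, _ = pssm_score(control[1], fam.domain.model)
            assert score < fam.domain.model.ga_threshold
        assert made > 0
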