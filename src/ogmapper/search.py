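"""Seed-and-extend local protein search against the reference proteins.

Candidate targets are gathered through a k-mer index and aligned with an
affine-gap Smith-Waterman kernel; sensitivity presets trade k-mer size for
speed, and the iterative preset re-searches unmatched queries at higher
sensitivity.  Ranking is total and documented (evalue asc, bit score desc,
target_id asc) so runs are byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .geneprediction import six_frame
from .refdb import ReferenceDatabase

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "SearchParams",
    "SearchResult",
    "build_kmer_index",
    "smith_waterman",
    "search",
    "blastx_search",
    "best_seed_ortholog",
    "default_scheme",
]

# 20 residues + X (unknown) + * (stop, only seen in translated frames)
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX*"
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

# default effective search-space length used for E-values.  A fixed constant
# (rather than the literal residue count of the loaded database) keeps hit
# statistics — and therefore written reports — invariant under
# taxon-restricted subsetting of the reference bundle.
DEFAULT_EFFECTIVE_DB_LENGTH = 1e7

DEFAULT_EVALUE_CUTOFF = 1e-3
DEFAULT_MIN_BIT_SCORE = 60.0


def _blosum62_matrix() -> np.ndarray:
    src = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    mat = np.full((n, n), -4, dtype=np.int32)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a == "*" or b == "*":
                mat[i, j] = -4
            else:
                mat[i, j] = int(src[a][b])
    return mat


@dataclass
class ScoringScheme:
    """Substitution scores, affine gap penalties and Karlin-Altschul
    calibration constants (gapped BLOSUM62/11/1 defaults)."""

    matrix: np.ndarray
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    effective_db_length: float = DEFAULT_EFFECTIVE_DB_LENGTH

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")

    def bit_score(self, raw_score: int) -> float:
        return (self.karlin_lambda * raw_score - math.log(self.karlin_k)) / math.log(2)

    def evalue(self, raw_score: int, query_length: int) -> float:
        return (
            self.karlin_k
            * query_length
            * self.effective_db_length
            * math.exp(-self.karlin_lambda * raw_score)
        )


_DEFAULT_SCHEME: ScoringScheme | None = None


def default_scheme() -> ScoringScheme:
    global _DEFAULT_SCHEME
    if _DEFAULT_SCHEME is None:
        _DEFAULT_SCHEME = ScoringScheme(matrix=_blosum62_matrix())
    return _DEFAULT_SCHEME


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    target_id: str
    raw_score: int
    bit_score: float
    evalue: float
    query_start: int  # 1-based inclusive
    query_end: int
    target_start: int
    target_end: int
    aligned_pairs: tuple[tuple[int, int], ...]  # matched columns only
    percent_identity: float
    gap_columns: int = 0
    frame: int = 0  # set by blastx-like searches; 0 == protein space

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_pairs) + self.gap_columns

    def sort_key(self):
        return (self.evalue, -self.bit_score, self.target_id)


@dataclass(frozen=True)
class SearchParams:
    """Sensitivity preset plus filtering cutoffs."""

    preset: str = "fast"  # fast | sensitive | iterative
    kmer_size: int = 5
    min_shared_kmers: int = 2
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
    min_bit_score: float = DEFAULT_MIN_BIT_SCORE

    def __post_init__(self):
        if self.kmer_size < 2:
            raise ValueError("kmer_size must be >= 2")
        if self.preset not in ("fast", "sensitive", "iterative"):
            raise ValueError(f"unknown preset {self.preset!r}")

    @classmethod
    def from_preset(cls, preset: str, **overrides) -> "SearchParams":
        base = {
            "fast": dict(kmer_size=5, min_shared_kmers=2),
            "sensitive": dict(kmer_size=3, min_shared_kmers=1),
            "iterative": dict(kmer_size=5, min_shared_kmers=2),
        }
        if preset not in base:
            raise ValueError(f"unknown preset {preset!r}")
        kw = dict(preset=preset, **base[preset])
        kw.update(overrides)
        return cls(**kw)

    def sensitive_variant(self) -> "SearchParams":
        return replace(self, preset="sensitive", kmer_size=3, min_shared_kmers=1)


@dataclass
class SearchResult:
    hits: dict[str, list[AlignmentHit]]
    unmatched: list[str]


# ---------------------------------------------------------------------------
# Smith-Waterman kernel


@njit(cache=True)
def _sw_fill(q, t, sub, gap_open, gap_extend):  # pragma: no cover - numba
    n = q.shape[0]
    m = t.shape[0]
    NEG = -(10**9)
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG, np.int32)
    F = np.full((n + 1, m + 1), NEG, np.int32)
    ptr_h = np.zeros((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    ptr_e = np.zeros((n + 1, m + 1), np.uint8)  # 1 opened from H
    ptr_f = np.zeros((n + 1, m + 1), np.uint8)
    best = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptr_e[i, j] = 1
            else:
                E[i, j] = e_ext
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptr_f[i, j] = 1
            else:
                F[i, j] = f_ext
            h = H[i - 1, j - 1] + sub[qi, t[j - 1]]
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
    return H, ptr_h, ptr_e, ptr_f, best


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} outside alphabet") from None


def _traceback(ptr_h, ptr_e, ptr_f, i, j):
    """Walk pointers from cell (i, j); returns matched columns and gap count."""
    pairs = []
    gaps = 0
    state = 0  # 0 = H, 1 = E (consumes target), 2 = F (consumes query)
    while True:
        if state == 0:
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                pairs.append((i, j))
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            opened = ptr_e[i, j]
            j -= 1
            gaps += 1
            state = 0 if opened else 1
        else:
            opened = ptr_f[i, j]
            i -= 1
            gaps += 1
            state = 0 if opened else 2
    pairs.reverse()
    return pairs, gaps


def smith_waterman(
    q: str,
    t: str,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentHit:
    """Optimal affine-gap local alignment of ``q`` against ``t``.

    Ties among maximal cells are broken by smallest query_start, then
    smallest target_start of the traced alignment.
    """
    if not q or not t:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or default_scheme()
    qa, ta = _encode(q), _encode(t)
    H, ph, pe, pf, best = _sw_fill(
        qa, ta, scheme.matrix, np.int32(scheme.gap_open), np.int32(scheme.gap_extend)
    )
    best = int(best)
    if best <= 0:
        return AlignmentHit(
            query_id, target_id, 0, scheme.bit_score(0),
            scheme.evalue(0, len(q)), 0, 0, 0, 0, (), 0.0,
        )
    cells = np.argwhere(H == best)
    chosen = None
    for i, j in cells:
        pairs, gaps = _traceback(ph, pe, pf, int(i), int(j))
        key = (pairs[0][0], pairs[0][1])
        if chosen is None or key < chosen[0]:
            chosen = (key, pairs, gaps, int(i), int(j))
    _, pairs, gaps, end_i, end_j = chosen
    identities = sum(1 for qi, tj in pairs if q[qi - 1] == t[tj - 1])
    ncols = len(pairs) + gaps
    return AlignmentHit(
        query_id=query_id,
        target_id=target_id,
        raw_score=best,
        bit_score=scheme.bit_score(best),
        evalue=scheme.evalue(best, len(q)),
        query_start=pairs[0][0],
        query_end=end_i,
        target_start=pairs[0][1],
        target_end=end_j,
        aligned_pairs=tuple(pairs),
        percent_identity=100.0 * identities / ncols if ncols else 0.0,
        gap_columns=gaps,
    )


# ---------------------------------------------------------------------------
# k-mer candidate filter


def build_kmer_index(db: ReferenceDatabase, k: int) -> dict[str, list[tuple[str, int]]]:
    """Map every length-k substring of every reference protein to its
    (protein_id, 0-based offset) postings.  Cached on the database object."""
    if k < 2:
        raise ValueError("k must be >= 2")
    cached = db._kmer_indexes.get(k)
    if cached is not None:
        return cached
    index: dict[str, list[tuple[str, int]]] = {}
    for pid in sorted(db.proteins):
        seq = db.proteins[pid].sequence
        for off in range(len(seq) - k + 1):
            index.setdefault(seq[off : off + k], []).append((pid, off))
    db._kmer_indexes[k] = index
    return index


def _candidates(query: str, index, k: int, min_shared: int) -> list[str]:
    kmers = {query[i : i + k] for i in range(len(query) - k + 1)}
    counts: dict[str, int] = {}
    for kmer in kmers:
        if "X" in kmer or "*" in kmer:
            continue
        postings = index.get(kmer)
        if not postings:
            continue
        for pid in {p for p, _ in postings}:
            counts[pid] = counts.get(pid, 0) + 1
    return sorted(pid for pid, c in counts.items() if c >= min_shared)


# ---------------------------------------------------------------------------
# search drivers


def _search_one(query_id, seq, db, index, params, scheme) -> list[AlignmentHit]:
    hits = []
    for pid in _candidates(seq, index, params.kmer_size, params.min_shared_kmers):
        hit = smith_waterman(
            seq, db.proteins[pid].sequence, scheme, query_id=query_id, target_id=pid
        )
        if hit.evalue <= params.evalue_cutoff and hit.bit_score >= params.min_bit_score:
            hits.append(hit)
    hits.sort(key=AlignmentHit.sort_key)
    return hits


def search(
    queries,
    db: ReferenceDatabase,
    params: SearchParams | None = None,
    scheme: ScoringScheme | None = None,
) -> SearchResult:
    """Rank reference hits per query.

    ``queries`` is an iterable of (query_id, protein_sequence).  Under the
    iterative preset the fast pass runs first and only unmatched queries are
    re-searched with the sensitive preset.
    """
    params = params or SearchParams()
    scheme = scheme or default_scheme()
    queries = list(queries)
    if params.preset == "iterative":
        fast = replace(params, preset="fast")
        first = search(queries, db, fast, scheme)
        remaining = [(qid, s) for qid, s in queries if qid in set(first.unmatched)]
        second = search(remaining, db, params.sensitive_variant(), scheme)
        hits = dict(first.hits)
        hits.update(second.hits)
        ordered = {qid: hits[qid] for qid, _ in queries if qid in hits}
        return SearchResult(hits=ordered, unmatched=list(second.unmatched))
    index = build_kmer_index(db, params.kmer_size)
    hits: dict[str, list[AlignmentHit]] = {}
    unmatched: list[str] = []
    for qid, seq in queries:
        found = _search_one(qid, seq, db, index, params, scheme) if seq else []
        if found:
            hits[qid] = found
        else:
            unmatched.append(qid)
    return SearchResult(hits=hits, unmatched=unmatched)


def blastx_search(
    nuc_queries,
    db: ReferenceDatabase,
    params: SearchParams | None = None,
    scheme: ScoringScheme | None = None,
    table: int = 11,
) -> SearchResult:
    """Translate nucleotide queries in six frames, search in protein space,
    and report hits with nucleotide-space query coordinates (minus-strand
    frames have query_start > query_end, the conventional encoding)."""
    params = params or SearchParams()
    scheme = scheme or default_scheme()
    hits: dict[str, list[AlignmentHit]] = {}
    unmatched: list[str] = []
    for qid, nuc in nuc_queries:
        if len(nuc) < 3 * params.kmer_size:
            unmatched.append(qid)
            continue
        per_target: dict[str, AlignmentHit] = {}
        for frame in six_frame(nuc, table):
            if len(frame.protein) < params.kmer_size:
                continue
            sub = search([(qid, frame.protein)], db, params, scheme)
            for hit in sub.hits.get(qid, []):
                mapped = _to_nucleotide_coords(hit, frame)
                prev = per_target.get(hit.target_id)
                if prev is None or mapped.sort_key() < prev.sort_key():
                    per_target[hit.target_id] = mapped
        ranked = sorted(per_target.values(), key=AlignmentHit.sort_key)
        if ranked:
            hits[qid] = ranked
        else:
            unmatched.append(qid)
    return SearchResult(hits=hits, unmatched=unmatched)


def _to_nucleotide_coords(hit: AlignmentHit, frame) -> AlignmentHit:
    first = frame.nt_span(hit.query_start)
    last = frame.nt_span(hit.query_end)
    if frame.frame > 0:
        q_start, q_end = first[0], last[1]
    else:
        q_start, q_end = first[1], last[0]  # decreasing == minus strand
    return replace(hit, query_start=q_start, query_end=q_end, frame=frame.frame)


def best_seed_ortholog(
    hits: list[AlignmentHit],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    min_bit_score: float = DEFAULT_MIN_BIT_SCORE,
) -> AlignmentHit | None:
    """First hit (per the search ranking) passing both cutoffs, else None."""
    for hit in hits:
        if hit.evalue <= evalue_cutoff and hit.bit_score >= min_bit_score:
            return hit
    return None


def hit_table_row(hit: AlignmentHit) -> list[str]:
    """Conventional 12-column tabular alignment row."""
    mismatches = sum(
        1 for _ in hit.aligned_pairs
    ) - int(round(hit.percent_identity * hit.alignment_length / 100.0))
    return [
        hit.query_id,
        hit.target_id,
        f"{hit.percent_identity:.1f}",
        str(hit.alignment_length),
        str(mismatches),
        str(hit.gap_columns),
        str(hit.query_start),
        str(hit.query_end),
        str(hit.target_start),
        str(hit.target_end),
        f"{hit.evalue:.2e}",
        f"{hit.bit_score:.1f}",
    ]
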