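"""Protein-domain annotation in three modes: transfer, realign-refine and
de novo scanning, with gathering (GA) thresholds and clan disambiguation.

Models are gapless position-specific scoring matrices.  Transfer maps a
reference protein's domain intervals onto the query through the seed
alignment; refinement rescores the transferred window and keeps the hit
only if it clears the model's GA threshold (so refinement can drop or
adjust hits but never add them); de novo scanning evaluates every model
over the full query.  Overlapping hits of the same clan compete, best
score wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .refdb import AA_ALPHABET, DomainModel, ReferenceDatabase
from .search import AlignmentHit

__all__ = [
    "DomainHit",
    "map_coordinates",
    "transfer_domains",
    "pssm_score",
    "realign_refine",
    "denovo_scan",
    "clan_disambiguate",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_UNKNOWN_SCORE = -1  # X or other non-standard residues

DEFAULT_PAD = 10
DEFAULT_OVERLAP_FRAC = 0.5


@dataclass(frozen=True)
class DomainHit:
    query_id: str
    model_id: str
    clan_id: str
    start: int  # 1-based inclusive on the query
    end: int
    score: float
    mode: str  # transferred | refined | denovo


def map_coordinates(
    hit: AlignmentHit, target_interval: tuple[int, int]
) -> tuple[int, int] | None:
    """Map a target-coordinate interval onto the query via aligned columns.

    Endpoints falling in gaps snap inward to the nearest aligned column;
    returns None when the interval lies wholly outside the aligned region.
    """
    t_start, t_end = target_interval
    q_lo = None
    q_hi = None
    for q, t in hit.aligned_pairs:
        if t_start <= t <= t_end:
            if q_lo is None:
                q_lo = q
            q_hi = q
    if q_lo is None:
        return None
    return q_lo, q_hi


def transfer_domains(
    db: ReferenceDatabase, query_id: str, seed_hit: AlignmentHit
) -> list[DomainHit]:
    """Carry the seed protein's domain annotations over to the query."""
    out: list[DomainHit] = []
    for ann in db.domains_of(seed_hit.target_id):
        mapped = map_coordinates(seed_hit, (ann.start, ann.end))
        if mapped is None:
            continue
        clan = db.domain_models[ann.model_id].clan_id if ann.model_id in db.domain_models else ""
        out.append(
            DomainHit(query_id, ann.model_id, clan, mapped[0], mapped[1],
                      ann.score, "transferred")
        )
    out.sort(key=lambda h: (h.start, h.model_id))
    return out


def _encode_window(window: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, -1) for c in window], dtype=np.int64)


def pssm_score(window: str, model: DomainModel) -> tuple[int, tuple[int, int]]:
    """Best gapless placement of the model inside ``window``.

    The model may overhang either window edge (prefix/suffix truncation);
    the score sums per-position scores over the in-window overlap.  Returns
    (best score, 1-based interval of the overlap); ties pick the smallest
    start.
    """
    if not window:
        raise ValueError("window must be non-empty")
    w = _encode_window(window)
    n = len(w)
    L = model.length
    valid = w >= 0
    S = model.pssm[:, np.where(valid, w, 0)].copy()  # (L, n)
    S[:, ~valid] = _UNKNOWN_SCORE
    best_score = None
    best_iv = None
    # model row r sits at window index off + r; trace along diagonal `off`
    for off in range(-(L - 1), n):
        s = int(np.trace(S, offset=off))
        lo = max(0, off)
        hi = min(n, off + L)
        if lo >= hi:
            continue
        if best_score is None or s > best_score:
            best_score = s
            best_iv = (lo + 1, hi)
    return best_score, best_iv


def realign_refine(
    query_seq: str,
    transferred: DomainHit,
    db: ReferenceDatabase,
    pad: int = DEFAULT_PAD,
) -> DomainHit | None:
    """Rescore a transferred hit in a padded window; keep iff >= GA."""
    model = db.domain_models.get(transferred.model_id)
    if model is None:
        raise ValueError(f"model {transferred.model_id} not in database")
    w_start = max(1, transferred.start - pad)
    w_end = min(len(query_seq), transferred.end + pad)
    window = query_seq[w_start - 1 : w_end]
    if not window:
        return None
    score, (lo, hi) = pssm_score(window, model)
    if score < model.ga_threshold:
        return None
    return DomainHit(
        transferred.query_id,
        transferred.model_id,
        model.clan_id,
        w_start + lo - 1,
        w_start + hi - 1,
        float(score),
        "refined",
    )


def denovo_scan(
    query_seq: str,
    db: ReferenceDatabase,
    query_id: str = "query",
    overlap_frac: float = DEFAULT_OVERLAP_FRAC,
) -> list[DomainHit]:
    """Scan every model over the full sequence; GA gate then clan competition."""
    hits: list[DomainHit] = []
    if not query_seq:
        return hits
    for mid in sorted(db.domain_models):
        model = db.domain_models[mid]
        score, iv = pssm_score(query_seq, model)
        if score >= model.ga_threshold:
            hits.append(
                DomainHit(query_id, mid, model.clan_id, iv[0], iv[1],
                          float(score), "denovo")
            )
    hits = clan_disambiguate(hits, overlap_frac)
    hits.sort(key=lambda h: (h.start, h.model_id))
    return hits


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def clan_disambiguate(
    hits: list[DomainHit], overlap_frac: float = DEFAULT_OVERLAP_FRAC
) -> list[DomainHit]:
    """Greedy same-clan competition: hits are processed by descending score
    (ties: smaller start, then model_id) and dropped when they overlap an
    already-kept hit of the same non-empty clan by more than ``overlap_frac``
    of the shorter interval.  Clan-less hits never compete.  Idempotent."""
    ordered = sorted(hits, key=lambda h: (-h.score, h.start, h.model_id))
    kept: list[DomainHit] = []
    for hit in ordered:
        if hit.clan_id:
            shorter = lambda other: min(
                hit.end - hit.start + 1, other.end - other.start + 1
            )
            clash = any(
                k.clan_id == hit.clan_id and _overlap(hit, k) > overlap_frac * shorter(k)
                for k in kept
            )
            if clash:
                continue
        kept.append(hit)
    kept.sort(key=lambda h: (h.start, h.model_id))
    return kept
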