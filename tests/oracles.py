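"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written as plain brute force (full DP,
exhaustive enumeration, naive scans) and must stay independent of the code
paths it validates.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

NEG = float("-inf")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> int:
    return int(_BLOSUM62[a][b])


def sw_score_oracle(q, t, score_fn=blosum62, gap_open=11, gap_extend=1):
    """Full O(nm) affine-gap local-alignment DP; returns the best score.

    A gap of length L costs gap_open + L * gap_extend.
    """
    m = len(t)
    h_prev = [0] * (m + 1)
    f_prev = [NEG] * (m + 1)
    best = 0
    for i in range(1, len(q) + 1):
        h_row = [0] * (m + 1)
        f_row = [NEG] * (m + 1)
        e = NEG
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = max(h_row[j - 1] - gap_open - gap_extend, e - gap_extend)
            f = max(h_prev[j] - gap_open - gap_extend, f_prev[j] - gap_extend)
            f_row[j] = f
            h = h_prev[j - 1] + score_fn(qi, t[j - 1])
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_row[j] = h
            if h > best:
                best = h
        h_prev = h_row
        f_prev = f_row
    return int(best)


def rescore_traceback(q, t, pairs, gap_columns, score_fn=blosum62,
                      gap_open=11, gap_extend=1):
    """Re-derive the raw score of a traced alignment from its columns."""
    score = sum(score_fn(q[qi - 1], t[tj - 1]) for qi, tj in pairs)
    # reconstruct individual gap runs from coordinate jumps
    gaps = []
    for (q0, t0), (q1, t1) in zip(pairs, pairs[1:]):
        dq, dt = q1 - q0 - 1, t1 - t0 - 1
        if dq:
            gaps.append(dq)
        if dt:
            gaps.append(dt)
    assert sum(gaps) == gap_columns
    score -= sum(gap_open + g * gap_extend for g in gaps)
    return score


# ---------------------------------------------------------------------------
# taxonomy


def lineage_oracle(parents: dict[int, int], t: int) -> list[int]:
    path = [t]
    while parents[path[-1]] != path[-1]:
        path.append(parents[path[-1]])
    return list(reversed(path))


def lca_oracle(parents: dict[int, int], taxa) -> int:
    """Intersect lineages in root-first order; the last common element."""
    taxa = list(taxa)
    common = lineage_oracle(parents, taxa[0])
    for t in taxa[1:]:
        other = set(lineage_oracle(parents, t))
        common = [x for x in common if x in other]
    return common[-1]


# ---------------------------------------------------------------------------
# ORF enumeration


_COMP = str.maketrans("ACGTN", "TGCAN")


def orf_oracle(seq, contig_id="contig", table=11, min_aa=30,
               starts=("ATG", "GTG", "TTG")):
    """Enumerate every (frame, stop codon) pair in all six frames and emit
    the maximal ORF for each; returns a set of
    (contig_id, start, end, strand, protein) tuples."""
    ct = CodonTable.unambiguous_dna_by_id[table]
    stops = set(ct.stop_codons)
    seq = seq.upper()
    out = set()
    for strand in "+-":
        s = seq if strand == "+" else seq.translate(_COMP)[::-1]
        for off in range(3):
            codons = [
                (pos, s[pos : pos + 3]) for pos in range(off, len(s) - 2, 3)
            ]
            stop_positions = [
                pos for pos, c in codons if "N" not in c and c in stops
            ]
            region_start = off
            for stop in stop_positions:
                first_start = None
                for pos in range(region_start, stop, 3):
                    c = s[pos : pos + 3]
                    if "N" not in c and c in starts:
                        first_start = pos
                        break
                if first_start is not None and (stop - first_start) // 3 >= min_aa:
                    prot = ["M"]
                    for pos in range(first_start + 3, stop, 3):
                        c = s[pos : pos + 3]
                        prot.append("X" if "N" in c else ct.forward_table[c])
                    s_coords = (first_start + 1, stop + 3)
                    if strand == "+":
                        coords = s_coords
                    else:
                        coords = (len(s) - s_coords[1] + 1, len(s) - s_coords[0] + 1)
                    out.add((contig_id, coords[0], coords[1], strand, "".join(prot)))
                region_start = stop + 3
    return out


# ---------------------------------------------------------------------------
# PSSM scanning


def pssm_brute(window, model, alphabet="ACDEFGHIKLMNPQRSTVWY", unknown=-1):
    """Exhaustive offset enumeration of a gapless PSSM over a window."""
    idx = {aa: i for i, aa in enumerate(alphabet)}
    L = model.length
    n = len(window)
    best = None
    for off in range(-(L - 1), n):
        lo, hi = max(0, off), min(n, off + L)
        if lo >= hi:
            continue
        score = 0
        for w in range(lo, hi):
            r = w - off
            ai = idx.get(window[w])
            score += int(model.pssm[r, ai]) if ai is not None else unknown
        if best is None or score > best[0]:
            best = (score, (lo + 1, hi))
    return best


# ---------------------------------------------------------------------------
# gene-tree orthology


def gene_tree_orthologs_oracle(family, seed_name):
    """Brute force over all leaf pairs: orthologs of the seed are the leaves
    whose gene-tree LCA with it is a speciation node, found by explicit
    ancestor-set walks."""
    leaves = {lf.name: lf for lf in family.leaves}
    seed = leaves[seed_name]
    ancestors = []
    node = seed
    while node is not None:
        ancestors.append(node)
        node = node.parent
    index = {id(n): i for i, n in enumerate(ancestors)}
    out = set()
    for name, leaf in leaves.items():
        if name == seed_name:
            continue
        node = leaf
        while id(node) not in index:
            node = node.parent
        if node.label == "S":
            out.add(name)
    return out


def best_hit_oracle(hits):
    """Re-sort the full hit list by the documented total order."""
    return min(hits, key=lambda h: (h.evalue, -h.bit_score, h.target_id))
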