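"""Prokaryotic ORF prediction from contigs and six-frame translation.

This is a deterministic stand-in for a trained gene caller: per reading
frame, each stop codon yields at most one ORF, running from the
upstream-most in-frame start codon (after the previous stop) through the
stop codon itself.  Coordinates are always 1-based inclusive on the
forward strand; start codons are normalized to M in the protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio.Data import CodonTable

__all__ = ["Orf", "Frame", "find_orfs", "translate", "six_frame", "reverse_complement"]

_NUC = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# curated start-codon sets; anything else falls back to the table's own list
_START_CODONS = {1: ("ATG",), 11: ("ATG", "GTG", "TTG")}

DEFAULT_MIN_AA = 30


@dataclass(frozen=True)
class Orf:
    """A predicted gene: forward-strand coordinates include the stop codon."""

    contig_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    protein: str
    translation_table: int


@dataclass(frozen=True)
class Frame:
    """One of six translation frames with a residue->nucleotide mapping."""

    frame: int  # +1, +2, +3, -1, -2, -3
    protein: str
    seq_length: int

    def nt_span(self, residue: int) -> tuple[int, int]:
        """Forward-strand 1-based codon span of 1-based ``residue``."""
        if not 1 <= residue <= len(self.protein):
            raise IndexError(f"residue {residue} outside frame of {len(self.protein)}")
        off = abs(self.frame) - 1
        if self.frame > 0:
            start = off + 3 * (residue - 1) + 1
            return start, start + 2
        r = off + 3 * (residue - 1) + 1  # codon start on the reverse complement
        return self.seq_length - r - 1, self.seq_length - r + 1


def _check_nucleotides(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _NUC
    if bad:
        raise ValueError(f"non-nucleotide characters in input: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    return _check_nucleotides(seq).translate(_COMPLEMENT)[::-1]


def _codon_table(table: int) -> CodonTable.CodonTable:
    try:
        return CodonTable.unambiguous_dna_by_id[table]
    except KeyError:
        raise ValueError(f"unknown translation table {table}") from None


def _translate_codon(codon: str, table: CodonTable.CodonTable) -> str:
    if "N" in codon:
        return "X"
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def translate(nuc: str, table: int = 11) -> str:
    """Translate in frame +1; stops become '*', N-containing codons 'X'."""
    seq = _check_nucleotides(nuc)
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    ct = _codon_table(table)
    return "".join(
        _translate_codon(seq[i : i + 3], ct) for i in range(0, len(seq) - 2, 3)
    )


def six_frame(nuc: str, table: int = 11) -> list[Frame]:
    """Frames +1, +2, +3, -1, -2, -3 with coordinate mappings."""
    seq = _check_nucleotides(nuc)
    rc = seq.translate(_COMPLEMENT)[::-1]
    frames = []
    for f in (1, 2, 3):
        sub = seq[f - 1 :]
        frames.append(Frame(f, translate(sub, table) if len(sub) >= 3 else "", len(seq)))
    for f in (1, 2, 3):
        sub = rc[f - 1 :]
        frames.append(Frame(-f, translate(sub, table) if len(sub) >= 3 else "", len(seq)))
    return frames


def find_orfs(
    contig: str,
    contig_id: str = "contig",
    table: int = 11,
    min_aa: int = DEFAULT_MIN_AA,
) -> list[Orf]:
    """All complete ORFs in the six frames of ``contig``.

    Per (frame, stop codon) at most one ORF is emitted; ORFs with fewer than
    ``min_aa`` residues are dropped.  Codons containing N never act as start
    or stop codons and translate to X.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = _check_nucleotides(contig)
    ct = _codon_table(table)
    starts = frozenset(_START_CODONS.get(table, tuple(ct.start_codons)))
    stops = frozenset(ct.stop_codons)
    length = len(seq)
    orfs: list[Orf] = []
    for strand, s in (("+", seq), ("-", seq.translate(_COMPLEMENT)[::-1])):
        for off in range(3):
            start_pos: int | None = None  # 0-based codon start on s
            for pos in range(off, length - 2, 3):
                codon = s[pos : pos + 3]
                if "N" in codon:
                    continue
                if codon in stops:
                    if start_pos is not None:
                        n_res = (pos - start_pos) // 3
                        if n_res >= min_aa:
                            prot = "M" + "".join(
                                _translate_codon(s[i : i + 3], ct)
                                for i in range(start_pos + 3, pos, 3)
                            )
                            s_start, s_end = start_pos + 1, pos + 3
                            if strand == "+":
                                fwd = (s_start, s_end)
                            else:
                                fwd = (length - s_end + 1, length - s_start + 1)
                            orfs.append(
                                Orf(contig_id, fwd[0], fwd[1], strand, prot, table)
                            )
                    start_pos = None
                elif start_pos is None and codon in starts:
                    start_pos = pos
    orfs.sort(key=lambda o: (o.contig_id, o.start, o.strand))
    return orfs


def find_orfs_many(
    contigs: Iterable[tuple[str, str]],
    table: int = 11,
    min_aa: int = DEFAULT_MIN_AA,
) -> list[Orf]:
    """Run :func:`find_orfs` over (contig_id, sequence) pairs."""
    out: list[Orf] = []
    for contig_id, seq in contigs:
        out.extend(find_orfs(seq, contig_id=contig_id, table=table, min_aa=min_aa))
    return out


def orf_protein_id(orf: Orf, index: int) -> str:
    """Stable id for a predicted protein: ``<contig>_<n>`` (1-based)."""
    return f"{orf.contig_id}_{index}"
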