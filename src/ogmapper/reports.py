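"""Output writers and parsers: annotation/ortholog TSVs, GFF3 handling and
functional decoration of arbitrary GFF files.

All writers are deterministic; '#'-prefixed run-metadata headers can be
suppressed for byte-reproducible comparisons.  Decoration appends ``em_*``
attributes (a stable, documented vocabulary) and never touches coordinates.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

from . import __version__
from .annotation import TERM_SOURCES, FunctionalAnnotation
from .errors import FormatError
from .orthology import OrthologSet

ANNOTATION_COLUMNS = (
    "query",
    "seed_ortholog",
    "evalue",
    "score",
    "eggNOG_OGs",
    "max_annot_lvl",
    "COG_category",
    "Description",
    "Preferred_name",
    "GOs",
    "EC",
    "KEGG_ko",
    "KEGG_Pathway",
    "KEGG_Module",
    "BiGG_Reaction",
    "CAZy",
    "PFAMs",
)

# annotation-TSV column -> internal term source
_COLUMN_SOURCES = {
    "GOs": "GO",
    "EC": "EC",
    "KEGG_ko": "KEGG_ko",
    "KEGG_Pathway": "KEGG_pathway",
    "KEGG_Module": "KEGG_module",
    "BiGG_Reaction": "BiGG",
    "CAZy": "CAZy",
}

ORTHOLOG_COLUMNS = (
    "query",
    "seed_ortholog",
    "scope_og",
    "level_name",
    "ortholog_protein",
    "ortholog_species",
    "type",
)


def _dash(value: str) -> str:
    return value if value else "-"


def _undash(value: str) -> str:
    return "" if value == "-" else value


def _join_terms(terms) -> str:
    return ",".join(sorted(terms)) if terms else "-"


def annotation_row(ann: FunctionalAnnotation) -> list[str]:
    # full-precision floats so write -> read is an exact inverse
    row = [
        ann.query_id,
        ann.seed_ortholog,
        repr(ann.seed_evalue),
        repr(ann.seed_score),
        _dash(ann.og_string),
        _dash(ann.max_annot_level),
        _dash(ann.cog_category),
        _dash(ann.description),
        _dash(ann.preferred_name),
    ]
    for col in ANNOTATION_COLUMNS[9:16]:
        row.append(_join_terms(ann.terms_for(_COLUMN_SOURCES[col])))
    row.append(_join_terms(ann.pfams))
    return row


def write_annotations(
    records: list[FunctionalAnnotation],
    path,
    metadata: bool = True,
    params_line: str = "",
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if metadata:
            fh.write(f"## ogmapper v{__version__}\n")
            fh.write(f"## time: {time.strftime('%Y-%m-%d %H:%M:%S')}\n")
            if params_line:
                fh.write(f"## params: {params_line}\n")
        fh.write("#" + "\t".join(ANNOTATION_COLUMNS) + "\n")
        for ann in records:
            fh.write("\t".join(annotation_row(ann)) + "\n")


def read_annotations(path) -> list[FunctionalAnnotation]:
    """Inverse of :func:`write_annotations` (metadata lines are skipped)."""
    records = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#"):
                cols = tuple(line[1:].split("\t"))
                if cols != ANNOTATION_COLUMNS:
                    raise FormatError(f"{path}:{lineno}: unexpected columns {cols}")
                header_seen = True
                continue
            if not header_seen:
                raise FormatError(f"{path}:{lineno}: data before header")
            f = line.split("\t")
            if len(f) != len(ANNOTATION_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong column count")
            terms = {}
            for i, col in enumerate(ANNOTATION_COLUMNS[9:16], start=9):
                if f[i] != "-":
                    terms[_COLUMN_SOURCES[col]] = frozenset(f[i].split(","))
            pfams = tuple(f[16].split(",")) if f[16] != "-" else ()
            records.append(
                FunctionalAnnotation(
                    query_id=f[0],
                    seed_ortholog=f[1],
                    seed_evalue=float(f[2]),
                    seed_score=float(f[3]),
                    og_string=_undash(f[4]),
                    max_annot_level=_undash(f[5]),
                    cog_category=_undash(f[6]),
                    description=_undash(f[7]),
                    preferred_name=_undash(f[8]),
                    terms=terms,
                    pfams=pfams,
                )
            )
    return records


def write_orthologs(sets: list[OrthologSet], db, path, metadata: bool = True) -> None:
    """One row per (query, ortholog) with species and pair type."""
    with open(path, "w", encoding="utf-8") as fh:
        if metadata:
            fh.write(f"## ogmapper v{__version__}\n")
        fh.write("#" + "\t".join(ORTHOLOG_COLUMNS) + "\n")
        for oset in sets:
            level_name = db.taxonomy.name_of(oset.scope.level)
            for o in oset.orthologs:
                fh.write(
                    "\t".join(
                        [
                            oset.query_id,
                            oset.scope.seed_protein_id,
                            oset.scope.chosen_og,
                            level_name,
                            o.protein_id,
                            str(db.proteins[o.protein_id].tax_id),
                            o.type,
                        ]
                    )
                    + "\n"
                )


def write_domain_hits(domain_hits: dict, path, metadata: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if metadata:
            fh.write(f"## ogmapper v{__version__}\n")
        fh.write("#query\tmodel\tclan\tstart\tend\tscore\tmode\n")
        for qid in sorted(domain_hits):
            for h in domain_hits[qid]:
                fh.write(
                    f"{qid}\t{h.model_id}\t{h.clan_id or '-'}\t{h.start}\t{h.end}"
                    f"\t{h.score:g}\t{h.mode}\n"
                )


# ---------------------------------------------------------------------------
# GFF3


@dataclass
class GffRecord:
    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: str
    strand: str
    phase: str
    attributes: list[tuple[str, str]]  # decoded values, input order preserved

    def get_attribute(self, key: str) -> str | None:
        for k, v in self.attributes:
            if k == key:
                return v
        return None


_ENCODE = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C"}


def _encode_value(value: str) -> str:
    out = value.replace("%", "%25")
    for raw, enc in _ENCODE.items():
        out = out.replace(raw, enc)
    return out


def _decode_value(value: str) -> str:
    out = value
    for raw, enc in _ENCODE.items():
        out = out.replace(enc, raw)
    return out.replace("%25", "%")


def parse_gff(path) -> tuple[list[str], list[GffRecord], list[str]]:
    """Parse GFF3 into (comment/directive lines, records, trailing FASTA
    lines).  Attribute order is preserved; a ##FASTA section is tolerated."""
    comments: list[str] = []
    records: list[GffRecord] = []
    fasta: list[str] = []
    in_fasta = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if in_fasta:
                fasta.append(line)
                continue
            if line == "##FASTA":
                in_fasta = True
                fasta.append(line)
                continue
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line)
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start > end:
                raise FormatError(f"{path}:{lineno}: start > end")
            attributes: list[tuple[str, str]] = []
            if cols[8] not in (".", ""):
                for chunk in cols[8].split(";"):
                    if not chunk:
                        continue
                    if "=" not in chunk:
                        raise FormatError(f"{path}:{lineno}: malformed attribute {chunk!r}")
                    k, v = chunk.split("=", 1)
                    attributes.append((k, _decode_value(v)))
            records.append(
                GffRecord(cols[0], cols[1], cols[2], start, end,
                          cols[5], cols[6], cols[7], attributes)
            )
    return comments, records, fasta


def _format_record(rec: GffRecord) -> str:
    attrs = (
        ";".join(f"{k}={_encode_value(v)}" for k, v in rec.attributes)
        if rec.attributes
        else "."
    )
    return "\t".join(
        [rec.seqid, rec.source, rec.type, str(rec.start), str(rec.end),
         rec.score, rec.strand, rec.phase, attrs]
    )


def write_gff(path, comments, records, fasta=(), extra_comments=()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        wrote_version = False
        for c in comments:
            fh.write(c + "\n")
            if c.startswith("##gff-version"):
                wrote_version = True
                for ec in extra_comments:
                    fh.write(ec + "\n")
        if not wrote_version:
            for ec in extra_comments:
                fh.write(ec + "\n")
        for rec in records:
            fh.write(_format_record(rec) + "\n")
        for line in fasta:
            fh.write(line + "\n")


# attribute key -> extractor over a FunctionalAnnotation
_EM_FIELDS = (
    ("em_target", lambda a: a.seed_ortholog),
    ("em_score", lambda a: f"{a.seed_score:.1f}"),
    ("em_evalue", lambda a: f"{a.seed_evalue:.3e}"),
    ("em_OGs", lambda a: a.og_string),
    ("em_COG_cat", lambda a: a.cog_category),
    ("em_desc", lambda a: a.description),
    ("em_Preferred_name", lambda a: a.preferred_name),
    ("em_GOs", lambda a: ",".join(sorted(a.terms_for("GO")))),
    ("em_KEGG_ko", lambda a: ",".join(sorted(a.terms_for("KEGG_ko")))),
    ("em_PFAMs", lambda a: ",".join(a.pfams)),
)

EM_ATTRIBUTE_KEYS = tuple(k for k, _ in _EM_FIELDS)


def decorate_gff(
    gff_in,
    annotations: list[FunctionalAnnotation],
    gff_out,
    id_attribute: str = "ID",
) -> int:
    """Append ``em_*`` attributes to records whose ``id_attribute`` matches a
    query id.  Coordinates and existing attributes pass through unchanged.
    Returns the number of annotation queries that matched no record."""
    comments, records, fasta = parse_gff(gff_in)
    by_query = {a.query_id: a for a in annotations}
    matched: set[str] = set()
    for rec in records:
        key = rec.get_attribute(id_attribute)
        if key is None or key not in by_query:
            continue
        matched.add(key)
        ann = by_query[key]
        existing = {k for k, _ in rec.attributes}
        for attr, extract in _EM_FIELDS:
            if attr in existing:
                continue
            value = extract(ann)
            if value:
                rec.attributes.append((attr, value))
    write_gff(
        gff_out,
        comments,
        records,
        fasta,
        extra_comments=("## functional annotations added by ogmapper",),
    )
    return len(by_query) - len(matched)


def strip_em_attributes(records: list[GffRecord]) -> None:
    """Remove every ``em_*`` attribute in place (decoration inverse)."""
    for rec in records:
        rec.attributes = [
            (k, v) for k, v in rec.attributes if k not in EM_ATTRIBUTE_KEYS
        ]


def orfs_to_gff_records(orfs) -> list[GffRecord]:
    """CDS records (GFF3 convention) for predicted ORFs, ids ``contig_N``."""
    counters: dict[str, int] = {}
    records = []
    for orf in orfs:
        counters[orf.contig_id] = counters.get(orf.contig_id, 0) + 1
        oid = f"{orf.contig_id}_{counters[orf.contig_id]}"
        records.append(
            GffRecord(
                seqid=orf.contig_id,
                source="ogmapper",
                type="CDS",
                start=orf.start,
                end=orf.end,
                score=".",
                strand=orf.strand,
                phase="0",
                attributes=[("ID", oid), ("partial", "00")],
            )
        )
    return records
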