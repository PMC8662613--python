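"""The reference-database bundle: proteins, per-level orthologous groups,
pairwise orthology, functional annotations and domain models.

On-disk layout is one directory of plain-text files so that databases are
diffable and trivially generated by the simulator::

    proteins.faa            FASTA, record id == protein_id
    taxonomy.tsv            tax_id, parent_id, name, rank
    ogs.tsv                 og_id, level, description, cog_categories, members
    orthologs.tsv           protein_a, protein_b   (unordered, stored a < b)
    annotations.tsv         protein_id, source, terms (comma-joined)
    domain_models.tsv       model_id, clan_id, length, ga_threshold
    domain_pssms.tsv        model_id, position, one column per residue
    domain_annotations.tsv  protein_id, model_id, start, end, score
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import ConsistencyError, FormatError
from .taxonomy import TaxonomyTree, load_taxonomy, save_taxonomy

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

ANNOTATION_SOURCES = (
    "GO",
    "KEGG_ko",
    "KEGG_pathway",
    "KEGG_module",
    "EC",
    "BiGG",
    "CAZy",
    "name",
)

_VALID_RESIDUES = frozenset(AA_ALPHABET + "X")


@dataclass(frozen=True)
class RefProtein:
    protein_id: str
    tax_id: int
    sequence: str


@dataclass(frozen=True)
class OrthologousGroup:
    """A set of proteins descending from one ancestral gene at one level."""

    og_id: str
    level: int
    members: frozenset[str]
    description: str = ""
    cog_categories: str = ""


@dataclass
class DomainModel:
    """Gapless position-specific scoring model with a gathering threshold."""

    model_id: str
    clan_id: str
    length: int
    pssm: np.ndarray  # shape (length, 20), integer scores over AA_ALPHABET
    ga_threshold: float

    def __eq__(self, other) -> bool:
        if not isinstance(other, DomainModel):
            return NotImplemented
        return (
            self.model_id == other.model_id
            and self.clan_id == other.clan_id
            and self.length == other.length
            and self.ga_threshold == other.ga_threshold
            and np.array_equal(self.pssm, other.pssm)
        )


@dataclass(frozen=True, order=True)
class DomainAnnotation:
    protein_id: str
    model_id: str
    start: int  # 1-based inclusive
    end: int
    score: float


@dataclass
class ReferenceDatabase:
    """Validated bundle of every table the annotation pipeline consumes.

    ``orthologs`` stores each unordered pair once as a sorted tuple;
    ``annotations`` maps protein_id -> source -> frozenset of terms.
    """

    taxonomy: TaxonomyTree
    proteins: dict[str, RefProtein]
    ogs: dict[str, OrthologousGroup]
    orthologs: set[tuple[str, str]]
    annotations: dict[str, dict[str, frozenset[str]]]
    domain_models: dict[str, DomainModel] = field(default_factory=dict)
    domain_annotations: list[DomainAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self._ogs_by_protein: dict[str, list[str]] | None = None
        self._kmer_indexes: dict[int, dict] = {}

    # -- convenience -----------------------------------------------------

    def has_pair(self, a: str, b: str) -> bool:
        if a == b:
            return False
        return (min(a, b), max(a, b)) in self.orthologs

    def ogs_containing(self, protein_id: str) -> list[str]:
        """og_ids containing the protein (unordered; see orthology.ogs_of)."""
        if self._ogs_by_protein is None:
            by_prot: dict[str, list[str]] = {}
            for og_id in sorted(self.ogs):
                for member in self.ogs[og_id].members:
                    by_prot.setdefault(member, []).append(og_id)
            self._ogs_by_protein = by_prot
        return list(self._ogs_by_protein.get(protein_id, []))

    def terms_of(self, protein_id: str, source: str) -> frozenset[str]:
        return self.annotations.get(protein_id, {}).get(source, frozenset())

    def domains_of(self, protein_id: str) -> list[DomainAnnotation]:
        return [d for d in self.domain_annotations if d.protein_id == protein_id]

    def total_residues(self) -> int:
        return sum(len(p.sequence) for p in self.proteins.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReferenceDatabase):
            return NotImplemented
        return (
            self.taxonomy == other.taxonomy
            and self.proteins == other.proteins
            and self.ogs == other.ogs
            and self.orthologs == other.orthologs
            and self.annotations == other.annotations
            and self.domain_models == other.domain_models
            and sorted(self.domain_annotations) == sorted(other.domain_annotations)
        )


# ---------------------------------------------------------------------------
# validation


def validate(db: ReferenceDatabase) -> None:
    """Raise :class:`ConsistencyError` on any referential or structural
    violation; silent on success.  Validation is idempotent."""
    tax = db.taxonomy
    for pid, prot in db.proteins.items():
        if pid != prot.protein_id:
            raise ConsistencyError(f"protein key {pid!r} != id {prot.protein_id!r}")
        if not prot.sequence:
            raise ConsistencyError(f"protein {pid}: empty sequence")
        bad = set(prot.sequence) - _VALID_RESIDUES
        if bad:
            raise ConsistencyError(f"protein {pid}: invalid residues {sorted(bad)}")
        if prot.tax_id not in tax:
            raise ConsistencyError(f"protein {pid}: unknown taxon {prot.tax_id}")
        if not tax.is_leaf(prot.tax_id):
            raise ConsistencyError(f"protein {pid}: taxon {prot.tax_id} is not a leaf")

    for og_id, og in db.ogs.items():
        if og_id != og.og_id:
            raise ConsistencyError(f"OG key {og_id!r} != id {og.og_id!r}")
        if len(og.members) < 2:
            raise ConsistencyError(f"OG {og_id}: fewer than 2 members")
        if og.level not in tax:
            raise ConsistencyError(f"OG {og_id}: unknown level {og.level}")
        level_clade = tax.subtree(og.level)
        for member in og.members:
            if member not in db.proteins:
                raise ConsistencyError(f"OG {og_id}: unknown member {member}")
            if db.proteins[member].tax_id not in level_clade:
                raise ConsistencyError(
                    f"OG {og_id}: member {member} (taxon "
                    f"{db.proteins[member].tax_id}) outside level {og.level}"
                )

    og_ids_by_protein: dict[str, list[str]] = {}
    for og_id, og in db.ogs.items():
        for member in og.members:
            og_ids_by_protein.setdefault(member, []).append(og_id)

    for a, b in db.orthologs:
        if a >= b:
            raise ConsistencyError(f"ortholog pair ({a}, {b}) not stored sorted")
        for p in (a, b):
            if p not in db.proteins:
                raise ConsistencyError(f"ortholog pair references unknown {p}")
        shared = set(og_ids_by_protein.get(a, ())) & set(og_ids_by_protein.get(b, ()))
        if not shared:
            raise ConsistencyError(f"ortholog pair ({a}, {b}) shares no OG")

    for pid, by_source in db.annotations.items():
        if pid not in db.proteins:
            raise ConsistencyError(f"annotation references unknown protein {pid}")
        for source, terms in by_source.items():
            if source not in ANNOTATION_SOURCES:
                raise ConsistencyError(f"annotation {pid}: unknown source {source!r}")
            if not terms:
                raise ConsistencyError(f"annotation {pid}/{source}: empty term set")
            for t in terms:
                if "," in t or "\t" in t or not t:
                    raise ConsistencyError(
                        f"annotation {pid}/{source}: malformed term {t!r}"
                    )

    for mid, model in db.domain_models.items():
        if mid != model.model_id:
            raise ConsistencyError(f"model key {mid!r} != id {model.model_id!r}")
        if model.pssm.shape != (model.length, len(AA_ALPHABET)):
            raise ConsistencyError(f"model {mid}: pssm shape {model.pssm.shape}")
        if not np.isfinite(model.ga_threshold):
            raise ConsistencyError(f"model {mid}: non-finite GA threshold")

    for d in db.domain_annotations:
        if d.protein_id not in db.proteins:
            raise ConsistencyError(f"domain annotation on unknown {d.protein_id}")
        if d.model_id not in db.domain_models:
            raise ConsistencyError(f"domain annotation uses unknown {d.model_id}")
        plen = len(db.proteins[d.protein_id].sequence)
        if not (1 <= d.start <= d.end <= plen):
            raise ConsistencyError(
                f"domain annotation {d.protein_id}/{d.model_id}: "
                f"bad interval {d.start}-{d.end} (protein length {plen})"
            )

    _check_og_nesting(db, og_ids_by_protein)


def _check_og_nesting(db, og_ids_by_protein) -> None:
    # if p sits in G1 at level L1 and G2 at L2 with L1 inside subtree(L2),
    # G1's membership must nest inside G2's
    tax = db.taxonomy
    checked: set[tuple[str, str]] = set()
    for og_ids in og_ids_by_protein.values():
        for g1 in og_ids:
            for g2 in og_ids:
                if g1 == g2 or (g1, g2) in checked:
                    continue
                checked.add((g1, g2))
                o1, o2 = db.ogs[g1], db.ogs[g2]
                if o1.level == o2.level:
                    continue
                if tax.is_ancestor(o2.level, o1.level):
                    if not o1.members <= o2.members:
                        raise ConsistencyError(
                            f"OG nesting violated: {g1} (level {o1.level}) not "
                            f"a subset of {g2} (level {o2.level})"
                        )


# ---------------------------------------------------------------------------
# building from individual table files


def build_database(
    proteins_fasta,
    og_table,
    orthologs_table,
    annotations_table,
    domain_models_table,
    domain_pssms_table,
    domain_annotations_table,
    taxonomy: TaxonomyTree,
) -> ReferenceDatabase:
    """Assemble and validate a database from its component files."""
    proteins = _read_proteins(proteins_fasta)
    ogs = _read_ogs(og_table)
    orthologs = _read_orthologs(orthologs_table)
    annotations = _read_annotations(annotations_table)
    models = _read_domain_models(domain_models_table, domain_pssms_table)
    dom_anns = _read_domain_annotations(domain_annotations_table)
    db = ReferenceDatabase(
        taxonomy=taxonomy,
        proteins=proteins,
        ogs=ogs,
        orthologs=orthologs,
        annotations=annotations,
        domain_models=models,
        domain_annotations=dom_anns,
    )
    validate(db)
    return db


# -- per-table readers/writers ----------------------------------------------


def _open_rows(path, expected_header):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing table file: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if tuple(header) != tuple(expected_header):
            raise FormatError(
                f"{path}: expected header {list(expected_header)}, got {header}"
            )
        yield from ((lineno, row) for lineno, row in enumerate(reader, start=2) if row)


def _read_proteins(path) -> dict[str, RefProtein]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing table file: {path}")
    proteins: dict[str, RefProtein] = {}
    with open(path, encoding="utf-8") as fh:
        for title, seq in SimpleFastaParser(fh):
            fields = title.split(" ")
            pid = fields[0]
            try:
                tax_id = int(dict(f.split("=", 1) for f in fields[1:])["tax"])
            except (KeyError, ValueError) as exc:
                raise FormatError(
                    f"{path}: record {pid!r} lacks a 'tax=<id>' tag"
                ) from exc
            if pid in proteins:
                raise FormatError(f"{path}: duplicate protein_id {pid}")
            proteins[pid] = RefProtein(pid, tax_id, seq.upper())
    return proteins


def _write_proteins(proteins: dict[str, RefProtein], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(proteins):
            p = proteins[pid]
            fh.write(f">{pid} tax={p.tax_id}\n{p.sequence}\n")


def _read_ogs(path) -> dict[str, OrthologousGroup]:
    ogs = {}
    for lineno, row in _open_rows(
        path, ("og_id", "level", "description", "cog_categories", "members")
    ):
        if len(row) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 columns")
        og_id = row[0]
        if og_id in ogs:
            raise FormatError(f"{path}:{lineno}: duplicate og_id {og_id}")
        members = frozenset(m for m in row[4].split(",") if m)
        ogs[og_id] = OrthologousGroup(og_id, int(row[1]), members, row[2], row[3])
    return ogs


def _write_ogs(ogs, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(("og_id", "level", "description", "cog_categories", "members"))
        for og_id in sorted(ogs):
            og = ogs[og_id]
            w.writerow(
                (og.og_id, og.level, og.description, og.cog_categories,
                 ",".join(sorted(og.members)))
            )


def _read_orthologs(path) -> set[tuple[str, str]]:
    pairs = set()
    for lineno, row in _open_rows(path, ("protein_a", "protein_b")):
        if len(row) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns")
        a, b = row
        if a == b:
            raise FormatError(f"{path}:{lineno}: self-pair {a}")
        pairs.add((min(a, b), max(a, b)))
    return pairs


def _write_orthologs(pairs, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(("protein_a", "protein_b"))
        for a, b in sorted(pairs):
            w.writerow((a, b))


def _read_annotations(path) -> dict[str, dict[str, frozenset[str]]]:
    out: dict[str, dict[str, frozenset[str]]] = {}
    for lineno, row in _open_rows(path, ("protein_id", "source", "terms")):
        if len(row) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns")
        pid, source, terms = row
        by_source = out.setdefault(pid, {})
        if source in by_source:
            raise FormatError(f"{path}:{lineno}: duplicate ({pid}, {source}) row")
        by_source[source] = frozenset(t for t in terms.split(",") if t)
    return out


def _write_annotations(annotations, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(("protein_id", "source", "terms"))
        for pid in sorted(annotations):
            for source in sorted(annotations[pid]):
                w.writerow((pid, source, ",".join(sorted(annotations[pid][source]))))


def _read_domain_models(meta_path, pssm_path) -> dict[str, DomainModel]:
    meta: dict[str, tuple[str, int, float]] = {}
    for lineno, row in _open_rows(
        meta_path, ("model_id", "clan_id", "length", "ga_threshold")
    ):
        if len(row) != 4:
            raise FormatError(f"{meta_path}:{lineno}: expected 4 columns")
        meta[row[0]] = (row[1], int(row[2]), float(row[3]))
    rows: dict[str, dict[int, list[int]]] = {m: {} for m in meta}
    header = ("model_id", "position") + tuple(AA_ALPHABET)
    for lineno, row in _open_rows(pssm_path, header):
        mid, pos = row[0], int(row[1])
        if mid not in meta:
            raise FormatError(f"{pssm_path}:{lineno}: unknown model {mid}")
        rows[mid][pos] = [int(v) for v in row[2:]]
    models = {}
    for mid, (clan, length, ga) in meta.items():
        if sorted(rows[mid]) != list(range(1, length + 1)):
            raise FormatError(f"{pssm_path}: model {mid}: missing pssm rows")
        pssm = np.array([rows[mid][i] for i in range(1, length + 1)], dtype=np.int64)
        models[mid] = DomainModel(mid, clan, length, pssm, ga)
    return models


def _write_domain_models(models, meta_path, pssm_path) -> None:
    with open(meta_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(("model_id", "clan_id", "length", "ga_threshold"))
        for mid in sorted(models):
            m = models[mid]
            w.writerow((m.model_id, m.clan_id, m.length, repr(float(m.ga_threshold))))
    with open(pssm_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(("model_id", "position") + tuple(AA_ALPHABET))
        for mid in sorted(models):
            m = models[mid]
            for i in range(m.length):
                w.writerow([mid, i + 1] + [int(v) for v in m.pssm[i]])


def _read_domain_annotations(path) -> list[DomainAnnotation]:
    out = []
    for lineno, row in _open_rows(
        path, ("protein_id", "model_id", "start", "end", "score")
    ):
        if len(row) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 columns")
        out.append(
            DomainAnnotation(row[0], row[1], int(row[2]), int(row[3]), float(row[4]))
        )
    return out


def _write_domain_annotations(anns, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(("protein_id", "model_id", "start", "end", "score"))
        for d in sorted(anns):
            w.writerow((d.protein_id, d.model_id, d.start, d.end, repr(float(d.score))))


# ---------------------------------------------------------------------------
# directory save / load


_FILES = {
    "proteins": "proteins.faa",
    "taxonomy": "taxonomy.tsv",
    "ogs": "ogs.tsv",
    "orthologs": "orthologs.tsv",
    "annotations": "annotations.tsv",
    "domain_models": "domain_models.tsv",
    "domain_pssms": "domain_pssms.tsv",
    "domain_annotations": "domain_annotations.tsv",
}


def save_database(db: ReferenceDatabase, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_proteins(db.proteins, directory / _FILES["proteins"])
    save_taxonomy(db.taxonomy, directory / _FILES["taxonomy"])
    _write_ogs(db.ogs, directory / _FILES["ogs"])
    _write_orthologs(db.orthologs, directory / _FILES["orthologs"])
    _write_annotations(db.annotations, directory / _FILES["annotations"])
    _write_domain_models(
        db.domain_models,
        directory / _FILES["domain_models"],
        directory / _FILES["domain_pssms"],
    )
    _write_domain_annotations(
        db.domain_annotations, directory / _FILES["domain_annotations"]
    )


def load_database(directory) -> ReferenceDatabase:
    directory = Path(directory)
    for fname in _FILES.values():
        if not (directory / fname).exists():
            raise FormatError(f"missing table file: {directory / fname}")
    taxonomy = load_taxonomy(directory / _FILES["taxonomy"])
    return build_database(
        directory / _FILES["proteins"],
        directory / _FILES["ogs"],
        directory / _FILES["orthologs"],
        directory / _FILES["annotations"],
        directory / _FILES["domain_models"],
        directory / _FILES["domain_pssms"],
        directory / _FILES["domain_annotations"],
        taxonomy,
    )


# ---------------------------------------------------------------------------
# taxon-restricted subsetting


def subset_by_taxon(db: ReferenceDatabase, tax_id: int) -> ReferenceDatabase:
    """Restrict the database to proteins of species inside ``subtree(tax_id)``.

    OGs whose membership drops below two are removed; pairwise orthologies
    must still share a surviving OG.  The taxonomy itself is kept whole so
    level names and lineage queries are unchanged.  An empty result is a
    warning, not an error.
    """
    if tax_id not in db.taxonomy:
        raise KeyError(f"unknown tax_id {tax_id}")
    clade = db.taxonomy.subtree(tax_id)
    keep = {pid for pid, p in db.proteins.items() if p.tax_id in clade}
    if not keep:
        warnings.warn(f"subset to taxon {tax_id} leaves zero proteins")
    ogs = {}
    for og_id, og in db.ogs.items():
        members = frozenset(og.members & keep)
        if len(members) >= 2:
            ogs[og_id] = replace(og, members=members)
    og_ids_by_protein: dict[str, set[str]] = {}
    for og_id, og in ogs.items():
        for m in og.members:
            og_ids_by_protein.setdefault(m, set()).add(og_id)
    orthologs = {
        (a, b)
        for a, b in db.orthologs
        if a in keep
        and b in keep
        and og_ids_by_protein.get(a, set()) & og_ids_by_protein.get(b, set())
    }
    sub = ReferenceDatabase(
        taxonomy=db.taxonomy,
        proteins={pid: db.proteins[pid] for pid in keep},
        ogs=ogs,
        orthologs=orthologs,
        annotations={pid: dict(v) for pid, v in db.annotations.items() if pid in keep},
        domain_models=dict(db.domain_models),
        domain_annotations=[d for d in db.domain_annotations if d.protein_id in keep],
    )
    validate(sub)
    return sub
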