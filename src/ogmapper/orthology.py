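"""Scope resolution and typed ortholog-set expansion from a seed ortholog.

Starting from the best reference hit (the seed), the query inherits the
seed's orthologous-group memberships across taxonomic levels.  A scope (one
OG, one level) is chosen either automatically or pinned to a lineage, the
pairwise-orthology relation is expanded into the transfer set, and each
pair is classified one2one / one2many / many2one / many2many by counting
co-orthologs on either side.  In-paralogs of the seed — co-members of the
scope OG that are not in the pairwise relation with it — are excluded by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .refdb import OrthologousGroup, ReferenceDatabase

ORTHOLOG_TYPES = ("one2one", "one2many", "many2one", "many2many")


@dataclass(frozen=True)
class ScopeSelection:
    query_id: str
    seed_protein_id: str
    chosen_og: str
    level: int
    mode: str  # "auto" or "fixed:<tax_id>"


@dataclass(frozen=True)
class TypedOrtholog:
    protein_id: str
    type: str

    def __post_init__(self):
        if self.type not in ORTHOLOG_TYPES:
            raise ValueError(f"unknown ortholog type {self.type!r}")


@dataclass(frozen=True)
class OrthologSet:
    query_id: str
    scope: ScopeSelection
    orthologs: tuple[TypedOrtholog, ...]

    def protein_ids(self) -> list[str]:
        return [o.protein_id for o in self.orthologs]


def ogs_of(db: ReferenceDatabase, protein_id: str) -> list[OrthologousGroup]:
    """OGs containing the protein, most specific level first (ties: og_id)."""
    if protein_id not in db.proteins:
        raise KeyError(f"unknown protein {protein_id}")
    og_ids = db.ogs_containing(protein_id)
    og_ids.sort(key=lambda og_id: (-db.taxonomy.depth(db.ogs[og_id].level), og_id))
    return [db.ogs[og_id] for og_id in og_ids]


def select_scope(
    db: ReferenceDatabase,
    seed: str,
    mode: str = "auto",
    fixed_taxon: int | None = None,
    min_species: int = 3,
    query_id: str = "",
) -> ScopeSelection | None:
    """Choose the annotation scope for a seed ortholog.

    auto: the most specific OG of the seed spanning at least ``min_species``
    distinct species, falling back to the seed's most specific OG when none
    qualifies.  fixed: the most specific OG whose level is ancestor-or-equal
    of ``fixed_taxon``; returns None (explicit no-scope) when the seed has no
    OG at or above that taxon.
    """
    candidates = ogs_of(db, seed)
    if not candidates:
        return None
    if mode == "auto":
        chosen = None
        for og in candidates:
            n_species = len({db.proteins[m].tax_id for m in og.members})
            if n_species >= min_species:
                chosen = og
                break
        if chosen is None:
            chosen = candidates[0]
        return ScopeSelection(query_id, seed, chosen.og_id, chosen.level, "auto")
    if mode == "fixed":
        if fixed_taxon is None:
            raise ValueError("fixed mode requires a taxon")
        if fixed_taxon not in db.taxonomy:
            raise KeyError(f"unknown tax_id {fixed_taxon}")
        ancestors = set(db.taxonomy.lineage(fixed_taxon))
        for og in candidates:  # already deepest-first
            if og.level in ancestors:
                return ScopeSelection(
                    query_id, seed, og.og_id, og.level, f"fixed:{fixed_taxon}"
                )
        return None
    raise ValueError(f"unknown scope mode {mode!r}")


def classify_type(
    db: ReferenceDatabase,
    seed: str,
    other: str,
    scope_og: OrthologousGroup | str,
) -> str:
    """Ortholog type of (seed, other) from the seed's perspective.

    Counts, within the scope OG, the seed-species co-orthologs of ``other``
    (the 'many' on the seed side) and vice versa.
    """
    if isinstance(scope_og, str):
        scope_og = db.ogs[scope_og]
    if not db.has_pair(seed, other):
        raise ValueError(f"({seed}, {other}) is not in the pairwise relation")
    if seed not in scope_og.members or other not in scope_og.members:
        raise ValueError("both proteins must be members of the scope OG")
    seed_sp = db.proteins[seed].tax_id
    other_sp = db.proteins[other].tax_id
    a = sum(
        1
        for x in scope_og.members
        if db.proteins[x].tax_id == seed_sp and db.has_pair(x, other)
    )
    b = sum(
        1
        for y in scope_og.members
        if db.proteins[y].tax_id == other_sp and db.has_pair(seed, y)
    )
    return ("many" if a > 1 else "one") + "2" + ("many" if b > 1 else "one")


def orthologs_of(
    db: ReferenceDatabase,
    scope: ScopeSelection,
    target_taxa: set[int] | None = None,
    allowed_types: set[str] | None = None,
) -> OrthologSet:
    """Expand the scope into the typed transfer set.

    Returns every scope-OG member pairwise-orthologous to the seed whose
    species lies under some target taxon (when given) and whose type is
    allowed, plus the seed itself (always included; typed one2one by
    convention).
    """
    og = db.ogs[scope.chosen_og]
    seed = scope.seed_protein_id
    if allowed_types is None:
        allowed_types = set(ORTHOLOG_TYPES)
    in_range: set[int] | None = None
    if target_taxa is not None:
        in_range = set()
        for t in target_taxa:
            in_range |= db.taxonomy.subtree(t)
    typed: list[TypedOrtholog] = [TypedOrtholog(seed, "one2one")]
    for pid in sorted(og.members):
        if pid == seed or not db.has_pair(seed, pid):
            continue  # non-paired co-members are in-paralogs: excluded
        if in_range is not None and db.proteins[pid].tax_id not in in_range:
            continue
        pair_type = classify_type(db, seed, pid, og)
        if pair_type not in allowed_types:
            continue
        typed.append(TypedOrtholog(pid, pair_type))
    return OrthologSet(scope.query_id, scope, tuple(typed))
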