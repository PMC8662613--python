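"""Functional-term transfer from the ortholog set and the end-to-end
annotation driver (search -> scope -> orthologs -> transfer -> domains)."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from . import domains as domains_mod
from .orthology import (
    ORTHOLOG_TYPES,
    OrthologSet,
    orthologs_of,
    ogs_of,
    select_scope,
)
from .refdb import ReferenceDatabase
from .search import (
    AlignmentHit,
    ScoringScheme,
    SearchParams,
    best_seed_ortholog,
    search,
)

TERM_SOURCES = ("GO", "KEGG_ko", "KEGG_pathway", "KEGG_module", "EC", "BiGG", "CAZy")


@dataclass(frozen=True)
class FunctionalAnnotation:
    """Per-query annotation record; term sets are deduplicated frozensets and
    rendered sorted (empty sets print as '-')."""

    query_id: str
    seed_ortholog: str
    seed_evalue: float
    seed_score: float
    og_string: str  # comma-joined og_id@level_name, most specific first
    max_annot_level: str
    cog_category: str
    description: str
    preferred_name: str
    terms: dict[str, frozenset[str]] = field(default_factory=dict)
    pfams: tuple[str, ...] = ()

    def terms_for(self, source: str) -> frozenset[str]:
        return self.terms.get(source, frozenset())


@dataclass
class PipelineParams:
    """Everything the end-to-end driver needs, with pipeline defaults."""

    search: SearchParams = field(default_factory=SearchParams)
    scope_mode: str = "auto"  # auto | fixed
    scope_taxon: int | None = None
    min_species: int = 3
    target_taxa: set[int] | None = None
    allowed_types: set[str] = field(default_factory=lambda: set(ORTHOLOG_TYPES))
    term_policy: str = "union"  # union | majority
    majority_frac: float = 0.5
    domain_mode: str = "transfer"  # none | transfer | refine | denovo
    domain_pad: int = domains_mod.DEFAULT_PAD
    clan_overlap_frac: float = domains_mod.DEFAULT_OVERLAP_FRAC


@dataclass
class PipelineResult:
    annotations: list[FunctionalAnnotation]
    ortholog_sets: list[OrthologSet]
    domain_hits: dict[str, list[domains_mod.DomainHit]]
    hits: dict[str, list[AlignmentHit]]
    unmatched: list[str]


def transfer_annotations(
    db: ReferenceDatabase,
    ortholog_set: OrthologSet,
    policy: str = "union",
    majority_frac: float = 0.5,
) -> FunctionalAnnotation:
    """Aggregate per-source terms across the ortholog set.

    union: any term held by any ortholog.  majority: a term is kept when at
    least ``majority_frac`` of the orthologs *having at least one term for
    that source* carry it (orthologs silent on a source do not dilute it).
    """
    if policy not in ("union", "majority"):
        raise ValueError(f"unknown term policy {policy!r}")
    members = ortholog_set.protein_ids()
    scope = ortholog_set.scope
    og = db.ogs[scope.chosen_og]
    terms: dict[str, frozenset[str]] = {}
    for source in TERM_SOURCES:
        per_ortholog = [db.terms_of(p, source) for p in members]
        annotated = [s for s in per_ortholog if s]
        if not annotated:
            continue
        if policy == "union":
            merged = frozenset().union(*annotated)
        else:
            counts = Counter(t for s in annotated for t in s)
            need = majority_frac * len(annotated)
            merged = frozenset(t for t, c in counts.items() if c >= need)
        if merged:
            terms[source] = merged
    names = Counter()
    for p in members:
        for name in db.terms_of(p, "name"):
            names[name] += 1
    preferred = ""
    if names:
        top = max(names.values())
        preferred = min(n for n, c in names.items() if c == top)
    og_string = ",".join(
        f"{g.og_id}@{db.taxonomy.name_of(g.level)}"
        for g in ogs_of(db, scope.seed_protein_id)
    )
    return FunctionalAnnotation(
        query_id=ortholog_set.query_id,
        seed_ortholog=scope.seed_protein_id,
        seed_evalue=0.0,
        seed_score=0.0,
        og_string=og_string,
        max_annot_level=db.taxonomy.name_of(scope.level),
        cog_category=og.cog_categories,
        description=og.description,
        preferred_name=preferred,
        terms=terms,
    )


def annotate(
    queries,
    db: ReferenceDatabase,
    params: PipelineParams | None = None,
    scheme: ScoringScheme | None = None,
) -> PipelineResult:
    """Annotate (query_id, protein_sequence) pairs end to end.

    Unmatched queries (no passing hit, or no scope in fixed mode) land in
    ``unmatched``, never in the annotation table.  Per-query failures do not
    abort the batch.
    """
    params = params or PipelineParams()
    queries = list(queries)
    res = search(queries, db, params.search, scheme)
    seqs = dict(queries)
    annotations: list[FunctionalAnnotation] = []
    ortholog_sets: list[OrthologSet] = []
    domain_hits: dict[str, list[domains_mod.DomainHit]] = {}
    unmatched = list(res.unmatched)
    for qid, _ in queries:
        hits = res.hits.get(qid)
        if not hits:
            continue
        seed_hit = best_seed_ortholog(
            hits, params.search.evalue_cutoff, params.search.min_bit_score
        )
        if seed_hit is None:
            unmatched.append(qid)
            continue
        scope = select_scope(
            db,
            seed_hit.target_id,
            mode=params.scope_mode,
            fixed_taxon=params.scope_taxon,
            min_species=params.min_species,
            query_id=qid,
        )
        if scope is None:
            unmatched.append(qid)
            continue
        oset = orthologs_of(db, scope, params.target_taxa, params.allowed_types)
        ann = transfer_annotations(db, oset, params.term_policy, params.majority_frac)
        dhits = _domain_stage(db, qid, seqs[qid], seed_hit, params)
        if dhits:
            domain_hits[qid] = dhits
        ann = FunctionalAnnotation(
            query_id=ann.query_id,
            seed_ortholog=ann.seed_ortholog,
            seed_evalue=seed_hit.evalue,
            seed_score=seed_hit.bit_score,
            og_string=ann.og_string,
            max_annot_level=ann.max_annot_level,
            cog_category=ann.cog_category,
            description=ann.description,
            preferred_name=ann.preferred_name,
            terms=ann.terms,
            pfams=tuple(sorted({h.model_id for h in dhits})),
        )
        annotations.append(ann)
        ortholog_sets.append(oset)
    return PipelineResult(annotations, ortholog_sets, domain_hits, res.hits, unmatched)


def _domain_stage(db, qid, seq, seed_hit, params) -> list[domains_mod.DomainHit]:
    if params.domain_mode == "none":
        return []
    if params.domain_mode == "denovo":
        return domains_mod.denovo_scan(seq, db, qid, params.clan_overlap_frac)
    transferred = domains_mod.transfer_domains(db, qid, seed_hit)
    if params.domain_mode == "transfer":
        return transferred
    if params.domain_mode == "refine":
        refined = []
        for t in transferred:
            r = domains_mod.realign_refine(seq, t, db, params.domain_pad)
            if r is not None:
                refined.append(r)
        return refined
    raise ValueError(f"unknown domain mode {params.domain_mode!r}")
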