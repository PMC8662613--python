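"""Ground-truth simulator: species taxonomy, duplication-loss gene families,
sequence evolution, paralog-divergent functional labels and planted domains.

The simulator emits a valid :class:`~ogmapper.refdb.ReferenceDatabase` plus a
held-out query species with an answer key, so every pipeline stage can be
benchmarked offline against known truth.  Two genes are true orthologs iff
their gene-tree LCA is a speciation node; functional terms diverge only at
duplication nodes, which is exactly the premise orthology-restricted
transfer exploits.

All randomness flows from ``SimParams.random_seed``: equal parameters give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import OgmapperError
from .refdb import (
    AA_ALPHABET,
    DomainAnnotation,
    DomainModel,
    OrthologousGroup,
    RefProtein,
    ReferenceDatabase,
    validate,
)
from .taxonomy import TaxonNode, TaxonomyTree

_COG_LETTERS = "CEGHIJKLMNOPQTUV"


@dataclass
class SimParams:
    n_species: int = 16
    tree_depth: int = 8
    duplication_rate: float = 0.3  # expected duplications per lineage per branch
    loss_rate: float = 0.1  # loss probability per lineage per branch
    root_protein_length: int = 200
    substitution_rate: float = 1.0  # per site per unit branch length
    rate_sigma: float = 0.8  # lognormal rate heterogeneity across gene branches
    functional_divergence_prob: float = 0.8  # per duplication event
    n_families: int = 100
    random_seed: int = 0
    # secondary knobs (documented defaults, not usually touched)
    n_base_terms: int = 6
    swap_fraction: float = 0.5
    domain_prob: float = 0.5
    domain_length: int = 30
    domain_conservation: float = 0.1  # rate multiplier inside planted domains
    domain_match_score: int = 5
    domain_mismatch_score: int = -2
    ga_fraction: float = 0.6  # GA threshold as a fraction of the self-score

    def __post_init__(self):
        for name in ("duplication_rate", "loss_rate", "substitution_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.functional_divergence_prob <= 1:
            raise ValueError("functional_divergence_prob must be in [0, 1]")
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")


# ---------------------------------------------------------------------------
# species tree / taxonomy


class SpeciesNode:
    __slots__ = ("tax_id", "name", "blen", "children", "parent", "depth")

    def __init__(self, blen: float, depth: int):
        self.tax_id = 0
        self.name = ""
        self.blen = blen
        self.children: list[SpeciesNode] = []
        self.parent: SpeciesNode | None = None
        self.depth = depth

    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


def simulate_taxonomy(
    n_species: int, depth: int, rng: np.random.Generator
) -> tuple[TaxonomyTree, SpeciesNode]:
    """Random bifurcating species tree; internal nodes become internal taxa.

    Built by repeatedly splitting a random leaf shallower than ``depth``;
    branch lengths are exponential with mean 0.1.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if n_species > 2**depth:
        raise ValueError(f"cannot place {n_species} species within depth {depth}")
    root = SpeciesNode(0.0, 0)
    leaves = [root]
    while len(leaves) < n_species or leaves == [root]:
        splittable = [i for i, lf in enumerate(leaves) if lf.depth < depth]
        if not splittable:
            raise OgmapperError("ran out of splittable leaves")
        idx = splittable[int(rng.integers(len(splittable)))]
        node = leaves.pop(idx)
        for _ in range(2):
            child = SpeciesNode(float(rng.exponential(0.1)), node.depth + 1)
            child.parent = node
            node.children.append(child)
        leaves.extend(node.children)
    # breadth-first tax ids: root == 1
    queue = [root]
    nodes: dict[int, TaxonNode] = {}
    next_id = 1
    order: list[SpeciesNode] = []
    while queue:
        node = queue.pop(0)
        node.tax_id = next_id
        next_id += 1
        order.append(node)
        queue.extend(node.children)
    for node in order:
        if node.is_leaf():
            node.name = f"sp{node.tax_id}"
            rank = "species"
        else:
            node.name = f"clade{node.tax_id}"
            rank = "clade"
        parent_id = node.parent.tax_id if node.parent else node.tax_id
        nodes[node.tax_id] = TaxonNode(node.tax_id, parent_id, node.name, rank)
    return TaxonomyTree.from_nodes(nodes), root


# ---------------------------------------------------------------------------
# gene trees


class GeneNode:
    """Gene-tree node: label 'S' (speciation), 'D' (duplication) or 'leaf'."""

    __slots__ = ("label", "species", "children", "parent", "blen", "name", "depth")

    def __init__(self, label: str, species: int = 0, blen: float = 0.0):
        self.label = label
        self.species = species  # tax_id for leaves / speciation site
        self.children: list[GeneNode] = []
        self.parent: GeneNode | None = None
        self.blen = blen
        self.name = ""
        self.depth = 0

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def leaves(self) -> list["GeneNode"]:
        return [n for n in self.walk() if n.label == "leaf"]


@dataclass
class PlantedDomain:
    model: DomainModel
    start: int  # 1-based inclusive, identical in every leaf (no indels)
    end: int


@dataclass
class SimulatedFamily:
    family_id: int
    root: GeneNode
    leaves: list[GeneNode]
    leaf_species: dict[str, int]
    true_pairs: set[tuple[str, str]]  # sorted tuples, speciation-LCA rule
    true_types: dict[tuple[str, str], str]  # ordered (x, y) -> type from x side
    sequences: dict[str, str] = field(default_factory=dict)
    root_sequence: str = ""
    terms: dict[str, frozenset[str]] = field(default_factory=dict)
    domain: PlantedDomain | None = None

    def is_true_pair(self, a: str, b: str) -> bool:
        return (min(a, b), max(a, b)) in self.true_pairs


def _evolve_branch(sp_child: SpeciesNode, params: SimParams, rng) -> GeneNode | None:
    """One gene lineage entering the branch that leads to ``sp_child``."""
    if rng.random() < params.loss_rate:
        return None
    t = sp_child.blen
    k = int(rng.poisson(params.duplication_rate))
    positions = sorted(float(u) for u in rng.random(k)) if k else []

    def chain(i: int, entry: float) -> GeneNode | None:
        if i == len(positions):
            node = _descend(sp_child, params, rng)
            if node is not None:
                node.blen += (1.0 - entry) * t
            return node
        u = positions[i]
        main = chain(i + 1, u)
        side = _descend(sp_child, params, rng)
        if side is not None:
            side.blen += (1.0 - u) * t
        kids = [c for c in (main, side) if c is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].blen += (u - entry) * t
            return kids[0]
        dup = GeneNode("D", species=sp_child.tax_id)
        dup.blen = (u - entry) * t
        for c in kids:
            c.parent = dup
            dup.children.append(c)
        return dup

    return chain(0, 0.0)


def _descend(sp_node: SpeciesNode, params: SimParams, rng) -> GeneNode | None:
    """A gene lineage sitting exactly at species-tree node ``sp_node``."""
    if sp_node.is_leaf():
        return GeneNode("leaf", species=sp_node.tax_id)
    kids = []
    for sp_child in sp_node.children:
        sub = _evolve_branch(sp_child, params, rng)
        if sub is not None:
            kids.append(sub)
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]  # unary speciation nodes are suppressed
    spec = GeneNode("S", species=sp_node.tax_id)
    for c in kids:
        c.parent = spec
        spec.children.append(c)
    return spec


def _gene_lca_label(a: GeneNode, b: GeneNode) -> str:
    ancestors = {}
    node, d = a, 0
    while node is not None:
        ancestors[id(node)] = node
        node = node.parent
    node = b
    while node is not None:
        if id(node) in ancestors:
            return ancestors[id(node)].label
        node = node.parent
    raise OgmapperError("leaves share no ancestor")


def simulate_family(
    species_root: SpeciesNode,
    params: SimParams,
    rng: np.random.Generator,
    family_id: int = 0,
    taxonomy: TaxonomyTree | None = None,
) -> SimulatedFamily:
    """Birth-death gene evolution along the species tree.

    Families with fewer than two surviving leaves are rejected and redrawn;
    a rejection rate above ~99% raises with advice to change the rates.
    """
    root = None
    for _ in range(500):
        root = _descend(species_root, params, rng)
        if root is not None and len(root.leaves()) >= 2:
            break
        root = None
    if root is None:
        raise OgmapperError(
            "family rejection rate too high; lower loss_rate or raise "
            "duplication_rate"
        )
    leaves = root.leaves()
    per_species: dict[int, int] = {}
    sp_name = (lambda t: taxonomy.name_of(t)) if taxonomy else (lambda t: f"sp{t}")
    for leaf in leaves:
        per_species[leaf.species] = per_species.get(leaf.species, 0) + 1
        leaf.name = (
            f"fam{family_id:03d}_{sp_name(leaf.species)}_g{per_species[leaf.species]}"
        )
    leaf_species = {leaf.name: leaf.species for leaf in leaves}
    true_pairs: set[tuple[str, str]] = set()
    ortho_of: dict[str, set[str]] = {leaf.name: set() for leaf in leaves}
    for i, x in enumerate(leaves):
        for y in leaves[i + 1 :]:
            if _gene_lca_label(x, y) == "S":
                true_pairs.add((min(x.name, y.name), max(x.name, y.name)))
                ortho_of[x.name].add(y.name)
                ortho_of[y.name].add(x.name)
    true_types: dict[tuple[str, str], str] = {}
    for x in leaves:
        for y in leaves:
            if y.name not in ortho_of[x.name]:
                continue
            a = sum(
                1
                for z in leaves
                if z.species == x.species and y.name in ortho_of[z.name]
            )
            b = sum(
                1
                for z in leaves
                if z.species == y.species and z.name in ortho_of[x.name]
            )
            true_types[(x.name, y.name)] = (
                ("many" if a > 1 else "one") + "2" + ("many" if b > 1 else "one")
            )
    return SimulatedFamily(
        family_id=family_id,
        root=root,
        leaves=leaves,
        leaf_species=leaf_species,
        true_pairs=true_pairs,
        true_types=true_types,
    )


# ---------------------------------------------------------------------------
# sequences, functions, domains


def evolve_sequences(
    family: SimulatedFamily,
    root_length: int,
    rate: float,
    rng: np.random.Generator,
    conserved: tuple[int, int, float] | None = None,
    rate_sigma: float = 0.0,
) -> None:
    """Stationary replace-with-background evolution along the gene tree.

    Along a branch of length t each site substitutes with probability
    1 - exp(-rate * t) to a residue drawn uniformly from the 20-letter
    background (so with ``rate_sigma == 0`` two leaves at total distance T
    differ per site with probability (1 - exp(-rate*T)) * 19/20).
    ``rate_sigma`` > 0 draws an independent lognormal rate multiplier per
    gene-tree branch, decoupling sequence distance from tree distance the
    way real rate heterogeneity does.  ``conserved`` is an optional
    (start0, end0, factor) slow-evolving interval used for planted domains.
    """
    n_aa = len(AA_ALPHABET)
    site_rate = np.full(root_length, rate)
    if conserved is not None:
        s0, e0, factor = conserved
        site_rate[s0 : e0 + 1] = rate * factor
    root_seq = rng.integers(0, n_aa, root_length)

    def recurse(node: GeneNode, seq: np.ndarray) -> None:
        if node.label == "leaf":
            family.sequences[node.name] = "".join(AA_ALPHABET[i] for i in seq)
            return
        for child in node.children:
            mult = float(np.exp(rng.normal(0.0, rate_sigma))) if rate_sigma else 1.0
            p_sub = 1.0 - np.exp(-site_rate * mult * child.blen)
            mask = rng.random(root_length) < p_sub
            child_seq = seq.copy()
            child_seq[mask] = rng.integers(0, n_aa, int(mask.sum()))
            recurse(child, child_seq)

    family.root_sequence = "".join(AA_ALPHABET[i] for i in root_seq)
    recurse(family.root, root_seq)


def assign_functions(
    family: SimulatedFamily,
    base_terms: frozenset[str],
    divergence_prob: float,
    rng: np.random.Generator,
    swap_fraction: float = 0.5,
) -> None:
    """Terms are inherited unchanged through speciations; at each duplication,
    with probability ``divergence_prob`` one child lineage swaps a fraction of
    its terms for fresh novel terms."""
    if not base_terms:
        raise ValueError("base_terms must be non-empty")
    counter = [0]

    def swap(terms: frozenset[str]) -> frozenset[str]:
        pool = sorted(terms)
        n_swap = max(1, round(len(pool) * swap_fraction))
        drop = set(
            pool[i] for i in rng.choice(len(pool), size=n_swap, replace=False)
        )
        novel = set()
        for _ in range(n_swap):
            novel.add(f"GO:n{family.family_id:03d}x{counter[0]:04d}")
            counter[0] += 1
        return frozenset((terms - drop) | novel)

    def recurse(node: GeneNode, terms: frozenset[str]) -> None:
        if node.label == "leaf":
            family.terms[node.name] = terms
            return
        child_terms = [terms for _ in node.children]
        if node.label == "D" and rng.random() < divergence_prob:
            victim = int(rng.integers(len(node.children)))
            child_terms[victim] = swap(terms)
        for child, t in zip(node.children, child_terms):
            recurse(child, t)

    recurse(family.root, frozenset(base_terms))


def plant_domain(
    family: SimulatedFamily, params: SimParams, rng: np.random.Generator
) -> tuple[int, int]:
    """Choose the conserved interval for this family's domain (0-based)."""
    dlen = min(params.domain_length, params.root_protein_length)
    start0 = int(rng.integers(0, params.root_protein_length - dlen + 1))
    return start0, start0 + dlen - 1


def build_domain_model(
    family: SimulatedFamily, start0: int, end0: int, params: SimParams
) -> PlantedDomain:
    """PSSM rewarding the root motif residue at each position; the gathering
    threshold sits at ``ga_fraction`` of the motif self-score so planted
    domains and shuffled negatives separate by construction."""
    motif = family.root_sequence[start0 : end0 + 1]
    length = len(motif)
    pssm = np.full((length, len(AA_ALPHABET)), params.domain_mismatch_score, np.int64)
    for i, aa in enumerate(motif):
        pssm[i, AA_ALPHABET.index(aa)] = params.domain_match_score
    self_score = params.domain_match_score * length
    model = DomainModel(
        model_id=f"DM{family.family_id:03d}",
        clan_id=f"CL{family.family_id:03d}",
        length=length,
        pssm=pssm,
        ga_threshold=params.ga_fraction * self_score,
    )
    return PlantedDomain(model=model, start=start0 + 1, end=end0 + 1)


def simulate_families(
    species_root: SpeciesNode,
    taxonomy: TaxonomyTree,
    params: SimParams,
    rng: np.random.Generator,
) -> list[SimulatedFamily]:
    families = []
    for fi in range(params.n_families):
        fam = simulate_family(species_root, params, rng, family_id=fi, taxonomy=taxonomy)
        conserved = None
        if rng.random() < params.domain_prob:
            s0, e0 = plant_domain(fam, params, rng)
            conserved = (s0, e0, params.domain_conservation)
        evolve_sequences(
            fam, params.root_protein_length, params.substitution_rate, rng,
            conserved, params.rate_sigma,
        )
        if conserved is not None:
            fam.domain = build_domain_model(fam, conserved[0], conserved[1], params)
        base = frozenset(
            f"GO:f{fi:03d}t{i:02d}" for i in range(params.n_base_terms)
        )
        assign_functions(
            fam, base, params.functional_divergence_prob, rng, params.swap_fraction
        )
        families.append(fam)
    return families


# ---------------------------------------------------------------------------
# benchmark emission


@dataclass
class AnswerKey:
    heldout_species: int | None
    true_orthologs: dict[str, set[str]]  # query -> db protein ids
    true_terms: dict[str, frozenset[str]]  # query -> GO terms
    true_domains: dict[str, list[tuple[str, int, int]]]  # query -> (model, s, e)
    family_of: dict[str, int]


@dataclass
class Benchmark:
    params: SimParams
    taxonomy: TaxonomyTree
    species_root: SpeciesNode
    families: list[SimulatedFamily]
    db: ReferenceDatabase
    queries: list[tuple[str, str]]
    key: AnswerKey


def build_reference_database(
    families: list[SimulatedFamily],
    taxonomy: TaxonomyTree,
    heldout_species: int | None,
    rng: np.random.Generator,
) -> ReferenceDatabase:
    """Assemble the database from simulated families, excluding the held-out
    species.  OGs are the per-internal-taxon restrictions of each family;
    groups with fewer than two surviving members are dropped."""
    internal_taxa = [t for t in sorted(taxonomy.nodes) if not taxonomy.is_leaf(t)]
    subtree_cache = {t: taxonomy.subtree(t) for t in internal_taxa}
    proteins: dict[str, RefProtein] = {}
    ogs: dict[str, OrthologousGroup] = {}
    orthologs: set[tuple[str, str]] = set()
    annotations: dict[str, dict[str, frozenset[str]]] = {}
    domain_models: dict[str, DomainModel] = {}
    domain_annotations: list[DomainAnnotation] = []
    from .domains import pssm_score  # deferred: avoids import cycle at load

    for fam in families:
        db_leaves = [
            lf for lf in fam.leaves if lf.species != heldout_species
        ]
        for lf in db_leaves:
            proteins[lf.name] = RefProtein(lf.name, lf.species, fam.sequences[lf.name])
            annotations[lf.name] = {
                "GO": fam.terms[lf.name],
                "name": frozenset({f"FAM{fam.family_id:03d}"}),
            }
        cog = _COG_LETTERS[int(rng.integers(len(_COG_LETTERS)))]
        names = {lf.name for lf in db_leaves}
        for level in internal_taxa:
            members = frozenset(
                lf.name for lf in db_leaves if lf.species in subtree_cache[level]
            )
            if len(members) >= 2:
                og_id = f"fam{fam.family_id:03d}@{level}"
                ogs[og_id] = OrthologousGroup(
                    og_id,
                    level,
                    members,
                    description=f"simulated family {fam.family_id}",
                    cog_categories=cog,
                )
        for a, b in fam.true_pairs:
            if a in names and b in names:
                orthologs.add((a, b))
        if fam.domain is not None:
            model = fam.domain.model
            domain_models[model.model_id] = model
            for lf in db_leaves:
                window = fam.sequences[lf.name][fam.domain.start - 1 : fam.domain.end]
                score, _ = pssm_score(window, model)
                domain_annotations.append(
                    DomainAnnotation(
                        lf.name, model.model_id, fam.domain.start, fam.domain.end,
                        float(score),
                    )
                )
    db = ReferenceDatabase(
        taxonomy=taxonomy,
        proteins=proteins,
        ogs=ogs,
        orthologs=orthologs,
        annotations=annotations,
        domain_models=domain_models,
        domain_annotations=domain_annotations,
    )
    validate(db)
    return db


def emit_benchmark(params: SimParams, holdout: bool = True) -> Benchmark:
    """Simulate a full benchmark: reference database, held-out queries and
    the answer key (true orthologs, terms and domains per query)."""
    rng = np.random.default_rng(params.random_seed)
    taxonomy, species_root = simulate_taxonomy(
        params.n_species, params.tree_depth, rng
    )
    families = simulate_families(species_root, taxonomy, params, rng)
    heldout_species = None
    if holdout:
        species = sorted(taxonomy.leaves())
        heldout_species = species[int(rng.integers(len(species)))]
    db = build_reference_database(families, taxonomy, heldout_species, rng)
    queries: list[tuple[str, str]] = []
    key = AnswerKey(heldout_species, {}, {}, {}, {})
    if heldout_species is not None:
        for fam in families:
            for lf in fam.leaves:
                if lf.species != heldout_species:
                    continue
                queries.append((lf.name, fam.sequences[lf.name]))
                key.true_orthologs[lf.name] = {
                    other
                    for other in (p for pair in fam.true_pairs for p in pair)
                    if other in db.proteins and fam.is_true_pair(lf.name, other)
                }
                key.true_terms[lf.name] = fam.terms[lf.name]
                key.family_of[lf.name] = fam.family_id
                if fam.domain is not None:
                    key.true_domains[lf.name] = [
                        (fam.domain.model.model_id, fam.domain.start, fam.domain.end)
                    ]
                else:
                    key.true_domains[lf.name] = []
    return Benchmark(params, taxonomy, species_root, families, db, queries, key)


def make_negative_control(
    benchmark: Benchmark, query_id: str, rng: np.random.Generator
) -> tuple[str, str] | None:
    """Copy a planted-domain query with its domain window re-randomized until
    the window scores below the model's GA threshold (so any transferred
    domain on the control is a false positive by construction)."""
    from .domains import pssm_score

    fam = benchmark.families[benchmark.key.family_of[query_id]]
    if fam.domain is None:
        return None
    seq = dict(benchmark.queries)[query_id]
    model = fam.domain.model
    s0, e0 = fam.domain.start - 1, fam.domain.end - 1
    for _ in range(100):
        shuffled = "".join(
            AA_ALPHABET[int(i)] for i in rng.integers(0, len(AA_ALPHABET), e0 - s0 + 1)
        )
        candidate = seq[:s0] + shuffled + seq[e0 + 1 :]
        score, _ = pssm_score(candidate, model)
        if score < model.ga_threshold:
            return f"{query_id}_neg", candidate
    raise OgmapperError("could not construct a sub-GA negative control")
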