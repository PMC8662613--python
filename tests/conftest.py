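import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ogmapper.refdb import (
    DomainAnnotation,
    DomainModel,
    OrthologousGroup,
    RefProtein,
    ReferenceDatabase,
    validate,
)
from ogmapper.taxonomy import TaxonNode, TaxonomyTree
from ogmapper import simdata


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_tax() -> TaxonomyTree:
    """root(1) -> cladeL(2){spA(4), spB(5)}, cladeR(3){spC(6), spD(7)}."""
    nodes = {
        1: TaxonNode(1, 1, "root", "no rank"),
        2: TaxonNode(2, 1, "cladeL", "clade"),
        3: TaxonNode(3, 1, "cladeR", "clade"),
        4: TaxonNode(4, 2, "spA", "species"),
        5: TaxonNode(5, 2, "spB", "species"),
        6: TaxonNode(6, 3, "spC", "species"),
        7: TaxonNode(7, 3, "spD", "species"),
    }
    return TaxonomyTree.from_nodes(nodes)


_BASE = "MKVLAEGHIKLNPQRSTVWYMKVLAEGHIKLNPQRSTVWY"  # 40 aa


def _variant(seq: str, *subs) -> str:
    out = list(seq)
    for pos, aa in subs:
        out[pos] = aa
    return "".join(out)


@pytest.fixture
def tiny_db(tiny_tax) -> ReferenceDatabase:
    """Four proteins, nested OGs, one in-paralog (pB2 not paired with pA),
    one domain model planted on pA at 5..12."""
    pA = _BASE
    pB = _variant(_BASE, (3, "I"), (20, "V"))
    pB2 = _variant(_BASE, (3, "I"), (8, "W"), (25, "F"))
    pC = _variant(_BASE, (5, "D"), (15, "N"), (30, "Y"))
    proteins = {
        "pA": RefProtein("pA", 4, pA),
        "pB": RefProtein("pB", 5, pB),
        "pB2": RefProtein("pB2", 5, pB2),
        "pC": RefProtein("pC", 6, pC),
    }
    ogs = {
        "og_L": OrthologousGroup("og_L", 2, frozenset({"pA", "pB", "pB2"}),
                                 "left-clade family", "E"),
        "og_root": OrthologousGroup(
            "og_root", 1, frozenset({"pA", "pB", "pB2", "pC"}), "root family", "E"
        ),
    }
    orthologs = {("pA", "pB"), ("pA", "pC"), ("pB", "pC"), ("pB2", "pC")}
    annotations = {
        "pA": {"GO": frozenset({"GO:0001", "GO:0002"}), "name": frozenset({"nA"})},
        "pB": {
            "GO": frozenset({"GO:0001", "GO:0003"}),
            "KEGG_ko": frozenset({"K00001"}),
            "name": frozenset({"nA"}),
        },
        "pB2": {"GO": frozenset({"GO:0009"}), "name": frozenset({"nB"})},
        "pC": {
            "GO": frozenset({"GO:0001"}),
            "EC": frozenset({"1.1.1.1"}),
            "name": frozenset({"nA"}),
        },
    }
    motif = pA[4:12]  # 1-based 5..12
    pssm = np.full((8, 20), -2, dtype=np.int64)
    alpha = "ACDEFGHIKLMNPQRSTVWY"
    for i, aa in enumerate(motif):
        pssm[i, alpha.index(aa)] = 5
    models = {"DM1": DomainModel("DM1", "CL1", 8, pssm, 24.0)}
    dom_anns = [DomainAnnotation("pA", "DM1", 5, 12, 40.0)]
    db = ReferenceDatabase(
        taxonomy=tiny_tax,
        proteins=proteins,
        ogs=ogs,
        orthologs=orthologs,
        annotations=annotations,
        domain_models=models,
        domain_annotations=dom_anns,
    )
    validate(db)
    return db


@pytest.fixture(scope="session")
def small_benchmark() -> simdata.Benchmark:
    """Session-wide simulated benchmark reused by several suites."""
    params = simdata.SimParams(
        n_species=10, n_families=10, root_protein_length=120, random_seed=7
    )
    return simdata.emit_benchmark(params)


def random_taxonomy(rng, n: int) -> TaxonomyTree:
    """Uniform random parent assignment (node i attaches to a lower id)."""
    nodes = {1: TaxonNode(1, 1, "root", "no rank")}
    for i in range(2, n + 1):
        parent = int(rng.integers(1, i))
        nodes[i] = TaxonNode(i, parent, f"t{i}", "no rank")
    return TaxonomyTree.from_nodes(nodes)


def random_protein(rng, length: int) -> str:
    alpha = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(alpha[i] for i in rng.integers(0, 20, length))
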