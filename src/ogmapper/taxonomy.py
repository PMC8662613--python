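"""Rooted taxonomy tree: lineage, ancestry, LCA and subtree queries.

The taxonomy is the coordinate system for every orthologous-group level and
every scope decision downstream.  It is loaded from a flat four-column TSV
dump (``tax_id``, ``parent_id``, ``name``, ``rank``); the root is its own
parent, following the NCBI convention, which keeps lineage walks loop-free
without a null sentinel.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FormatError

_COLUMNS = ("tax_id", "parent_id", "name", "rank")


@dataclass(frozen=True)
class TaxonNode:
    """One taxon; the root is the unique node with ``parent_id == tax_id``."""

    tax_id: int
    parent_id: int
    name: str
    rank: str


@dataclass
class TaxonomyTree:
    """Validated rooted tree over :class:`TaxonNode` objects.

    Construction via :meth:`from_nodes` checks that every parent resolves,
    that exactly one root exists and that parent walks terminate, so query
    methods can assume a well-formed tree.
    """

    nodes: dict[int, TaxonNode]
    root_id: int
    _children: dict[int, list[int]] = field(default_factory=dict, repr=False)
    _depth: dict[int, int] = field(default_factory=dict, repr=False)

    @classmethod
    def from_nodes(cls, nodes: dict[int, TaxonNode]) -> "TaxonomyTree":
        if not nodes:
            raise FormatError("taxonomy has no nodes")
        roots = [t for t, n in nodes.items() if n.parent_id == n.tax_id]
        if len(roots) != 1:
            raise FormatError(f"expected exactly one root, found {len(roots)}")
        root = roots[0]
        for node in nodes.values():
            if node.parent_id not in nodes:
                raise FormatError(
                    f"taxon {node.tax_id} has unknown parent {node.parent_id}"
                )
        tree = cls(nodes=dict(nodes), root_id=root)
        children: dict[int, list[int]] = {t: [] for t in nodes}
        for node in nodes.values():
            if node.tax_id != root:
                children[node.parent_id].append(node.tax_id)
        for kids in children.values():
            kids.sort()
        tree._children = children
        # depth doubles as the acyclicity check: a parent walk longer than
        # |nodes| means a cycle that never reaches the root
        for t in nodes:
            tree._depth[t] = len(tree.lineage(t)) - 1
        return tree

    # -- queries ---------------------------------------------------------

    def __contains__(self, tax_id: int) -> bool:
        return tax_id in self.nodes

    def _check(self, tax_id: int) -> None:
        if tax_id not in self.nodes:
            raise KeyError(f"unknown tax_id {tax_id}")

    def lineage(self, tax_id: int) -> list[int]:
        """Path of tax_ids from the root (first) down to ``tax_id`` (last)."""
        self._check(tax_id)
        path = [tax_id]
        seen = {tax_id}
        cur = tax_id
        while cur != self.root_id:
            cur = self.nodes[cur].parent_id
            if cur in seen or len(path) > len(self.nodes):
                raise FormatError(f"cycle detected walking parents of {tax_id}")
            seen.add(cur)
            path.append(cur)
        path.reverse()
        return path

    def depth(self, tax_id: int) -> int:
        """Edges between the root and ``tax_id`` (root has depth 0)."""
        self._check(tax_id)
        return self._depth[tax_id]

    def lca(self, taxa) -> int:
        """Deepest node ancestral-or-equal to every taxon in ``taxa``."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of an empty taxon set is undefined")
        common = set(self.lineage(taxa[0]))
        for t in taxa[1:]:
            common &= set(self.lineage(t))
        # the common ancestors form a root-anchored chain; deepest wins
        return max(common, key=lambda t: self._depth[t])

    def is_ancestor(self, a: int, b: int) -> bool:
        """True iff ``a`` lies on the lineage of ``b`` (a == b counts)."""
        self._check(a)
        return a in self.lineage(b)

    def children(self, tax_id: int) -> list[int]:
        self._check(tax_id)
        return list(self._children[tax_id])

    def subtree(self, tax_id: int) -> set[int]:
        """``tax_id`` plus all of its descendants."""
        self._check(tax_id)
        out = set()
        stack = [tax_id]
        while stack:
            cur = stack.pop()
            out.add(cur)
            stack.extend(self._children[cur])
        return out

    def leaves(self) -> set[int]:
        return {t for t in self.nodes if not self._children[t]}

    def is_leaf(self, tax_id: int) -> bool:
        self._check(tax_id)
        return not self._children[tax_id]

    def name_of(self, tax_id: int) -> str:
        self._check(tax_id)
        return self.nodes[tax_id].name

    def __eq__(self, other) -> bool:
        if not isinstance(other, TaxonomyTree):
            return NotImplemented
        return self.nodes == other.nodes and self.root_id == other.root_id


def load_taxonomy(path) -> TaxonomyTree:
    """Load and validate a taxonomy from a 4-column TSV dump."""
    path = Path(path)
    nodes: dict[int, TaxonNode] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty taxonomy file") from None
        if tuple(header[:4]) != _COLUMNS:
            raise FormatError(
                f"{path}: expected header {list(_COLUMNS)}, got {header[:4]}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                tax_id, parent_id = int(row[0]), int(row[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer id") from exc
            if tax_id <= 0:
                raise FormatError(f"{path}:{lineno}: tax_id must be positive")
            if tax_id in nodes:
                raise FormatError(f"{path}:{lineno}: duplicate tax_id {tax_id}")
            nodes[tax_id] = TaxonNode(tax_id, parent_id, row[2], row[3])
    return TaxonomyTree.from_nodes(nodes)


def save_taxonomy(tree: TaxonomyTree, path) -> None:
    """Write the TSV dump that :func:`load_taxonomy` reads back."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for tax_id in sorted(tree.nodes):
            n = tree.nodes[tax_id]
            writer.writerow([n.tax_id, n.parent_id, n.name, n.rank])
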