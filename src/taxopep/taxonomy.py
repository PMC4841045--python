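"""Ranked taxonomy tree with lineage, rank-projection and LCA queries.

The tree is a rooted hierarchy over the eight canonical ranks
(root, superkingdom, phylum, class, order, family, genus, species).
Rank skipping along an edge is permitted (e.g. phylum -> genus), but the
rank must strictly deepen from parent to child.  The lowest common
ancestor (LCA) of a set of taxa is the deepest node shared by all of
their root-to-node lineages; it is the primitive behind placing an
observed peptide on the tree when the peptide's sequence occurs in
proteins of several species.

Taxonomies are supplied as flat TSV tables (columns: taxon_id,
parent_id, rank, name; the root row has an empty parent_id) rather than
parsed from NCBI taxdump files, which keeps fixtures self-contained.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import pandas as pd
import skbio

__all__ = [
    "RANKS",
    "RANK_INDEX",
    "TaxonomyNode",
    "TaxonomyTree",
    "load_taxonomy",
    "write_taxonomy",
    "lineage",
    "lowest_common_ancestor",
    "ancestor_at_rank",
    "to_newick",
    "from_newick",
]

#: Canonical ranks from shallowest to deepest.
RANKS: tuple[str, ...] = (
    "root",
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Rank name -> depth index (root=0 ... species=7).
RANK_INDEX: dict[str, int] = {r: i for i, r in enumerate(RANKS)}


class TaxonomyError(ValueError):
    """Raised for malformed taxonomy tables or unknown taxa."""


@dataclass(frozen=True)
class TaxonomyNode:
    """A single taxon: opaque id, display name, rank, and parent link."""

    taxon_id: str
    name: str
    rank: str
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if self.rank not in RANK_INDEX:
            raise TaxonomyError(
                f"unknown rank {self.rank!r} for taxon {self.taxon_id!r}; "
                f"expected one of {RANKS}"
            )

    @property
    def rank_index(self) -> int:
        return RANK_INDEX[self.rank]


class TaxonomyTree:
    """Validated rooted taxonomy supporting lineage and LCA queries.

    Parameters
    ----------
    nodes
        The taxa.  Exactly one must have ``parent_id`` unset (the root);
        every other node's parent must exist and have a strictly
        shallower rank.
    """

    def __init__(self, nodes: Iterable[TaxonomyNode]) -> None:
        self._nodes: dict[str, TaxonomyNode] = {}
        for node in nodes:
            if node.taxon_id in self._nodes:
                raise TaxonomyError(f"duplicate taxon_id {node.taxon_id!r}")
            self._nodes[node.taxon_id] = node
        if not self._nodes:
            raise TaxonomyError("taxonomy has no nodes")

        roots = [n for n in self._nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise TaxonomyError(
                f"expected exactly one root, found {len(roots)}: "
                f"{sorted(n.taxon_id for n in roots)}"
            )
        self._root = roots[0]

        self._children: dict[str, list[str]] = {t: [] for t in self._nodes}
        for node in self._nodes.values():
            if node.parent_id is None:
                continue
            parent = self._nodes.get(node.parent_id)
            if parent is None:
                raise TaxonomyError(
                    f"taxon {node.taxon_id!r} references unknown parent "
                    f"{node.parent_id!r}"
                )
            if node.rank_index <= parent.rank_index:
                raise TaxonomyError(
                    f"rank of {node.taxon_id!r} ({node.rank}) does not deepen "
                    f"from parent {parent.taxon_id!r} ({parent.rank})"
                )
            self._children[node.parent_id].append(node.taxon_id)
        for kids in self._children.values():
            kids.sort()

        # Strictly increasing ranks already rule out cycles among valid
        # parent links, but a disconnected component cycling on itself
        # would slip through the root check; walk every lineage once.
        self._lineage_ids: dict[str, tuple[str, ...]] = {}
        for taxon_id in self._nodes:
            self._lineage_of(taxon_id)

    def _lineage_of(self, taxon_id: str) -> tuple[str, ...]:
        cached = self._lineage_ids.get(taxon_id)
        if cached is not None:
            return cached
        chain: list[str] = []
        seen: set[str] = set()
        cur: str | None = taxon_id
        while cur is not None:
            if cur in seen:
                raise TaxonomyError(f"cycle detected at taxon {cur!r}")
            seen.add(cur)
            done = self._lineage_ids.get(cur)
            if done is not None:
                chain.extend(reversed(done))
                break
            chain.append(cur)
            cur = self._nodes[cur].parent_id
        result = tuple(reversed(chain))
        # cache every suffix of the walk
        for i, t in enumerate(result):
            self._lineage_ids.setdefault(t, result[: i + 1])
        return result

    # -- basic container protocol -------------------------------------

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[TaxonomyNode]:
        return iter(self._nodes.values())

    def __getitem__(self, taxon_id: str) -> TaxonomyNode:
        try:
            return self._nodes[taxon_id]
        except KeyError:
            raise TaxonomyError(f"unknown taxon {taxon_id!r}") from None

    @property
    def root(self) -> TaxonomyNode:
        return self._root

    @property
    def nodes(self) -> Mapping[str, TaxonomyNode]:
        return dict(self._nodes)

    def children(self, taxon_id: str) -> list[TaxonomyNode]:
        self[taxon_id]
        return [self._nodes[t] for t in self._children[taxon_id]]

    # -- queries -------------------------------------------------------

    def lineage(self, taxon_id: str) -> list[TaxonomyNode]:
        """Root-first path from the root down to ``taxon_id``."""
        self[taxon_id]
        return [self._nodes[t] for t in self._lineage_ids[taxon_id]]

    def lowest_common_ancestor(self, taxa: Iterable[str]) -> TaxonomyNode:
        """Deepest node present on every given taxon's lineage.

        ``lca({t})`` is ``t`` itself; taxa in disjoint subtrees meet at
        the root.  Raises on an empty set or an unknown taxon.
        """
        taxa = list(taxa)
        if not taxa:
            raise TaxonomyError("LCA of an empty taxon set is undefined")
        lineages = [self._lineage_ids[self[t].taxon_id] for t in taxa]
        shortest = min(lineages, key=len)
        lca_id = shortest[0]
        for depth in range(len(shortest)):
            candidate = shortest[depth]
            if all(len(ln) > depth and ln[depth] == candidate for ln in lineages):
                lca_id = candidate
            else:
                break
        return self._nodes[lca_id]

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> TaxonomyNode | None:
        """The unique lineage node at ``rank``, or None if skipped/above."""
        if rank not in RANK_INDEX:
            raise TaxonomyError(f"unknown rank {rank!r}")
        for node in self.lineage(taxon_id):
            if node.rank == rank:
                return node
        return None

    def descendants(self, taxon_id: str) -> list[TaxonomyNode]:
        """All nodes strictly below ``taxon_id`` (preorder)."""
        out: list[TaxonomyNode] = []
        stack = list(reversed(self._children[self[taxon_id].taxon_id]))
        while stack:
            t = stack.pop()
            out.append(self._nodes[t])
            stack.extend(reversed(self._children[t]))
        return out

    def subset(self, keep: Iterable[str]) -> "TaxonomyTree":
        """New tree restricted to ``keep``; parents must be kept too."""
        keep = set(keep)
        return TaxonomyTree(self._nodes[t] for t in self._nodes if t in keep)


# -- module-level operation wrappers ----------------------------------


def lineage(tree: TaxonomyTree, taxon_id: str) -> list[TaxonomyNode]:
    """Root-first lineage of ``taxon_id`` in ``tree``."""
    return tree.lineage(taxon_id)


def lowest_common_ancestor(tree: TaxonomyTree, taxa: Iterable[str]) -> TaxonomyNode:
    """LCA of a nonempty set of taxa."""
    return tree.lowest_common_ancestor(taxa)


def ancestor_at_rank(tree: TaxonomyTree, taxon_id: str, rank: str) -> TaxonomyNode | None:
    """Project a taxon to a requested rank along its lineage."""
    return tree.ancestor_at_rank(taxon_id, rank)


# -- I/O ---------------------------------------------------------------

_COLUMNS = ["taxon_id", "parent_id", "rank", "name"]


def load_taxonomy(path) -> TaxonomyTree:
    """Read a taxonomy node table (TSV) into a validated tree.

    The table must carry the columns taxon_id, parent_id, rank, name;
    exactly one row (the root) leaves parent_id empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TaxonomyError(f"taxonomy table is missing columns {missing}")
    nodes = [
        TaxonomyNode(
            taxon_id=row.taxon_id,
            name=row.name,
            rank=row.rank,
            parent_id=row.parent_id or None,
        )
        for row in df.itertuples(index=False)
    ]
    return TaxonomyTree(nodes)


def write_taxonomy(tree: TaxonomyTree, path) -> None:
    """Write the tree back to the flat TSV dialect read by load_taxonomy."""
    df = pd.DataFrame(
        [
            {
                "taxon_id": n.taxon_id,
                "parent_id": n.parent_id or "",
                "rank": n.rank,
                "name": n.name,
            }
            for n in tree
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def _label(node: TaxonomyNode, rich: bool) -> str:
    if rich:
        return f"{node.taxon_id}|{node.rank}|{node.name}"
    return node.name


def to_newick(tree: TaxonomyTree, rich_labels: bool = False) -> str:
    """Serialize to Newick.

    With ``rich_labels`` the label of each node is "taxon_id|rank|name",
    which is enough to rebuild the tree with :func:`from_newick`; plain
    labels carry display names only.
    """

    def build(taxon_id: str) -> skbio.TreeNode:
        node = tree[taxon_id]
        sk = skbio.TreeNode(name=_label(node, rich_labels))
        for child in tree.children(taxon_id):
            sk.append(build(child.taxon_id))
        return sk

    buf = io.StringIO()
    build(tree.root.taxon_id).write(buf, format="newick")
    return buf.getvalue().strip()


def from_newick(newick: str) -> TaxonomyTree:
    """Rebuild a tree from rich-label Newick produced by :func:`to_newick`."""
    sk = skbio.TreeNode.read(io.StringIO(newick), format="newick")
    nodes: list[TaxonomyNode] = []

    def walk(sknode: skbio.TreeNode, parent_id: str | None) -> None:
        parts = (sknode.name or "").split("|")
        if len(parts) != 3:
            raise TaxonomyError(
                f"newick label {sknode.name!r} is not taxon_id|rank|name; "
                "only rich-label newick can be read back"
            )
        taxon_id, rank, name = parts
        nodes.append(TaxonomyNode(taxon_id, name, rank, parent_id))
        for child in sknode.children:
            walk(child, taxon_id)

    walk(sk, None)
    return TaxonomyTree(nodes)
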