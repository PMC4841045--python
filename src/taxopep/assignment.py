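"""Split-by-taxonomy protein grouping and LCA placement of peptides.

In a combined human + microbial search space, many peptide sequences
occur in proteins of several organisms.  Left unchecked, such peptides
merge proteins from different phyla — or from human and bacteria —
into one inference group, attributing evidence to organisms it does
not support.  The split-by-taxonomy rule prevents this: every peptide
is projected to the taxa of its source proteins at a chosen *split
rank* (phylum by default), and a peptide whose projections span two or
more split-rank taxa is discarded from protein identification
entirely.  Protein groups are then formed within a single split-rank
taxon, so no group can span phyla, and quantification may further be
restricted to peptides unique to one group.

Independently of grouping, each observed peptide is placed on the
taxonomy tree at the lowest common ancestor (LCA) of its source
species, yielding a per-node count of specifically attributable
peptides — the peptide-level evidence tree.  Genera without at least
one peptide attributed at the genus node or below are pruned from that
report; their peptides are listed separately rather than re-attributed
upward, because re-attribution would inflate family-level counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .digestion import PeptideIndex
from .taxonomy import RANK_INDEX, TaxonomyNode, TaxonomyTree

__all__ = [
    "GroupingParams",
    "PeptideRecord",
    "PeptideAssignment",
    "ProteinGroup",
    "TaxonPeptideTree",
    "assign_peptide_lca",
    "build_taxon_peptide_tree",
    "group_proteins_split_by_taxonomy",
    "split_rank_projection",
]

#: Peptide statuses.
UNIQUE_TO_SPLIT_TAXON = "unique-to-one-split-taxon"
CROSS_SPLIT_SHARED = "cross-split-shared"


@dataclass(frozen=True)
class GroupingParams:
    """Split rank and grouping thresholds.

    ``split_rank`` must lie strictly between root and species; phylum is
    the default, the compromise between stringency of identification
    and retention of peptides.
    """

    split_rank: str = "phylum"
    min_peptides_per_group: int = 1
    quantify_unique_only: bool = True

    def __post_init__(self) -> None:
        if self.split_rank not in RANK_INDEX:
            raise ValueError(f"unknown rank {self.split_rank!r}")
        if not 0 < RANK_INDEX[self.split_rank] < RANK_INDEX["species"]:
            raise ValueError("split_rank must be strictly between root and species")
        if self.min_peptides_per_group < 1:
            raise ValueError("min_peptides_per_group must be >= 1")


def split_rank_projection(tree: TaxonomyTree, taxon_id: str, split_rank: str) -> str | None:
    """Project a taxon to the split rank.

    Returns the lineage node at ``split_rank`` when present; if the
    lineage skips that rank, falls back to the deepest ancestor at or
    above it (excluding root), so that every below-root taxon projects
    somewhere and the discard rule stays well defined.
    """
    target = RANK_INDEX[split_rank]
    best: str | None = None
    for node in tree.lineage(taxon_id):
        if node.rank == "root" or node.rank_index > target:
            continue
        best = node.taxon_id
    return best


@dataclass(frozen=True)
class PeptideRecord:
    """Placement of one observed peptide: sources, LCA, split projection."""

    peptide: str
    source_taxa: frozenset[str]
    lca: TaxonomyNode
    split_taxa: frozenset[str]
    status: str


@dataclass
class PeptideAssignment:
    """LCA/split annotation for all observed peptides matched in the index."""

    records: dict[str, PeptideRecord]
    unmatched: frozenset[str]
    params: GroupingParams
    tree: TaxonomyTree

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, peptide: str) -> PeptideRecord:
        return self.records[peptide]

    @property
    def cross_split_shared(self) -> frozenset[str]:
        return frozenset(
            p for p, r in self.records.items() if r.status == CROSS_SPLIT_SHARED
        )

    def to_frame(self) -> pd.DataFrame:
        peps = sorted(self.records)
        recs = [self.records[p] for p in peps]
        return pd.DataFrame(
            {
                "peptide": peps,
                "lca_taxon": [r.lca.taxon_id for r in recs],
                "lca_rank": [r.lca.rank for r in recs],
                "lca_name": [r.lca.name for r in recs],
                "source_taxa": [";".join(sorted(r.source_taxa)) for r in recs],
                "split_taxa": [";".join(sorted(r.split_taxa)) for r in recs],
                "status": [r.status for r in recs],
            }
        )


def assign_peptide_lca(
    observed: Iterable[str],
    index: PeptideIndex,
    tree: TaxonomyTree,
    params: GroupingParams | None = None,
) -> PeptideAssignment:
    """Annotate observed peptides with source taxa, LCA and split projection.

    Peptides absent from the index are collected in ``unmatched`` (never
    silently dropped).  A peptide is ``cross-split-shared`` iff its
    source taxa project to two or more split-rank taxa; such peptides
    are excluded from protein identification downstream.
    """
    if params is None:
        params = GroupingParams()
    db = index.database
    if db is None:
        raise ValueError("peptide index must be built from a database")
    for acc in db.accessions:
        if db.taxon_of(acc) not in tree:
            raise ValueError(f"database taxon {db.taxon_of(acc)!r} not in taxonomy tree")

    records: dict[str, PeptideRecord] = {}
    unmatched: set[str] = set()
    for pep in set(observed):
        accessions = index.accessions_for(pep)
        if not accessions:
            unmatched.add(pep)
            continue
        taxa = frozenset(db.taxon_of(a) for a in accessions)
        lca = tree.lowest_common_ancestor(taxa)
        split_taxa = frozenset(
            t
            for t in (split_rank_projection(tree, x, params.split_rank) for x in taxa)
            if t is not None
        )
        status = CROSS_SPLIT_SHARED if len(split_taxa) >= 2 else UNIQUE_TO_SPLIT_TAXON
        records[pep] = PeptideRecord(pep, taxa, lca, split_taxa, status)
    return PeptideAssignment(records, frozenset(unmatched), params, tree)


@dataclass
class TaxonPeptideTree:
    """Per-node counts of peptides specifically attributable to each taxon.

    ``attributed_count[t]`` is the number of distinct observed peptides
    whose LCA is node ``t``; each matched peptide is counted at exactly
    one node.  When genus pruning is on, genera lacking any peptide at
    the genus node or below are absent from ``tree``; their peptides
    are in ``pruned_peptides``.
    """

    tree: TaxonomyTree
    attributed_count: dict[str, int]
    has_unique: dict[str, bool]
    pruned_genera: frozenset[str]
    pruned_peptides: frozenset[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node in self.tree:
            rows.append(
                {
                    "taxon_id": node.taxon_id,
                    "name": node.name,
                    "rank": node.rank,
                    "attributed_peptides": self.attributed_count.get(node.taxon_id, 0),
                }
            )
        return pd.DataFrame(rows).sort_values("taxon_id", ignore_index=True)


def build_taxon_peptide_tree(
    assignment: PeptideAssignment,
    tree: TaxonomyTree,
    prune_genera_without_unique: bool = True,
) -> TaxonPeptideTree:
    """Count peptides at their LCA nodes and prune unsupported genera.

    A genus is retained iff at least one peptide has its LCA at the
    genus node or below it (i.e. the genus has at least one peptide
    unique to it among genera).  Pruned genera are removed with their
    subtrees; the peptides counted there are reported in
    ``pruned_peptides``, not re-attributed to ancestors.
    """
    counts: dict[str, int] = {}
    for rec in assignment.records.values():
        counts[rec.lca.taxon_id] = counts.get(rec.lca.taxon_id, 0) + 1

    genus_nodes = [n for n in tree if n.rank == "genus"]
    has_unique: dict[str, bool] = {}
    for g in genus_nodes:
        below = [g.taxon_id] + [d.taxon_id for d in tree.descendants(g.taxon_id)]
        has_unique[g.taxon_id] = any(counts.get(t, 0) > 0 for t in below)

    pruned_genera: set[str] = set()
    pruned_peptides: set[str] = set()
    out_tree = tree
    if prune_genera_without_unique:
        drop: set[str] = set()
        for g in genus_nodes:
            if not has_unique[g.taxon_id]:
                pruned_genera.add(g.taxon_id)
                drop.add(g.taxon_id)
                drop.update(d.taxon_id for d in tree.descendants(g.taxon_id))
        if drop:
            out_tree = tree.subset(t for t in tree.nodes if t not in drop)
            for rec in assignment.records.values():
                if rec.lca.taxon_id in drop:
                    pruned_peptides.add(rec.peptide)
            counts = {t: c for t, c in counts.items() if t not in drop}

    return TaxonPeptideTree(
        tree=out_tree,
        attributed_count=counts,
        has_unique=has_unique,
        pruned_genera=frozenset(pruned_genera),
        pruned_peptides=frozenset(pruned_peptides),
    )


@dataclass(frozen=True)
class ProteinGroup:
    """Inferred protein group confined to a single split-rank taxon.

    The leading accession (first member) carries the most identifying
    peptides, ties broken lexicographically.  ``unique_peptides`` are
    the identifying peptides matching no other surviving group — the
    only peptides used for quantification under the unique-only rule.
    """

    group_id: str
    member_accessions: tuple[str, ...]
    split_taxon: str
    identifying_peptides: frozenset[str]
    unique_peptides: frozenset[str]

    @property
    def leading_accession(self) -> str:
        return self.member_accessions[0]


def group_proteins_split_by_taxonomy(
    db,
    observed: Iterable[str],
    index: PeptideIndex,
    tree: TaxonomyTree,
    params: GroupingParams | None = None,
) -> tuple[list[ProteinGroup], PeptideAssignment]:
    """Form protein groups that cannot span split-rank taxa.

    Procedure: (1) discard cross-split-shared peptides from the
    identifying set; (2) partition the remaining peptide-to-protein map
    by the proteins' split-rank taxon; (3) within each partition merge
    proteins with identical identifying-peptide sets, then greedily
    subsume proteins whose set is a subset of a larger group's set
    (groups ordered by descending identifying-peptide count, ties
    lexicographic by leading accession); (4) drop groups with fewer
    than ``min_peptides_per_group`` identifying peptides; (5) mark as
    unique the peptides mapping to exactly one surviving group.

    Returns the groups plus the underlying :class:`PeptideAssignment`
    (which records discarded and unmatched peptides).
    """
    if params is None:
        params = GroupingParams()
    if index.params is None:
        raise ValueError("index lacks digestion parameters")
    assignment = assign_peptide_lca(observed, index, tree, params)

    # peptide -> proteins restricted to identifying (non-discarded) peptides
    protein_peps: dict[str, set[str]] = {}
    for pep, rec in assignment.records.items():
        if rec.status == CROSS_SPLIT_SHARED:
            continue
        for acc in index.accessions_for(pep):
            protein_peps.setdefault(acc, set()).add(pep)

    # partition proteins by split taxon
    partitions: dict[str, list[str]] = {}
    for acc in sorted(protein_peps):
        taxon = index.database.taxon_of(acc)
        split = split_rank_projection(tree, taxon, params.split_rank)
        if split is None:
            continue
        partitions.setdefault(split, []).append(acc)

    raw_groups: list[tuple[str, list[str], frozenset[str]]] = []
    for split_taxon in sorted(partitions):
        accs = partitions[split_taxon]
        # merge identical peptide sets
        by_set: dict[frozenset[str], list[str]] = {}
        for acc in accs:
            by_set.setdefault(frozenset(protein_peps[acc]), []).append(acc)
        candidates = [
            (peps, sorted(members)) for peps, members in by_set.items() if peps
        ]
        # greedy subset subsumption, largest identifying set first
        candidates.sort(key=lambda c: (-len(c[0]), c[1][0]))
        survivors: list[tuple[frozenset[str], list[str]]] = []
        for peps, members in candidates:
            host = next((s for s in survivors if peps <= s[0]), None)
            if host is not None:
                host[1].extend(members)
            else:
                survivors.append((peps, list(members)))
        for peps, members in survivors:
            if len(peps) < params.min_peptides_per_group:
                continue
            # leading accession: most identifying peptides, then lexicographic
            members.sort(key=lambda a: (-len(protein_peps[a]), a))
            raw_groups.append((split_taxon, members, peps))

    # deterministic ordering, then unique-peptide marking across all groups
    raw_groups.sort(key=lambda g: (g[0], -len(g[2]), g[1][0]))
    pep_group_count: dict[str, int] = {}
    for _, _, peps in raw_groups:
        for p in peps:
            pep_group_count[p] = pep_group_count.get(p, 0) + 1

    groups: list[ProteinGroup] = []
    for i, (split_taxon, members, peps) in enumerate(raw_groups, start=1):
        unique = frozenset(p for p in peps if pep_group_count[p] == 1)
        groups.append(
            ProteinGroup(
                group_id=f"PG{i:05d}",
                member_accessions=tuple(members),
                split_taxon=split_taxon,
                identifying_peptides=frozenset(peps),
                unique_peptides=unique,
            )
        )
    return groups, assignment


def protein_groups_frame(groups: Iterable[ProteinGroup]) -> pd.DataFrame:
    """proteinGroups-style table for export."""
    return pd.DataFrame(
        [
            {
                "group_id": g.group_id,
                "leading_accession": g.leading_accession,
                "members": ";".join(g.member_accessions),
                "split_taxon": g.split_taxon,
                "n_identifying_peptides": len(g.identifying_peptides),
                "n_unique_peptides": len(g.unique_peptides),
            }
            for g in groups
        ]
    )
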