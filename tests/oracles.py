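"""Independent brute-force oracles used to validate the implementation.

Each oracle recomputes a quantity by the most direct method available
(exhaustive enumeration, full sort, lineage materialization) without
touching the code path it checks.
"""

from __future__ import annotations

import numpy as np

from taxopep.taxonomy import RANKS, TaxonomyNode, TaxonomyTree


def brute_force_digest(sequence, params):
    """All substrings whose boundaries are termini or cleavage sites and
    whose internal cleavage-site count is within the missed-cleavage cap."""
    n = len(sequence)
    standard = set("ACDEFGHIKLMNPQRSTVWY")

    def is_site(i):  # bond after residue i
        if i < 0 or i >= n - 1:
            return False
        if sequence[i] not in params.cleavage_residues:
            return False
        if params.block_proline and sequence[i + 1] == "P":
            return False
        return True

    out = set()
    for start in range(n):
        if not (start == 0 or is_site(start - 1)):
            continue
        for end in range(start + 1, n + 1):
            if not (end == n or is_site(end - 1)):
                continue
            internal = sum(1 for i in range(start, end - 1) if is_site(i))
            if internal > params.max_missed_cleavages:
                continue
            pep = sequence[start:end]
            if len(pep) < params.min_length:
                continue
            if params.max_length is not None and len(pep) > params.max_length:
                continue
            if any(aa not in standard for aa in pep):
                continue
            out.add(pep)
    return out


def brute_force_lca(tree: TaxonomyTree, taxa):
    """Materialize all lineages, intersect as sets, pick the deepest node."""
    lineages = [[n.taxon_id for n in tree.lineage(t)] for t in taxa]
    common = set(lineages[0])
    for ln in lineages[1:]:
        common &= set(ln)
    # deepest = latest position on any single lineage
    deepest = max(common, key=lambda t: lineages[0].index(t))
    return deepest


def random_tree(rng: np.random.Generator, max_nodes: int = 200) -> TaxonomyTree:
    """Random ranked tree with rank skipping, for LCA property checks."""
    n = int(rng.integers(5, max_nodes + 1))
    nodes = [TaxonomyNode("n0", "root", "root", None)]
    ranks = [0]
    for i in range(1, n):
        parent = int(rng.integers(0, i))
        if ranks[parent] >= len(RANKS) - 1:
            parent = 0  # species cannot have children; reattach to root
        rank_idx = int(rng.integers(ranks[parent] + 1, len(RANKS)))
        nodes.append(
            TaxonomyNode(f"n{i}", f"node {i}", RANKS[rank_idx], f"n{parent}")
        )
        ranks.append(rank_idx)
    return TaxonomyTree(nodes)


def brute_force_discarded(tree, index, observed, split_rank):
    """Peptides whose source taxa project to >= 2 split-rank taxa.

    Projection oracle: walk each full lineage and keep the deepest
    below-root node not deeper than the split rank.
    """
    target = RANKS.index(split_rank)
    discarded = set()
    for pep in observed:
        accs = index.accessions_for(pep)
        if not accs:
            continue
        projections = set()
        for acc in accs:
            taxon = index.database.taxon_of(acc)
            proj = None
            for node in tree.lineage(taxon):
                if node.rank != "root" and node.rank_index <= target:
                    proj = node.taxon_id
            if proj is not None:
                projections.add(proj)
        if len(projections) >= 2:
            discarded.add(pep)
    return discarded


def brute_force_topn(evidence, pools, top_n):
    """Full-sort top-N genus abundance: per genus and sample, sort every
    nonzero pool intensity descending and sum the first top_n."""
    out = {}
    for genus, peps in pools.items():
        if len(peps) < top_n:
            continue
        row = {}
        for s in evidence.samples:
            vals = sorted(
                (float(evidence.intensities.at[p, s]) for p in peps), reverse=True
            )
            row[s] = sum(v for v in vals[:top_n] if v > 0)
        out[genus] = row
    return out
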