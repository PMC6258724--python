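"""Lineage delineation by branch-length collapse on a marker-gene phylogeny.

Tips are partitioned into lineages by a pre-order traversal: at each
internal node, if the mean pairwise patristic distance among the clade's
tips falls below the collapse threshold (default 0.6 substitutions/site),
the whole clade becomes one lineage and the traversal does not descend;
otherwise it recurses into the children.  Tips reached individually form
singleton lineages, so the result is always a partition of the tip set.

A lineage is *novel* when every member tip is a query genome (no
described reference falls inside the clade); novel lineages are
cross-checked against AAI group structure to grade candidate phyla.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from magdelin import aai as aai_mod
from magdelin.types import AAIMatrix, Lineage, PhyloTree, QUERY


def patristic_distances(ptree: PhyloTree) -> pd.DataFrame:
    """Symmetric tip x tip matrix of path-length (patristic) distances."""
    pdm = ptree.tree.phylogenetic_distance_matrix()
    labels = sorted(ptree.tip_labels())
    taxa = {t.label: t for t in ptree.tree.taxon_namespace if t.label in set(labels)}
    mat = pd.DataFrame(0.0, index=labels, columns=labels, dtype=float)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            d = pdm.patristic_distance(taxa[la], taxa[lb])
            mat.loc[la, lb] = mat.loc[lb, la] = d
    return mat


def _clade_tips(node) -> list[str]:
    return [leaf.taxon.label for leaf in node.leaf_iter()]


def mean_intra_distance(
    ptree: PhyloTree, node, distances: Optional[pd.DataFrame] = None
) -> float:
    """Mean pairwise patristic distance among the tips under ``node``.

    A single-tip clade has mean 0 by convention.
    """
    tips = _clade_tips(node)
    if len(tips) < 2:
        return 0.0
    if distances is None:
        distances = patristic_distances(ptree)
    sub = distances.loc[tips, tips].to_numpy()
    n = len(tips)
    iu = np.triu_indices(n, k=1)
    return float(sub[iu].mean())


def _midpoint_reroot(tree) -> None:
    """Root ``tree`` at the midpoint of its longest tip-to-tip path.

    Deterministic: the longest path breaks ties by lexicographic tip labels.
    When the midpoint falls exactly on an internal node the tree is rooted
    at that node; otherwise the containing edge is split.
    """
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    if len(leaves) < 2:
        return
    pdm = tree.phylogenetic_distance_matrix()
    best = None
    for i, u in enumerate(leaves):
        for v in leaves[i + 1 :]:
            d = pdm.patristic_distance(u.taxon, v.taxon)
            key = (-d, u.taxon.label, v.taxon.label)
            if best is None or key < best[0]:
                best = (key, u, v, d)
    _, u, v, dmax = best
    if dmax <= 0:
        return

    def ancestors(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out

    chain_u, chain_v = ancestors(u), ancestors(v)
    ids_v = {id(n) for n in chain_v}
    mrca = next(n for n in chain_u if id(n) in ids_v)
    up = []  # child nodes of the path edges, walking u -> mrca
    for n in chain_u:
        if n is mrca:
            break
        up.append(n)
    down = []  # child nodes of the path edges, walking mrca -> v
    for n in chain_v:
        if n is mrca:
            break
        down.append(n)
    down.reverse()

    half = dmax / 2.0
    eps = 1e-9 * max(dmax, 1.0)
    cum = 0.0  # distance walked from u
    for n in up:
        length = float(n.edge.length)
        if cum + length > half + eps:
            # split: the child end of this edge is nearer u, at distance cum
            into_child = half - cum
            tree.reroot_at_edge(n.edge, length1=length - into_child, length2=into_child)
            return
        cum += length
        if abs(cum - half) <= eps:
            tree.reroot_at_node(n.parent_node)
            return
    for n in down:
        length = float(n.edge.length)
        if cum + length > half + eps:
            # the parent end of this edge is nearer u, at distance cum
            from_parent = half - cum
            tree.reroot_at_edge(n.edge, length1=from_parent, length2=length - from_parent)
            return
        cum += length
        if abs(cum - half) <= eps and not n.is_leaf():
            tree.reroot_at_node(n)
            return


def _rooted_tree(ptree: PhyloTree) -> PhyloTree:
    """Midpoint-root an unrooted input; rooted trees pass through unchanged."""
    if ptree.tree.is_rooted:
        return ptree
    tree = ptree.tree.clone(depth=1)
    tree.is_rooted = True
    _midpoint_reroot(tree)
    return PhyloTree(tree=tree, source=dict(ptree.source))


def collapse_lineages(ptree: PhyloTree, threshold: float = 0.6) -> list[Lineage]:
    """Partition tips into maximal clades with mean intra distance < threshold."""
    if threshold <= 0:
        raise ValueError(f"collapse threshold must be positive, got {threshold}")
    ptree = _rooted_tree(ptree)
    distances = patristic_distances(ptree)
    lineages: list[Lineage] = []

    def visit(node) -> None:
        tips = _clade_tips(node)
        if len(tips) == 1:
            lineages.append(
                Lineage(
                    lineage_id="",
                    members=tips,
                    mean_intra_distance=0.0,
                    novel=all(ptree.source[t] == QUERY for t in tips),
                )
            )
            return
        mean_d = mean_intra_distance(ptree, node, distances)
        if mean_d < threshold:
            lineages.append(
                Lineage(
                    lineage_id="",
                    members=sorted(tips),
                    mean_intra_distance=mean_d,
                    novel=all(ptree.source[t] == QUERY for t in tips),
                )
            )
            return
        for child in node.child_nodes():
            visit(child)

    visit(ptree.tree.seed_node)
    # deterministic ids by first member
    lineages.sort(key=lambda lin: lin.members[0])
    for k, lin in enumerate(lineages, start=1):
        lin.lineage_id = f"L{k:03d}"
    # partition check (defensive; the traversal guarantees it)
    all_members = [t for lin in lineages for t in lin.members]
    if sorted(all_members) != sorted(ptree.tip_labels()):
        raise AssertionError("lineages do not partition the tip set")
    return lineages


def classify_novel(lineage: Lineage, ptree: PhyloTree) -> bool:
    """Novel iff every member tip is tagged query."""
    return all(ptree.source[t] == QUERY for t in lineage.members)


def delineation_report(
    lineages: list[Lineage],
    matrix: Optional[AAIMatrix] = None,
    grouping: Optional[Mapping[str, str]] = None,
    singleton_floor: float = 50.0,
) -> pd.DataFrame:
    """Join tree lineages with the AAI novelty verdict.

    ``grouping`` maps genome id -> group for the AAI check; when omitted
    it is derived from lineage membership (restricted to genomes present
    in the AAI matrix).  Lineages that are novel on the tree *and*
    AAI-confirmed are graded 'candidate'; novel but unconfirmed lineages
    are 'tree-only'; lineages containing reference tips are 'not-novel'.
    """
    if grouping is None and matrix is not None:
        grouping = {
            member: lin.lineage_id
            for lin in lineages
            for member in lin.members
            if member in set(matrix.genomes)
        }
    rows = []
    for lin in lineages:
        verdict = ""
        if lin.novel and matrix is not None and grouping:
            in_matrix = [m for m in lin.members if m in set(matrix.genomes)]
            group_ids = {grouping[m] for m in in_matrix if m in grouping}
            if len(group_ids) == 1:
                verdict = aai_mod.confirm_novel_group(
                    matrix, grouping, group_ids.pop(), singleton_floor
                )
            else:
                verdict = aai_mod.INDETERMINATE
        if not lin.novel:
            status = "not-novel"
        elif verdict in (aai_mod.CONFIRMED, aai_mod.CONFIRMED_WEAK):
            status = "candidate"
        else:
            status = "tree-only"
        rows.append(
            {
                "lineage_id": lin.lineage_id,
                "n_members": len(lin.members),
                "members": ",".join(lin.members),
                "mean_intra_distance": lin.mean_intra_distance,
                "novel": lin.novel,
                "aai_verdict": verdict,
                "status": status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lineage_id",
            "n_members",
            "members",
            "mean_intra_distance",
            "novel",
            "aai_verdict",
            "status",
        ],
    )
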