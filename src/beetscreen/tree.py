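"""Neighbor-joining trees with optional bootstrap support.

The NJ implementation is the standard Saitou–Nei/Studier–Keppler algorithm
(Q-matrix pair selection, the usual branch-length formulas), vectorised
over the working distance matrix and made deterministic by breaking Q ties
on the lexicographically smallest (taxon id, taxon id) pair. Negative
estimated branch lengths are clamped to zero (they carry no biological
meaning and downstream UniFrac requires non-negative lengths).

Trees are scikit-bio ``TreeNode`` objects, so newick serialisation,
midpoint rooting and tip-to-tip path distances come with the container.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .distance import distance_matrix
from .io import Alignment, SequenceRecord

__all__ = [
    "neighbor_joining",
    "patristic",
    "bootstrap_support",
    "read_newick",
    "write_newick",
    "midpoint_root",
]


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Build an unrooted NJ tree from a distance matrix.

    For an additive matrix the returned tree's patristic distances
    reproduce the input exactly (up to float error).
    """
    ids = list(matrix.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("neighbor joining requires at least 2 taxa")
    if n == 2:
        d = float(matrix[ids[0], ids[1]])
        half = max(d / 2.0, 0.0)
        a, b = TreeNode(name=ids[0], length=half), TreeNode(name=ids[1], length=half)
        return TreeNode(children=[a, b])

    D = matrix.data.astype(np.float64).copy()
    nodes = [TreeNode(name=i) for i in ids]
    labels = list(ids)  # smallest leaf label under each working node
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        Q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # deterministic tie-break on leaf labels
        ties = np.argwhere(Q == qmin)
        best = min(
            (tuple(sorted((labels[active[a]], labels[active[b]]))), (a, b))
            for a, b in ties
        )
        ai, bi = best[1]
        i, j = active[ai], active[bi]
        dij = sub[ai, bi]
        li = 0.5 * dij + (totals[ai] - totals[bi]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = float(li)
        child_j.length = float(lj)
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining taxa
        new_d = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = new_d
        D[np.asarray(active), i] = new_d
        D[i, i] = 0.0
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    i, j = active
    d = float(D[i, j])
    a, b = nodes[i], nodes[j]
    # attach the last two working nodes with the remaining distance split
    if a.is_tip() and not b.is_tip():
        a, b = b, a
    if not a.is_tip():
        b.length = max(d, 0.0)
        a.append(b)
        return a
    a.length = max(d / 2.0, 0.0)
    b.length = max(d / 2.0, 0.0)
    return TreeNode(children=[a, b])


def patristic(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distances."""
    return tree.tip_tip_distances()


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Midpoint-rooted copy of the tree (UniFrac needs a root)."""
    return tree.copy().root_at_midpoint()


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalised as the smaller side
    (ties by sorted tip names) so rooting does not matter."""
    tips = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = tips - side
        if len(side) < 2 or len(other) < 2:
            continue  # trivial split
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        parts.add(canon)
    return parts


def bootstrap_support(
    alignment: Alignment,
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "jukes_cantor",
) -> dict[frozenset[str], float]:
    """Column-resampling bootstrap support for the NJ point-estimate tree.

    Returns support (fraction of replicate trees containing the
    bipartition) keyed by canonical bipartition of the point tree.
    """
    if alignment.length < 2:
        raise ValueError("alignment too short to bootstrap (< 2 columns)")
    point = neighbor_joining(distance_matrix(alignment, model=model))
    target = _bipartitions(point)
    if not target:
        return {}
    rng = np.random.default_rng(seed)
    arr = alignment.to_array()
    hits = {bp: 0 for bp in target}
    for _ in range(n_replicates):
        cols = rng.integers(0, alignment.length, size=alignment.length)
        rep_records = [
            SequenceRecord(r.id, arr[k, cols].tobytes().decode("ascii"))
            for k, r in enumerate(alignment.records)
        ]
        try:
            rep_tree = neighbor_joining(distance_matrix(Alignment(rep_records), model=model))
        except ValueError:
            continue  # replicate with no comparable columns for some pair
        rep_parts = _bipartitions(rep_tree)
        for bp in target:
            if bp in rep_parts:
                hits[bp] += 1
    return {bp: hits[bp] / n_replicates for bp in target}


def read_newick(text_or_path) -> TreeNode:
    """Parse newick text (or a file path) into a TreeNode."""
    s = str(text_or_path)
    if s.lstrip().startswith("("):
        import io as _io

        tree = TreeNode.read(_io.StringIO(s), format="newick")
    else:
        tree = TreeNode.read(s, format="newick")
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        dupes = sorted({x for x in names if names.count(x) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes!r}")
    return tree


def write_newick(tree: TreeNode, path=None) -> str:
    """Serialise to newick; returns the text, optionally also writing it."""
    import io as _io

    buf = _io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
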