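"""Abundance-weighted UniFrac and principal coordinate analysis.

Weighted UniFrac between communities A and B on a rooted tree is
``sum_i b_i |A_i - B_i|`` over branches i, where ``b_i`` is the branch
length and ``A_i`` the fraction of community A descending from the branch.
The normalised variant divides by ``sum_i b_i (A_i + B_i)`` so the result
lies in [0, 1]. PCoA is classical metric scaling: Gower double-centering
of -D^2/2 followed by an eigendecomposition; negative eigenvalues are
reported but excluded from coordinates and variance fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .cluster import OTUTable
from .tree import midpoint_root

__all__ = [
    "CommunityProfile",
    "OrdinationResult",
    "weighted_unifrac",
    "unifrac_matrix",
    "pcoa",
]


@dataclass(frozen=True)
class CommunityProfile:
    """Relative abundance over tree leaves for one library."""

    library_id: str
    abundances: Mapping[str, float]

    def __post_init__(self):
        vals = np.array(list(self.abundances.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError(f"negative abundance in profile {self.library_id!r}")
        if vals.size and abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"profile {self.library_id!r} sums to {vals.sum():.12f}, not 1"
            )


def _ensure_rooted(tree: TreeNode) -> TreeNode:
    if len(tree.children) > 2:
        return midpoint_root(tree)
    return tree


def _branch_fractions(tree: TreeNode, profiles: list[CommunityProfile]):
    """Per-branch (length, per-profile descendant fraction) arrays.

    Single postorder accumulation; every branch with a defined length
    contributes, including pendant edges.
    """
    leaf_names = {t.name for t in tree.tips()}
    for p in profiles:
        missing = set(p.abundances) - leaf_names
        if missing:
            raise ValueError(
                f"profile {p.library_id!r} references leaves absent from the "
                f"tree: {sorted(missing)[:5]!r}"
            )
    k = len(profiles)
    lengths = []
    fracs = []
    acc: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = np.array(
                [p.abundances.get(node.name, 0.0) for p in profiles], dtype=float
            )
        else:
            vec = np.zeros(k)
            for child in node.children:
                vec += acc[id(child)]
        acc[id(node)] = vec
        if node.parent is not None:
            lengths.append(float(node.length or 0.0))
            fracs.append(vec)
    return np.array(lengths), np.array(fracs)


def weighted_unifrac(
    tree: TreeNode,
    a: CommunityProfile,
    b: CommunityProfile,
    normalized: bool = False,
) -> float:
    """Abundance-weighted UniFrac distance between two profiles."""
    tree = _ensure_rooted(tree)
    lengths, fracs = _branch_fractions(tree, [a, b])
    raw = float(np.sum(lengths * np.abs(fracs[:, 0] - fracs[:, 1])))
    if not normalized:
        return raw
    denom = float(np.sum(lengths * (fracs[:, 0] + fracs[:, 1])))
    if denom == 0.0:
        return 0.0
    return raw / denom


def table_profiles(
    table: OTUTable, leaf_map: Mapping[str, str] | None = None
) -> list[CommunityProfile]:
    """One CommunityProfile per library; ``leaf_map`` maps otu_id to the
    tree leaf name (identity by default)."""
    rel = table.relative_abundance()
    profiles = []
    for lib in table.library_ids:
        col = rel[lib]
        ab: dict[str, float] = {}
        for otu, frac in col.items():
            if frac <= 0:
                continue
            leaf = leaf_map.get(otu, otu) if leaf_map else otu
            ab[leaf] = ab.get(leaf, 0.0) + float(frac)
        profiles.append(CommunityProfile(lib, ab))
    return profiles


def unifrac_matrix(
    tree: TreeNode,
    table: OTUTable,
    leaf_map: Mapping[str, str] | None = None,
    normalized: bool = False,
) -> DistanceMatrix:
    """Pairwise weighted UniFrac over every library of an OTU table."""
    tree = _ensure_rooted(tree)
    profiles = table_profiles(table, leaf_map)
    lengths, fracs = _branch_fractions(tree, profiles)
    k = len(profiles)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            raw = float(np.sum(lengths * np.abs(fracs[:, i] - fracs[:, j])))
            if normalized:
                denom = float(np.sum(lengths * (fracs[:, i] + fracs[:, j])))
                raw = raw / denom if denom else 0.0
            d[i, j] = d[j, i] = raw
    return DistanceMatrix(d, [p.library_id for p in profiles])


@dataclass(frozen=True)
class OrdinationResult:
    """Sample coordinates on the positive-eigenvalue axes."""

    coordinates: pd.DataFrame  # samples x axes ("PC1", "PC2", ...)
    eigenvalues: np.ndarray  # all eigenvalues, descending (may be negative)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(matrix, ids=None, eps: float = 1e-10) -> OrdinationResult:
    """Classical (Gower) principal coordinate analysis.

    Accepts a scikit-bio DistanceMatrix or a plain square array (with
    optional ``ids``).
    """
    if isinstance(matrix, DistanceMatrix):
        D = matrix.data.astype(np.float64)
        ids = list(matrix.ids)
    else:
        D = np.asarray(matrix, dtype=np.float64)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("PCoA requires a square distance matrix")
        ids = list(ids) if ids is not None else [f"s{i}" for i in range(D.shape[0])]
    if not np.allclose(D, D.T):
        raise ValueError("PCoA requires a symmetric distance matrix")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = eps * max(abs(eigvals[0]), 1.0)
    pos = eigvals > tol
    lam = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(lam)
    # sign convention: the largest-magnitude loading of each axis positive
    for k in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, k]))
        if coords[pivot, k] < 0:
            coords[:, k] = -coords[:, k]
    prop = lam / lam.sum() if lam.size else lam
    frame = pd.DataFrame(
        coords,
        index=ids,
        columns=[f"PC{k + 1}" for k in range(coords.shape[1])],
    )
    return OrdinationResult(frame, eigvals, prop)
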