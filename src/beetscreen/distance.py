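"""Pairwise evolutionary distances from an alignment.

Two models are provided: the uncorrected proportion of differing sites
(p-distance, the natural scale for a "97% identity" OTU threshold) and the
Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3), the default of the classic
PHYLIP-style distance tools. Columns where either row carries a gap ("-",
".") or an ambiguous base ("N") are excluded pair by pair (pairwise
deletion); "U" is treated as "T".
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix

from .io import Alignment, SequenceRecord

__all__ = ["pairwise_distance", "distance_matrix", "JCSaturationError"]

MODELS = ("p", "jukes_cantor")
GAP_POLICIES = ("pairwise",)

#: p-distance at and beyond which the Jukes-Cantor log is undefined
JC_LIMIT = 0.75


class JCSaturationError(ValueError):
    """Raised when p >= 3/4 makes the Jukes-Cantor distance undefined."""


def _encode(residues: str) -> np.ndarray:
    """Map residues to integer codes; 0..3 = ACGT, -1 = missing (gap/N)."""
    table = np.full(256, -1, dtype=np.int8)
    for i, base in enumerate("ACGT"):
        table[ord(base)] = i
    table[ord("U")] = table[ord("T")]
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return table[arr]


def _jc_transform(p: np.ndarray | float, context: str = "") -> np.ndarray | float:
    if np.any(np.asarray(p) >= JC_LIMIT):
        raise JCSaturationError(
            f"p-distance >= {JC_LIMIT} saturates the Jukes-Cantor model"
            + (f" ({context})" if context else "")
        )
    return -0.75 * np.log1p(-(4.0 / 3.0) * p)


def pairwise_distance(
    row_a: SequenceRecord | str,
    row_b: SequenceRecord | str,
    model: str = "jukes_cantor",
    gap_policy: str = "pairwise",
) -> float:
    """Distance between two equal-length aligned rows.

    Parameters
    ----------
    model : "p" or "jukes_cantor"
    gap_policy : only "pairwise" (pairwise deletion) is supported; the
        argument is kept explicit so the convention is visible at call sites.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    a = row_a.residues if isinstance(row_a, SequenceRecord) else row_a.upper()
    b = row_b.residues if isinstance(row_b, SequenceRecord) else row_b.upper()
    if len(a) != len(b):
        raise ValueError(f"rows differ in length: {len(a)} vs {len(b)}")
    ca, cb = _encode(a), _encode(b)
    comparable = (ca >= 0) & (cb >= 0)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable (non-gap, non-N) columns between rows")
    p = float((ca[comparable] != cb[comparable]).sum()) / n_comp
    if model == "p":
        return p
    return float(_jc_transform(p))


def _pairwise_counts(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match and comparable-site counts for all row pairs, via BLAS.

    codes: (n, L) int8, -1 for missing. Returns (matches, comparable),
    both (n, n) float64.
    """
    n, L = codes.shape
    valid = (codes >= 0).astype(np.float32)
    onehot = np.zeros((n, 4 * L), dtype=np.float32)
    for k in range(4):
        onehot[:, k * L : (k + 1) * L] = codes == k
    matches = onehot @ onehot.T
    comparable = valid @ valid.T
    return matches.astype(np.float64), comparable.astype(np.float64)


def distance_matrix(
    alignment: Alignment,
    model: str = "jukes_cantor",
    gap_policy: str = "pairwise",
) -> DistanceMatrix:
    """All-pairs distances under the chosen model.

    Equivalent to looping :func:`pairwise_distance` over every pair (the
    test suite asserts this) but computed with one-hot matrix products so
    study-scale alignments (thousands of rows) stay fast.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    if len(alignment) < 2:
        raise ValueError("distance matrix requires at least 2 rows")
    codes = np.vstack([_encode(r.residues) for r in alignment.records])
    matches, comparable = _pairwise_counts(codes)
    if np.any(comparable[~np.eye(len(alignment), dtype=bool)] == 0):
        ii, jj = np.where(comparable == 0)
        pair = next((alignment.ids[i], alignment.ids[j]) for i, j in zip(ii, jj) if i != j)
        raise ValueError(f"no comparable columns between rows {pair[0]!r} and {pair[1]!r}")
    with np.errstate(invalid="ignore"):
        p = (comparable - matches) / comparable
    np.fill_diagonal(p, 0.0)
    p = np.clip((p + p.T) / 2.0, 0.0, 1.0)  # exact symmetry despite float32 BLAS
    if model == "jukes_cantor":
        off = ~np.eye(p.shape[0], dtype=bool)
        if np.any(p[off] >= JC_LIMIT):
            ii, jj = np.where((p >= JC_LIMIT) & off)
            pair = (alignment.ids[ii[0]], alignment.ids[jj[0]])
            raise JCSaturationError(
                f"p-distance >= {JC_LIMIT} between rows {pair[0]!r} and {pair[1]!r}"
            )
        d = np.zeros_like(p)
        d[off] = -0.75 * np.log1p(-(4.0 / 3.0) * p[off])
    else:
        d = p
    return DistanceMatrix(d, alignment.ids)
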