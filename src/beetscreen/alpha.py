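"""Per-library alpha diversity: richness, coverage and evenness.

Conventions (the classic mothur-era clone-library set):

* Good's coverage  Cx = 1 - n1/N, with n1 the number of singleton OTUs.
* Chao1 (bias-corrected)  S_obs + n1(n1-1) / (2(n2+1)).
* ACE with the rare/abundant split at 10 and the squared coefficient of
  variation clamped at zero; falls back to S_obs (flagged) when C_ACE = 0.
* Shannon H' in natural log.
* Inverse Simpson with the unbiased finite-sample form
  D = sum n_i(n_i-1) / (N(N-1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import OTUTable

__all__ = [
    "AbundanceVector",
    "AlphaSummary",
    "coverage",
    "chao1",
    "ace",
    "shannon",
    "inverse_simpson",
    "summarize",
]


@dataclass(frozen=True)
class AbundanceVector:
    """Non-zero OTU counts for one library."""

    counts: np.ndarray

    def __init__(self, counts):
        arr = np.asarray(counts)
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            arr = np.round(arr).astype(np.int64)
        arr = arr.astype(np.int64, copy=False)
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr[arr > 0])

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def s_obs(self) -> int:
        return int(self.counts.size)

    @property
    def n1(self) -> int:
        return int((self.counts == 1).sum())

    @property
    def n2(self) -> int:
        return int((self.counts == 2).sum())


def _vec(v) -> AbundanceVector:
    return v if isinstance(v, AbundanceVector) else AbundanceVector(v)


def coverage(v) -> float:
    """Good's coverage Cx = 1 - n1/N (fraction, not percent)."""
    v = _vec(v)
    if v.N == 0:
        raise ValueError("empty abundance vector")
    return 1.0 - v.n1 / v.N


def chao1(v) -> float:
    """Bias-corrected Chao1 richness estimate."""
    v = _vec(v)
    if v.N == 0:
        raise ValueError("empty abundance vector")
    return v.s_obs + v.n1 * (v.n1 - 1) / (2.0 * (v.n2 + 1))


def ace(v, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator.

    Returns S_obs (with a warning) when every rare OTU is a singleton
    (C_ACE = 0), where the estimator is undefined.
    """
    v = _vec(v)
    if v.N == 0:
        raise ValueError("empty abundance vector")
    c = v.counts
    rare = c[c <= rare_cutoff]
    s_abund = int((c > rare_cutoff).sum())
    s_rare = int(rare.size)
    n_rare = int(rare.sum())
    if s_rare == 0:
        return float(v.s_obs)
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        warnings.warn(
            "all rare OTUs are singletons; ACE undefined, returning S_obs",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(v.s_obs)
    ss = sum(i * (i - 1) * int((rare == i).sum()) for i in range(1, rare_cutoff + 1))
    gamma2 = max(
        (s_rare / c_ace) * ss / (n_rare * (n_rare - 1)) - 1.0 if n_rare > 1 else 0.0,
        0.0,
    )
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def shannon(v) -> float:
    """Shannon entropy H' in nats."""
    v = _vec(v)
    if v.N == 0:
        raise ValueError("empty abundance vector")
    p = v.counts / v.N
    return float(-(p * np.log(p)).sum())


def inverse_simpson(v) -> float:
    """Reciprocal of the unbiased Simpson concentration
    D = sum n_i(n_i-1) / (N(N-1))."""
    v = _vec(v)
    if v.N < 2:
        raise ValueError("inverse Simpson requires N >= 2")
    d = float((v.counts * (v.counts - 1.0)).sum()) / (v.N * (v.N - 1.0))
    if d == 0.0:
        raise ValueError("all OTUs are singletons; Simpson concentration is 0")
    return 1.0 / d


@dataclass(frozen=True)
class AlphaSummary:
    library_id: str
    n_sequences: int
    s_obs: int
    n_singletons: int
    coverage: float
    chao1: float
    ace: float
    shannon: float
    inverse_simpson: float


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of printed summary tables."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def summarize(table: OTUTable) -> pd.DataFrame:
    """One alpha-summary row per library (the printed table-row block)."""
    rows = []
    for lib in table.library_ids:
        v = AbundanceVector(table.counts[lib].values)
        rows.append(
            AlphaSummary(
                library_id=lib,
                n_sequences=v.N,
                s_obs=v.s_obs,
                n_singletons=v.n1,
                coverage=coverage(v),
                chao1=chao1(v),
                ace=ace(v),
                shannon=shannon(v),
                inverse_simpson=inverse_simpson(v),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("library_id")
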