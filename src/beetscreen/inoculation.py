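"""Inoculation-test evaluation: ratio normalisation, Welch's t, effect class.

Inoculation assays are run in repeated batches on different dates; absolute
dry weights drift between batches, so every seedling's weight is first
divided by the mean control weight of its own batch (and tissue). The
treated ratio sample is then compared against the control ratio sample
with Welch's two-tailed t-test, and the isolate is classed as promoting
(mean ratio > 1, p < alpha), inhibiting (mean ratio < 1, p < alpha) or
neutral. Under a multiplicative batch model the ratio step removes the
batch effect exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectResult",
    "ratios_to_control",
    "welch_t",
    "classify_effect",
    "evaluate_all",
]

CONTROL = "control"
TISSUES = ("shoot", "root", "whole")


@dataclass(frozen=True)
class EffectResult:
    isolate_id: str
    tissue: str
    mean_ratio: float
    t_statistic: float
    degrees_of_freedom: float
    p_two_tailed: float
    effect_class: str  # promoting | inhibiting | neutral
    significance_level: float | None  # 0.05, 0.01 or None


def _weights(records: pd.DataFrame, tissue: str) -> pd.Series:
    if tissue == "whole":
        return records["shoot_mg"] + records["root_mg"]
    return records[f"{tissue}_mg"]


def ratios_to_control(records: pd.DataFrame, tissue: str = "whole") -> pd.DataFrame:
    """Per-seedling dry-weight ratios to the same-batch control mean.

    ``records`` columns: isolate_id (or "control"), batch, shoot_mg,
    root_mg. Returns the records plus a ``ratio`` column; control seedlings
    are converted too, so each batch's control ratios average exactly 1.
    """
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
    w = _weights(records, tissue)
    if (w <= 0).any():
        raise ValueError("dry weights must be positive")
    out = records.copy()
    out["_w"] = w
    ratios = np.empty(len(out))
    for batch, grp in out.groupby("batch"):
        controls = grp.loc[grp["isolate_id"] == CONTROL, "_w"]
        if controls.empty:
            raise ValueError(f"batch {batch!r} has no control seedlings")
        ratios[out.index.get_indexer(grp.index)] = grp["_w"] / controls.mean()
    out["ratio"] = ratios
    return out.drop(columns="_w")


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t: returns (t, Satterthwaite df, two-tailed p).

    Degenerate case (both samples constant and equal) returns (0, df, 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def classify_effect(
    isolate_id: str,
    treated_ratios,
    control_ratios,
    tissue: str = "whole",
    alpha: float = 0.05,
    alpha_strong: float = 0.01,
) -> EffectResult:
    """Welch comparison of treated vs control ratio samples, classed by
    the sign of (mean ratio - 1) at the significance thresholds."""
    t, df, p = welch_t(treated_ratios, control_ratios)
    mean_ratio = float(np.mean(treated_ratios))
    if p < alpha:
        effect = "promoting" if mean_ratio > 1.0 else "inhibiting"
        level = alpha_strong if p < alpha_strong else alpha
    else:
        effect, level = "neutral", None
    return EffectResult(isolate_id, tissue, mean_ratio, t, df, p, effect, level)


def evaluate_all(
    records: pd.DataFrame,
    tissue: str = "whole",
    alpha: float = 0.05,
    alpha_strong: float = 0.01,
    per_batch_means: bool = False,
) -> pd.DataFrame:
    """EffectResult table for every isolate present in ``records``.

    ``per_batch_means`` collapses each batch to its mean ratio before the
    test (an alternative unit of analysis; per-seedling is the default).
    No multiple-testing correction is applied across isolates; a
    Bonferroni-adjusted significance column is appended for reference.
    """
    ratios = ratios_to_control(records, tissue)
    isolates = sorted(set(ratios["isolate_id"]) - {CONTROL})
    rows = []
    for iso in isolates:
        treated = ratios.loc[ratios["isolate_id"] == iso]
        ctrl = ratios.loc[
            (ratios["isolate_id"] == CONTROL)
            & (ratios["batch"].isin(set(treated["batch"])))
        ]
        if per_batch_means:
            t_sample = treated.groupby("batch")["ratio"].mean().values
            c_sample = ctrl.groupby("batch")["ratio"].mean().values
        else:
            t_sample = treated["ratio"].values
            c_sample = ctrl["ratio"].values
        res = classify_effect(iso, t_sample, c_sample, tissue, alpha, alpha_strong)
        rows.append(res.__dict__)
    frame = pd.DataFrame(rows).set_index("isolate_id")
    if len(frame):
        frame["significant_bonferroni"] = frame["p_two_tailed"] < alpha / len(frame)
    return frame
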