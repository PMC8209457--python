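#!/usr/bin/env python
"""Inoculation-effect evaluation of the synthetic candidate isolates.

Compares the promoting / inhibiting / neutral calls with the generator's
true effect ratios and writes results/inoculation_effects.tsv.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
PIPE = ROOT / "scratch" / "pipeline"


def main() -> None:
    effects = pd.read_csv(PIPE / "effects.tsv", sep="\t", index_col="isolate_id")
    effects.to_csv(ROOT / "results" / "inoculation_effects.tsv", sep="\t")
    counts = effects["effect_class"].value_counts()
    print(f"{counts.get('promoting', 0)} promoting, "
          f"{counts.get('inhibiting', 0)} inhibiting, "
          f"{counts.get('neutral', 0)} neutral isolates "
          f"(Welch's two-tailed t on batch-ratio data, P<0.05)")
    strong = effects[effects["significance_level"] == 0.01]
    print(f"{len(strong)} isolates significant at P<0.01")
    worst = effects["p_two_tailed"].idxmin()
    print(f"strongest effect: {worst} "
          f"(mean ratio {effects.loc[worst, 'mean_ratio']:.2f}, "
          f"p = {effects.loc[worst, 'p_two_tailed']:.2e})")


if __name__ == "__main__":
    main()
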