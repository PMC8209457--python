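#!/usr/bin/env python
"""Taxonomic composition of the synthetic study with significance flags.

Summarises the per-rank composition tables produced by the pipeline
(percent relative abundance per library, flags against the same-tissue
fully fertilised reference library).
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
PIPE = ROOT / "scratch" / "pipeline"


def main() -> None:
    for rank in ("phylum", "genus"):
        frame = pd.read_csv(PIPE / f"composition_{rank}.tsv", sep="\t", index_col="taxon")
        pct_cols = [c for c in frame.columns if not c.startswith("sig_")]
        sig_cols = [c for c in frame.columns if c.startswith("sig_")]
        n_flagged = int(frame[sig_cols].sum().sum()) if sig_cols else 0
        print(f"{rank}: {len(frame)} taxa; column sums "
              f"{frame[pct_cols].sum().round(1).min()}-"
              f"{frame[pct_cols].sum().round(1).max()}%; "
              f"{n_flagged} (taxon, library) pairs differ from the NPK reference "
              f"at P<0.05")
        top = frame[pct_cols].mean(axis=1).sort_values(ascending=False).head(5)
        print("  dominant taxa:", ", ".join(f"{t} ({v:.1f}%)" for t, v in top.items()))


if __name__ == "__main__":
    main()
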