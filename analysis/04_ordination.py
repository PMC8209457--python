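#!/usr/bin/env python
"""Weighted-UniFrac PCoA of the 12 synthetic clone libraries.

States the variance explained by the leading axes and whether PC1
separates above-ground (leaf blade, petiole) from below-ground (taproot,
lateral root) communities; writes results/pcoa_plot.png.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
PIPE = ROOT / "scratch" / "pipeline"

MARKERS = {"leaf_blade": "o", "petiole": "s", "taproot": "D", "lateral_root": "^"}


def main() -> None:
    coords = pd.read_csv(PIPE / "pcoa_coords.tsv", sep="\t", index_col="library_id")
    eigs = pd.read_csv(PIPE / "pcoa_eigenvalues.tsv", sep="\t", index_col="axis")
    samples = pd.read_csv(PIPE / "samples.tsv", sep="\t", index_col="library_id")
    prop = eigs["proportion_explained"].dropna()
    print(f"PC1 explains {100 * prop.iloc[0]:.1f}%, PC2 {100 * prop.iloc[1]:.1f}% "
          f"of weighted-UniFrac variance")

    above = [l for l in coords.index
             if samples.loc[l, "tissue"] in ("leaf_blade", "petiole")]
    below = [l for l in coords.index if l not in above]
    pc1 = coords["PC1"]
    separated = (pc1[above].max() < pc1[below].min()
                 or pc1[below].max() < pc1[above].min())
    print(f"PC1 separates above- from below-ground libraries: {separated}")

    fig, ax = plt.subplots(figsize=(5, 4))
    for lib in coords.index:
        tissue = samples.loc[lib, "tissue"]
        ax.scatter(coords.loc[lib, "PC1"], coords.loc[lib, "PC2"],
                   marker=MARKERS[tissue], label=tissue, color="k", s=35)
        ax.annotate(lib, (coords.loc[lib, "PC1"], coords.loc[lib, "PC2"]),
                    fontsize=6, xytext=(3, 3), textcoords="offset points")
    handles, labels = ax.get_legend_handles_labels()
    uniq = dict(zip(labels, handles))
    ax.legend(uniq.values(), uniq.keys(), fontsize=7)
    ax.set_xlabel(f"PC1 ({100 * prop.iloc[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * prop.iloc[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(ROOT / "results" / "pcoa_plot.png", dpi=150)
    print(f"wrote {ROOT / 'results' / 'pcoa_plot.png'}")


if __name__ == "__main__":
    main()
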