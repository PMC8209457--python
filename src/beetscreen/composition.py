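"""Taxonomic composition tables and two-library frequency comparison.

Sequences carry per-rank taxonomy labels with classifier confidences; a
sequence counts toward its rank taxon when the confidence reaches the
threshold (default 0.8), otherwise it rolls up under
"unclassified <deepest confident parent>". Frequency differences between
two libraries are tested with an exact Poisson-ratio comparison: given
counts x, y from libraries of sizes Nx, Ny, the probability of observing y
is

    P(y | x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1)),   r = Ny/Nx,

and the two-sided p doubles the smaller tail (capped at 1). The statistic
is evaluated in a canonical orientation (the two libraries sorted by
(count, size)) so that swapping the libraries cannot change the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "RANKS",
    "TaxonomyAssignment",
    "aggregate",
    "compare_two_libraries",
    "composition_report",
]

RANKS = ("phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class TaxonomyAssignment:
    """Lineage and per-rank confidence for one sequence."""

    sequence_id: str
    lineage: dict  # rank -> taxon name
    confidence: dict  # rank -> float in [0, 1]

    def taxon_at(self, rank: str, min_confidence: float) -> str:
        """Rank label, or 'unclassified <deepest confident parent>'."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        if (
            rank in self.lineage
            and self.confidence.get(rank, 0.0) >= min_confidence
        ):
            return self.lineage[rank]
        parent = "Root"
        for r in RANKS:
            if r == rank:
                break
            if r in self.lineage and self.confidence.get(r, 0.0) >= min_confidence:
                parent = self.lineage[r]
        return f"unclassified {parent}"


def assignments_from_frame(frame: pd.DataFrame) -> list[TaxonomyAssignment]:
    """Build assignments from a long-format TSV frame with columns
    sequence_id, rank, taxon, confidence."""
    out = []
    for seq_id, grp in frame.groupby("sequence_id", sort=False):
        lineage = dict(zip(grp["rank"], grp["taxon"]))
        conf = dict(zip(grp["rank"], grp["confidence"].astype(float)))
        out.append(TaxonomyAssignment(seq_id, lineage, conf))
    return out


def aggregate(
    assignments: Sequence[TaxonomyAssignment],
    metadata: pd.DataFrame,
    rank: str,
    min_confidence: float = 0.8,
    as_percent: bool = True,
) -> pd.DataFrame:
    """Taxon x library table at one rank.

    ``metadata`` is indexed by sequence_id with a ``library_id`` column.
    Returns percentages (columns sum to 100) by default, else raw counts.
    """
    missing = [a.sequence_id for a in assignments if a.sequence_id not in metadata.index]
    if missing:
        raise ValueError(f"sequences without metadata: {missing[:5]!r}")
    libs = list(dict.fromkeys(metadata["library_id"]))
    counts: dict[str, dict[str, int]] = {}
    lib_sizes = {l: 0 for l in libs}
    for a in assignments:
        lib = metadata.loc[a.sequence_id, "library_id"]
        taxon = a.taxon_at(rank, min_confidence)
        counts.setdefault(taxon, {l: 0 for l in libs})[lib] += 1
        lib_sizes[lib] += 1
    frame = pd.DataFrame(counts).T.reindex(columns=libs).fillna(0).astype(int)
    frame = frame.sort_index()
    if not as_percent:
        return frame
    sizes = pd.Series(lib_sizes)
    return 100.0 * frame.div(sizes, axis=1)


def _log_point_prob(y: np.ndarray, x: int, r: float) -> np.ndarray:
    """log P(y | x) of the exact Poisson-ratio comparison."""
    y = np.asarray(y, dtype=float)
    return (
        y * np.log(r)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.log1p(r)
    )


def _tails(x: int, n_x: int, y: int, n_y: int) -> tuple[float, float]:
    """Lower and upper exact tail probabilities of y given x."""
    r = n_y / n_x
    lower = float(np.exp(_log_point_prob(np.arange(0, y + 1), x, r)).sum())
    # upper tail by complement plus the point mass, clipped for float noise
    point = float(np.exp(_log_point_prob(np.array([y]), x, r))[0])
    upper = min(max(1.0 - lower + point, point), 1.0)
    lower = min(lower, 1.0)
    return lower, upper


def compare_two_libraries(x: int, n_x: int, y: int, n_y: int) -> float:
    """Two-sided exact p for a taxon seen x/Nx vs y/Ny times.

    Tail doubling capped at 1; evaluated with the libraries in canonical
    (count, size) order so the result is symmetric under swapping them.
    """
    for val, name in ((x, "x"), (y, "y")):
        if val < 0:
            raise ValueError(f"negative count {name}={val}")
    if n_x <= 0 or n_y <= 0:
        raise ValueError("library sizes must be positive")
    if x > n_x or y > n_y:
        raise ValueError("count exceeds library size")
    if (x, n_x) > (y, n_y):
        x, n_x, y, n_y = y, n_y, x, n_x
    lower, upper = _tails(x, n_x, y, n_y)
    return min(1.0, 2.0 * min(lower, upper))


def composition_report(
    assignments: Sequence[TaxonomyAssignment],
    metadata: pd.DataFrame,
    library_metadata: pd.DataFrame,
    *,
    ranks: Sequence[str] = RANKS,
    reference_by_tissue: dict | None = None,
    min_confidence: float = 0.8,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per-rank composition tables with significance flags against the
    same-tissue reference (the fully fertilised plot's library).

    Returns, per rank, a percent table plus one boolean flag column per
    non-reference library (``sig_<library>``) marking taxa whose frequency
    differs from the library's same-tissue reference at ``alpha``.
    No multiple-testing correction is applied across taxa, mirroring the
    single-table shading convention of clone-library reports.
    """
    out: dict[str, pd.DataFrame] = {}
    sizes = metadata.groupby("library_id").size()
    for rank in ranks:
        counts = aggregate(assignments, metadata, rank, min_confidence, as_percent=False)
        percent = 100.0 * counts.div(sizes.reindex(counts.columns), axis=1)
        report = percent.copy()
        if reference_by_tissue:
            for lib in counts.columns:
                tissue = library_metadata.loc[lib, "tissue"]
                ref = reference_by_tissue.get(tissue)
                if ref is None or ref == lib or ref not in counts.columns:
                    continue
                flags = [
                    compare_two_libraries(
                        int(counts.loc[t, ref]),
                        int(sizes[ref]),
                        int(counts.loc[t, lib]),
                        int(sizes[lib]),
                    )
                    < alpha
                    for t in counts.index
                ]
                report[f"sig_{lib}"] = flags
        out[rank] = report
    return out
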