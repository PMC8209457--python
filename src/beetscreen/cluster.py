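"""Threshold agglomerative clustering of sequences into OTUs.

The classic clone-library workflow feeds a pairwise distance matrix into
hierarchical clustering and cuts at a distance threshold (0.03 for the
"97% identity" species proxy). Furthest-neighbour (complete) linkage is the
default: it guarantees that no two members of an OTU are further apart than
the threshold, which is the property the identity cutoff is meant to convey.
Nearest and average linkage are provided for sensitivity analysis.

Merging is fully deterministic: at each step the candidate pair with the
smallest linkage distance wins, ties broken by the lexicographically
smallest (member id, member id) pair; OTU ids are assigned by descending
OTU size, then smallest member id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "OTUPartition",
    "OTUTable",
    "cluster",
    "build_table",
    "classify_otus_by_provenance",
    "representative",
]

LINKAGES = ("furthest", "nearest", "average")


@dataclass(frozen=True)
class OTUPartition:
    """Assignment of every sequence to exactly one OTU."""

    assignments: Mapping[str, str]  # sequence_id -> otu_id
    threshold: float
    linkage: str

    @property
    def otu_ids(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def members(self, otu_id: str) -> list[str]:
        return sorted(s for s, o in self.assignments.items() if o == otu_id)

    @property
    def n_otus(self) -> int:
        return len(set(self.assignments.values()))


def cluster(
    matrix: DistanceMatrix,
    threshold: float = 0.03,
    linkage: str = "furthest",
) -> OTUPartition:
    """Agglomerate until the smallest inter-cluster linkage distance
    exceeds ``threshold``.

    With ``furthest`` linkage every OTU's maximum intra-OTU pairwise
    distance is guaranteed <= threshold.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    ids = list(matrix.ids)
    n = len(ids)
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        return OTUPartition({ids[0]: "OTU-1"}, threshold, linkage)

    D = matrix.data.astype(np.float64).copy()
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    # members[i]: sorted member ids of cluster currently rooted at slot i
    members: list[list[str] | None] = [[i_] for i_ in ids]
    sizes = np.ones(n, dtype=np.int64)
    row_min = D.min(axis=1)
    row_arg = D.argmin(axis=1)

    def resolve_tie(m: float) -> tuple[int, int]:
        # among all active pairs at exactly the minimum linkage distance,
        # pick the lexicographically smallest (min member id, min member id)
        best = None
        rows = np.where(active & (row_min == m))[0]
        for i in rows:
            js = np.where(active & (D[i] == m))[0]
            for j in js:
                a, b = sorted((min(members[i]), min(members[j])))
                key = (a, b)
                if best is None or key < best[0]:
                    best = (key, (i, j) if min(members[i]) <= min(members[j]) else (j, i))
        assert best is not None
        return best[1]

    n_active = n
    while n_active > 1:
        m = row_min[active].min()
        if not np.isfinite(m) or m > threshold:
            break
        candidates = np.where(active & (row_min == m))[0]
        if len(candidates) == 1 and D[candidates[0]].min() == m and \
                (D[candidates[0]] == m).sum() == 1:
            i = int(candidates[0])
            j = int(row_arg[i])
        else:
            i, j = resolve_tie(m)
        if min(members[j]) < min(members[i]):
            i, j = j, i
        # merge slot j into slot i
        di, dj = D[i].copy(), D[j].copy()
        if linkage == "furthest":
            new = np.maximum(di, dj)
        elif linkage == "nearest":
            new = np.minimum(di, dj)
        else:  # average: size-weighted mean of pairwise distances
            new = (sizes[i] * di + sizes[j] * dj) / (sizes[i] + sizes[j])
        new[i] = np.inf
        D[i, :] = new
        D[:, i] = new
        D[j, :] = np.inf
        D[:, j] = np.inf
        active[j] = False
        n_active -= 1
        members[i] = sorted(members[i] + members[j])
        members[j] = None
        sizes[i] += sizes[j]
        row_min[i] = D[i].min()
        row_arg[i] = D[i].argmin()
        row_min[j] = np.inf
        # rows whose cached minimum involved i or j, or improved via new
        # column i, need refreshing
        for k in np.where(active)[0]:
            if k == i:
                continue
            if D[k, i] <= row_min[k]:
                row_min[k] = D[k, i]
                row_arg[k] = i
            elif row_arg[k] in (i, j):
                row_min[k] = D[k].min()
                row_arg[k] = D[k].argmin()

    clusters = [members[i] for i in np.where(active)[0] if members[i]]
    # OTU ids by descending size then smallest member id
    clusters.sort(key=lambda ms: (-len(ms), ms[0]))
    assignments: dict[str, str] = {}
    for rank, ms in enumerate(clusters, start=1):
        for s in ms:
            assignments[s] = f"OTU-{rank}"
    return OTUPartition(assignments, threshold, linkage)


@dataclass
class OTUTable:
    """OTU x library count table with per-library metadata.

    ``counts``: DataFrame indexed by otu_id, columns = library ids,
    non-negative integers. ``metadata``: DataFrame indexed by library id
    with columns tissue, condition, provenance ("clone"|"isolate"), medium.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    representatives: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"libraries without metadata: {sorted(missing)!r}")
        zero_rows = self.counts.index[(self.counts.sum(axis=1) == 0)]
        if len(zero_rows):
            self.counts = self.counts.drop(index=zero_rows)

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Column-normalised fractions (0..1)."""
        return self.counts.div(self.counts.sum(axis=0), axis=1)

    def subset_libraries(self, library_ids) -> "OTUTable":
        sub = self.counts[list(library_ids)]
        return OTUTable(
            sub.loc[sub.sum(axis=1) > 0],
            self.metadata.loc[list(library_ids)],
            self.representatives,
        )

    def to_tsv(self, path) -> None:
        header = self.metadata.loc[self.library_ids].T
        with open(path, "w") as fh:
            for row_name in ["tissue", "condition", "provenance", "medium"]:
                cells = "\t".join(str(v) for v in header.loc[row_name])
                fh.write(f"#{row_name}\t{cells}\n")
            self.counts.to_csv(fh, sep="\t", index_label="otu_id")

    @classmethod
    def from_tsv(cls, path) -> "OTUTable":
        meta_rows = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                name, *cells = line[1:].rstrip("\n").split("\t")
                meta_rows[name] = cells
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            counts = pd.read_csv(fh, sep="\t", index_col="otu_id")
        metadata = pd.DataFrame(meta_rows, index=counts.columns)
        return cls(counts, metadata)


def build_table(
    partition: OTUPartition,
    sequence_library: Mapping[str, str],
    library_metadata: pd.DataFrame,
) -> OTUTable:
    """Tabulate counts[otu, library] from a partition and a
    sequence -> library map."""
    unmapped = sorted(set(partition.assignments) - set(sequence_library))
    if unmapped:
        raise ValueError(f"sequences without a library: {unmapped[:5]!r}")
    libs = list(library_metadata.index)
    otus = partition.otu_ids
    counts = pd.DataFrame(0, index=otus, columns=libs, dtype=np.int64)
    for seq_id, otu_id in partition.assignments.items():
        counts.loc[otu_id, sequence_library[seq_id]] += 1
    return OTUTable(counts, library_metadata)


def classify_otus_by_provenance(table: OTUTable, library_ids=None) -> dict[str, int]:
    """Count OTUs that contain only isolates, both, or only clones,
    within an optional library subset."""
    if "provenance" not in table.metadata.columns:
        raise ValueError("library metadata lacks a 'provenance' column")
    libs = list(library_ids) if library_ids is not None else table.library_ids
    sub = table.counts[libs]
    prov = table.metadata.loc[libs, "provenance"]
    clone_libs = [l for l in libs if prov[l] == "clone"]
    isolate_libs = [l for l in libs if prov[l] == "isolate"]
    present = sub.sum(axis=1) > 0
    has_clone = sub[clone_libs].sum(axis=1) > 0 if clone_libs else present & False
    has_isolate = sub[isolate_libs].sum(axis=1) > 0 if isolate_libs else present & False
    return {
        "isolate_only": int((present & has_isolate & ~has_clone).sum()),
        "both": int((present & has_isolate & has_clone).sum()),
        "clone_only": int((present & has_clone & ~has_isolate).sum()),
    }


def representative(
    otu_id: str,
    table: OTUTable,
    partition: OTUPartition,
    sequence_library: Mapping[str, str],
    rule: str = "most_abundant_isolate",
) -> str:
    """Pick one deterministic representative sequence for an OTU.

    ``most_abundant_isolate``: the isolate-provenance member whose library
    contributed the most members of this OTU, ties broken by smallest
    sequence id. ``smallest_id``: the lexicographically smallest member.
    """
    if rule not in ("most_abundant_isolate", "smallest_id"):
        raise ValueError(f"unknown representative rule {rule!r}")
    members = partition.members(otu_id)
    if not members:
        raise ValueError(f"unknown OTU {otu_id!r}")
    if rule == "smallest_id":
        return members[0]
    prov = table.metadata["provenance"]
    isolates = [s for s in members if prov[sequence_library[s]] == "isolate"]
    if not isolates:
        raise ValueError(f"OTU {otu_id!r} contains no isolate sequence")
    lib_counts = pd.Series([sequence_library[s] for s in members]).value_counts()
    isolates.sort(key=lambda s: (-int(lib_counts[sequence_library[s]]), s))
    return isolates[0]
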