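"""Synthetic sugar-beet study generator with known ground truth.

Emulates the layout of the field survey this pipeline targets: twelve 16S
clone libraries (4 tissues x 3 fertilisation plots, 150-180 sequences
each) and four lateral-root isolate collections (2 plots x 2 media,
150-180 isolates each), with tissue-structured and condition-structured
OTU abundances, medium-dependent culturability bias, and planted OTUs
constructed to satisfy each candidate-selection criterion (plus
pathogen-like decoys and at least one OTU recalcitrant to isolation on
any medium).

Sampling model: counts per sample are a multinomial draw of the designed
depth with probabilities proportional to
``base_abundance x tissue_affinity[tissue] x condition_stability[cond]``
(isolate collections additionally weight by ``culturability[medium]`` on
the lateral-root abundances). A deterministic "expected" sampling mode
replaces the draw with per-OTU rounding of the expected counts, giving a
noiseless study on which full-pipeline candidate recovery is exact.

All randomness derives from one seed expanded into per-stage substreams
via ``numpy.random.SeedSequence(seed, spawn_key=(stage,))``, so identical
(design, seed) pairs give byte-identical outputs and stages can be
regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SequenceRecord, Alignment, write_fasta, fasta_text
from .selection import load_reference_lists

__all__ = [
    "StudyDesign",
    "GroundTruthOTU",
    "SyntheticStudy",
    "plant_truth",
    "draw_library",
    "draw_isolate_collection",
    "emit_sequences",
    "emit_inoculation_records",
    "simulate_study",
]

TISSUES = ("leaf_blade", "petiole", "taproot", "lateral_root")
TISSUE_CODES = {"leaf_blade": "LB", "petiole": "PE", "taproot": "TR", "lateral_root": "LR"}
CONDITIONS = ("NPK", "PK", "K")
MEDIA = ("R2A", "TSA")
ABOVE = ("leaf_blade", "petiole")
BELOW = ("taproot", "lateral_root")

PLANTED_ROLES = (
    "novel",
    "tissue_specific",
    "persistent",
    "abundant",
    "known_pgpb",
    "pathogen_like",
)
#: planted roles that must end up in the candidate set
CANDIDATE_ROLES = ("novel", "tissue_specific", "persistent", "abundant", "known_pgpb")

_PHYLA = ("Proteobacteria", "Bacteroidetes", "Actinobacteria", "Firmicutes")


@dataclass
class StudyDesign:
    """Study geometry and calibration knobs.

    Depth ranges and the 12-library x 4-collection layout mirror the field
    survey; ``background_share_cap`` / ``planted_share_floor`` bound the
    expected below-ground relative abundances of culturable background vs
    planted OTUs so that selection outcomes are determined by design rather
    than sampling accidents (tighten the cap and raise the depths for
    exact multinomial recovery).
    """

    tissues: tuple = TISSUES
    conditions: tuple = CONDITIONS
    media: tuple = MEDIA
    isolate_conditions: tuple = ("PK", "K")
    clone_depth_range: tuple = (150, 180)
    isolate_depth_range: tuple = (150, 180)
    fixed_depth: int | None = None  # overrides both ranges when set
    n_otus: int = 120
    planted_per_role: int = 2
    culturable_background_fraction: float = 0.6
    background_share_cap: float = 0.005
    above_share_floor: float = 0.008
    planted_share_floor: float = 0.02
    alignment_length: int = 1200
    sampling: str = "multinomial"  # or "expected"
    seed: int = 0

    def __post_init__(self):
        if not self.tissues or not self.conditions:
            raise ValueError("tissues and conditions must be non-empty")
        for lo, hi in (self.clone_depth_range, self.isolate_depth_range):
            if lo <= 0 or hi < lo:
                raise ValueError("depth ranges must be positive and ordered")
        if self.fixed_depth is not None and self.fixed_depth <= 0:
            raise ValueError("fixed_depth must be positive")
        if self.sampling not in ("multinomial", "expected"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")
        if self.alignment_length < 500:
            raise ValueError("alignment template must span at least 500 columns")

    @property
    def clone_samples(self) -> list[tuple[str, str, str]]:
        """(sample_id, tissue, condition) for the 12 clone libraries."""
        return [
            (f"{TISSUE_CODES.get(t, t[:2].upper())}-{c}", t, c)
            for t in self.tissues
            for c in self.conditions
        ]

    @property
    def isolate_samples(self) -> list[tuple[str, str, str]]:
        """(sample_id, condition, medium) for the isolate collections."""
        return [
            (f"LR-{c}-{m[0]}", c, m)
            for c in self.isolate_conditions
            for m in self.media
        ]


@dataclass
class GroundTruthOTU:
    otu_id: str
    lineage: dict
    base_abundance: float
    tissue_affinity: dict
    condition_stability: dict
    culturability: dict
    identity_to_reference: float
    planted_role: str = "background"

    def __post_init__(self):
        if not any(v > 0 for v in self.tissue_affinity.values()):
            raise ValueError(f"{self.otu_id}: all tissue affinities are zero")
        for d in (self.tissue_affinity, self.condition_stability):
            if any(not np.isfinite(v) or v < 0 for v in d.values()):
                raise ValueError(f"{self.otu_id}: non-finite or negative weight")
        if any(not 0.0 <= v <= 1.0 for v in self.culturability.values()):
            raise ValueError(f"{self.otu_id}: culturability outside [0, 1]")
        if not 0.0 <= self.identity_to_reference <= 1.0:
            raise ValueError(f"{self.otu_id}: identity outside [0, 1]")


def _rng(design_seed: int, *stage) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(design_seed, spawn_key=stage))


def _library_weight(otu: GroundTruthOTU, tissue: str, condition: str) -> float:
    return (
        otu.base_abundance
        * otu.tissue_affinity.get(tissue, 0.0)
        * otu.condition_stability.get(condition, 0.0)
    )


def expected_shares(truth: list[GroundTruthOTU], design: StudyDesign) -> pd.DataFrame:
    """Expected relative abundance of every OTU in every sample."""
    cols = {}
    for sample, tissue, cond in design.clone_samples:
        w = np.array([_library_weight(o, tissue, cond) for o in truth])
        cols[sample] = w / w.sum() if w.sum() else w
    for sample, cond, medium in design.isolate_samples:
        w = np.array(
            [
                _library_weight(o, "lateral_root", cond) * o.culturability.get(medium, 0.0)
                for o in truth
            ]
        )
        cols[sample] = w / w.sum() if w.sum() else w
    return pd.DataFrame(cols, index=[o.otu_id for o in truth])


def _calibrate(truth: list[GroundTruthOTU], design: StudyDesign, max_iter: int = 400):
    """Scale base abundances / below-ground affinities so expected shares
    respect the design's caps and floors (see class docstring)."""
    below_samples = [s for s, t, _ in design.clone_samples if t in BELOW]
    below_samples += [s for s, _, _ in design.isolate_samples]
    above_samples = [s for s, t, _ in design.clone_samples if t in ABOVE]
    planted = [o for o in truth if o.planted_role != "background"]
    cult_bg = [
        o
        for o in truth
        if o.planted_role == "background" and max(o.culturability.values()) > 0
    ]
    cap = design.background_share_cap
    floor_above = design.above_share_floor
    floor_planted = design.planted_share_floor
    for _ in range(max_iter):
        shares = expected_shares(truth, design)
        ok = True
        for o in planted:
            row = shares.loc[o.otu_id]
            m = min(row[s] for s in below_samples)
            if m < floor_planted:
                o.base_abundance *= min(floor_planted / max(m, 1e-12) * 1.05, 10.0)
                ok = False
        for o in cult_bg:
            row = shares.loc[o.otu_id]
            worst_below = max(row[s] for s in below_samples)
            if worst_below > cap:
                scale = cap / worst_below * 0.9
                for t in BELOW:
                    o.tissue_affinity[t] *= scale
                ok = False
            if above_samples:
                active = [
                    s
                    for s in above_samples
                    if o.condition_stability.get(s.split("-", 1)[1], 0.0) > 0
                ]
                if active:
                    best_above = max(row[s] for s in active)
                    if best_above < floor_above:
                        o.base_abundance *= min(
                            floor_above / max(best_above, 1e-12) * 1.05, 10.0
                        )
                        ok = False
        if ok:
            return
    raise RuntimeError("abundance calibration failed to converge")


def plant_truth(design: StudyDesign) -> list[GroundTruthOTU]:
    """Draw the ground-truth community: log-normal(0, 1.5) base weights,
    habitat-structured tissue affinities, per-condition stability jitter,
    medium-dependent culturability, and the configured planted roles."""
    n_planted = design.planted_per_role * len(PLANTED_ROLES)
    if design.n_otus < n_planted:
        raise ValueError(
            f"n_otus={design.n_otus} smaller than {n_planted} planted OTUs"
        )
    rng = _rng(design.seed, 0)
    pgpb_genera, pathogen_genera = load_reference_lists()
    truth: list[GroundTruthOTU] = []

    def lineage_for(idx: int, genus: str | None = None) -> dict:
        phylum = _PHYLA[idx % len(_PHYLA)]
        return {
            "phylum": phylum,
            "class": f"{phylum}_cl{idx % 3 + 1}",
            "order": f"Order_{idx % 17 + 1:02d}",
            "family": f"Family_{idx % 29 + 1:02d}",
            "genus": genus or f"Genus_{idx + 1:03d}",
        }

    def stability(kind: str, idx: int) -> dict:
        if kind == "stable":
            return {c: float(rng.uniform(0.8, 1.2)) for c in design.conditions}
        out = {c: float(rng.lognormal(0.0, 0.3)) for c in design.conditions}
        if kind == "one_zero":
            dead = design.conditions[idx % len(design.conditions)]
            out[dead] = 0.0
        return out

    idx = 0
    for role in PLANTED_ROLES:
        for _ in range(design.planted_per_role):
            if role == "known_pgpb":
                genus = pgpb_genera[idx % len(pgpb_genera)]
            elif role == "pathogen_like":
                genus = pathogen_genera[idx % len(pathogen_genera)]
            else:
                genus = None
            above_aff = 0.0 if role in ("novel", "tissue_specific") else float(
                rng.uniform(0.0, 0.05)
            )
            affinity = {
                "leaf_blade": above_aff,
                "petiole": above_aff,
                "taproot": float(rng.uniform(0.8, 1.2)),
                "lateral_root": float(rng.uniform(0.8, 1.2)),
            }
            identity = (
                float(rng.uniform(0.90, 0.965))
                if role == "novel"
                else float(rng.uniform(0.975, 1.0))
            )
            truth.append(
                GroundTruthOTU(
                    otu_id=f"GT-{idx + 1:03d}",
                    lineage=lineage_for(idx, genus),
                    base_abundance=float(rng.lognormal(0.0, 1.5)),
                    tissue_affinity={t: affinity.get(t, 0.0) for t in design.tissues},
                    condition_stability=stability("stable", idx),
                    culturability={m: 1.0 for m in design.media},
                    identity_to_reference=identity,
                    planted_role=role,
                )
            )
            idx += 1

    n_background = design.n_otus - n_planted
    n_cult = int(round(design.culturable_background_fraction * n_background))
    n_cult = min(n_cult, max(n_background - 1, 0))  # keep >= 1 unculturable
    for b in range(n_background):
        culturable = b < n_cult
        if culturable:
            # generalists: visible above ground, minor below ground
            affinity = {
                "leaf_blade": float(rng.uniform(0.9, 1.1)),
                "petiole": float(rng.uniform(0.9, 1.1)),
                "taproot": float(rng.uniform(0.2, 0.4)),
                "lateral_root": float(rng.uniform(0.2, 0.4)),
            }
            kind = rng.random()
            if kind < 0.4:  # oligotroph: R2A-leaning
                cult = {"R2A": float(rng.uniform(0.6, 1.0)), "TSA": float(rng.uniform(0.0, 0.3))}
            elif kind < 0.7:  # copiotroph: TSA-leaning
                cult = {"R2A": float(rng.uniform(0.0, 0.3)), "TSA": float(rng.uniform(0.6, 1.0))}
            else:
                cult = {m: float(rng.uniform(0.5, 1.0)) for m in design.media}
            stab = stability("one_zero", idx)
        else:
            habitat = rng.random()
            if habitat < 0.6:  # uncultured below-ground diversity
                affinity = {
                    "leaf_blade": float(rng.uniform(0.0, 0.05)),
                    "petiole": float(rng.uniform(0.0, 0.05)),
                    "taproot": float(rng.lognormal(0.0, 0.5)),
                    "lateral_root": float(rng.lognormal(0.0, 0.5)),
                }
            elif habitat < 0.8:
                affinity = {
                    "leaf_blade": float(rng.lognormal(0.0, 0.5)),
                    "petiole": float(rng.lognormal(0.0, 0.5)),
                    "taproot": float(rng.uniform(0.0, 0.05)),
                    "lateral_root": float(rng.uniform(0.0, 0.05)),
                }
            else:
                affinity = {t: float(rng.lognormal(0.0, 0.5)) for t in TISSUES}
            cult = {m: 0.0 for m in design.media}
            stab = stability("jitter", idx)
        truth.append(
            GroundTruthOTU(
                otu_id=f"GT-{idx + 1:03d}",
                lineage=lineage_for(idx),
                base_abundance=float(rng.lognormal(0.0, 1.5)),
                tissue_affinity={t: affinity.get(t, 0.0) for t in design.tissues},
                condition_stability=stab,
                culturability={m: cult.get(m, 0.0) for m in design.media},
                identity_to_reference=float(rng.uniform(0.975, 1.0)),
                planted_role="background",
            )
        )
        idx += 1

    _calibrate(truth, design)
    return truth


def _rounded_counts(probs: np.ndarray, depth: int) -> np.ndarray:
    """Deterministic per-OTU rounding of expected counts; the total is
    restored by adjusting the largest count."""
    counts = np.floor(probs * depth + 0.5).astype(np.int64)
    diff = int(depth - counts.sum())
    step = 1 if diff > 0 else -1
    for _ in range(abs(diff)):  # spread the fixup across the largest counts
        counts[np.argmax(counts)] += step
    if counts.min() < 0:
        raise ValueError("rounding produced a negative count")
    return counts


def _draw(weights: np.ndarray, depth: int, rng, sampling: str) -> np.ndarray:
    total = weights.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    probs = weights / total
    if sampling == "expected":
        return _rounded_counts(probs, depth)
    return rng.multinomial(depth, probs)


def draw_library(
    truth: list[GroundTruthOTU],
    tissue: str,
    condition: str,
    depth: int,
    rng: np.random.Generator,
    sampling: str = "multinomial",
) -> np.ndarray:
    """Multinomial clone-library counts over the ground-truth OTUs."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    weights = np.array([_library_weight(o, tissue, condition) for o in truth])
    return _draw(weights, depth, rng, sampling)


def draw_isolate_collection(
    truth: list[GroundTruthOTU],
    condition: str,
    medium: str,
    n_isolates: int,
    rng: np.random.Generator,
    sampling: str = "multinomial",
) -> np.ndarray:
    """Randomly picked colonies: lateral-root abundances biased by
    per-medium culturability."""
    if n_isolates <= 0:
        raise ValueError("n_isolates must be positive")
    weights = np.array(
        [
            _library_weight(o, "lateral_root", condition) * o.culturability.get(medium, 0.0)
            for o in truth
        ]
    )
    if weights.sum() <= 0:
        raise ValueError(f"no OTU is culturable on medium {medium!r}")
    return _draw(weights, n_isolates, rng, sampling)


def emit_sequences(
    truth: list[GroundTruthOTU],
    read_counts: pd.DataFrame,
    seed: int,
    alignment_length: int = 1200,
    threshold: float = 0.03,
) -> tuple[list[SequenceRecord], dict[str, str], dict[str, str]]:
    """Aligned reads whose pairwise geometry encodes the planted partition.

    Per-OTU representatives are the template with ~6% of columns
    substituted (separation enforced by a post-check that all
    inter-representative p-distances exceed ``threshold + 2 * read noise``);
    per-read variants stay within 0.8% of their representative, so furthest
    -neighbour clustering at the threshold recovers the partition exactly.

    ``read_counts``: OTU x sample count table. Returns (records,
    read -> sample map, read -> true OTU map).
    """
    L = alignment_length
    if L < 500:
        raise ValueError("template must span at least 500 alignment columns")
    n_otus = len(truth)
    k_read = int(0.008 * L)
    sep_min = threshold + 2.0 * (2.0 * k_read / L)  # worst-case read drift
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for attempt in range(20):
        rng = _rng(seed, 3, attempt)
        template = rng.integers(0, 4, size=L)
        m = int(round(0.06 * L))
        reps = np.tile(template, (n_otus, 1))
        for k in range(n_otus):
            pos = rng.choice(L, size=m, replace=False)
            shift = rng.integers(1, 4, size=m)
            reps[k, pos] = (reps[k, pos] + shift) % 4
        # verify separation of representatives
        eq = (reps[:, None, :] == reps[None, :, :]).sum(axis=2)
        p = 1.0 - eq / L
        np.fill_diagonal(p, 1.0)
        if p.min() > sep_min:
            break
    else:
        raise RuntimeError(
            f"could not separate {n_otus} OTUs at length {L}; "
            "increase the template length"
        )
    records: list[SequenceRecord] = []
    read_sample: dict[str, str] = {}
    read_otu: dict[str, str] = {}
    otu_index = {o.otu_id: k for k, o in enumerate(truth)}
    serial = 0
    for sample in read_counts.columns:
        col = read_counts[sample]
        for otu_id, count in col.items():
            k = otu_index[otu_id]
            for _ in range(int(count)):
                serial += 1
                read = reps[k].copy()
                n_subs = int(rng.integers(0, k_read + 1))
                if n_subs:
                    pos = rng.choice(L, size=n_subs, replace=False)
                    shift = rng.integers(1, 4, size=n_subs)
                    read[pos] = (read[pos] + shift) % 4
                rid = f"{sample}_{serial:05d}"
                residues = bases[read].tobytes().decode("ascii")
                records.append(SequenceRecord(rid, residues))
                read_sample[rid] = sample
                read_otu[rid] = truth[k].otu_id
    return records, read_sample, read_otu


def emit_inoculation_records(
    effect_map: dict[str, float],
    n_per_test: int = 12,
    n_repeats: int = 3,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Seedling dry-weight records for repeated inoculation tests.

    Every (isolate, repeat) batch has its own control group and its own
    multiplicative baseline, so absolute weights are not comparable across
    batches but ratios to the batch control mean are. ``effect_map`` gives
    each isolate's true dry-weight ratio (1.0 = no effect).
    """
    if n_per_test < 2:
        raise ValueError("n_per_test must be at least 2 for Welch's test")
    rng = _rng(seed, 5)
    base_shoot, base_root = 40.0, 15.0
    rows = []
    for iso, ratio in sorted(effect_map.items()):
        for rep in range(1, n_repeats + 1):
            batch = f"{iso}_b{rep}"
            batch_factor = float(rng.lognormal(0.0, 0.2))
            for group, mult in (("control", 1.0), ("treated", ratio)):
                label = CONTROL_LABEL if group == "control" else iso
                for _ in range(n_per_test):
                    noise = rng.lognormal(0.0, noise_sd, size=2)
                    rows.append(
                        {
                            "isolate_id": label,
                            "batch": batch,
                            "shoot_mg": base_shoot * batch_factor * mult * noise[0],
                            "root_mg": base_root * batch_factor * mult * noise[1],
                        }
                    )
    return pd.DataFrame(rows)


CONTROL_LABEL = "control"


@dataclass
class SyntheticStudy:
    design: StudyDesign
    truth: list[GroundTruthOTU]
    counts: pd.DataFrame  # true-OTU x sample counts
    sample_metadata: pd.DataFrame
    sequences: list[SequenceRecord] = field(default_factory=list)
    read_sample: dict = field(default_factory=dict)
    read_otu: dict = field(default_factory=dict)
    taxonomy: pd.DataFrame | None = None
    best_hits: pd.DataFrame | None = None
    inoculation: pd.DataFrame | None = None

    @property
    def planted_candidates(self) -> set[str]:
        """OTUs that the selection stage must recover (ground truth)."""
        return {
            o.otu_id for o in self.truth if o.planted_role in CANDIDATE_ROLES
        }

    def truth_json(self) -> str:
        payload = {
            "design": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.design).items()
            },
            "otus": [asdict(o) for o in self.truth],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.sequences:
            write_fasta(self.sequences, out / "sequences.fasta")
            pd.DataFrame(
                {
                    "sequence_id": list(self.read_sample),
                    "library_id": list(self.read_sample.values()),
                }
            ).merge(
                self.sample_metadata.reset_index(names="library_id"), on="library_id"
            ).to_csv(out / "metadata.tsv", sep="\t", index=False)
        self.counts.to_csv(out / "true_counts.tsv", sep="\t", index_label="otu_id")
        self.sample_metadata.to_csv(out / "samples.tsv", sep="\t", index_label="library_id")
        if self.taxonomy is not None:
            self.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index=False)
        if self.best_hits is not None:
            self.best_hits.to_csv(out / "best_hits.tsv", sep="\t", index=False)
        if self.inoculation is not None:
            self.inoculation.to_csv(out / "inoculation.tsv", sep="\t", index=False)
        (out / "ground_truth.json").write_text(self.truth_json())

    def fasta_bytes(self) -> bytes:
        return fasta_text(self.sequences).encode()


def _sample_metadata(design: StudyDesign) -> pd.DataFrame:
    rows = []
    for sample, tissue, cond in design.clone_samples:
        rows.append(
            {"library_id": sample, "tissue": tissue, "condition": cond,
             "provenance": "clone", "medium": "-"}
        )
    for sample, cond, medium in design.isolate_samples:
        rows.append(
            {"library_id": sample, "tissue": "lateral_root", "condition": cond,
             "provenance": "isolate", "medium": medium}
        )
    return pd.DataFrame(rows).set_index("library_id")


def _emit_taxonomy(
    truth: list[GroundTruthOTU], read_otu: dict[str, str], seed: int
) -> pd.DataFrame:
    """Long-format per-sequence taxonomy with confidences; a fifth of the
    OTUs get sub-threshold genus confidence to exercise unclassified
    roll-up."""
    rng = _rng(seed, 4)
    by_otu = {o.otu_id: o for o in truth}
    low_conf = {
        o.otu_id: rng.random() < 0.2 for o in truth
    }
    rows = []
    ranks = ("phylum", "class", "order", "family", "genus")
    for rid, otu_id in read_otu.items():
        o = by_otu[otu_id]
        for depth_i, rank in enumerate(ranks):
            conf = float(rng.uniform(0.92, 1.0) - 0.01 * depth_i)
            if rank == "genus" and low_conf[otu_id]:
                conf = float(rng.uniform(0.3, 0.79))
            rows.append(
                {
                    "sequence_id": rid,
                    "rank": rank,
                    "taxon": o.lineage[rank],
                    "confidence": round(conf, 3),
                }
            )
    return pd.DataFrame(rows)


def _emit_best_hits(truth: list[GroundTruthOTU]) -> pd.DataFrame:
    rows = []
    for o in truth:
        rows.append(
            {
                "otu_id": o.otu_id,
                "identity": round(o.identity_to_reference, 4),
                "closest_taxon": f"{o.lineage['genus']} reference_sp",
            }
        )
    return pd.DataFrame(rows)


def study_evidence(study: "SyntheticStudy"):
    """Selection-engine evidence built directly from the true OTU table.

    Mirrors what the sequence pipeline assembles after clustering (relative
    abundances, isolate availability, best hits) but indexed by the true
    OTU ids, for tests and analyses that bypass sequence emission.
    """
    from .selection import OTUEvidence

    rel = study.counts.div(study.counts.sum(axis=0), axis=1)
    meta = {
        lib: study.sample_metadata.loc[lib].to_dict()
        for lib in study.counts.columns
    }
    isolate_libs = [
        lib
        for lib in study.counts.columns
        if study.sample_metadata.loc[lib, "provenance"] == "isolate"
    ]
    out = []
    for o in study.truth:
        if study.counts.loc[o.otu_id].sum() == 0:
            continue  # never observed; the pipeline cannot see it
        has_iso = bool(study.counts.loc[o.otu_id, isolate_libs].sum() > 0)
        out.append(
            OTUEvidence(
                otu_id=o.otu_id,
                abundance={lib: float(rel.loc[o.otu_id, lib]) for lib in study.counts.columns},
                library_meta=meta,
                has_isolate=has_iso,
                best_hit_identity=o.identity_to_reference,
                best_hit_taxon=f"{o.lineage['genus']} reference_sp",
                representative_isolate=f"iso_{o.otu_id}" if has_iso else None,
            )
        )
    return out


def recovery_design(seed: int, n_otus: int = 60, depth: int = 1000) -> StudyDesign:
    """The calibration under which planted-truth recovery is exact:
    deep multinomial sampling with widened background/planted margins
    (background expected share <= 0.15%, planted floors 2%)."""
    return StudyDesign(
        seed=seed,
        n_otus=n_otus,
        fixed_depth=depth,
        background_share_cap=0.0015,
        sampling="multinomial",
    )


def simulate_study(
    design: StudyDesign,
    include_sequences: bool = True,
    include_inoculation: bool = True,
) -> SyntheticStudy:
    """Generate the complete synthetic study for a design."""
    truth = plant_truth(design)
    depth_rng = _rng(design.seed, 1)
    meta = _sample_metadata(design)
    counts = {}
    for k, (sample, tissue, cond) in enumerate(design.clone_samples):
        depth = design.fixed_depth or int(
            depth_rng.integers(design.clone_depth_range[0], design.clone_depth_range[1] + 1)
        )
        counts[sample] = draw_library(
            truth, tissue, cond, depth, _rng(design.seed, 2, k), design.sampling
        )
    for k, (sample, cond, medium) in enumerate(design.isolate_samples):
        depth = design.fixed_depth or int(
            depth_rng.integers(design.isolate_depth_range[0], design.isolate_depth_range[1] + 1)
        )
        counts[sample] = draw_isolate_collection(
            truth, cond, medium, depth, _rng(design.seed, 2, 100 + k), design.sampling
        )
    count_frame = pd.DataFrame(counts, index=[o.otu_id for o in truth])
    study = SyntheticStudy(design, truth, count_frame, meta)
    if include_sequences:
        records, read_sample, read_otu = emit_sequences(
            truth, count_frame, design.seed, design.alignment_length
        )
        study.sequences = records
        study.read_sample = read_sample
        study.read_otu = read_otu
        study.taxonomy = _emit_taxonomy(truth, read_otu, design.seed)
    study.best_hits = _emit_best_hits(truth)
    if include_inoculation:
        effect_map = {}
        cycle = [1.3, 0.75, 1.0]
        for i, o in enumerate(sorted(truth, key=lambda o: o.otu_id)):
            if o.planted_role in CANDIDATE_ROLES:
                effect_map[f"iso_{o.otu_id}"] = cycle[i % len(cycle)]
        study.inoculation = emit_inoculation_records(effect_map, seed=design.seed)
    return study
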