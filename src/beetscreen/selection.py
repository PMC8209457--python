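"""Rule-based screening of candidate plant growth-promoting bacteria.

An OTU with at least one cultured isolate becomes a candidate when it
satisfies any of four criteria on the combined clone-library / isolate-
collection evidence:

* **novelty** — best-hit identity to the closest known species strictly
  below 97%;
* **tissue specificity** — present (count >= 1) in the below-ground
  compartments (taproot, lateral root) and absent from every above-ground
  library;
* **persistence** — for at least one below-ground tissue, present under
  every fertilisation condition observed for that tissue (clone libraries
  and isolate collections pooled per condition);
* **abundance** — strictly more than 1% relative abundance in at least one
  below-ground clone library or isolate collection;

or when its best hit matches a curated list of known PGPB genera. OTUs
whose best hit matches a curated plant/animal/human pathogen genus list
are excluded outright. The criteria combine as OR; the isolate requirement
and the pathogen exclusion are mandatory AND terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "OTUEvidence",
    "SelectionFlags",
    "SelectionConfig",
    "flag_novelty",
    "flag_tissue_specificity",
    "flag_persistence",
    "flag_abundance",
    "flag_reference_lists",
    "select_candidates",
    "load_reference_lists",
]

BELOW_GROUND = ("taproot", "lateral_root")


@dataclass(frozen=True)
class OTUEvidence:
    """Everything the screen needs to know about one OTU.

    ``abundance`` maps library_id -> relative abundance fraction (0..1);
    ``library_meta`` maps library_id -> dict with at least tissue,
    condition, provenance.
    """

    otu_id: str
    abundance: Mapping[str, float]
    library_meta: Mapping[str, Mapping[str, str]]
    has_isolate: bool
    best_hit_identity: float | None = None
    best_hit_taxon: str | None = None
    representative_isolate: str | None = None

    def __post_init__(self):
        for lib, a in self.abundance.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(
                    f"OTU {self.otu_id}: abundance {a} in {lib} outside [0, 1]"
                )
            if lib not in self.library_meta:
                raise ValueError(f"OTU {self.otu_id}: no metadata for {lib!r}")

    def _libs(self, tissues=None, conditions=None):
        for lib, meta in self.library_meta.items():
            if tissues is not None and meta["tissue"] not in tissues:
                continue
            if conditions is not None and meta["condition"] not in conditions:
                continue
            yield lib

    def present_in(self, lib: str) -> bool:
        return self.abundance.get(lib, 0.0) > 0.0


@dataclass(frozen=True)
class SelectionFlags:
    otu_id: str
    novelty: bool
    tissue_specificity: bool
    persistence: bool
    abundance: bool
    known_pgpb: bool
    pathogen_excluded: bool
    has_isolate: bool
    selected: bool
    rationale: tuple[str, ...]


@dataclass
class SelectionConfig:
    novelty_threshold: float = 0.97
    abundance_threshold: float = 0.01
    target_tissues: tuple[str, ...] = BELOW_GROUND
    known_pgpb_genera: tuple[str, ...] = ()
    pathogen_genera: tuple[str, ...] = ()
    persistence_pooled: bool = False  # pool tissues instead of per-tissue

    @classmethod
    def with_reference_lists(cls, **kw) -> "SelectionConfig":
        pgpb, path = load_reference_lists()
        kw.setdefault("known_pgpb_genera", tuple(pgpb))
        kw.setdefault("pathogen_genera", tuple(path))
        return cls(**kw)


def load_reference_lists() -> tuple[list[str], list[str]]:
    """Editable curated genus lists shipped as package data."""
    text = resources.files("beetscreen.data").joinpath("reference_lists.json").read_text()
    data = json.loads(text)
    return data["known_pgpb_genera"], data["pathogen_genera"]


def flag_novelty(evidence: OTUEvidence, threshold: float = 0.97) -> bool | None:
    """Strictly-below-threshold best-hit identity; None when undetermined."""
    if evidence.best_hit_identity is None:
        return None
    return evidence.best_hit_identity < threshold


def flag_tissue_specificity(
    evidence: OTUEvidence, target_tissues: Sequence[str] = BELOW_GROUND
) -> bool:
    """Present somewhere below ground, absent from every other tissue."""
    in_target = any(
        evidence.present_in(lib) for lib in evidence._libs(tissues=set(target_tissues))
    )
    non_target = {
        m["tissue"] for m in evidence.library_meta.values()
    } - set(target_tissues)
    in_other = any(
        evidence.present_in(lib) for lib in evidence._libs(tissues=non_target)
    )
    return in_target and not in_other


def flag_persistence(
    evidence: OTUEvidence,
    tissues: Sequence[str] = BELOW_GROUND,
    pooled: bool = False,
) -> bool:
    """Stable presence across every fertilisation condition.

    Per-tissue by default: true if for some below-ground tissue the OTU is
    present under each condition observed for that tissue (clone libraries
    and isolate collections pooled within a condition). ``pooled`` relaxes
    this to presence per condition anywhere below ground.
    """
    meta = evidence.library_meta
    if pooled:
        conds = {m["condition"] for m in meta.values() if m["tissue"] in tissues}
        return bool(conds) and all(
            any(
                evidence.present_in(lib)
                for lib in evidence._libs(tissues=set(tissues), conditions={c})
            )
            for c in conds
        )
    for tissue in tissues:
        conds = {m["condition"] for m in meta.values() if m["tissue"] == tissue}
        if not conds:
            continue
        if all(
            any(
                evidence.present_in(lib)
                for lib in evidence._libs(tissues={tissue}, conditions={c})
            )
            for c in conds
        ):
            return True
    return False


def flag_abundance(
    evidence: OTUEvidence,
    threshold: float = 0.01,
    target_tissues: Sequence[str] = BELOW_GROUND,
) -> bool:
    """Strictly more than ``threshold`` in any below-ground sample."""
    return any(
        evidence.abundance.get(lib, 0.0) > threshold
        for lib in evidence._libs(tissues=set(target_tissues))
    )


def _genus(taxon: str | None) -> str | None:
    if not taxon:
        return None
    return taxon.split()[0]


def flag_reference_lists(
    evidence: OTUEvidence,
    known_pgpb_taxa: Sequence[str] = (),
    pathogen_taxa: Sequence[str] = (),
) -> tuple[bool, bool]:
    """(known_pgpb, pathogen_excluded) from genus-level list matches."""
    genus = _genus(evidence.best_hit_taxon)
    known = genus is not None and genus in set(known_pgpb_taxa)
    pathogen = genus is not None and genus in set(pathogen_taxa)
    return known, not pathogen


def evaluate(evidence: OTUEvidence, config: SelectionConfig) -> SelectionFlags:
    """All flags plus the combined selection decision for one OTU."""
    novelty = flag_novelty(evidence, config.novelty_threshold)
    tissue = flag_tissue_specificity(evidence, config.target_tissues)
    persist = flag_persistence(
        evidence, config.target_tissues, pooled=config.persistence_pooled
    )
    abundant = flag_abundance(
        evidence, config.abundance_threshold, config.target_tissues
    )
    known, path_ok = flag_reference_lists(
        evidence, config.known_pgpb_genera, config.pathogen_genera
    )
    criteria = {
        "novelty": bool(novelty),
        "tissue_specificity": tissue,
        "persistence": persist,
        "abundance": abundant,
        "known_pgpb": known,
    }
    rationale = tuple(name for name, hit in criteria.items() if hit)
    selected = bool(rationale) and evidence.has_isolate and path_ok
    return SelectionFlags(
        otu_id=evidence.otu_id,
        novelty=bool(novelty),
        tissue_specificity=tissue,
        persistence=persist,
        abundance=abundant,
        known_pgpb=known,
        pathogen_excluded=path_ok,
        has_isolate=evidence.has_isolate,
        selected=selected,
        rationale=rationale,
    )


@dataclass
class CandidateSet:
    flags: list[SelectionFlags] = field(default_factory=list)
    representatives: dict[str, str] = field(default_factory=dict)

    @property
    def selected_otus(self) -> list[str]:
        return [f.otu_id for f in self.flags if f.selected]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.flags:
            rows.append(
                {
                    "otu_id": f.otu_id,
                    "selected": f.selected,
                    "representative_isolate": self.representatives.get(f.otu_id, ""),
                    "novelty": f.novelty,
                    "tissue_specificity": f.tissue_specificity,
                    "persistence": f.persistence,
                    "abundance": f.abundance,
                    "known_pgpb": f.known_pgpb,
                    "pathogen_excluded": f.pathogen_excluded,
                    "has_isolate": f.has_isolate,
                    "rationale": ";".join(f.rationale),
                }
            )
        return pd.DataFrame(rows).set_index("otu_id")


def select_candidates(
    evidence_set: Sequence[OTUEvidence], config: SelectionConfig | None = None
) -> CandidateSet:
    """Run the screen over a set of OTUs; sorted by otu_id, deterministic.

    An empty candidate set is a valid outcome.
    """
    if config is None:
        config = SelectionConfig.with_reference_lists()
    result = CandidateSet()
    for ev in sorted(evidence_set, key=lambda e: e.otu_id):
        flags = evaluate(ev, config)
        result.flags.append(flags)
        if flags.selected and ev.representative_isolate:
            result.representatives[ev.otu_id] = ev.representative_isolate
    return result
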