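"""Bundled summary tables from the sugar-beet field survey.

The package ships the survey's printed per-library summary statistics
(16 clone libraries / isolate collections), the OTU-level clone-library
percentages of the 14 inoculation-tested OTUs, their BLAST best hits, and
a partly *synthetic* reconstruction of the isolate-collection abundances
(see ``data/collection_abundance.tsv`` for the derivation). These serve as
worked-example fixtures; full-resolution sequence data lives in public
archives and is not redistributed here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .selection import OTUEvidence

__all__ = [
    "load_library_summary",
    "load_otu_profiles",
    "load_best_hits",
    "load_collection_abundance",
    "survey_evidence",
]

CLONE_LIBRARIES = (
    "LB-NPK", "LB-PK", "LB-K",
    "PE-NPK", "PE-PK", "PE-K",
    "TR-NPK", "TR-PK", "TR-K",
    "LR-NPK", "LR-PK", "LR-K",
)
COLLECTIONS = ("LR-PK-R", "LR-PK-T", "LR-K-R", "LR-K-T")

_TISSUE = {"LB": "leaf_blade", "PE": "petiole", "TR": "taproot", "LR": "lateral_root"}


def _read(name: str, **kw) -> pd.DataFrame:
    path = resources.files("beetscreen.data").joinpath(name)
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#", **kw)


def load_library_summary() -> pd.DataFrame:
    """Per-library statistics block (N, OTUs, singletons, coverage %,
    richness and diversity indices), indexed by library id."""
    return _read("library_summary.tsv", index_col="library_id")


def load_otu_profiles() -> pd.DataFrame:
    """Clone-library percent abundances of the 14 inoculation-tested OTUs."""
    return _read("otu_profiles.tsv", index_col="otu_id")


def load_collection_abundance() -> pd.DataFrame:
    """Isolate-collection percent abundances of the same OTUs
    (reconstructed; see module docstring)."""
    return _read("collection_abundance.tsv", index_col="otu_id")


def load_best_hits() -> pd.DataFrame:
    """BLAST best-hit species and percent identity per tested OTU."""
    return _read("best_hits.tsv", index_col="otu_id")


def library_metadata() -> dict[str, dict[str, str]]:
    """tissue/condition/provenance metadata for the 16 survey samples."""
    meta: dict[str, dict[str, str]] = {}
    for lib in CLONE_LIBRARIES:
        code, cond = lib.split("-", 1)
        meta[lib] = {
            "tissue": _TISSUE[code],
            "condition": cond,
            "provenance": "clone",
            "medium": "-",
        }
    for col in COLLECTIONS:
        _, cond, medium = col.split("-")
        meta[col] = {
            "tissue": "lateral_root",
            "condition": cond,
            "provenance": "isolate",
            "medium": {"R": "R2A", "T": "TSA"}[medium],
        }
    return meta


def survey_evidence() -> list[OTUEvidence]:
    """The 14 tested OTUs as selection-engine evidence.

    Abundances are fractions; every OTU has an isolate by construction
    (each was inoculated onto seedlings).
    """
    profiles = load_otu_profiles()
    collections = load_collection_abundance()
    hits = load_best_hits()
    meta = library_metadata()
    out = []
    for otu_id, row in profiles.iterrows():
        ab = {lib: float(row[lib]) / 100.0 for lib in CLONE_LIBRARIES}
        for col in COLLECTIONS:
            ab[col] = float(collections.loc[otu_id, col]) / 100.0
        hit = hits.loc[otu_id]
        out.append(
            OTUEvidence(
                otu_id=str(otu_id),
                abundance=ab,
                library_meta=meta,
                has_isolate=True,
                best_hit_identity=float(hit["identity_pct"]) / 100.0,
                best_hit_taxon=str(hit["closest_species"]),
                representative_isolate=str(row["isolate"]),
            )
        )
    return out
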