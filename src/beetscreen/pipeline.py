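"""End-to-end screen: simulate -> distances -> OTUs -> diversity ->
tree/ordination -> composition -> selection -> inoculation.

Stages communicate through files in one output directory, make-style: a
stage reruns when an output is missing or older than an input, so a
completed directory is a no-op and deleting one intermediate reruns only
that stage and everything downstream. A ``manifest.json`` records the
configuration, seeds, and SHA-256 of every output for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from . import alpha as alpha_mod
from . import beta, cluster as cluster_mod, composition as comp_mod
from . import inoculation as inoc_mod
from . import selection as sel_mod
from . import tree as tree_mod
from .distance import distance_matrix
from .io import Alignment, read_fasta
from .simulate import StudyDesign, simulate_study

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    n_otus: int = 120
    sampling: str = "multinomial"
    alignment_length: int = 1200
    cluster_threshold: float = 0.03
    cluster_linkage: str = "furthest"
    distance_model: str = "p"
    unifrac_normalized: bool = False
    min_confidence: float = 0.8
    novelty_threshold: float = 0.97
    abundance_threshold: float = 0.01
    alpha_level: float = 0.05
    ranks: tuple = ("phylum", "genus")

    def validate(self) -> None:
        if not 0 <= self.cluster_threshold <= 1:
            raise ValueError("cluster_threshold must lie in [0, 1]")
        if self.distance_model not in ("p", "jukes_cantor"):
            raise ValueError(f"unknown distance model {self.distance_model!r}")
        if self.cluster_linkage not in cluster_mod.LINKAGES:
            raise ValueError(f"unknown linkage {self.cluster_linkage!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class _Stage:
    name: str
    inputs: list
    outputs: list
    func: object
    ran: bool = False


def _stale(stage: _Stage) -> bool:
    outs = [Path(p) for p in stage.outputs]
    if not all(p.exists() for p in outs):
        return True
    ins = [Path(p) for p in stage.inputs if Path(p).exists()]
    if ins and outs:
        newest_in = max(p.stat().st_mtime for p in ins)
        oldest_out = min(p.stat().st_mtime for p in outs)
        return newest_in > oldest_out
    return False


def run_pipeline(config: PipelineConfig, force: bool = False) -> Path:
    """Run (or resume) every stage; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    f = {
        name: out / name
        for name in (
            "sequences.fasta", "metadata.tsv", "samples.tsv", "taxonomy.tsv",
            "sequence_best_hits.tsv", "inoculation.tsv", "ground_truth.json",
            "distances.npz", "partition.tsv", "otutable.tsv", "alpha.tsv",
            "tree.nwk", "leaf_map.tsv", "unifrac.tsv", "pcoa_coords.tsv",
            "pcoa_eigenvalues.tsv", "candidates.tsv", "effects.tsv",
        )
    }
    comp_files = [out / f"composition_{r}.tsv" for r in config.ranks]

    def stage_simulate():
        design = StudyDesign(
            n_otus=config.n_otus,
            sampling=config.sampling,
            alignment_length=config.alignment_length,
            seed=config.seed,
        )
        study = simulate_study(design)
        study.write(out)
        hits = study.best_hits.set_index("otu_id")
        rows = [
            {
                "sequence_id": rid,
                "identity": hits.loc[gt, "identity"],
                "closest_taxon": hits.loc[gt, "closest_taxon"],
            }
            for rid, gt in study.read_otu.items()
        ]
        pd.DataFrame(rows).to_csv(f["sequence_best_hits.tsv"], sep="\t", index=False)

    def stage_distances():
        records = read_fasta(f["sequences.fasta"])
        dm = distance_matrix(Alignment(records), model=config.distance_model)
        np.savez_compressed(f["distances.npz"], data=dm.data, ids=np.array(dm.ids))

    def _load_dm() -> DistanceMatrix:
        z = np.load(f["distances.npz"], allow_pickle=False)
        return DistanceMatrix(z["data"], [str(x) for x in z["ids"]])

    def _load_meta():
        meta = pd.read_csv(f["metadata.tsv"], sep="\t").set_index("sequence_id")
        samples = pd.read_csv(f["samples.tsv"], sep="\t", index_col="library_id")
        return meta, samples

    def stage_cluster():
        dm = _load_dm()
        part = cluster_mod.cluster(dm, config.cluster_threshold, config.cluster_linkage)
        meta, samples = _load_meta()
        table = cluster_mod.build_table(part, meta["library_id"].to_dict(), samples)
        pd.Series(part.assignments, name="otu_id").rename_axis("sequence_id").to_csv(
            f["partition.tsv"], sep="\t"
        )
        table.to_tsv(f["otutable.tsv"])

    def stage_alpha():
        table = cluster_mod.OTUTable.from_tsv(f["otutable.tsv"])
        alpha_mod.summarize(table).to_csv(f["alpha.tsv"], sep="\t")

    def _representatives():
        part = pd.read_csv(f["partition.tsv"], sep="\t", index_col="sequence_id")["otu_id"]
        meta, samples = _load_meta()
        # one representative sequence per OTU: the smallest member id
        reps = part.reset_index().groupby("otu_id")["sequence_id"].min()
        return part, reps, meta, samples

    def stage_tree():
        part, reps, meta, samples = _representatives()
        records = {r.id: r for r in read_fasta(f["sequences.fasta"])}
        rep_records = [records[s] for s in reps.values]
        rename = dict(zip(reps.values, reps.index))  # seq id -> otu id
        aln = Alignment(
            [type(r)(rename[r.id], r.residues) for r in rep_records]
        )
        if len(aln) < 2:
            raise RuntimeError("fewer than 2 OTUs; no tree to build")
        nj = tree_mod.neighbor_joining(distance_matrix(aln, model=config.distance_model))
        tree_mod.write_newick(nj, f["tree.nwk"])
        reps.rename("representative").to_csv(f["leaf_map.tsv"], sep="\t")

    def stage_pcoa():
        table = cluster_mod.OTUTable.from_tsv(f["otutable.tsv"])
        clone_libs = [
            l for l in table.library_ids if table.metadata.loc[l, "provenance"] == "clone"
        ]
        sub = table.subset_libraries(clone_libs)
        njt = tree_mod.read_newick(f["tree.nwk"])
        dm = beta.unifrac_matrix(njt, sub, normalized=config.unifrac_normalized)
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            f["unifrac.tsv"], sep="\t"
        )
        res = beta.pcoa(dm)
        res.coordinates.to_csv(f["pcoa_coords.tsv"], sep="\t", index_label="library_id")
        pd.DataFrame(
            {
                "eigenvalue": res.eigenvalues,
                "proportion_explained": list(res.proportion_explained)
                + [np.nan] * (len(res.eigenvalues) - len(res.proportion_explained)),
            }
        ).to_csv(f["pcoa_eigenvalues.tsv"], sep="\t", index_label="axis")

    def stage_compose():
        taxa = pd.read_csv(f["taxonomy.tsv"], sep="\t")
        assignments = comp_mod.assignments_from_frame(taxa)
        meta, samples = _load_meta()
        refs = {
            samples.loc[l, "tissue"]: l
            for l in samples.index
            if samples.loc[l, "condition"] == "NPK"
            and samples.loc[l, "provenance"] == "clone"
        }
        report = comp_mod.composition_report(
            assignments,
            meta,
            samples,
            ranks=config.ranks,
            reference_by_tissue=refs,
            min_confidence=config.min_confidence,
            alpha=config.alpha_level,
        )
        for rank, frame in report.items():
            frame.to_csv(out / f"composition_{rank}.tsv", sep="\t", index_label="taxon")

    def stage_select():
        table = cluster_mod.OTUTable.from_tsv(f["otutable.tsv"])
        part, reps, meta, samples = _representatives()
        hits = pd.read_csv(f["sequence_best_hits.tsv"], sep="\t", index_col="sequence_id")
        rel = table.relative_abundance()
        lib_meta = {
            l: samples.loc[l].to_dict() for l in table.library_ids
        }
        isolate_libs = {
            l for l in table.library_ids if samples.loc[l, "provenance"] == "isolate"
        }
        prov = meta["library_id"].map(samples["provenance"])
        evidence = []
        for otu in table.otu_ids:
            members = part.index[part == otu]
            iso_members = [s for s in members if prov[s] == "isolate"]
            rep = reps[otu]
            evidence.append(
                sel_mod.OTUEvidence(
                    otu_id=otu,
                    abundance={l: float(rel.loc[otu, l]) for l in table.library_ids},
                    library_meta=lib_meta,
                    has_isolate=bool(iso_members),
                    best_hit_identity=float(hits.loc[rep, "identity"]),
                    best_hit_taxon=str(hits.loc[rep, "closest_taxon"]),
                    representative_isolate=min(iso_members) if iso_members else None,
                )
            )
        cfg = sel_mod.SelectionConfig.with_reference_lists(
            novelty_threshold=config.novelty_threshold,
            abundance_threshold=config.abundance_threshold,
        )
        sel_mod.select_candidates(evidence, cfg).to_frame().to_csv(
            f["candidates.tsv"], sep="\t"
        )

    def stage_inoculation():
        records = pd.read_csv(f["inoculation.tsv"], sep="\t")
        inoc_mod.evaluate_all(records, alpha=config.alpha_level).to_csv(
            f["effects.tsv"], sep="\t"
        )

    stages = [
        _Stage(
            "simulate",
            [],
            [f[k] for k in (
                "sequences.fasta", "metadata.tsv", "samples.tsv", "taxonomy.tsv",
                "sequence_best_hits.tsv", "inoculation.tsv", "ground_truth.json",
            )],
            stage_simulate,
        ),
        _Stage("distances", [f["sequences.fasta"]], [f["distances.npz"]], stage_distances),
        _Stage(
            "cluster",
            [f["distances.npz"], f["metadata.tsv"], f["samples.tsv"]],
            [f["partition.tsv"], f["otutable.tsv"]],
            stage_cluster,
        ),
        _Stage("alpha", [f["otutable.tsv"]], [f["alpha.tsv"]], stage_alpha),
        _Stage(
            "tree",
            [f["partition.tsv"], f["sequences.fasta"]],
            [f["tree.nwk"], f["leaf_map.tsv"]],
            stage_tree,
        ),
        _Stage(
            "pcoa",
            [f["otutable.tsv"], f["tree.nwk"]],
            [f["unifrac.tsv"], f["pcoa_coords.tsv"], f["pcoa_eigenvalues.tsv"]],
            stage_pcoa,
        ),
        _Stage(
            "compose",
            [f["taxonomy.tsv"], f["metadata.tsv"], f["samples.tsv"]],
            comp_files,
            stage_compose,
        ),
        _Stage(
            "select",
            [f["otutable.tsv"], f["partition.tsv"], f["sequence_best_hits.tsv"]],
            [f["candidates.tsv"]],
            stage_select,
        ),
        _Stage("inoculation", [f["inoculation.tsv"]], [f["effects.tsv"]], stage_inoculation),
    ]

    for stage in stages:
        if force or _stale(stage):
            try:
                stage.func()
            except Exception as exc:
                raise RuntimeError(f"stage {stage.name!r} failed: {exc}") from exc
            stage.ran = True

    manifest = {
        "config": asdict(config),
        "stages": {
            s.name: {
                "ran": s.ran,
                "outputs": {
                    Path(p).name: _sha256(Path(p)) for p in s.outputs if Path(p).exists()
                },
            }
            for s in stages
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
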