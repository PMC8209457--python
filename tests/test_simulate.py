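"""The synthetic-study generator: determinism, conservation, contracts."""

import numpy as np
import pytest

from beetscreen.simulate import (
    StudyDesign,
    draw_isolate_collection,
    draw_library,
    emit_inoculation_records,
    emit_sequences,
    plant_truth,
    simulate_study,
    PLANTED_ROLES,
    _rng,
)


class TestPlantTruth:
    def test_role_counts_by_construction(self):
        design = StudyDesign(seed=2, n_otus=50, planted_per_role=2)
        truth = plant_truth(design)
        assert len(truth) == 50
        planted = [o for o in truth if o.planted_role != "background"]
        assert len(planted) == 2 * len(PLANTED_ROLES) == 12

    def test_same_seed_identical_truth(self):
        design = StudyDesign(seed=9, n_otus=40)
        t1, t2 = plant_truth(design), plant_truth(design)
        assert [o.__dict__ for o in t1] == [o.__dict__ for o in t2]

    def test_too_many_roles_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            plant_truth(StudyDesign(seed=0, n_otus=10, planted_per_role=2))

    def test_at_least_one_unculturable_otu(self):
        truth = plant_truth(StudyDesign(seed=4, n_otus=40))
        assert any(max(o.culturability.values()) == 0.0 for o in truth)

    def test_unculturable_otu_never_reaches_collections(self):
        """Monte-Carlo check of the sampling contract: culturability 0 on
        all media means clone libraries only, across 100 replicate draws."""
        design = StudyDesign(seed=4, n_otus=40)
        truth = plant_truth(design)
        dead = [i for i, o in enumerate(truth) if max(o.culturability.values()) == 0.0]
        assert dead
        clone_hits = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            lib = draw_library(truth, "lateral_root", "PK", 200, rng)
            clone_hits += lib[dead].sum() > 0
            for medium in design.media:
                col = draw_isolate_collection(truth, "PK", medium, 200, rng)
                assert col[dead].sum() == 0
        assert clone_hits >= 1


class TestDraws:
    def _single_otu_truth(self):
        design = StudyDesign(seed=1, n_otus=13, planted_per_role=1)
        return plant_truth(design)

    def test_single_positive_otu_takes_all_counts(self):
        truth = self._single_otu_truth()[:1]
        counts = draw_library(truth, "taproot", "NPK", 175, np.random.default_rng(0))
        assert counts.tolist() == [175]

    def test_law_of_large_numbers_equal_weights(self):
        truth = self._single_otu_truth()[:2]
        for o in truth:
            o.base_abundance = 1.0
            o.tissue_affinity = {t: 1.0 for t in o.tissue_affinity}
            o.condition_stability = {c: 1.0 for c in o.condition_stability}
        counts = draw_library(truth, "taproot", "NPK", 10**5, np.random.default_rng(1))
        assert abs(counts[0] / 10**5 - 0.5) < 0.01

    def test_zero_affinity_tissue_never_sampled(self):
        truth = self._single_otu_truth()[:3]
        truth[0].tissue_affinity["leaf_blade"] = 0.0
        for seed in range(5):
            counts = draw_library(truth, "leaf_blade", "NPK", 300,
                                  np.random.default_rng(seed))
            assert counts[0] == 0

    def test_all_zero_weights_rejected(self):
        truth = self._single_otu_truth()[:1]
        truth[0].condition_stability["K"] = 0.0
        with pytest.raises(ValueError, match="zero"):
            draw_library(truth, "taproot", "K", 10, np.random.default_rng(0))

    def test_full_culturability_reduces_to_library_draw(self):
        truth = self._single_otu_truth()
        for o in truth:
            o.culturability = {m: 1.0 for m in o.culturability}
        a = draw_library(truth, "lateral_root", "PK", 500, np.random.default_rng(7))
        b = draw_isolate_collection(truth, "PK", "R2A", 500, np.random.default_rng(7))
        assert (a == b).all()

    def test_medium_exclusive_otu_absent_from_other_medium(self):
        truth = self._single_otu_truth()
        truth[0].culturability = {"R2A": 0.0, "TSA": 1.0}
        for seed in range(5):
            col = draw_isolate_collection(truth, "PK", "R2A", 300,
                                          np.random.default_rng(seed))
            assert col[0] == 0

    def test_copiotroph_bias_matches_renormalised_weights(self):
        """Expected TSA frequency computable exactly from the weights."""
        truth = self._single_otu_truth()[:3]
        for o in truth:
            o.base_abundance = 1.0
            o.tissue_affinity["lateral_root"] = 1.0
            o.condition_stability["PK"] = 1.0
        truth[0].culturability = {"R2A": 0.2, "TSA": 1.0}
        truth[1].culturability = {"R2A": 1.0, "TSA": 1.0}
        truth[2].culturability = {"R2A": 1.0, "TSA": 0.5}
        w = np.array([1.0, 1.0, 0.5])
        expected = w / w.sum()
        n = 2 * 10**5
        counts = draw_isolate_collection(truth, "PK", "TSA", n, np.random.default_rng(3))
        assert np.allclose(counts / n, expected, atol=0.01)


class TestSequences:
    def test_representative_separation_and_recovery(self, seq_study):
        from beetscreen.cluster import cluster
        from beetscreen.distance import distance_matrix
        from beetscreen.io import Alignment

        dm = distance_matrix(Alignment(seq_study.sequences), model="p")
        part = cluster(dm, 0.03, "furthest")
        observed_truth = set(seq_study.read_otu.values())
        assert part.n_otus == len(observed_truth)
        # clusters must be pure w.r.t. the planted partition
        seen = {}
        for sid, otu in part.assignments.items():
            true = seq_study.read_otu[sid]
            assert seen.setdefault(otu, true) == true

    def test_one_read_per_otu_gives_n_otus_clusters(self):
        import pandas as pd
        from beetscreen.cluster import cluster
        from beetscreen.distance import distance_matrix
        from beetscreen.io import Alignment

        design = StudyDesign(seed=8, n_otus=14, planted_per_role=1, alignment_length=600)
        truth = plant_truth(design)
        counts = pd.DataFrame({"L1": [1] * len(truth)}, index=[o.otu_id for o in truth])
        records, _, _ = emit_sequences(truth, counts, seed=8, alignment_length=600)
        part = cluster(distance_matrix(Alignment(records), model="p"), 0.03)
        assert part.n_otus == len(truth)

    def test_byte_identical_fasta_for_fixed_seed(self, seq_study):
        from beetscreen.simulate import StudyDesign, simulate_study

        again = simulate_study(seq_study.design, include_inoculation=False)
        assert seq_study.fasta_bytes() == again.fasta_bytes()

    def test_short_template_rejected(self):
        with pytest.raises(ValueError, match="500"):
            emit_sequences([], None, seed=0, alignment_length=100)


class TestInoculationRecords:
    def test_record_counts_by_construction(self):
        rec = emit_inoculation_records({"iso": 1.2}, n_per_test=12, n_repeats=3, seed=0)
        treated = rec[rec["isolate_id"] == "iso"]
        assert len(treated) == 36
        assert treated["batch"].nunique() == 3

    def test_every_batch_has_controls(self):
        rec = emit_inoculation_records({"a": 1.2, "b": 0.8}, seed=1)
        for batch, grp in rec.groupby("batch"):
            assert (grp["isolate_id"] == "control").any()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n_per_test"):
            emit_inoculation_records({"iso": 1.0}, n_per_test=1)


class TestStudyConservation:
    def test_column_sums_equal_designed_depths(self, small_study):
        sums = small_study.counts.sum(axis=0)
        lo, hi = small_study.design.clone_depth_range
        assert ((sums >= lo) & (sums <= hi)).all()

    def test_counts_deterministic(self, small_study):
        again = simulate_study(
            small_study.design, include_sequences=False, include_inoculation=False
        )
        assert (again.counts.values == small_study.counts.values).all()

    def test_reads_map_to_exactly_one_otu_each(self, seq_study):
        assert set(seq_study.read_otu) == {r.id for r in seq_study.sequences}
        assert set(seq_study.read_sample) == set(seq_study.read_otu)

    def test_written_study_is_reloadable(self, tmp_path, seq_study):
        import pandas as pd

        seq_study.write(tmp_path / "study")
        counts = pd.read_csv(tmp_path / "study" / "true_counts.tsv", sep="\t",
                             index_col="otu_id")
        assert (counts.values == seq_study.counts.values).all()

    def test_substreams_are_independent(self):
        a = _rng(1, 0).integers(0, 1000, 5)
        b = _rng(1, 1).integers(0, 1000, 5)
        assert not (a == b).all()
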