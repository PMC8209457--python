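"""Weighted UniFrac and PCoA against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from beetscreen.beta import (
    CommunityProfile,
    pcoa,
    table_profiles,
    unifrac_matrix,
    weighted_unifrac,
)
from beetscreen.cluster import OTUTable
from beetscreen.tree import read_newick


def brute_force_weighted_unifrac(tree, a, b, normalized=False):
    """Independent traversal: for every branch, sum the leaf abundances
    below it by explicit subtree membership."""
    num = den = 0.0
    for node in tree.traverse(include_self=True):
        if node.parent is None:
            continue
        leaves = {t.name for t in node.tips()} or {node.name}
        fa = sum(a.abundances.get(l, 0.0) for l in leaves)
        fb = sum(b.abundances.get(l, 0.0) for l in leaves)
        length = node.length or 0.0
        num += length * abs(fa - fb)
        den += length * (fa + fb)
    if normalized:
        return num / den if den else 0.0
    return num


class TestWeightedUnifrac:
    def test_identical_profiles_zero(self):
        tree = read_newick("((a:0.2,b:0.3):0.1,(c:0.4,d:0.1):0.2);")
        p = CommunityProfile("x", {"a": 0.5, "c": 0.5})
        assert weighted_unifrac(tree, p, CommunityProfile("y", dict(p.abundances))) == 0.0

    def test_two_leaf_hand_evaluation(self):
        b1, b2 = 0.3, 0.7
        tree = read_newick(f"(a:{b1},b:{b2});")
        pa = CommunityProfile("A", {"a": 1.0})
        pb = CommunityProfile("B", {"b": 1.0})
        assert weighted_unifrac(tree, pa, pb) == pytest.approx(b1 + b2)
        assert weighted_unifrac(tree, pa, pb, normalized=True) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_six_leaf_trees(self, rng):
        from test_tree import random_additive_matrix
        from beetscreen.tree import neighbor_joining, midpoint_root

        for _ in range(10):
            tree = midpoint_root(neighbor_joining(random_additive_matrix(6, rng)))
            leaves = [t.name for t in tree.tips()]
            wa = rng.dirichlet(np.ones(len(leaves)))
            wb = rng.dirichlet(np.ones(len(leaves)))
            pa = CommunityProfile("A", dict(zip(leaves, wa)))
            pb = CommunityProfile("B", dict(zip(leaves, wb)))
            for normalized in (False, True):
                ours = weighted_unifrac(tree, pa, pb, normalized=normalized)
                oracle = brute_force_weighted_unifrac(tree, pa, pb, normalized)
                assert ours == pytest.approx(oracle, abs=1e-12)

    def test_matches_scikit_bio(self, rng):
        from skbio.diversity.beta import weighted_unifrac as skbio_wu
        from test_tree import random_additive_matrix
        from beetscreen.tree import neighbor_joining, midpoint_root

        tree = midpoint_root(neighbor_joining(random_additive_matrix(6, rng)))
        leaves = [t.name for t in tree.tips()]
        ca = rng.integers(0, 30, size=len(leaves))
        cb = rng.integers(0, 30, size=len(leaves))
        ca[0] += 1
        cb[1] += 1
        pa = CommunityProfile("A", dict(zip(leaves, ca / ca.sum())))
        pb = CommunityProfile("B", dict(zip(leaves, cb / cb.sum())))
        for normalized in (False, True):
            ours = weighted_unifrac(tree, pa, pb, normalized=normalized)
            theirs = skbio_wu(
                [*ca], [*cb], taxa=leaves, tree=tree, normalized=normalized,
                validate=True,
            )
            assert ours == pytest.approx(float(theirs), abs=1e-10)

    def test_unknown_leaf_rejected(self):
        tree = read_newick("(a:0.2,b:0.3);")
        with pytest.raises(ValueError, match="absent"):
            weighted_unifrac(
                tree,
                CommunityProfile("A", {"a": 1.0}),
                CommunityProfile("B", {"zzz": 1.0}),
            )

    def test_unnormalised_profile_rejected(self):
        with pytest.raises(ValueError, match="sums"):
            CommunityProfile("A", {"a": 0.7})


class TestUnifracMatrix:
    def _table(self):
        counts = pd.DataFrame(
            {"L1": [5, 5, 0], "L2": [5, 5, 0], "L3": [0, 2, 8]},
            index=["a", "b", "c"],
        )
        meta = pd.DataFrame(
            {
                "tissue": ["taproot"] * 3,
                "condition": ["NPK", "PK", "K"],
                "provenance": ["clone"] * 3,
                "medium": ["-"] * 3,
            },
            index=["L1", "L2", "L3"],
        )
        return OTUTable(counts, meta)

    def test_duplicate_libraries_distance_zero_and_symmetry(self):
        tree = read_newick("((a:0.2,b:0.3):0.1,c:0.5);")
        dm = unifrac_matrix(tree, self._table())
        assert dm["L1", "L2"] == 0.0
        assert np.allclose(dm.data, dm.data.T)

    def test_matches_per_pair_calls(self):
        tree = read_newick("((a:0.2,b:0.3):0.1,c:0.5);")
        table = self._table()
        dm = unifrac_matrix(tree, table)
        profiles = {p.library_id: p for p in table_profiles(table)}
        for i in ("L1", "L2", "L3"):
            for j in ("L1", "L2", "L3"):
                expected = weighted_unifrac(tree, profiles[i], profiles[j])
                assert dm[i, j] == pytest.approx(expected, abs=1e-12)


class TestPCoA:
    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        d = np.abs(pts - pts.T)
        res = pcoa(DistanceMatrix(d, ["p0", "p1", "p2"]))
        assert res.proportion_explained[0] == pytest.approx(1.0)
        assert res.coordinates.shape[1] == 1

    def test_euclidean_recovery(self, rng):
        pts = rng.normal(size=(7, 2))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        ids = [f"p{i}" for i in range(7)]
        res = pcoa(DistanceMatrix(d, ids))
        coords = res.coordinates.values
        rec = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        assert np.allclose(rec, d, atol=1e-9)

    def test_duplicate_rows_coincide(self):
        d = np.array(
            [[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]], dtype=float
        )
        res = pcoa(DistanceMatrix(d, ["a", "b", "c"]))
        assert np.allclose(res.coordinates.loc["a"], res.coordinates.loc["b"], atol=1e-9)

    def test_matches_scikit_bio_eigenvalues(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        dm = DistanceMatrix(d, [f"p{i}" for i in range(6)])
        ours = pcoa(dm)
        theirs = skbio_pcoa(dm, method="eigh")
        n_pos = ours.coordinates.shape[1]
        assert np.allclose(
            ours.eigenvalues[:n_pos], theirs.eigvals.values[:n_pos], atol=1e-9
        )

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]), ids=["a", "b"])


class TestStructuralSeparation:
    def test_leading_axis_separates_above_from_below_ground(self):
        """Tissue-affinity structure in the generator must surface as
        above-/below-ground separation on PC1 of weighted-UniFrac PCoA."""
        from skbio import DistanceMatrix as DM
        from beetscreen.simulate import StudyDesign, simulate_study
        from beetscreen.tree import neighbor_joining

        hits = 0
        n_seeds = 5  # the acceptance suite runs the full 20
        for seed in range(n_seeds):
            study = simulate_study(
                StudyDesign(seed=seed, n_otus=40),
                include_sequences=False,
                include_inoculation=False,
            )
            clone = [
                l
                for l in study.counts.columns
                if study.sample_metadata.loc[l, "provenance"] == "clone"
            ]
            table = OTUTable(study.counts[clone].copy(), study.sample_metadata.loc[clone])
            rng = np.random.default_rng(seed)
            n = len(table.otu_ids)
            m = rng.uniform(0.05, 0.5, size=(n, n))
            m = (m + m.T) / 2.0
            np.fill_diagonal(m, 0.0)
            tree = neighbor_joining(DM(m, table.otu_ids))
            pc1 = pcoa(unifrac_matrix(tree, table)).coordinates["PC1"]
            above = [
                l
                for l in clone
                if study.sample_metadata.loc[l, "tissue"] in ("leaf_blade", "petiole")
            ]
            below = [l for l in clone if l not in above]
            hits += pc1[above].max() < pc1[below].min() or pc1[below].max() < pc1[above].min()
        assert hits == n_seeds
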