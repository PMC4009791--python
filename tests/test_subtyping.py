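"""Prototype-guided k-means, bootstrap stability, consensus clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somportraits.som import SOMConfig, SOMModel
from somportraits.spots import Spot
from somportraits.subtyping import (
    bootstrap_stability,
    consensus_cluster,
    kmeans_assign,
    prototype_from_spot,
)


def _blob_metadata(centers, n_per, spread=0.1, seed=0):
    """Well-separated sample clusters in a small metagene space."""
    rng = np.random.default_rng(seed)
    cols = []
    for c in centers:
        cols.append(np.asarray(c)[:, None]
                    + rng.normal(0, spread, size=(len(c), n_per)))
    metadata = np.hstack(cols)
    labels = np.repeat([f"C{i + 1}" for i in range(len(centers))], n_per)
    return metadata, pd.Series(labels, index=[f"s{i}" for i in range(metadata.shape[1])])


class TestPrototypes:
    def _model(self, metadata, rows, cols):
        K = rows * cols
        return SOMModel(SOMConfig(rows=rows, cols=cols), metadata,
                        np.zeros(K, dtype=int), [f"g{i}" for i in range(K)],
                        [f"s{j}" for j in range(metadata.shape[1])])

    def test_spot_prototype_by_construction(self):
        metadata = np.arange(12.0).reshape(6, 2)  # max value 11
        model = self._model(metadata, 2, 3)
        spot = Spot("A", metagenes=(0, 2, 5), genes=("g0",), centroid=(0, 0))
        proto = prototype_from_spot(spot, model)
        expected = np.zeros(6)
        expected[[0, 2, 5]] = 11.0
        np.testing.assert_array_equal(proto, expected)

    def test_disjoint_spots_disjoint_supports(self):
        metadata = np.random.default_rng(0).normal(size=(9, 2))
        model = self._model(metadata, 3, 3)
        p1 = prototype_from_spot(Spot("A", (0, 1), ("g",), (0, 0)), model)
        p2 = prototype_from_spot(Spot("B", (7, 8), ("g",), (2, 2)), model)
        assert not np.any((p1 != 0) & (p2 != 0))

    def test_zero_metadata_degenerate_warning(self):
        model = self._model(np.zeros((4, 2)), 2, 2)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            proto = prototype_from_spot(Spot("A", (0,), ("g",), (0, 0)), model)
        np.testing.assert_array_equal(proto, 0.0)

    def test_empty_spot_rejected(self):
        model = self._model(np.ones((4, 2)), 2, 2)
        with pytest.raises(ValueError, match="empty"):
            prototype_from_spot(Spot("A", (), (), (0, 0)), model)


class TestKMeans:
    def test_true_centroids_are_a_fixed_point(self):
        metadata, labels = _blob_metadata([[0, 0, 5], [5, 5, 0]], 20, seed=1)
        true_centroids = {
            "C1": metadata[:, :20].mean(axis=1),
            "C2": metadata[:, 20:].mean(axis=1),
        }
        result = kmeans_assign(metadata, true_centroids,
                               sample_ids=labels.index)
        assert (result.labels == labels).all()
        assert len(result.objective_path) <= 3  # converged immediately

    def test_k1_centroid_is_overall_mean(self):
        rng = np.random.default_rng(2)
        metadata = rng.normal(size=(5, 30))
        result = kmeans_assign(metadata, {"C1": rng.normal(size=5)})
        np.testing.assert_allclose(result.centroids.loc["C1"].to_numpy(),
                                   metadata.mean(axis=1), atol=1e-12)

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(3)
        metadata = rng.normal(size=(8, 100))
        init = {f"C{i}": rng.normal(size=8) for i in range(1, 5)}
        result = kmeans_assign(metadata, init)
        path = result.objective_path
        assert all(b <= a + 1e-9 for a, b in zip(path, path[1:]))

    def test_centroids_equal_member_means_at_convergence(self):
        metadata, _ = _blob_metadata([[0, 0], [4, 4], [0, 8]], 15, seed=4)
        init = {f"C{i + 1}": metadata[:, i * 15] for i in range(3)}
        result = kmeans_assign(metadata, init, sample_ids=[f"s{i}" for i in range(45)])
        points = metadata.T
        for cls in result.class_names:
            members = points[(result.labels == cls).to_numpy()]
            np.testing.assert_allclose(result.centroids.loc[cls].to_numpy(),
                                       members.mean(axis=0), atol=1e-9)

    def test_planted_subtype_recovery(self, reference_cohort, reference_model):
        from sklearn.metrics import adjusted_rand_score
        from somportraits.spots import detect_spots

        cfg, _, truth = reference_cohort
        spotset = detect_spots(reference_model)
        module_spots = sorted(spotset, key=lambda s: -len(s.genes))[:5]
        # drop the contamination spot: keep the four subtype modules
        contam = set(truth.module_gene_ids("contamination"))
        keep = [s for s in module_spots if len(contam & set(s.genes)) < len(s.genes) / 2]
        assert len(keep) >= 4
        prototypes = {s.label: prototype_from_spot(s, reference_model)
                      for s in keep[:4]}
        result = kmeans_assign(reference_model.metadata, prototypes,
                               sample_ids=reference_model.sample_ids)
        ari = adjusted_rand_score(truth.sample_labels.to_numpy(),
                                  result.labels.to_numpy())
        assert ari >= 0.95


class TestBootstrapStability:
    def test_perfectly_separated_clusters_score_one(self):
        metadata, labels = _blob_metadata([[0, 0, 10], [10, 10, 0]], 25, seed=5)
        scores = bootstrap_stability(metadata, labels, n_reps=100, seed=0)
        np.testing.assert_allclose(scores.to_numpy(), 1.0)

    def test_midway_sample_scores_about_half(self):
        """A sample exactly midway between two mirror-image clusters flips
        with the resampling draw, so its score converges to ~0.5. Mirror
        symmetry (c2 = −c1, one midway twin per class) removes the dataset-
        level asymmetry that would otherwise pin the score at 0 or 1."""
        rng = np.random.default_rng(6)
        n = 200
        c1 = np.vstack([rng.normal(-5, 2.0, n), rng.normal(0, 2.0, n)])
        metadata = np.hstack([c1, -c1, np.zeros((2, 2))])
        labels = pd.Series(["C1"] * n + ["C2"] * n + ["C1", "C2"],
                           index=[f"s{i}" for i in range(2 * n)] + ["midA", "midB"])
        scores = bootstrap_stability(metadata, labels, n_reps=500, seed=1)
        assert abs(scores["midA"] - 0.5) < 0.1
        assert abs(scores["midB"] - 0.5) < 0.1

    def test_seeded_determinism(self):
        metadata, labels = _blob_metadata([[0, 1], [3, 4]], 10, seed=7)
        s1 = bootstrap_stability(metadata, labels, n_reps=50, seed=2)
        s2 = bootstrap_stability(metadata, labels, n_reps=50, seed=2)
        pd.testing.assert_series_equal(s1, s2)

    def test_single_class_rejected(self):
        metadata, labels = _blob_metadata([[0, 1]], 10)
        with pytest.raises(ValueError, match="two classes"):
            bootstrap_stability(metadata, labels)

    def test_four_class_labels_more_stable_than_underspecified_three(self):
        """When the data hold four clusters and the three-class scheme merges
        two distant ones, members of the merged class sit closer to foreign
        centroids and defect under resampling: four-class stability scores
        stochastically dominate (Mann-Whitney, p < 0.01)."""
        rng = np.random.default_rng(0)
        centers, n_per = [0.0, 2.0, 8.0, 10.0], 30
        cols, labs = [], []
        for i, c in enumerate(centers):
            pts = rng.normal(0, 0.5, size=(5, n_per))
            pts[0] += c
            cols.append(pts)
            labs += [f"C{i + 1}"] * n_per
        metadata = np.hstack(cols)
        labels4 = pd.Series(labs, index=[f"s{i}" for i in range(4 * n_per)])
        labels3 = labels4.replace({"C2": "mid", "C3": "mid"})
        s4 = bootstrap_stability(metadata, labels4, n_reps=200, seed=1)
        s3 = bootstrap_stability(metadata, labels3, n_reps=200, seed=1)
        stat = stats.mannwhitneyu(s4.dropna(), s3.dropna(), alternative="greater")
        assert stat.pvalue < 0.01

    def test_default_cohort_true_labels_at_stability_ceiling(self, reference_cohort,
                                                             reference_model):
        """The reference cohort's subtypes are cleanly separated in metagene
        space, so the true four-class labels are maximally stable."""
        _, _, truth = reference_cohort
        labels4 = truth.sample_labels.loc[reference_model.sample_ids]
        s4 = bootstrap_stability(reference_model.metadata, labels4,
                                 n_reps=150, seed=3)
        np.testing.assert_allclose(s4.to_numpy(), 1.0)


class TestConsensus:
    def test_two_blobs_binary_consensus(self):
        metadata, labels = _blob_metadata([[0, 0], [8, 8]], 15, seed=8)
        result = consensus_cluster(metadata, labels.index, k_range=(2,),
                                   n_reps=100, seed=0)
        cons = result.consensus[2]
        same = labels.to_numpy()[:, None] == labels.to_numpy()[None, :]
        observed = cons.to_numpy()
        np.testing.assert_allclose(observed[same], 1.0)
        np.testing.assert_allclose(observed[~same], 0.0)

    def test_consensus_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(9)
        metadata = rng.normal(size=(6, 24))
        result = consensus_cluster(metadata, k_range=(2, 3), n_reps=50, seed=1)
        for k, cons in result.consensus.items():
            arr = cons.to_numpy()
            np.testing.assert_allclose(arr, arr.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(arr), 1.0)
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_cdf_nondecreasing_from_zero_to_one(self):
        rng = np.random.default_rng(10)
        metadata = rng.normal(size=(6, 20))
        result = consensus_cluster(metadata, k_range=(2, 3), n_reps=50, seed=2)
        for k, (grid, cdf) in result.cdf.items():
            assert (np.diff(cdf) >= 0).all()
            assert cdf[-1] == pytest.approx(1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        metadata, labels = _blob_metadata([[0, 0], [5, 5], [0, 9]], 8, seed=12)
        n = metadata.shape[1]
        perm = rng.permutation(n)
        ids = [f"s{i}" for i in range(n)]
        r1 = consensus_cluster(metadata, ids, k_range=(3,), n_reps=80, seed=3)
        r2 = consensus_cluster(metadata[:, perm], [ids[i] for i in perm],
                               k_range=(3,), n_reps=80, seed=3)
        c1 = r1.consensus[3].loc[ids, ids].to_numpy()
        c2 = r2.consensus[3].loc[ids, ids].to_numpy()
        # resampling indices differ, but the co-clustering structure agrees
        np.testing.assert_allclose(c1, c2, atol=0.1)

    def test_subsample_smaller_than_k_rejected(self):
        metadata, _ = _blob_metadata([[0, 0], [5, 5]], 3, seed=13)
        with pytest.raises(ValueError, match="subsample"):
            consensus_cluster(metadata, k_range=(5,), subsample_fraction=0.5)

    def test_cdf_gain_collapses_after_planted_k(self, clean_reference_model):
        """On a corrected (contamination-free) cohort with four planted
        subtypes, the consensus CDF stops improving beyond k = 4."""
        model = clean_reference_model
        result = consensus_cluster(model.metadata, model.sample_ids,
                                   k_range=(2, 3, 4, 5), n_reps=150, seed=4)
        gains = result.incremental_gains()
        assert gains[5] < 0.5 * gains[4]
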