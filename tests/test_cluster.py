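"""Multimodality screening, Ward agglomeration and cluster-count selection
against analytic limits and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import calinski_harabasz_score

from gliamorph.cluster import (
    ClusterError,
    fit_clusters,
    labels_at_k,
    mmi,
    mmi_table,
    renumber_by_size,
    select_multimodal,
    thorndike_select,
    vrc,
    vrc_select,
    ward_hca,
    z_normalize,
)

#: the published multimodality indices of the 15 descriptors
PRINTED_MMI = {
    "cell_circularity": 0.669,
    "convex_hull_area_um2": 0.577,
    "cell_perimeter_um": 0.567,
    "convex_hull_span_ratio": 0.558,
    "convex_hull_circularity": 0.546,
    "maxmin_hull_radii_ratio": 0.479,
    "roughness": 0.450,
    "convex_hull_perimeter_um": 0.439,
    "density": 0.429,
    "mean_hull_radius_um": 0.429,
    "cell_area_um2": 0.412,
    "bounding_circle_diameter_um": 0.408,
    "max_span_across_hull_um": 0.404,
    "fractal_dimension": 0.396,
    "lacunarity": 0.393,
}


class TestMMI:
    """Analytic limits of (skew^2+1)/(excess kurtosis + finite-n term)."""

    def test_uniform_limit_five_ninths(self, rng):
        x = rng.uniform(0, 1, 100_000)
        assert mmi(x).value == pytest.approx(5 / 9, abs=0.02)

    def test_normal_limit_one_third(self, rng):
        x = rng.normal(0, 1, 100_000)
        assert mmi(x).value == pytest.approx(1 / 3, abs=0.02)

    def test_two_point_limit_one(self):
        x = np.r_[np.full(50_000, -1.0), np.full(50_000, 1.0)]
        assert mmi(x).value == pytest.approx(1.0, abs=0.02)

    def test_small_sample_and_constant_rejected(self):
        with pytest.raises(ClusterError, match="n >= 4"):
            mmi([1.0, 2.0, 3.0])
        with pytest.raises(ClusterError, match="constant"):
            mmi([2.0] * 10)

    @given(
        scale=st.floats(0.001, 1e4),
        shift=st.floats(-1e4, 1e4),
    )
    @settings(max_examples=50, deadline=None)
    def test_location_scale_invariance(self, scale, shift):
        rng = np.random.default_rng(12)
        x = rng.normal(3, 2, 500)
        assert mmi(scale * x + shift).value == pytest.approx(mmi(x).value, abs=1e-9)


class TestSelection:
    def test_published_values_select_the_published_four(self):
        mmis = pd.Series(PRINTED_MMI)
        picked = select_multimodal(mmis, threshold=0.55)
        assert picked == [
            "cell_circularity",
            "convex_hull_area_um2",
            "cell_perimeter_um",
            "convex_hull_span_ratio",
        ]

    def test_threshold_is_strict(self):
        picked = select_multimodal(pd.Series({"a": 0.55, "b": 0.56}), threshold=0.55)
        assert picked == ["b"]

    def test_nothing_multimodal_warns(self):
        with pytest.warns(UserWarning, match="no descriptor"):
            assert select_multimodal(pd.Series({"a": 0.3, "b": 0.3})) == []


class TestZNormalize:
    def test_sample_sd_convention(self):
        z, tf = z_normalize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert list(z["x"]) == [-1.0, 0.0, 1.0]

    def test_reapplication_is_identity(self, rng):
        df = pd.DataFrame(rng.normal(5, 3, (40, 3)), columns=list("abc"))
        z, _ = z_normalize(df)
        z2, _ = z_normalize(z)
        pd.testing.assert_frame_equal(z, z2)

    def test_stored_transform_applies_to_new_cells(self, rng):
        df = pd.DataFrame(rng.normal(5, 3, (40, 2)), columns=list("ab"))
        _, tf = z_normalize(df)
        new = pd.Series({"a": 7.0, "b": 1.0})
        out = tf.apply_vector(new)
        assert out["a"] == pytest.approx((7.0 - df["a"].mean()) / df["a"].std(ddof=1))

    def test_constant_column_rejected(self):
        with pytest.raises(ClusterError, match="constant"):
            z_normalize(pd.DataFrame({"x": [1.0, 1.0, 1.0]}))


def brute_force_ward(X: np.ndarray) -> list[set[frozenset]]:
    """Reference agglomeration: at each step merge the pair whose union
    minimally increases the total within-cluster sum of squares."""

    def ess(idx):
        pts = X[sorted(idx)]
        return float(((pts - pts.mean(0)) ** 2).sum())

    clusters = [frozenset([i]) for i in range(len(X))]
    partitions = []
    while len(clusters) > 1:
        best, cost = None, np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                delta = ess(clusters[i] | clusters[j]) - ess(clusters[i]) - ess(clusters[j])
                if delta < cost:
                    cost, best = delta, (i, j)
        i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        partitions.append(set(clusters))
    return partitions


class TestWard:
    def test_merge_sequence_matches_brute_force(self, rng):
        X = rng.normal(0, 1, (8, 3))
        tree = ward_hca(X)
        oracle = brute_force_ward(X)
        for step, expected in enumerate(oracle):
            k = 8 - 1 - step
            if k < 1:
                break
            labels = fcluster(tree, t=k, criterion="maxclust")
            got = {
                frozenset(np.flatnonzero(labels == c)) for c in np.unique(labels)
            }
            assert got == expected

    def test_tight_pairs_recovered_at_their_k(self):
        X = np.array(
            [[0, 0], [0.1, 0], [10, 10], [10.1, 10], [20, 0], [20.1, 0]], float
        )
        tree = ward_hca(X)
        labels = fcluster(tree, t=3, criterion="maxclust")
        assert len(np.unique(labels)) == 3
        assert labels[0] == labels[1] and labels[2] == labels[3] and labels[4] == labels[5]

    def test_merge_heights_monotone(self, rng):
        X = rng.normal(0, 1, (30, 4))
        tree = ward_hca(X)
        assert (np.diff(tree[:, 2]) >= -1e-12).all()

    def test_duplicated_points_join_first(self, rng):
        X = rng.normal(0, 1, (6, 2))
        XX = np.vstack([X, X])
        tree = ward_hca(XX)
        labels = fcluster(tree, t=6, criterion="maxclust")
        for i in range(6):
            assert labels[i] == labels[i + 6]


class TestRenumbering:
    def test_cluster_one_is_largest(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (30, 2))])
        labels = np.r_[np.ones(10, int), np.full(30, 2)]
        out = renumber_by_size(labels, X)
        assert (out[10:] == 1).all() and (out[:10] == 2).all()

    def test_size_ties_broken_by_centroid_norm(self):
        X = np.array([[9.0, 0], [9.0, 0], [1.0, 0], [1.0, 0]])
        labels = np.array([1, 1, 2, 2])
        out = renumber_by_size(labels, X)
        assert (out == np.array([2, 2, 1, 1])).all()


class TestSelection_k:
    def test_two_blobs_give_k_two(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 3)), rng.normal(10, 1, (50, 3))])
        tree = ward_hca(X)
        assert thorndike_select(tree, X).chosen_k == 2
        assert vrc_select(tree, X).chosen_k == 2

    def test_four_blobs_give_k_four(self, rng):
        X = np.vstack([rng.normal(m, 0.5, (25, 2)) for m in ([0, 0], [6, 0], [0, 6], [6, 6])])
        tree = ward_hca(X)
        assert thorndike_select(tree, X).chosen_k == 4
        assert vrc_select(tree, X).chosen_k == 4

    def test_structureless_data_flagged_low_confidence(self, rng):
        X = rng.normal(0, 1, (100, 3))
        tree = ward_hca(X)
        with pytest.warns(UserWarning, match="no clear elbow"):
            res = thorndike_select(tree, X)
        assert res.low_confidence and res.chosen_k == 2


class TestVRC:
    def test_nine_point_toy_matches_direct_formula(self):
        X = np.array([[0.0], [0.5], [1.0], [10.0], [10.5], [11.0], [20.0], [20.5], [21.0]])
        labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        grand = X.mean()
        ssb = sum(3 * (X[labels == c].mean() - grand) ** 2 for c in (1, 2, 3))
        ssw = sum(((X[labels == c] - X[labels == c].mean()) ** 2).sum() for c in (1, 2, 3))
        expected = float(ssb / ssw) * (9 - 3) / (3 - 1)
        assert vrc(X, labels) == pytest.approx(expected, rel=1e-12)

    def test_matches_library_oracle(self, rng):
        X = rng.normal(0, 1, (60, 4))
        labels = rng.integers(1, 5, 60)
        assert vrc(X, labels) == pytest.approx(calinski_harabasz_score(X, labels), rel=1e-9)

    def test_singleton_clusters_give_infinity(self):
        X = np.array([[0.0], [10.0]])
        with pytest.warns(UserWarning, match="infinite"):
            assert vrc(X, np.array([1, 2])) == np.inf

    def test_k_one_rejected(self, rng):
        X = rng.normal(0, 1, (10, 2))
        with pytest.raises(ClusterError, match="k = 1"):
            vrc(X, np.ones(10, int))

    def test_between_plus_within_equals_total(self, rng):
        X = rng.normal(0, 2, (50, 3))
        labels = rng.integers(1, 4, 50)
        grand = X.mean(axis=0)
        total = ((X - grand) ** 2).sum()
        ssb = ssw = 0.0
        for c in np.unique(labels):
            mem = X[labels == c]
            ssb += len(mem) * ((mem.mean(0) - grand) ** 2).sum()
            ssw += ((mem - mem.mean(0)) ** 2).sum()
        assert ssb + ssw == pytest.approx(total, rel=1e-9)


def test_fit_clusters_recovers_archetypes(cohort_run):
    """On the default synthetic cohort both selection rules find k=4 and the
    k=4 partition matches the generating archetypes (ARI >= 0.8)."""
    from sklearn.metrics import adjusted_rand_score

    model = cohort_run.cluster_model
    assert model.vrc.chosen_k == 4
    assert model.thorndike.chosen_k == 4
    ari = adjusted_rand_score(
        cohort_run.metadata["archetype"], cohort_run.cluster_labels
    )
    assert ari >= 0.8
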