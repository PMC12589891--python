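"""SOM training, metaclustering, abundance statistics, cluster profiling."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from cartprofiler.som import (
    MetaclusteredSOM,
    SelfOrganizingMap,
    cluster_abundance,
    delta_mean_abundance,
    metacluster,
    minmax_scale_profiles,
    outcome_association,
    profile_clusters,
)


def _blobs(rng, k=5, n_per=1000, d=6, scale=10.0):
    centers = rng.normal(scale=scale, size=(k, d))
    X = np.vstack([rng.normal(c, 1.0, size=(n_per, d)) for c in centers])
    y = np.repeat(np.arange(k), n_per)
    perm = rng.permutation(len(X))
    return X[perm], y[perm]


class TestSOM:
    def test_single_event_codebook_converges_to_it(self):
        x = np.array([[2.0, -1.0, 5.0]])
        with pytest.warns(UserWarning, match="fewer events"):
            m = SelfOrganizingMap(xdim=3, ydim=3, rlen=5, seed=0).fit(x)
        np.testing.assert_allclose(m.codebook_, np.tile(x, (9, 1)), atol=1e-4)
        assert m.labels_.shape == (1,)

    def test_assignment_equals_exhaustive_nearest_codebook(self, rng):
        X = rng.normal(size=(1000, 8))
        m = SelfOrganizingMap(seed=3421).fit(X)
        oracle = cdist(X, m.codebook_).argmin(axis=1)
        np.testing.assert_array_equal(m.labels_, oracle)
        np.testing.assert_array_equal(m.predict(X), oracle)

    def test_same_seed_identical_codebook(self, rng):
        X = rng.normal(size=(2000, 5))
        a = SelfOrganizingMap(seed=3421).fit(X)
        b = SelfOrganizingMap(seed=3421).fit(X)
        np.testing.assert_array_equal(a.codebook_, b.codebook_)

    def test_sklearn_params_round_trip(self):
        m = SelfOrganizingMap(xdim=4, ydim=6, rlen=3, seed=1)
        assert SelfOrganizingMap(**m.get_params()).get_params() == m.get_params()


class TestMetacluster:
    def test_k_equal_nodes_is_identity(self, rng):
        X = rng.normal(size=(500, 4))
        m = SelfOrganizingMap(xdim=4, ydim=4, seed=0).fit(X)
        occ = m.occupied_nodes()
        mapping = metacluster(m.codebook_, k=len(occ), occupied=occ)
        assert len(set(mapping[occ])) == len(occ)

    def test_two_separated_blobs_split_perfectly(self, rng):
        X, y = _blobs(rng, k=2, n_per=2000, scale=20.0)
        m = MetaclusteredSOM(n_metaclusters=2, xdim=6, ydim=6, seed=3421).fit(X)
        assert adjusted_rand_score(y, m.labels_) == 1.0

    def test_50_node_map_consolidates_to_35(self, rng):
        """A 50-node SOM consolidated to 35 metaclusters covers exactly 35 labels."""
        X = rng.normal(size=(5000, 10))
        m = SelfOrganizingMap(xdim=10, ydim=5, rlen=10, seed=3421).fit(X)
        occ = m.occupied_nodes()
        mapping = metacluster(m.codebook_, k=35, occupied=occ)
        assert len(np.unique(mapping[occ])) == 35

    def test_k_exceeding_nodes_rejected(self, rng):
        X = rng.normal(size=(100, 3))
        m = SelfOrganizingMap(xdim=3, ydim=3, seed=0).fit(X)
        with pytest.raises(ValueError, match="k must lie"):
            metacluster(m.codebook_, k=10, occupied=m.occupied_nodes())

    def test_recovery_of_separated_populations(self, rng):
        X, y = _blobs(rng, k=5, n_per=1000)
        m = MetaclusteredSOM(n_metaclusters=5, seed=3421).fit(X)
        assert adjusted_rand_score(y, m.labels_) >= 0.9


class TestAbundance:
    def test_single_cluster_rows_are_100(self):
        tab = cluster_abundance([1, 1, 1, 1], ["a", "a", "b", "b"])
        assert np.allclose(tab.to_numpy(), 100.0)

    def test_equal_split_is_25_each(self):
        tab = cluster_abundance([1, 2, 3, 4], ["s"] * 4)
        assert np.allclose(tab.loc["s"], 25.0)

    def test_matches_counting_oracle(self, rng):
        labels = rng.integers(1, 6, size=500)
        samples = rng.choice(["a", "b", "c"], size=500)
        tab = cluster_abundance(labels, samples)
        for s in "abc":
            mask = samples == s
            for c in range(1, 6):
                expected = 100.0 * (labels[mask] == c).sum() / mask.sum()
                got = tab.loc[s].get(c, 0.0)
                assert got == pytest.approx(expected)

    def test_rows_sum_to_100(self, rng):
        tab = cluster_abundance(rng.integers(0, 10, 2000), rng.choice(list("abcd"), 2000))
        np.testing.assert_allclose(tab.sum(axis=1), 100.0, atol=1e-9)

    def test_empty_sample_row_is_nan(self):
        tab = cluster_abundance([1, 2], ["a", "a"], samples=["a", "b"])
        assert tab.loc["b"].isna().all()


class TestDeltaAndOutcome:
    def _tab(self):
        return pd.DataFrame(
            {"c1": [10.0, 20.0, 5.0], "c2": [90.0, 80.0, 95.0]},
            index=["p1", "p2", "p3"],
        )

    def test_identical_groups_zero_delta(self):
        tab = pd.DataFrame({"c1": [30.0, 30.0], "c2": [70.0, 70.0]}, index=["a", "b"])
        delta = delta_mean_abundance(tab, {"a": "C7R", "b": "GD2"})
        assert np.allclose(delta, 0.0)

    def test_arithmetic_example(self):
        delta = delta_mean_abundance(self._tab(), {"p1": "C7R", "p2": "C7R", "p3": "GD2"})
        assert delta["c1"] == pytest.approx(10.0)  # mean(10,20) - 5
        assert "mean(C7R) - mean(GD2)" in delta.attrs["convention"]

    def test_deltas_sum_to_zero(self, rng):
        raw = rng.random((6, 5))
        tab = pd.DataFrame(100 * raw / raw.sum(axis=1, keepdims=True), index=list("abcdef"))
        groups = dict(zip("abcdef", ["C7R"] * 3 + ["GD2"] * 3))
        assert delta_mean_abundance(tab, groups).sum() == pytest.approx(0.0, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            delta_mean_abundance(self._tab(), {"p1": "C7R", "p2": "C7R", "p3": "C7R"})

    def test_monotone_abundance_gives_rho_plus_minus_one(self):
        tab = pd.DataFrame({"up": [1.0, 2.0, 3.0], "down": [3.0, 2.0, 1.0]}, index=["x", "y", "z"])
        res = outcome_association(tab, {"x": 0, "y": 1, "z": 2})
        assert res.loc["up", "rho"] == pytest.approx(1.0)
        assert res.loc["down", "rho"] == pytest.approx(-1.0)

    def test_constant_abundance_flagged_undefined(self):
        tab = pd.DataFrame({"flat": [5.0, 5.0, 5.0]}, index=["x", "y", "z"])
        res = outcome_association(tab, {"x": 0, "y": 1, "z": 2})
        assert res.loc["flat", "undefined"]
        assert np.isnan(res.loc["flat", "rho"])

    def test_random_labels_mean_rho_near_zero(self, rng):
        """Permutation oracle: rho under shuffled outcomes averages ~0."""
        x = rng.random(8)
        outcomes = np.array([0, 0, 1, 1, 1, 2, 2, 2])
        rhos = []
        for _ in range(1000):
            perm = rng.permutation(outcomes)
            tab = pd.DataFrame({"c": x}, index=range(8))
            rhos.append(outcome_association(tab, dict(enumerate(perm)))["rho"].iloc[0])
        assert abs(np.nanmean(rhos)) < 0.05


class TestProfiles:
    def test_scaled_in_unit_interval_and_argmax_preserved(self, rng):
        X = rng.lognormal(1, 1, size=(600, 4))
        labels = rng.integers(0, 5, size=600)
        prof = profile_clusters(X, labels)
        assert (prof.scaled.to_numpy() >= 0).all() and (prof.scaled.to_numpy() <= 1).all()
        np.testing.assert_array_equal(
            prof.scaled.to_numpy().argmax(axis=0), prof.mfi.to_numpy().argmax(axis=0)
        )

    def test_max_attaining_cluster_scales_to_one_and_present(self, rng):
        X = np.vstack([np.full((10, 2), 1.0), np.full((10, 2), 9.0)])
        labels = [0] * 10 + [1] * 10
        prof = profile_clusters(X, labels)
        assert prof.scaled.iloc[1, 0] == 1.0
        assert prof.presence.iloc[1, 0]

    def test_constant_marker_ties_map_to_zero(self):
        X = np.column_stack([np.r_[np.zeros(5), np.ones(5)], np.full(10, 7.0)])
        prof = profile_clusters(X, [0] * 5 + [1] * 5)
        assert (prof.scaled.iloc[:, 1] == 0.0).all()
        assert not prof.presence.iloc[:, 1].any()

    def test_minmax_idempotent(self, rng):
        mfi = pd.DataFrame(rng.random((5, 4)))
        once = minmax_scale_profiles(mfi)
        twice = minmax_scale_profiles(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_presence_calls_on_handmade_fixture(self):
        # 5 clusters x 6 markers; hand-computed min-max and 0.58 calls
        mfi = pd.DataFrame(
            [
                [0.0, 10.0, 5.0, 1.0, 3.0, 2.0],
                [10.0, 0.0, 5.0, 1.0, 3.0, 2.0],
                [5.0, 5.0, 5.0, 1.0, 3.0, 2.0],
                [2.0, 8.0, 5.0, 1.0, 9.0, 2.0],
                [8.0, 2.0, 5.0, 1.0, 0.0, 2.0],
            ],
            columns=list("ABCDEF"),
        )
        scaled = minmax_scale_profiles(mfi)
        presence = scaled >= 0.58
        # marker A: scaled = x/10 -> present for clusters 1 (1.0) and 4 (0.8)
        assert list(presence["A"]) == [False, True, False, False, True]
        # marker B mirrors A
        assert list(presence["B"]) == [True, False, False, True, False]
        # markers C, D, F constant -> tie -> 0 -> absent everywhere
        for m in "CDF":
            assert not presence[m].any()
        # marker E: (3-0)/9=0.33, 1.0 at cluster 3
        assert list(presence["E"]) == [False, False, False, True, False]

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="2 clusters"):
            profile_clusters(np.ones((5, 2)), [0] * 5)


class TestEmbedding:
    def test_embedding_contract(self, rng):
        from cartprofiler.som import embed_2d

        centers = np.array([[0.0] * 4, [25.0] * 4])
        X = np.vstack([rng.normal(c, 0.5, size=(80, 4)) for c in centers])
        X[5] = X[4]  # exact duplicate pair
        emb = embed_2d(X, n_neighbors=10, seed=2553, n_epochs=50)
        assert emb.shape == (160, 2)
        # duplicates land together
        assert np.linalg.norm(emb[5] - emb[4]) < 1.0
        # blob separation exceeds within-blob spread
        a, b = emb[:80], emb[80:]
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        within = max(a.std(), b.std())
        assert between > within
        # same seed reproduces the layout
        emb2 = embed_2d(X, n_neighbors=10, seed=2553, n_epochs=50)
        np.testing.assert_allclose(emb, emb2, atol=1e-6)

    def test_too_few_events_rejected(self, rng):
        from cartprofiler.som import embed_2d

        with pytest.raises(ValueError, match="n_neighbors"):
            embed_2d(rng.normal(size=(10, 3)), n_neighbors=15)
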