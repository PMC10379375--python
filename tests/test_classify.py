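"""PCA, seeded k-means, cluster summaries and the loading report."""

import itertools

import numpy as np
import pandas as pd
import pytest

import timask.classify as clf
import timask.stats as st
from timask.errors import ParameterError, UsageError
from timask.masking import MaskingResult


def _std_matrix(columns: dict):
    n = len(next(iter(columns.values())))
    df = pd.DataFrame(columns, index=[f"m{i:02d}" for i in range(n)])
    return st.standardize(st.ParameterMatrix(df))


def _random_matrix(n=20, seed=0):
    rng = np.random.default_rng(seed)
    cols = {name: rng.normal(0, 1, n) for name in ("Imax", "DurInc", "DurDec", "AreaDec")}
    return _std_matrix(cols)


class TestPCA:
    def test_rank_one_data(self):
        base = [1.0, 2.0, 3.0, 4.0, 7.0]
        m = _std_matrix({"AreaInc": base, "AreaDec": base})  # exactly on y = x
        res = clf.pca_fit(m)
        assert np.allclose(res.explained_variance_ratio, [1.0, 0.0], atol=1e-12)
        assert np.allclose(np.abs(res.loadings["PCA1"]), 1 / np.sqrt(2))

    def test_scores_uncorrelated(self):
        res = clf.pca_fit(_random_matrix())
        cov = np.cov(res.full_scores.to_numpy(), rowvar=False)
        assert np.abs(cov[~np.eye(cov.shape[0], dtype=bool)]).max() < 1e-9

    def test_reconstruction_from_all_components(self):
        m = _random_matrix(seed=3)
        res = clf.pca_fit(m)
        recon = res.full_scores.to_numpy() @ res.loadings.to_numpy().T + res.mean
        assert np.allclose(recon, m.data.to_numpy(), atol=1e-9)

    def test_unit_norm_loadings_and_decreasing_evr(self):
        res = clf.pca_fit(_random_matrix(seed=5))
        assert np.allclose(np.linalg.norm(res.loadings.to_numpy(), axis=0), 1.0)
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() == pytest.approx(1.0)

    def test_sign_convention_largest_loading_positive(self):
        res = clf.pca_fit(_random_matrix(seed=7))
        for col in res.loadings:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_unstandardized_rejected_without_override(self):
        raw = st.ParameterMatrix(_random_matrix().data * 3.0 + 1.0)
        with pytest.raises(UsageError):
            clf.pca_fit(raw)
        assert clf.pca_fit(raw, allow_unstandardized=True) is not None


def _triplets():
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    offsets = np.array([[0.0, 0.0], [0.5, 0.0], [0.0, 0.5]])
    return np.vstack([c + offsets for c in centers])


def _brute_force_kmeans(x, k):
    """Minimal inertia over every assignment of n points to k clusters."""
    best = np.inf
    for labels in itertools.product(range(k), repeat=len(x)):
        labels = np.array(labels)
        if len(set(labels.tolist())) < k:
            continue
        inertia = sum(
            ((x[labels == c] - x[labels == c].mean(axis=0)) ** 2).sum()
            for c in range(k)
        )
        best = min(best, inertia)
    return best


class TestKMeans:
    def test_separated_triplets_recovered(self):
        x = _triplets()
        labels, inertia = clf.kmeans_fit(x, k=3, seed=0)
        # each triplet is one cluster
        for g in (labels[:3], labels[3:6], labels[6:]):
            assert len(set(g.tolist())) == 1
        assert inertia == pytest.approx(_brute_force_kmeans(x, 3))

    def test_k_equals_n_zero_inertia(self):
        x = _triplets()
        _, inertia = clf.kmeans_fit(x, k=len(x), seed=0)
        assert inertia == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_under_seed(self):
        x = np.random.default_rng(3).normal(size=(40, 2))
        l1, i1 = clf.kmeans_fit(x, k=3, seed=42)
        l2, i2 = clf.kmeans_fit(x, k=3, seed=42)
        assert np.array_equal(l1, l2) and i1 == i2

    def test_inertia_non_increasing_in_k(self):
        x = np.random.default_rng(9).normal(size=(30, 2))
        inertias = [clf.kmeans_fit(x, k=k, seed=0)[1] for k in range(1, 6)]
        assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_k_beyond_n_rejected(self):
        with pytest.raises(ParameterError):
            clf.kmeans_fit(_triplets(), k=10)


class TestClusterModel:
    def test_high_masking_cluster_gets_largest_label(self):
        m = _random_matrix(seed=11)
        ids = m.material_ids
        rng = np.random.default_rng(0)
        masking = [MaskingResult(i, 0.0, float(rng.uniform(0, 10)), 5) for i in ids]
        model = clf.fit_cluster_model(m, masking=masking, k=3, seed=1)
        summary = clf.summarize_clusters(model.labels, masking)
        means = summary.table.set_index("cluster")["mean_masking_score"]
        assert means.idxmax() == max(means.index)

    def test_labels_take_k_values(self):
        model = clf.fit_cluster_model(_random_matrix(seed=2), k=3, seed=0)
        assert set(model.labels.unique()) == {0, 1, 2}


class TestSummaries:
    def test_printed_cluster_scores_average(self):
        scores = [8.4, 9.3, 9.0, 7.0, 9.5, 8.8, 4.8, 9.0]
        masking = [MaskingResult(f"m{i}", 10 - s, s, 10) for i, s in enumerate(scores)]
        labels = pd.Series([0] * 8, index=[f"m{i}" for i in range(8)])
        summary = clf.summarize_clusters(labels, masking)
        assert round(summary.table["mean_masking_score"].iloc[0], 1) == 8.2
        assert "skipped" in summary.note

    def test_disjoint_ranges_significant(self):
        ids = [f"m{i:02d}" for i in range(20)]
        scores = [9.0 + 0.01 * i for i in range(8)] + [5.0 + 0.01 * i for i in range(12)]
        masking = [MaskingResult(i, 10 - s, s, 10) for i, s in zip(ids, scores)]
        labels = pd.Series([1] * 8 + [0] * 12, index=ids)
        summary = clf.summarize_clusters(labels, masking)
        assert summary.high_cluster == 1
        assert summary.p_two_tailed < 0.05 and summary.significant


def _model_with_pc1(loadings: dict):
    names = list(loadings)
    df = pd.DataFrame({"PCA1": [loadings[n] for n in names]}, index=names)
    return clf.ClusterModel(
        loadings=df, explained_variance_ratio=np.array([1.0]),
        scores=pd.DataFrame(), labels=pd.Series(dtype=int), k=1, seed=0, inertia=0.0,
    )


class TestLoadingReport:
    def test_six_fold_dominance(self):
        rep = clf.loading_report(_model_with_pc1({"AreaInc": 0.167, "AreaDec": 0.985}))
        assert rep.table["parameter"].iloc[0] == "AreaDec"
        assert rep.top_ratio == pytest.approx(5.9, abs=0.05)
        assert "~5.9x" in rep.summary or "5.9" in rep.summary

    def test_equal_loadings_ratio_one(self):
        rep = clf.loading_report(_model_with_pc1({"Imax": 0.5, "Tstart": 0.5, "DurDec": 0.5}))
        assert rep.top_ratio == 1.0

    def test_sign_flip_invariant(self):
        up = clf.loading_report(_model_with_pc1({"AreaDec": 0.9, "AreaInc": -0.3}))
        down = clf.loading_report(_model_with_pc1({"AreaDec": -0.9, "AreaInc": 0.3}))
        pd.testing.assert_frame_equal(up.table[["parameter", "abs_loading"]],
                                      down.table[["parameter", "abs_loading"]])
        assert up.top_ratio == down.top_ratio
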