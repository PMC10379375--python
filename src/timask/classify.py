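"""PCA + k-means classification of materials by their TI profiles.

The standardized parameter matrix is projected onto its principal
components; the first two scores (PCA1, PCA2) form the plane in which
k-means (k = 3 by default, k-means++ with restarts) groups the materials.
Raw k-means labels are permutation-arbitrary, so clusters are relabeled
deterministically: the cluster with the highest mean masking score always
receives the largest label (the "high-masking cluster" is stable across
runs); without masking data the centroid PCA1 coordinate is used instead.

PCA component signs are arbitrary as well; here the largest-magnitude
loading of each component is made positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ParameterError, UsageError, ValidationError
from .masking import MaskingResult
from .stats import ParameterMatrix, mann_whitney_u


@dataclass
class PCAResult:
    """Loadings (parameters x components, unit-norm columns), explained
    variance ratios over *all* components, and per-material scores."""

    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame          # first n_components columns
    full_scores: pd.DataFrame     # all components, for reconstruction
    mean: np.ndarray


@dataclass
class ClusterModel:
    """Fitted PCA + k-means model for one study."""

    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame
    labels: pd.Series
    k: int
    seed: int | None
    inertia: float


@dataclass
class ClusterSummary:
    """Per-cluster sizes, mean masking scores and the high-vs-rest test."""

    table: pd.DataFrame           # cluster, n, mean_masking_score, members
    high_cluster: int
    U: float | None
    p_two_tailed: float | None
    significant: bool | None
    note: str = ""


@dataclass
class LoadingReport:
    """Parameters ranked by |PCA1 loading| with the top-two ratio."""

    table: pd.DataFrame           # parameter, loading_pc1, abs_loading
    top_ratio: float

    @property
    def summary(self) -> str:
        first, second = self.table["parameter"].iloc[:2]
        return (
            f"{first} dominates PCA1; |loading| ~{self.top_ratio:.1f}x "
            f"that of {second}"
        )


def pca_fit(
    matrix: ParameterMatrix,
    n_components: int = 2,
    allow_unstandardized: bool = False,
) -> PCAResult:
    """Principal components of the (standardized) parameter matrix.

    All components are computed so explained-variance ratios sum to 1;
    ``n_components`` only selects how many score columns are exposed for
    downstream clustering.  Unstandardized input is rejected unless
    ``allow_unstandardized`` is set (raw-scale PCA, where large-magnitude
    parameters such as areas dominate the loadings).
    """
    if not matrix.standardized and not allow_unstandardized:
        raise UsageError(
            "pca_fit expects a standardized matrix; pass allow_unstandardized=True "
            "for a raw-scale analysis"
        )
    df = matrix.data
    n, p = df.shape
    if n <= p:
        raise ParameterError(f"need more materials ({n}) than parameters ({p}) for PCA")
    if not 1 <= n_components <= p:
        raise ParameterError(f"n_components must be in [1, {p}], got {n_components}")
    pca = PCA(n_components=p, svd_solver="full")
    full = pca.fit_transform(df.to_numpy())
    comps = pca.components_.copy()          # p x p, rows are components
    for j in range(p):
        if comps[j, np.argmax(np.abs(comps[j]))] < 0:
            comps[j] = -comps[j]
            full[:, j] = -full[:, j]
    names = [f"PCA{j + 1}" for j in range(p)]
    loadings = pd.DataFrame(comps.T, index=df.columns, columns=names)
    full_scores = pd.DataFrame(full, index=df.index, columns=names)
    return PCAResult(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        scores=full_scores.iloc[:, :n_components].copy(),
        full_scores=full_scores,
        mean=pca.mean_.copy(),
    )


def kmeans_fit(
    scores, k: int = 3, seed: int | None = None, n_init: int = 10
) -> tuple[np.ndarray, float]:
    """Seeded k-means (k-means++, best of ``n_init`` restarts) on scores."""
    x = np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if k < 1 or k > x.shape[0]:
        raise ParameterError(f"k must be in [1, {x.shape[0]}], got {k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(x)
    return labels, float(km.inertia_)


def _relabel(
    labels: np.ndarray,
    order_values: dict[int, float],
) -> np.ndarray:
    """Map raw labels so ascending ``order_values`` becomes 0..k-1.

    The cluster with the highest value receives the largest label; exact
    value ties break by raw label for determinism.
    """
    ordered = sorted(order_values, key=lambda lab: (order_values[lab], lab))
    mapping = {old: new for new, old in enumerate(ordered)}
    return np.array([mapping[l] for l in labels])


def fit_cluster_model(
    matrix: ParameterMatrix,
    masking: list[MaskingResult] | None = None,
    k: int = 3,
    seed: int | None = 0,
    n_init: int = 10,
    n_components: int = 2,
    cluster_space: str = "pca",
    allow_unstandardized: bool = False,
) -> ClusterModel:
    """Fit PCA and k-means and return a deterministically-labeled model.

    ``cluster_space="pca"`` clusters in the PCA1..PCA``n_components`` score
    plane (the plane in which the classification is visualized);
    ``"full"`` clusters in the full standardized parameter space.
    """
    if cluster_space not in ("pca", "full"):
        raise ParameterError(f"unknown cluster_space {cluster_space!r}")
    pca = pca_fit(matrix, n_components=n_components, allow_unstandardized=allow_unstandardized)
    space = pca.scores.to_numpy() if cluster_space == "pca" else matrix.data.to_numpy()
    raw_labels, inertia = kmeans_fit(space, k=k, seed=seed, n_init=n_init)

    if masking is not None:
        score_by_id = {m.material_id: m.masking_score for m in masking}
        missing = [i for i in matrix.material_ids if i not in score_by_id]
        if missing:
            raise ValidationError(f"masking results missing for materials {missing[:5]}")
        values = {
            lab: float(np.mean([score_by_id[i] for i, l in zip(matrix.material_ids, raw_labels) if l == lab]))
            for lab in np.unique(raw_labels)
        }
    else:
        pc1 = pca.scores.iloc[:, 0].to_numpy()
        values = {lab: float(pc1[raw_labels == lab].mean()) for lab in np.unique(raw_labels)}
    labels = _relabel(raw_labels, values)
    return ClusterModel(
        loadings=pca.loadings,
        explained_variance_ratio=pca.explained_variance_ratio,
        scores=pca.scores,
        labels=pd.Series(labels, index=matrix.data.index, name="cluster"),
        k=k, seed=seed, inertia=inertia,
    )


def summarize_clusters(
    labels: pd.Series, masking: list[MaskingResult], alpha: float = 0.05
) -> ClusterSummary:
    """Per-cluster masking summary plus highest-vs-rest Mann-Whitney test."""
    score_by_id = {m.material_id: m.masking_score for m in masking}
    missing = [i for i in labels.index if str(i) not in score_by_id]
    if missing:
        raise ValidationError(f"masking results missing for materials {missing[:5]}")
    rows = []
    for lab in sorted(labels.unique()):
        members = [str(i) for i in labels.index[labels == lab]]
        if not members:
            raise RuntimeError(f"cluster {lab} has no members after relabeling")
        scores = [score_by_id[m] for m in members]
        rows.append((int(lab), len(members), float(np.mean(scores)), members))
    table = pd.DataFrame(rows, columns=["cluster", "n", "mean_masking_score", "members"])
    high = int(table.loc[table["mean_masking_score"].idxmax(), "cluster"])
    if len(table) < 2:
        return ClusterSummary(table, high, None, None, None,
                              note="single cluster; high-vs-rest test skipped")
    in_high = [score_by_id[str(i)] for i in labels.index[labels == high]]
    rest = [score_by_id[str(i)] for i in labels.index[labels != high]]
    if min(len(in_high), len(rest)) < 2:
        return ClusterSummary(table, high, None, None, None,
                              note="a comparison group has < 2 members; test skipped")
    res = mann_whitney_u(in_high, rest)
    return ClusterSummary(table, high, res.U, res.p, bool(res.p < alpha))


def loading_report(model: ClusterModel) -> LoadingReport:
    """Rank parameters by |PCA1 loading|; report the top-two ratio.

    Magnitudes are used throughout, so the report is unaffected by the
    arbitrary sign of the component.
    """
    pc1 = model.loadings.iloc[:, 0]
    table = pd.DataFrame(
        {"parameter": pc1.index, "loading_pc1": pc1.to_numpy(),
         "abs_loading": np.abs(pc1.to_numpy())}
    ).sort_values(["abs_loading", "parameter"], ascending=[False, True], ignore_index=True)
    a, b = table["abs_loading"].iloc[0], table["abs_loading"].iloc[1]
    ratio = float(a / b) if b > 0 else float("inf")
    return LoadingReport(table=table, top_ratio=ratio)
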