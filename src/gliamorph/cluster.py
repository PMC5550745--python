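"""Descriptor selection and hierarchical morphotype clustering.

Descriptors are screened with the multimodality index

    MMI = (M3^2 + 1) / (M4 + 3 (n-1)^2 / ((n-2)(n-3)))

where M3 is the sample skewness, M4 the sample *excess* kurtosis and n the
sample size.  The finite-n term tends to 3, so for large samples a uniform
distribution scores 5/9, a normal 1/3, and a symmetric two-point mixture 1;
descriptors scoring strictly above 0.55 are taken as multimodal and hence
informative for separating cell populations.  (With raw, non-excess
kurtosis the 0.55 cut-off would lose its correspondence to the uniform
reference value; a ``kurtosis="raw"`` escape hatch is provided anyway.)

Clustering is agglomerative Ward on z-scored descriptors (merge cost =
increase in total within-cluster sum of squares, Euclidean metric).  The
cluster count is chosen two ways: the Thorndike elbow — the k where the
mean within-cluster-distance curve suddenly flattens (see
:func:`thorndike_select`) — and the variance ratio criterion
VRC_k = (SSB/SSW) x (N-k)/(k-1)
(Calinski-Harabasz), maximized over k.  Cluster ids are renumbered by
descending cluster size, ties broken by ascending centroid norm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

__all__ = [
    "mmi",
    "mmi_table",
    "select_multimodal",
    "ZTransform",
    "z_normalize",
    "ward_hca",
    "labels_at_k",
    "renumber_by_size",
    "thorndike_select",
    "vrc",
    "vrc_select",
    "ClusterModel",
    "fit_clusters",
]

MMI_THRESHOLD = 0.55


class ClusterError(ValueError):
    pass


@dataclass(frozen=True)
class MMIResult:
    value: float
    skewness: float
    excess_kurtosis: float
    n: int


def mmi(values, kurtosis: str = "excess") -> MMIResult:
    """Multimodality index of a numeric sample (n >= 4, nonzero variance)."""
    x = np.asarray(values, float)
    n = x.size
    if n < 4:
        raise ClusterError(f"MMI needs n >= 4, got n = {n}")
    if np.ptp(x) == 0 or x.std() == 0:
        raise ClusterError("MMI undefined for a constant sample")
    m3 = float(_skew(x, bias=True))
    g2 = float(_kurtosis(x, fisher=True, bias=True))
    m4 = g2 if kurtosis == "excess" else g2 + 3.0
    denom = m4 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return MMIResult(value=(m3**2 + 1.0) / denom, skewness=m3, excess_kurtosis=g2, n=n)


def mmi_table(table: pd.DataFrame, columns=None) -> pd.Series:
    """MMI of every (numeric) descriptor column, descending."""
    columns = list(columns) if columns is not None else list(table.columns)
    out = {c: mmi(table[c].to_numpy()).value for c in columns}
    return pd.Series(out, name="mmi").sort_values(ascending=False)


def select_multimodal(mmi_values: pd.Series, threshold: float = MMI_THRESHOLD) -> list[str]:
    """Descriptors with MMI strictly above the threshold, best first."""
    picked = mmi_values[mmi_values > threshold].sort_values(ascending=False)
    if picked.empty:
        warnings.warn(
            f"no descriptor exceeds the MMI threshold {threshold}; selection is empty"
        )
    return list(picked.index)


@dataclass(frozen=True)
class ZTransform:
    """Column-wise standardization (sample sd, ddof=1), reusable on new cells."""

    means: pd.Series
    sds: pd.Series

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        return (table[self.means.index] - self.means) / self.sds

    def apply_vector(self, values: dict[str, float] | pd.Series) -> pd.Series:
        s = pd.Series(values)[self.means.index]
        return (s - self.means) / self.sds


def z_normalize(table: pd.DataFrame) -> tuple[pd.DataFrame, ZTransform]:
    sds = table.std(ddof=1)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise ClusterError(f"constant column(s) cannot be z-scored: {bad}")
    tf = ZTransform(means=table.mean(), sds=sds)
    return tf.apply(table), tf


def ward_hca(z: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Ward linkage tree (scipy condensed format) on z-scored rows."""
    X = np.asarray(z, float)
    if len(X) < 2:
        raise ClusterError("need at least two cells to cluster")
    return linkage(X, method="ward", metric="euclidean")


def labels_at_k(tree: np.ndarray, k: int) -> np.ndarray:
    return fcluster(tree, t=k, criterion="maxclust")


def renumber_by_size(labels: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Renumber so cluster 1 is the largest; ties by ascending centroid norm."""
    labels = np.asarray(labels)
    X = np.asarray(X, float)
    ids = np.unique(labels)
    sizes = {i: (labels == i).sum() for i in ids}
    norms = {i: np.linalg.norm(X[labels == i].mean(axis=0)) for i in ids}
    order = sorted(ids, key=lambda i: (-sizes[i], norms[i]))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[v] for v in labels])


def _mean_within_cluster_distance(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for i in np.unique(labels):
        members = X[labels == i]
        centroid = members.mean(axis=0)
        total += np.linalg.norm(members - centroid, axis=1).sum()
    return total / len(X)


@dataclass(frozen=True)
class ThorndikeResult:
    chosen_k: int
    ks: np.ndarray
    curve: np.ndarray  # mean within-cluster distance per k in k_range
    flattening: np.ndarray  # slope ratio drop(k->k+1)/drop(k-1->k) per k
    low_confidence: bool

    #: a genuine elbow must cut the curve's slope to under a third
    RATIO_THRESHOLD = 1 / 3


def thorndike_select(
    tree: np.ndarray, X: np.ndarray, k_range: tuple[int, int] = (2, 9)
) -> ThorndikeResult:
    """Sudden flattening of the mean within-cluster-distance curve.

    The curve is evaluated from k-1 below to one beyond the range; the
    chosen k minimizes the slope ratio drop(k->k+1)/drop(k-1->k) — a small
    ratio means the curve declined steeply into k and flattened right
    after, which is the marked decline in slope the procedure looks for.
    A candidate only counts as an elbow when the slope falls to under a
    third, the decline into k is at least an average step of the curve,
    and the curve stays flat afterwards; otherwise the curve is considered
    elbow-free and the smallest k is returned with a low-confidence flag.
    """
    X = np.asarray(X, float)
    lo, hi = k_range
    if not 1 <= lo <= hi < len(X):
        raise ClusterError(f"k_range {k_range} invalid for n = {len(X)}")
    ks_eval = np.arange(max(1, lo - 1), min(hi + 1, len(X)) + 1)
    curve = np.array(
        [_mean_within_cluster_distance(X, labels_at_k(tree, k)) for k in ks_eval]
    )
    drops = -np.diff(curve)  # drops[i] = drop from ks_eval[i] to ks_eval[i+1]
    ks = np.arange(lo, hi + 1)
    ratio = np.full(len(ks), np.inf)
    sustained = np.zeros(len(ks), bool)
    for j, k in enumerate(ks):
        i = np.searchsorted(ks_eval, k)
        if 0 < i < len(ks_eval) - 1 and drops[i - 1] > 0:
            ratio[j] = max(drops[i], 0.0) / drops[i - 1]
            # a genuine elbow is prominent (the decline into k is at least
            # an average step of the curve) and stays flat afterwards;
            # chance dips of a smoothly declining curve fail one of the two
            sustained[j] = (
                drops[i:].max() <= 0.5 * drops[i - 1]
                and drops[i - 1] >= drops.mean()
            )
    eligible = (ratio < ThorndikeResult.RATIO_THRESHOLD) & sustained
    low = not eligible.any()
    if low:
        chosen = int(ks[0])
    else:
        masked = np.where(eligible, ratio, np.inf)
        chosen = int(ks[np.argmin(masked)])
    if low:
        warnings.warn("Thorndike curve has no clear elbow; smallest k returned")
    return ThorndikeResult(
        chosen_k=chosen,
        ks=ks,
        curve=curve[np.searchsorted(ks_eval, ks)],
        flattening=ratio,
        low_confidence=bool(low),
    )


def vrc(X: np.ndarray, labels: np.ndarray) -> float:
    """Variance ratio criterion (SSB/SSW) x (N-k)/(k-1) for one partition."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    N = len(X)
    ids = np.unique(labels)
    k = len(ids)
    if k < 2:
        raise ClusterError("VRC undefined for k = 1")
    grand = X.mean(axis=0)
    ssb = ssw = 0.0
    for i in ids:
        members = X[labels == i]
        c = members.mean(axis=0)
        ssb += len(members) * np.sum((c - grand) ** 2)
        ssw += np.sum((members - c) ** 2)
    if ssw == 0:
        warnings.warn("within-cluster sum of squares is zero; VRC is infinite")
        return np.inf
    return (ssb / ssw) * ((N - k) / (k - 1))


@dataclass(frozen=True)
class VRCResult:
    chosen_k: int
    ks: np.ndarray
    curve: np.ndarray


def vrc_select(
    tree: np.ndarray, X: np.ndarray, k_range: tuple[int, int] = (2, 9)
) -> VRCResult:
    """VRC over tree cuts in k_range; argmax, ties to the smaller k."""
    lo, hi = k_range
    ks = np.arange(lo, hi + 1)
    curve = np.array([vrc(X, labels_at_k(tree, k)) for k in ks])
    return VRCResult(chosen_k=int(ks[np.argmax(curve)]), ks=ks, curve=curve)


@dataclass(frozen=True)
class ClusterModel:
    """Fitted clustering of one cohort on the selected descriptors."""

    feature_names: tuple[str, ...]
    z_transform: ZTransform
    tree: np.ndarray
    thorndike: ThorndikeResult
    vrc: VRCResult
    chosen_k: int
    labels: np.ndarray  # at chosen_k, renumbered by descending size
    labels_by_k: dict[int, np.ndarray]
    k_range: tuple[int, int]
    range_constrained: bool = False


def fit_clusters(
    z_table: pd.DataFrame, k_range: tuple[int, int] = (2, 9), z_transform: ZTransform | None = None
) -> ClusterModel:
    """Ward tree + both k-selection procedures on a z-scored feature table.

    The reported ``chosen_k`` is the VRC argmax (the Thorndike choice is
    retained alongside); when the range pins k (lo == hi) the model notes
    it as range-constrained.
    """
    X = z_table.to_numpy(float)
    tree = ward_hca(X)
    lo, hi = k_range
    hi = min(hi, len(X) - 1)
    thorn = thorndike_select(tree, X, (lo, hi))
    v = vrc_select(tree, X, (lo, hi))
    chosen = v.chosen_k
    labels_by_k = {
        k: renumber_by_size(labels_at_k(tree, k), X) for k in range(lo, hi + 1)
    }
    return ClusterModel(
        feature_names=tuple(z_table.columns),
        z_transform=z_transform
        if z_transform is not None
        else ZTransform(
            means=pd.Series(0.0, index=z_table.columns),
            sds=pd.Series(1.0, index=z_table.columns),
        ),
        tree=tree,
        thorndike=thorn,
        vrc=v,
        chosen_k=chosen,
        labels=labels_by_k[chosen],
        labels_by_k=labels_by_k,
        k_range=(lo, hi),
        range_constrained=lo == hi,
    )
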