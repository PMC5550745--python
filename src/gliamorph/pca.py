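"""Correlation-matrix PCA over shape descriptors and cluster subdivision.

The components are eigenvectors of the descriptor correlation matrix;
loadings are eigenvectors scaled by the square root of their eigenvalue,
so each loading is the correlation between its descriptor and the
component score (bounded by 1).  One high-loading descriptor is then
picked per retained component and used to split each morphotype cluster
in two at the cohort mean (z = 0) of that descriptor, producing the x.1 /
x.2 sub-types; a two-sample test on the splitting descriptor (Student's t
when both sides look normal with equal variances, Mann-Whitney U
otherwise) guards against spurious splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PCAModel", "fit_pca", "select_pc_parameters", "SubtypeSplit", "split_cluster"]


class PCAError(ValueError):
    pass


@dataclass(frozen=True)
class PCAModel:
    feature_names: tuple[str, ...]
    loadings: pd.DataFrame  # descriptor x component, correlation-scaled
    explained: np.ndarray  # proportion of variance per component
    scores: pd.DataFrame  # cell x component
    eigenvalues: np.ndarray


def fit_pca(z_table: pd.DataFrame) -> PCAModel:
    """Eigendecomposition of the correlation matrix of the table columns."""
    X = z_table.to_numpy(float)
    n, p = X.shape
    if n <= p:
        warnings.warn(f"n = {n} <= p = {p}; principal components are unstable")
    sds = X.std(axis=0, ddof=1)
    if (sds == 0).any():
        bad = [c for c, s in zip(z_table.columns, sds) if s == 0]
        raise PCAError(f"constant column(s): {bad}")
    corr = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: the largest-|loading| descriptor is positive
    for j in range(p):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    loadings = evecs * np.sqrt(evals)
    Xz = (X - X.mean(axis=0)) / sds
    scores = Xz @ evecs
    comp_names = [f"PC{j + 1}" for j in range(p)]
    return PCAModel(
        feature_names=tuple(z_table.columns),
        loadings=pd.DataFrame(loadings, index=z_table.columns, columns=comp_names),
        explained=evals / evals.sum(),
        scores=pd.DataFrame(scores, index=z_table.index, columns=comp_names),
        eigenvalues=evals,
    )


#: the descriptor pair used in the published subdivision scheme
PAPER_PC_PARAMETERS = ("max_span_across_hull_um", "convex_hull_circularity")


def select_pc_parameters(
    model: PCAModel,
    exclusions: tuple[str, ...] = (),
    preset: str | None = None,
) -> tuple[str, str]:
    """One representative descriptor per retained component (PC1, PC2).

    The default rule takes, per component, the non-excluded descriptor of
    maximal absolute loading (PC2 additionally excludes PC1's pick).  The
    ``"paper"`` preset instead returns the maximum-span / hull-circularity
    pair chosen in the published scheme for its discriminator potency.
    """
    if preset == "paper":
        missing = [d for d in PAPER_PC_PARAMETERS if d not in model.feature_names]
        if missing:
            raise PCAError(f"preset descriptors not in model: {missing}")
        return PAPER_PC_PARAMETERS
    if preset is not None:
        raise PCAError(f"unknown preset {preset!r}")

    def best(component: str, banned: set[str]) -> str:
        cand = model.loadings[component].drop(index=[b for b in banned if b in model.loadings.index])
        if cand.empty:
            raise PCAError(f"no candidate descriptor left for {component}")
        return cand.abs().idxmax()

    banned = set(exclusions)
    pc1 = best("PC1", banned)
    if model.loadings.shape[1] < 2:
        raise PCAError("model has a single component; no PC2 descriptor")
    pc2 = best("PC2", banned | {pc1})
    return pc1, pc2


@dataclass(frozen=True)
class SubtypeSplit:
    cluster: int
    descriptor: str
    cut_z: float
    members_low: tuple  # Type x.1 (at or below the cut)
    members_high: tuple  # Type x.2 (above the cut)
    test_name: str
    statistic: float
    p_value: float
    validated: bool  # p < alpha
    alpha: float

    @property
    def split_performed(self) -> bool:
        return bool(self.members_low and self.members_high)


def split_cluster(
    z_values: pd.Series,
    members: pd.Index,
    cluster: int,
    descriptor: str,
    cut: float = 0.0,
    alpha: float = 0.001,
) -> SubtypeSplit:
    """Split one cluster on a descriptor's cohort z-scale at ``cut``.

    ``z_values`` holds the descriptor's z-scores over the *whole* cohort,
    so the cut (default 0) is the cohort mean, the plot-axis reading of
    the PC plane.  Type x.1 collects members at or below the cut, x.2
    those strictly above.  Requires >= 2 members on each side; otherwise
    the cluster stays unsplit with a warning.
    """
    vals = z_values.loc[members]
    low = tuple(vals.index[vals <= cut])
    high = tuple(vals.index[vals > cut])
    if len(low) < 2 or len(high) < 2:
        warnings.warn(
            f"cluster {cluster}: fewer than 2 members on one side of the "
            f"{descriptor} cut; not split"
        )
        return SubtypeSplit(
            cluster=cluster, descriptor=descriptor, cut_z=cut,
            members_low=tuple(members) if not high else (),
            members_high=tuple(members) if not low or len(low) < 2 else (),
            test_name="none", statistic=np.nan, p_value=np.nan,
            validated=False, alpha=alpha,
        )
    a = vals.loc[list(low)].to_numpy()
    b = vals.loc[list(high)].to_numpy()
    use_t = False
    if min(len(a), len(b)) >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm_a = stats.shapiro(a).pvalue > 0.05 if len(a) <= 5000 else True
            norm_b = stats.shapiro(b).pvalue > 0.05 if len(b) <= 5000 else True
            homo = stats.levene(a, b).pvalue > 0.05
        use_t = norm_a and norm_b and homo
    if use_t:
        res = stats.ttest_ind(a, b)
        test_name = "student_t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test_name = "mann_whitney_u"
    pval = float(res.pvalue)
    if pval >= alpha:
        warnings.warn(
            f"cluster {cluster}: sub-type split on {descriptor} not validated "
            f"(p = {pval:.3g} >= {alpha})"
        )
    return SubtypeSplit(
        cluster=cluster, descriptor=descriptor, cut_z=cut,
        members_low=low, members_high=high,
        test_name=test_name, statistic=float(res.statistic), p_value=pval,
        validated=pval < alpha, alpha=alpha,
    )
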