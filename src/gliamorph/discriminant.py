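"""Canonical linear discriminant analysis of morphotype clusters.

Fits the g-1 discriminant functions LD = A1*X1 + ... + Ap*Xp + C by the
generalized eigenproblem of the between-class scatter against the pooled
within-class scatter.  Conventions follow the classical canonical-analysis
output: raw coefficients are scaled so that the pooled within-class
variance of each score is 1, constants center the scores on the grand
mean, standardized coefficients multiply raw ones by the pooled
within-class standard deviations, and each function's share of the
eigenvalue sum is its proportion of trace.  The overall separation is
summarized by Wilks' lambda with Bartlett's chi-squared approximation, and
honesty of the classifier by leave-one-out cross-validation (equal priors,
nearest class centroid in discriminant space, which equals the linear
classification rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2 as _chi2

__all__ = [
    "DiscriminantModel",
    "fit_lda",
    "wilks_test",
    "loo_accuracy",
    "project",
    "territorial_map",
]


class DiscriminantError(ValueError):
    pass


@dataclass(frozen=True)
class DiscriminantModel:
    feature_names: tuple[str, ...]
    classes: np.ndarray
    coefficients: np.ndarray  # (p, m) raw canonical coefficients
    constants: np.ndarray  # (m,)
    std_coefficients: np.ndarray  # (p, m)
    eigenvalues: np.ndarray  # (m,)
    proportion_of_trace: np.ndarray  # (m,)
    canonical_correlations: np.ndarray  # (m,)
    centroids: pd.DataFrame  # class x function mean scores
    n: int
    degenerate: bool = False

    @property
    def n_functions(self) -> int:
        return self.coefficients.shape[1]


def _scatter_matrices(X: np.ndarray, labels: np.ndarray, strict: bool = True):
    classes = np.unique(labels)
    grand = X.mean(axis=0)
    p = X.shape[1]
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in classes:
        members = X[labels == c]
        if len(members) < 2:
            if strict:
                raise DiscriminantError(f"class {c!r} has fewer than 2 members")
            warnings.warn(f"class {c!r} is a singleton; it adds no within-class scatter")
        mu = members.mean(axis=0)
        dev = members - mu
        Sw += dev.T @ dev
        dmu = (mu - grand)[:, None]
        Sb += len(members) * (dmu @ dmu.T)
    return classes, Sw, Sb


def fit_lda(z_table: pd.DataFrame, labels, strict: bool = True) -> DiscriminantModel:
    """Fit min(g-1, p) canonical discriminant functions.

    Requires at least two classes with n >= 2 each (``strict=False``
    tolerates singleton classes, e.g. during leave-one-out refits); a
    near-singular pooled within-class scatter triggers a small ridge with
    a warning.  When all eigenvalues vanish (identical class means) the
    proportion of trace is reported uniform and the model flagged
    degenerate.
    """
    X = z_table.to_numpy(float)
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise DiscriminantError("labels and table lengths differ")
    classes, Sw, Sb = _scatter_matrices(X, labels, strict=strict)
    g = len(classes)
    if g < 2:
        raise DiscriminantError("need at least two classes")
    N, p = X.shape
    m = min(g - 1, p)

    cond = np.linalg.cond(Sw)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("pooled within-class scatter near-singular; adding ridge")
        Sw = Sw + 1e-8 * np.trace(Sw) / p * np.eye(p)

    evals, evecs = linalg.eigh(Sb, Sw)  # ascending; evecs' Sw evecs = I
    order = np.argsort(evals)[::-1][:m]
    evals = np.clip(evals[order], 0.0, None)
    A = evecs[:, order]
    # scale so pooled within-class variance of each score is 1
    A = A * np.sqrt(N - g)
    # orient each function so its largest-|coefficient| entry is positive
    for j in range(m):
        i = np.argmax(np.abs(A[:, j]))
        if A[i, j] < 0:
            A[:, j] = -A[:, j]

    grand = X.mean(axis=0)
    constants = -(grand @ A)

    pooled_sd = np.sqrt(np.diag(Sw) / (N - g))
    std_coef = A * pooled_sd[:, None]

    total = evals.sum()
    degenerate = total <= 1e-12
    if degenerate:
        warnings.warn("all discriminant eigenvalues ~0; proportion of trace undefined")
        prop = np.full(m, 1.0 / m)
    else:
        prop = evals / total
    can_corr = np.sqrt(evals / (1.0 + evals))

    scores = X @ A + constants
    cent = pd.DataFrame(
        [scores[labels == c].mean(axis=0) for c in classes],
        index=pd.Index(classes, name="class"),
        columns=[f"LD{j + 1}" for j in range(m)],
    )
    return DiscriminantModel(
        feature_names=tuple(z_table.columns),
        classes=classes,
        coefficients=A,
        constants=constants,
        std_coefficients=std_coef,
        eigenvalues=evals,
        proportion_of_trace=prop,
        canonical_correlations=can_corr,
        centroids=cent,
        n=N,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class WilksResult:
    lam: float
    chi2: float
    df: int
    p_value: float


def wilks_test(model: DiscriminantModel, p: int | None = None, g: int | None = None) -> WilksResult:
    """Wilks' lambda over all functions with Bartlett's chi-squared.

    lambda = prod 1/(1+ev_i); chi2 = -(N - 1 - (p+g)/2) ln(lambda);
    df = p (g - 1).
    """
    p = p if p is not None else len(model.feature_names)
    g = g if g is not None else len(model.classes)
    lam = float(np.prod(1.0 / (1.0 + model.eigenvalues)))
    factor = model.n - 1 - (p + g) / 2.0
    chi2 = -factor * np.log(lam) if lam > 0 else np.inf
    df = p * (g - 1)
    pval = float(_chi2.sf(chi2, df)) if np.isfinite(chi2) else 0.0
    return WilksResult(lam=lam, chi2=float(chi2), df=df, p_value=pval)


def project(model: DiscriminantModel, table: pd.DataFrame) -> pd.DataFrame:
    """Discriminant scores of (z-scored) descriptor rows."""
    missing = [f for f in model.feature_names if f not in table.columns]
    if missing:
        raise DiscriminantError(f"missing descriptor column(s): {missing}")
    X = table[list(model.feature_names)].to_numpy(float)
    scores = X @ model.coefficients + model.constants
    return pd.DataFrame(
        scores, index=table.index, columns=[f"LD{j + 1}" for j in range(model.n_functions)]
    )


def classify(model: DiscriminantModel, table: pd.DataFrame) -> np.ndarray:
    """Nearest class centroid in discriminant space (equal priors)."""
    scores = project(model, table).to_numpy()
    cents = model.centroids.to_numpy()
    d2 = ((scores[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    return model.classes[np.argmin(d2, axis=1)]


def loo_accuracy(z_table: pd.DataFrame, labels) -> tuple[float, pd.DataFrame]:
    """Leave-one-out cross-validated accuracy and confusion matrix.

    Each cell is classified by a model refit without it.  Cells whose
    class would vanish from the training set (singleton classes) are
    skipped with a warning.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    skip = set(classes[counts < 2])
    if skip:
        warnings.warn(f"singleton class(es) skipped in cross-validation: {sorted(skip)}")
    predicted, actual = [], []
    for i in range(len(z_table)):
        if labels[i] in skip:
            continue
        mask = np.ones(len(z_table), bool)
        mask[i] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_lda(z_table.iloc[mask], labels[mask], strict=False)
        predicted.append(classify(m, z_table.iloc[[i]])[0])
        actual.append(labels[i])
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    acc = float((predicted == actual).mean())
    confusion = pd.crosstab(
        pd.Series(actual, name="actual"), pd.Series(predicted, name="predicted")
    )
    return acc, confusion


def territorial_map(
    model: DiscriminantModel, z_table: pd.DataFrame, labels
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scores on (LD1, LD2) plus class centroids, ready for plotting."""
    scores = project(model, z_table)
    scores = scores.iloc[:, : min(2, model.n_functions)].copy()
    scores["label"] = np.asarray(labels)
    cents = model.centroids.iloc[:, : min(2, model.n_functions)]
    return scores, cents
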