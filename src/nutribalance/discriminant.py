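"""Canonical discriminant analysis of ionome representations.

Classical CDA: solve the generalized eigenproblem of the between-group
scatter B against the pooled within-group scatter W (unbiased n−g
divisor). Eigenvectors are scaled so vᵀWv = 1, which makes canonical
score space a within-group Mahalanobis whitening — nearest-group-mean
classification there is therefore invariant to any invertible linear map
of the inputs. That invariance is what makes alr- and ilr-based analyses
agree exactly on eigenvalues and cross-validated misclassification, while
raw or plain-log inputs (non-linear functions of the log-ratios) can and
do differ.

Ellipses: per-group 95% data ellipses (score covariance scaled by the
chi-square quantile with 2 df) and mean-confidence ellipses (covariance
divided by n), in the plane of the first two canonical axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .balances import SBP, transform_table
from .core import CompositionTable
from .errors import (
    DegenerateCovarianceError,
    InsufficientDataError,
    LabelError,
)

__all__ = [
    "DiscriminantModel",
    "EllipseSpec",
    "fit_cda",
    "compare_representations",
    "confidence_ellipses",
    "ellipses_disjoint",
    "cv_misclassification",
]


@dataclass
class DiscriminantModel:
    """Fitted canonical discriminant analysis.

    ``loadings`` (p × k) applied to centered inputs reproduce ``scores``
    (n × k); ``eigenvalues`` (k,) are nonincreasing and ≥ 0 with
    k = min(groups − 1, p).
    """

    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    scores: pd.DataFrame
    group_means: pd.DataFrame
    groups: pd.Series
    grand_mean: pd.Series
    group_sizes: pd.Series
    representation: str = "ilr"

    @property
    def n_axes(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        centered = X[self.loadings.index] - self.grand_mean
        out = centered.to_numpy() @ self.loadings.to_numpy()
        return pd.DataFrame(out, index=X.index, columns=self.scores.columns)

    def classify(self, X: pd.DataFrame) -> pd.Series:
        """Nearest group mean in canonical (within-whitened) space."""
        sc = self.transform(X).to_numpy()
        means = self.group_means.to_numpy()
        d2 = ((sc[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        picks = self.group_means.index[np.argmin(d2, axis=1)]
        return pd.Series(picks, index=X.index, name="predicted")


def _scatter_matrices(X: np.ndarray, groups: pd.Series) -> tuple[np.ndarray, np.ndarray, dict]:
    labels = groups.unique()
    n, p = X.shape
    g = len(labels)
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    means = {}
    for lab in labels:
        sub = X[(groups == lab).to_numpy()]
        m = sub.mean(axis=0)
        means[lab] = m
        c = sub - m
        W += c.T @ c
        d = (m - grand)[:, None]
        B += sub.shape[0] * (d @ d.T)
    W /= n - g
    B /= g - 1
    return W, B, means


def fit_cda(
    X: pd.DataFrame,
    groups: Sequence,
    representation: str = "ilr",
) -> DiscriminantModel:
    """Fit canonical discriminant axes to labeled multivariate data.

    Deterministic up to sign; each axis is oriented so its
    largest-magnitude loading is positive.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 groups, or a group with n ≤ dim + 1.
    DegenerateCovarianceError
        Singular pooled within-group scatter, naming collinear variables.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, float))
    groups = pd.Series(np.asarray(groups), index=X.index, name="group")
    arr = X.to_numpy(dtype=float)
    n, p = arr.shape
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise InsufficientDataError("discriminant analysis needs >= 2 groups")
    small = sizes[sizes <= p]
    if len(small):
        raise InsufficientDataError(
            f"groups too small for dim={p}: {dict(small)} (need n > dim per group)"
        )
    W, B, means = _scatter_matrices(arr, groups)
    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError:
        corr = np.corrcoef(arr, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise DegenerateCovarianceError(
            "pooled within-group scatter is singular; most collinear pair: "
            f"{X.columns[i]!r} ~ {X.columns[j]!r} (r={corr[i, j]:.4f})"
        ) from None
    order = np.argsort(evals)[::-1]
    k = min(len(sizes) - 1, p)
    evals = np.maximum(evals[order][:k], 0.0)
    V = evecs[:, order][:, :k]
    # eigh(B, W) normalizes vᵀWv = 1 already; fix signs
    for j in range(k):
        lead = np.argmax(np.abs(V[:, j]))
        if V[lead, j] < 0:
            V[:, j] = -V[:, j]
    axis_names = [f"can{j + 1}" for j in range(k)]
    grand = arr.mean(axis=0)
    scores = (arr - grand) @ V
    score_df = pd.DataFrame(scores, index=X.index, columns=axis_names)
    gm = pd.DataFrame(
        {lab: (means[lab] - grand) @ V for lab in sizes.index}
    ).T
    gm.columns = axis_names
    return DiscriminantModel(
        loadings=pd.DataFrame(V, index=X.columns, columns=axis_names),
        eigenvalues=evals,
        scores=score_df,
        group_means=gm,
        groups=groups,
        grand_mean=pd.Series(grand, index=X.columns),
        group_sizes=sizes,
        representation=representation,
    )


def compare_representations(
    table: CompositionTable,
    sbp: SBP,
    representations: Sequence[str] = ("raw", "log", "alr", "ilr"),
    denominator: str | None = None,
) -> dict[str, DiscriminantModel]:
    """Fit one CDA per data representation on identical samples."""
    if table.group is None:
        raise LabelError("the table has no group column")
    out = {}
    for rep in representations:
        X = transform_table(table, rep, sbp=sbp, denominator=denominator)
        out[rep] = fit_cda(X, table.group, representation=rep)
    return out


@dataclass(frozen=True)
class EllipseSpec:
    """One group's ellipse in the first canonical plane.

    kind "data_95" encloses ~95% of the group's theoretical score
    distribution (covariance scaled by χ²(0.95, 2)); kind
    "mean_confidence_95" shrinks the covariance by n for the confidence
    region about the group mean.
    """

    group: object
    kind: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_rad: float
    n: int
    cov: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "group": str(self.group), "kind": self.kind,
            "center": list(self.center), "semi_axes": list(self.semi_axes),
            "angle_rad": self.angle_rad, "n": self.n,
        }


def confidence_ellipses(
    model: DiscriminantModel, level: float = 0.95
) -> list[EllipseSpec]:
    """Per-group data and mean-confidence ellipses on the first two
    canonical axes. Groups with n < 3 are skipped with a warning."""
    if model.n_axes < 2:
        raise InsufficientDataError(
            "ellipses need at least 2 canonical axes; got "
            f"{model.n_axes} (>= 3 groups or >= 2 dims required)"
        )
    q = float(stats.chi2.ppf(level, 2))
    tag = f"{level * 100:g}".replace(".", "_")
    out: list[EllipseSpec] = []
    for lab, cnt in model.group_sizes.items():
        if cnt < 3:
            warnings.warn(f"group {lab!r} has n={cnt} < 3; no ellipse",
                          stacklevel=2)
            continue
        sub = model.scores[(model.groups == lab).to_numpy()].iloc[:, :2]
        cov = np.cov(sub.to_numpy(), rowvar=False)
        center = tuple(sub.mean().tolist())
        evals, evecs = np.linalg.eigh(cov)
        evals = np.maximum(evals[::-1], 0.0)
        evecs = evecs[:, ::-1]
        angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
        for kind, effective_cov in (
            (f"data_{tag}", cov),
            (f"mean_confidence_{tag}", cov / cnt),
        ):
            ev = np.maximum(np.linalg.eigvalsh(effective_cov)[::-1], 0.0)
            axes = tuple(np.sqrt(ev * q).tolist())
            out.append(EllipseSpec(group=lab, kind=kind, center=center,
                                   semi_axes=axes, angle_rad=angle, n=int(cnt),
                                   cov=effective_cov))
    return out


def ellipses_disjoint(a: EllipseSpec, b: EllipseSpec, level: float = 0.95) -> bool:
    """Approximate disjointness test: the center separation must exceed
    the sum of the two ellipses' radii along the center-to-center
    direction (a conservative directional check, not an exact overlap
    test)."""
    q = float(stats.chi2.ppf(level, 2))
    ca = np.asarray(a.center)
    cb = np.asarray(b.center)
    delta = cb - ca
    dist = np.linalg.norm(delta)
    if dist == 0:
        return False
    u = delta / dist

    def radius(e: EllipseSpec) -> float:
        # support-function radius along u: sqrt(q · uᵀΣu); conservative
        # (largest possible extent in that direction)
        if e.cov is not None:
            return float(np.sqrt(q * u @ e.cov @ u))
        return float(max(e.semi_axes))

    return dist > radius(a) + radius(b)


def cv_misclassification(
    X: pd.DataFrame,
    groups: Sequence,
    folds: int | None = None,
    seed: int = 0,
    representation: str = "ilr",
) -> float:
    """Cross-validated misclassification rate of nearest-group-mean
    classification in canonical space.

    ``folds=None`` runs leave-one-out; otherwise ``folds``-fold CV on a
    seed-shuffled index. Deterministic given seed and fold spec.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, float))
    groups = pd.Series(np.asarray(groups), index=X.index)
    n = len(X)
    if folds is None:
        splits = [([j for j in range(n) if j != i], [i]) for i in range(n)]
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        chunks = np.array_split(perm, folds)
        splits = [
            (np.concatenate([c for k, c in enumerate(chunks) if k != f]), chunks[f])
            for f in range(folds)
        ]
    wrong = 0
    for train, test in splits:
        model = fit_cda(X.iloc[list(train)], groups.iloc[list(train)],
                        representation=representation)
        pred = model.classify(X.iloc[list(test)])
        wrong += int((pred.to_numpy() != groups.iloc[list(test)].to_numpy()).sum())
    return wrong / n
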