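"""Distributional diagnostics and robust outlier screening.

Covers the checks run before multivariate analysis of an ionome table:

* Anderson–Darling normality test (mean and variance estimated from the
  sample, Stephens small-sample correction (1 + 0.75/n + 2.25/n²), case-3
  p-value approximation) applied per variable across the raw, log, alr
  and ilr representations of the same samples.
* Scale-dependency report: Pearson correlation matrices of raw parts
  under different closure scales, with sign-flip and magnitude-change
  summaries — raw-part correlations move with the scale (and closure
  induces spurious correlation), log-ratio correlations do not.
* Robust Mahalanobis outlier screening via the minimum covariance
  determinant estimator with a chi-square cutoff; masks are returned,
  never applied silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet

from .balances import SBP, transform_table
from .core import CompositionTable
from .errors import (
    DegenerateCovarianceError,
    DegenerateSampleError,
    InsufficientDataError,
    LabelError,
)

__all__ = [
    "anderson_darling",
    "NormalityReport",
    "normality_by_representation",
    "ScaleSpec",
    "ScaleCorrelationReport",
    "scale_dependency",
    "OutlierMask",
    "robust_outliers",
    "robust_outliers_by_group",
    "MIN_AD_N",
]

#: Smallest sample size accepted by the Anderson–Darling test.
MIN_AD_N = 8


def anderson_darling(x: Sequence[float]) -> tuple[float, float]:
    """Anderson–Darling test for normality with estimated parameters.

    Returns the small-sample-corrected statistic A²* and its p-value from
    the piecewise case-3 approximation (both parameters estimated).
    Deterministic; invariant to affine transforms of ``x``.

    Raises
    ------
    DegenerateSampleError
        For n < MIN_AD_N or a zero-variance sample.
    """
    arr = np.sort(np.asarray(x, dtype=float))
    n = arr.size
    if n < MIN_AD_N:
        raise DegenerateSampleError(f"need n >= {MIN_AD_N}, got n={n}")
    if not np.isfinite(arr).all():
        raise DegenerateSampleError("sample contains non-finite values")
    sd = arr.std(ddof=1)
    # relative check: fp noise from upstream transforms can leave a
    # numerically-constant sample with sd ~ 1e-17
    if sd <= 1e-13 * max(1.0, float(np.abs(arr).max())):
        raise DegenerateSampleError("zero-variance sample")
    w = (arr - arr.mean()) / sd
    i = np.arange(1, n + 1)
    logcdf = stats.norm.logcdf(w)
    logsf = stats.norm.logsf(w)
    a2 = -n - np.mean((2 * i - 1) * (logcdf + logsf[::-1]))
    a2 *= 1 + 0.75 / n + 2.25 / n**2
    if a2 >= 0.6:
        p = np.exp(1.2937 - 5.709 * a2 + 0.0186 * a2**2)
    elif a2 > 0.34:
        p = np.exp(0.9177 - 4.279 * a2 - 1.38 * a2**2)
    elif a2 > 0.2:
        p = 1 - np.exp(-8.318 + 42.796 * a2 - 59.938 * a2**2)
    else:
        p = 1 - np.exp(-13.436 + 101.14 * a2 - 223.73 * a2**2)
    return float(a2), float(min(max(p, 0.0), 1.0))


@dataclass
class NormalityReport:
    """Per-variable normality outcomes across data representations.

    ``table`` holds one row per (representation, group, variable) test;
    ``fraction_normal`` aggregates the share of tests not rejected at α
    per representation. "Normal" means the Anderson–Darling test did not
    reject at the declared α.
    """

    table: pd.DataFrame
    fraction_normal: dict[str, float]
    alpha: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> dict:
        return {"alpha": self.alpha, "fraction_normal": self.fraction_normal}


def normality_by_representation(
    table: CompositionTable,
    sbp: SBP,
    alpha: float = 0.01,
    representations: Sequence[str] = ("raw", "log", "alr", "ilr"),
    denominator: str | None = None,
) -> NormalityReport:
    """Run the Anderson–Darling test on every variable of every
    representation, within each group.

    Groups with fewer than MIN_AD_N samples (or degenerate variables) are
    skipped with a warning, not an error.
    """
    if table.group is not None:
        grouping = table.group
    else:
        grouping = pd.Series(["all"] * table.n, index=table.data.index)
    rows = []
    for rep in representations:
        X = transform_table(table, rep, sbp=sbp, denominator=denominator)
        for g, members in grouping.groupby(grouping, observed=True).groups.items():
            sub = X.loc[members]
            for col in X.columns:
                vals = sub[col].to_numpy()
                try:
                    a2, p = anderson_darling(vals)
                except DegenerateSampleError as exc:
                    warnings.warn(
                        f"normality test skipped for representation={rep}, "
                        f"group={g!r}, variable={col!r}: {exc}",
                        stacklevel=2,
                    )
                    continue
                rows.append((rep, g, col, len(vals), a2, p, p >= alpha))
    df = pd.DataFrame(
        rows,
        columns=["representation", "group", "variable", "n", "statistic",
                 "p_value", "normal"],
    )
    frac = {
        rep: float(sub["normal"].mean())
        for rep, sub in df.groupby("representation", observed=True)
    }
    return NormalityReport(table=df, fraction_normal=frac, alpha=alpha)


@dataclass(frozen=True)
class ScaleSpec:
    """One closure scale for the scale-dependency report.

    mode "as_is" uses the stored values; "reclose" re-closes each row's
    parts to ``kappa`` (e.g. the nutrient-sum scale); "filling" appends a
    filling value and closes to ``kappa`` (dry-matter embedding) but the
    correlation matrix is still reported over the measured parts.
    """

    name: str
    mode: str = "as_is"
    kappa: float | None = None

    def apply(self, table: CompositionTable) -> pd.DataFrame:
        if self.mode == "as_is":
            return table.data.copy()
        if self.mode == "reclose":
            if self.kappa is None:
                raise LabelError(f"scale {self.name!r}: reclose needs kappa")
            return table.close(self.kappa).data
        if self.mode == "filling":
            if self.kappa is None:
                raise LabelError(f"scale {self.name!r}: filling needs kappa")
            full = table.with_filling_value(self.kappa)
            return full.data[list(table.labels)]
        raise LabelError(f"unknown scale mode {self.mode!r}")


@dataclass
class ScaleCorrelationReport:
    """Pearson correlation matrices of the same samples under several
    closure scales, plus pairwise change summaries."""

    correlations: dict[str, pd.DataFrame]
    p_values: dict[str, pd.DataFrame]
    changes: pd.DataFrame  # long form: scale_a, scale_b, var_a, var_b, delta, sign_flip

    def n_sign_flips(self, scale_a: str, scale_b: str) -> int:
        sub = self.changes
        sel = (sub["scale_a"] == scale_a) & (sub["scale_b"] == scale_b)
        return int(sub.loc[sel, "sign_flip"].sum())

    def max_abs_delta(self, scale_a: str, scale_b: str) -> float:
        sub = self.changes
        sel = (sub["scale_a"] == scale_a) & (sub["scale_b"] == scale_b)
        return float(sub.loc[sel, "delta"].abs().max())


def _pearson_with_p(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    cols = list(X.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    vals = X.to_numpy()
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.pearsonr(vals[:, i], vals[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


def scale_dependency(
    table: CompositionTable,
    scales: Sequence[ScaleSpec],
    representation: str = "raw",
    sbp: SBP | None = None,
) -> ScaleCorrelationReport:
    """Correlation matrices of the same data expressed on several scales.

    With ``representation="raw"`` this demonstrates scale dependency and
    closure-induced spurious correlation; with a log-ratio representation
    ("ilr"/"clr"/"alr") the matrices are identical across scales because
    log-ratios are scale invariant.
    """
    if len(scales) < 2:
        raise LabelError("need at least two scale specs to compare")
    if table.n < 3:
        raise InsufficientDataError(f"need >= 3 samples, got {table.n}")
    corrs: dict[str, pd.DataFrame] = {}
    pvals: dict[str, pd.DataFrame] = {}
    for spec in scales:
        scaled = spec.apply(table)
        if representation == "raw":
            X = scaled
        else:
            sub = CompositionTable(scaled, kappa=table.kappa, unit=table.unit,
                                   group=table.group)
            X = transform_table(sub, representation, sbp=sbp)
        r, p = _pearson_with_p(X)
        corrs[spec.name] = r
        pvals[spec.name] = p
    names = [s.name for s in scales]
    rows = []
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            ra, rb = corrs[names[a_i]], corrs[names[b_i]]
            cols = list(ra.columns)
            for i in range(len(cols)):
                for j in range(i + 1, len(cols)):
                    va, vb = ra.iat[i, j], rb.iat[i, j]
                    rows.append((names[a_i], names[b_i], cols[i], cols[j],
                                 vb - va, bool(va * vb < 0)))
    changes = pd.DataFrame(
        rows, columns=["scale_a", "scale_b", "var_a", "var_b", "delta", "sign_flip"]
    )
    return ScaleCorrelationReport(correlations=corrs, p_values=pvals, changes=changes)


@dataclass
class OutlierMask:
    """Robust squared Mahalanobis distances with a chi-square cutoff.

    ``flagged[i]`` is True iff ``distances[i] > cutoff`` where the cutoff
    is the chi-square quantile at 1−α with ``df`` degrees of freedom (the
    dimension of the representation screened).
    """

    distances: np.ndarray
    cutoff: float
    flagged: np.ndarray
    alpha: float
    df: int
    representation: str = "ilr"
    index: pd.Index | None = None

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"robust_sq_mahalanobis": self.distances, "flagged": self.flagged},
            index=self.index,
        )


def robust_outliers(
    X,
    alpha: float = 0.01,
    seed: int = 0,
    representation: str = "ilr",
    support_fraction: float | None = None,
) -> OutlierMask:
    """Flag multivariate outliers by robust Mahalanobis distance.

    Location and scatter come from the minimum covariance determinant
    estimator (deterministic given ``seed``); the cutoff is
    chi²(1−α, dim). The mask is returned for the caller to apply.
    """
    index = X.index if isinstance(X, pd.DataFrame) else None
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    n, dim = arr.shape
    if n <= dim + 1:
        raise InsufficientDataError(
            f"robust screening needs n > dim+1 (n={n}, dim={dim})"
        )
    if not 0 < alpha < 1:
        raise LabelError(f"alpha must be in (0, 1), got {alpha}")
    mcd = MinCovDet(random_state=seed, support_fraction=support_fraction)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            mcd.fit(arr)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise DegenerateCovarianceError(
                f"robust scatter estimation failed ({exc}); remove collinear "
                "or constant variables, or screen a lower-dimensional "
                "representation"
            ) from None
    eigmin = float(np.linalg.eigvalsh(mcd.covariance_).min())
    if eigmin <= 1e-12 * max(1.0, float(np.abs(mcd.covariance_).max())):
        raise DegenerateCovarianceError(
            "robust scatter is singular; variables are collinear — drop "
            "redundant coordinates (e.g. use ilr, not clr) before screening"
        )
    d2 = mcd.mahalanobis(arr)
    cutoff = float(stats.chi2.ppf(1 - alpha, dim))
    return OutlierMask(distances=d2, cutoff=cutoff, flagged=d2 > cutoff,
                       alpha=alpha, df=dim, representation=representation,
                       index=index)


def robust_outliers_by_group(
    X: pd.DataFrame,
    group: pd.Series,
    alpha: float = 0.01,
    seed: int = 0,
    representation: str = "ilr",
) -> OutlierMask:
    """Per-group robust screening (each group gets its own MCD fit);
    results are combined into a single mask aligned with ``X``."""
    d2 = pd.Series(np.nan, index=X.index)
    flagged = pd.Series(False, index=X.index)
    cutoff = float(stats.chi2.ppf(1 - alpha, X.shape[1]))
    for g, members in group.groupby(group, observed=True).groups.items():
        sub = X.loc[members]
        mask = robust_outliers(sub, alpha=alpha, seed=seed,
                               representation=representation)
        d2.loc[members] = mask.distances
        flagged.loc[members] = mask.flagged
    return OutlierMask(distances=d2.to_numpy(), cutoff=cutoff,
                       flagged=flagged.to_numpy(), alpha=alpha, df=X.shape[1],
                       representation=representation, index=X.index)
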