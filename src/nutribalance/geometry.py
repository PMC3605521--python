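"""Aitchison geometry: distances, norms, and the log-Euclidean bias.

The Aitchison distance between two compositions is the Euclidean distance
between their ilr coordinate vectors — equivalently between their clr
vectors — and is invariant to the SBP chosen and to the closure constant.
The ordinary log-Euclidean distance ε (between ln-concentration vectors on
a common closure) is not: its square exceeds the squared Aitchison
distance by D·(ln g(x)/g(y))², a strictly non-negative bias that vanishes
only when the two geometric means coincide. This module computes both and
reports the decomposition, per pair and for whole tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .balances import SBP, ilr
from .core import Composition, CompositionTable
from .errors import DimensionError, LabelError, UnitMismatchError

__all__ = [
    "DistanceReport",
    "aitchison_distance",
    "aitchison_norm",
    "log_euclidean_bias",
    "pairwise_distances",
    "PairwiseDistances",
    "IDENTITY_RTOL",
    "ZERO_ATOL",
]

#: Relative tolerance for algebraic identities (e.g. ε² = 𝒜² + bias).
IDENTITY_RTOL = 1e-10
#: Absolute tolerance used near zero.
ZERO_ATOL = 1e-12


@dataclass(frozen=True)
class DistanceReport:
    """Paired Aitchison / log-Euclidean distances for one sample pair.

    Satisfies ``log_euclidean² == aitchison² + bias_term`` within
    ``IDENTITY_RTOL`` and ``log_euclidean >= aitchison``.
    """

    id_a: object
    id_b: object
    aitchison: float
    log_euclidean: float
    bias_term: float

    def __post_init__(self) -> None:
        for name in ("aitchison", "log_euclidean", "bias_term"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < -ZERO_ATOL:
                raise DimensionError(f"{name} must be finite and >= 0, got {v}")
        lhs = self.log_euclidean**2
        rhs = self.aitchison**2 + self.bias_term
        if abs(lhs - rhs) > IDENTITY_RTOL * max(1.0, abs(lhs)):
            raise DimensionError(
                f"inconsistent report: eps^2={lhs} != A^2+bias={rhs}"
            )


def _clr_vector(parts: np.ndarray) -> np.ndarray:
    logs = np.log(parts)
    return logs - logs.mean()


def _check_pair(a: Composition, b: Composition) -> None:
    if a.labels != b.labels:
        raise LabelError(
            f"part labels differ: {list(a.labels)} vs {list(b.labels)}"
        )


def aitchison_distance(a: Composition, b: Composition, sbp: SBP | None = None) -> float:
    """Aitchison distance 𝒜 between two compositions.

    Computed through the ilr coordinates of ``sbp`` when given, otherwise
    through the clr vectors; both routes agree to floating point because
    any valid SBP is an orthonormal basis of the same space.
    """
    _check_pair(a, b)
    if sbp is not None:
        va = ilr(a, sbp).values
        vb = ilr(b, sbp).values
    else:
        va = _clr_vector(a.parts)
        vb = _clr_vector(b.parts)
    return float(np.linalg.norm(va - vb))


def aitchison_norm(a: Composition, sbp: SBP | None = None) -> float:
    """Aitchison norm: the distance from the barycenter (equal parts),
    i.e. the Euclidean norm of the ilr coordinate vector."""
    if sbp is not None:
        return float(np.linalg.norm(ilr(a, sbp).values))
    return float(np.linalg.norm(_clr_vector(a.parts)))


def log_euclidean_bias(
    a: Composition, b: Composition, id_a="a", id_b="b"
) -> DistanceReport:
    """Decompose the ordinary log-Euclidean distance into Aitchison
    distance plus geometric-mean bias.

    ε is the Euclidean distance between ln-part vectors after closing both
    compositions to their (shared) κ; 𝒜 is closure-free. The report
    satisfies ε² = 𝒜² + D·(ln g(x)/g(y))².

    Raises
    ------
    UnitMismatchError
        If the two compositions carry different κ or units — mixing scales
        silently would corrupt the scale-sensitive bias term.
    """
    _check_pair(a, b)
    if abs(a.kappa - b.kappa) > ZERO_ATOL * max(a.kappa, b.kappa) or a.unit != b.unit:
        raise UnitMismatchError(
            f"compositions on different scales (kappa {a.kappa:g} {a.unit} vs "
            f"{b.kappa:g} {b.unit}); re-close explicitly before comparing"
        )
    ca, cb = a.close(), b.close()
    la, lb = np.log(ca.parts), np.log(cb.parts)
    eps = float(np.linalg.norm(la - lb))
    A = float(np.linalg.norm(_clr_vector(ca.parts) - _clr_vector(cb.parts)))
    bias = a.D * (np.log(ca.geometric_mean() / cb.geometric_mean())) ** 2
    return DistanceReport(id_a=id_a, id_b=id_b, aitchison=A,
                          log_euclidean=eps, bias_term=float(bias))


@dataclass
class PairwiseDistances:
    """All-pairs distances for a table: square matrices plus the long-form
    per-pair report stream."""

    aitchison: pd.DataFrame
    log_euclidean: pd.DataFrame
    bias_term: pd.DataFrame

    def matrix(self, metric: str) -> pd.DataFrame:
        if metric not in ("aitchison", "log_euclidean"):
            raise LabelError(f"unknown metric {metric!r}")
        return getattr(self, metric)

    def long_form(self) -> pd.DataFrame:
        ids = self.aitchison.index
        rows = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append(
                    (ids[i], ids[j],
                     self.aitchison.iat[i, j],
                     self.log_euclidean.iat[i, j],
                     self.bias_term.iat[i, j])
                )
        return pd.DataFrame(
            rows, columns=["id_a", "id_b", "aitchison", "log_euclidean", "bias_term"]
        )

    def to_csv(self, path: str | Path, square: bool = False, metric: str = "aitchison") -> None:
        if square:
            self.matrix(metric).to_csv(path, index_label="sample_id")
        else:
            self.long_form().to_csv(path, index=False)

    def within_group_summary(self, group: pd.Series) -> pd.DataFrame:
        """Median/quartile summary of within-group 𝒜 and ε distances —
        the per-group distance-distribution comparison report."""
        rows = []
        for g, members in group.groupby(group, observed=True).groups.items():
            idx = self.aitchison.index.get_indexer(members)
            if len(idx) < 2:
                continue
            sub_a = self.aitchison.to_numpy()[np.ix_(idx, idx)]
            sub_e = self.log_euclidean.to_numpy()[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            for name, vals in (("aitchison", sub_a[iu]), ("log_euclidean", sub_e[iu])):
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                rows.append((g, name, len(vals), q1, med, q3))
        return pd.DataFrame(
            rows, columns=["group", "metric", "n_pairs", "q1", "median", "q3"]
        )


def pairwise_distances(table: CompositionTable, sbp: SBP | None = None) -> PairwiseDistances:
    """All-pairs Aitchison and log-Euclidean distances with bias terms.

    Vectorized over the clr / log matrices; both distance matrices are
    symmetric with zero diagonal, and ε ≥ 𝒜 entrywise.
    """
    closed = table.close()
    logs = np.log(closed.data.to_numpy())
    clrs = logs - logs.mean(axis=1, keepdims=True)
    gml = logs.mean(axis=1)

    def _sq(M: np.ndarray) -> np.ndarray:
        gram = M @ M.T
        sq = np.diag(gram)[:, None] + np.diag(gram)[None, :] - 2 * gram
        np.fill_diagonal(sq, 0.0)
        return np.sqrt(np.maximum(sq, 0.0))

    A = _sq(clrs)
    eps = _sq(logs)
    bias = table.D * (gml[:, None] - gml[None, :]) ** 2
    idx = table.data.index
    as_df = lambda M: pd.DataFrame(M, index=idx, columns=idx)
    return PairwiseDistances(aitchison=as_df(A), log_euclidean=as_df(eps),
                             bias_term=as_df(bias))
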