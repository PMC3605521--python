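"""Core compositional types and elementary log-ratio transforms.

A composition is a vector of strictly positive parts carrying only
relative information; closing it rescales the parts to a constant sum
κ (the measurement scale: 1, 100 %, 1000 g·kg⁻¹, ...). This module
provides the :class:`Composition` / :class:`CompositionTable` containers,
the closure operator, the filling value (the unanalyzed remainder of the
tissue mass), the additive (alr) and centered (clr) log-ratio transforms,
and the dual/amalgamated ratio combinatorics of a D-part vector.

Unit bookkeeping is deliberately explicit: κ and the unit string live on
the container, and rescaling between units is a named operation
(:func:`convert_unit`), never an implicit side effect — the covariance
structure of *raw* parts depends on the scale chosen, so silent rescaling
is dangerous. Log-ratio quantities are invariant to the scale and do not
care.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DimensionError,
    FillingValueError,
    LabelError,
    PositivityError,
    UnitMismatchError,
)

__all__ = [
    "Composition",
    "CompositionTable",
    "RatioCounts",
    "closure",
    "filling_value",
    "with_filling_value",
    "alr",
    "clr",
    "count_ratios",
    "convert_unit",
    "replace_below_detection",
    "RESERVED_COLUMNS",
    "CLOSURE_RTOL",
]

#: Relative tolerance on the closed sum (sum(parts) == κ within CLOSURE_RTOL·κ).
CLOSURE_RTOL = 1e-12

#: CSV columns that are never part labels.
RESERVED_COLUMNS = ("sample_id", "group")

#: Known unit strings and their κ-per-unit factor relative to a mass fraction.
_UNIT_KAPPA = {"unitless": 1.0, "%": 100.0, "g/kg": 1000.0}


def _as_positive_array(values: Sequence[float], labels: Sequence[str] | None) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise DimensionError(f"expected a non-empty 1-D vector, got shape {arr.shape}")
    bad = ~(arr > 0) | ~np.isfinite(arr)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        name = labels[idx] if labels is not None else f"index {idx}"
        raise PositivityError(
            f"part {name!r} has non-positive or non-finite value {arr[idx]!r}; "
            "compositional parts must be strictly positive"
        )
    return arr


def _check_labels(labels: Sequence[str], D: int) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(labels) != D:
        raise LabelError(f"{len(labels)} labels for {D} parts")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise LabelError(f"duplicate part labels: {dupes}")
    for lab in labels:
        if lab in RESERVED_COLUMNS:
            raise LabelError(f"label {lab!r} is reserved")
    return labels


@dataclass(frozen=True, eq=False)
class Composition:
    """One sample's strictly positive part vector with measurement scale κ.

    Parameters
    ----------
    parts
        Strictly positive concentrations, length D ≥ 2. Need not sum to
        ``kappa``; call :meth:`close` (or :func:`closure`) for the closed
        representative. Log-ratio transforms are identical either way.
    labels
        Unique part names, e.g. ``("N", "P", "K", "Ca", "Mg")``.
    kappa
        Closure constant of the measurement scale (1, 100, 1000, ...).
    unit
        Unit annotation: ``"unitless"``, ``"%"`` or ``"g/kg"``.
    """

    parts: np.ndarray
    labels: tuple[str, ...]
    kappa: float = 1.0
    unit: str = "unitless"

    def __post_init__(self) -> None:
        arr = _as_positive_array(self.parts, list(self.labels) if self.labels else None)
        if arr.size < 2:
            raise DimensionError("a composition needs at least 2 parts")
        labels = _check_labels(self.labels, arr.size)
        if not self.kappa > 0:
            raise DimensionError(f"kappa must be positive, got {self.kappa}")
        object.__setattr__(self, "parts", arr)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "kappa", float(self.kappa))

    @property
    def D(self) -> int:
        """Number of parts."""
        return self.parts.size

    @property
    def is_closed(self) -> bool:
        """True when the parts already sum to κ within ``CLOSURE_RTOL``·κ."""
        return abs(self.parts.sum() - self.kappa) <= CLOSURE_RTOL * self.kappa

    def close(self, kappa: float | None = None) -> "Composition":
        """Return the closure of this composition to ``kappa`` (default: own κ)."""
        k = self.kappa if kappa is None else float(kappa)
        return closure(self.parts, k, labels=self.labels, unit=self.unit)

    def geometric_mean(self) -> float:
        """Geometric mean g(x) of the parts."""
        return float(np.exp(np.mean(np.log(self.parts))))

    def subcomposition(self, labels: Sequence[str]) -> "Composition":
        """Extract the named parts (order as given) without re-closing."""
        idx = [self.index_of(lab) for lab in labels]
        return Composition(self.parts[idx], tuple(labels), self.kappa, self.unit)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise LabelError(f"unknown part label {label!r}; have {list(self.labels)}") from None

    def as_series(self) -> pd.Series:
        return pd.Series(self.parts, index=list(self.labels))

    # -- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "parts": self.parts.tolist(),
            "labels": list(self.labels),
            "kappa": self.kappa,
            "unit": self.unit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Composition":
        return cls(np.asarray(d["parts"], float), tuple(d["labels"]),
                   d.get("kappa", 1.0), d.get("unit", "unitless"))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "Composition":
        return cls.from_dict(json.loads(s))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        body = ", ".join(f"{l}={v:.4g}" for l, v in zip(self.labels, self.parts))
        return f"Composition({body}; kappa={self.kappa:g} {self.unit})"


def closure(
    values: Sequence[float],
    kappa: float,
    labels: Sequence[str] | None = None,
    unit: str = "unitless",
) -> Composition:
    """Close a positive vector to constant sum ``kappa``.

    The closed parts are proportional to the inputs and sum to κ exactly;
    the operator is idempotent.
    """
    if not kappa > 0:
        raise DimensionError(f"kappa must be positive, got {kappa}")
    arr = _as_positive_array(values, list(labels) if labels is not None else None)
    if labels is None:
        labels = tuple(f"x{i + 1}" for i in range(arr.size))
    closed = arr * (float(kappa) / arr.sum())
    return Composition(closed, tuple(labels), float(kappa), unit)


def filling_value(concentrations: Sequence[float], kappa: float) -> float:
    """κ minus the sum of measured parts: the unanalyzed remainder.

    Raises
    ------
    FillingValueError
        If the parts already sum to κ or more (no strictly positive
        remainder exists — usually a wrong unit or κ).
    """
    arr = _as_positive_array(concentrations, None)
    total = float(arr.sum())
    if total >= kappa:
        raise FillingValueError(
            f"parts sum to {total:g} >= kappa {kappa:g}: no strictly positive "
            "filling value; check the measurement unit or closure constant"
        )
    return float(kappa) - total


def with_filling_value(comp: Composition, kappa: float, label: str = "Fv") -> Composition:
    """Append the filling value and close to ``kappa``.

    Embeds a measured subcomposition (e.g. the five nutrients on a
    dry-matter basis) into the full D+1-part composition whose last part
    is the remainder.
    """
    fv = filling_value(comp.parts, kappa)
    if label in comp.labels:
        raise LabelError(f"label {label!r} already present")
    parts = np.append(comp.parts, fv)
    return Composition(parts, comp.labels + (label,), float(kappa), comp.unit)


def alr(comp: Composition, denominator: str) -> pd.Series:
    """Additive log-ratio: ln(part / denominator part), one value per
    remaining part.

    Invariant to the closure constant. Entries are named ``"part/denom"``.
    """
    d = comp.index_of(denominator)
    keep = [i for i in range(comp.D) if i != d]
    vals = np.log(comp.parts[keep] / comp.parts[d])
    names = [f"{comp.labels[i]}/{comp.labels[d]}" for i in keep]
    return pd.Series(vals, index=names, name="alr")


def clr(comp: Composition) -> pd.Series:
    """Centered log-ratio: ln(part / geometric mean of all parts).

    The D entries sum to zero; invariant to the closure constant.
    """
    logs = np.log(comp.parts)
    vals = logs - logs.mean()
    return pd.Series(vals, index=list(comp.labels), name="clr")


@dataclass(frozen=True)
class RatioCounts:
    """How many ratio expressions a D-part vector can generate versus its
    actual degrees of freedom.

    ``dual`` counts unordered pairs x/y; ``amalgamated`` counts expressions
    of one part over the sum of one or two other parts (x/y and x/(y+z),
    dual forms included: D·C(D−1, 2) + C(D, 2) = D(D−1)²/2); ``dof`` = D−1
    is the number of linearly independent log-ratio coordinates.
    """

    D: int
    dual: int
    amalgamated: int
    dof: int

    def to_dict(self) -> dict:
        return {"D": self.D, "dual": self.dual,
                "amalgamated": self.amalgamated, "dof": self.dof}

    @classmethod
    def from_dict(cls, d: dict) -> "RatioCounts":
        return cls(d["D"], d["dual"], d["amalgamated"], d["dof"])


def count_ratios(D: int) -> RatioCounts:
    """Dual and amalgamated ratio counts for a D-part composition.

    dual = D(D−1)/2, amalgamated = D(D−1)²/2, dof = D−1.
    """
    D = int(D)
    if D < 2:
        raise DimensionError(f"need at least 2 parts, got D={D}")
    return RatioCounts(D=D, dual=D * (D - 1) // 2,
                       amalgamated=D * (D - 1) ** 2 // 2, dof=D - 1)


def convert_unit(comp: Composition, unit: str) -> Composition:
    """Explicitly rescale between ``%`` and ``g/kg`` (factor 10) or to
    ``unitless`` fractions. κ is converted consistently."""
    if comp.unit not in _UNIT_KAPPA or unit not in _UNIT_KAPPA:
        raise UnitMismatchError(
            f"can only convert between {sorted(_UNIT_KAPPA)}, "
            f"got {comp.unit!r} -> {unit!r}"
        )
    factor = _UNIT_KAPPA[unit] / _UNIT_KAPPA[comp.unit]
    return Composition(comp.parts * factor, comp.labels, comp.kappa * factor, unit)


def replace_below_detection(
    values: Sequence[float],
    detection_limit: float | Sequence[float],
    fraction: float = 0.65,
) -> np.ndarray:
    """Multiplicative replacement of zeros / below-detection values.

    Opt-in preprocessing hook: values below the detection limit are set to
    ``fraction * detection_limit`` and the remaining parts are scaled down
    multiplicatively so the total is preserved. By default compositions
    reject non-positive parts outright; use this only when a detection
    limit is actually known.
    """
    arr = np.asarray(values, dtype=float)
    dl = np.broadcast_to(np.asarray(detection_limit, dtype=float), arr.shape)
    if not (dl > 0).all():
        raise PositivityError("detection limits must be strictly positive")
    below = arr < dl
    if not below.any():
        return arr.copy()
    repl = fraction * dl
    total = arr.sum()
    out = arr.copy()
    out[below] = repl[below]
    kept = ~below
    # shrink the detected parts so the row total is unchanged
    out[kept] *= (total - out[below].sum()) / arr[kept].sum()
    if not (out > 0).all():
        raise PositivityError("replacement produced non-positive parts; "
                              "detection limits too large for this row")
    return out


class CompositionTable:
    """Sample-by-part table of compositions sharing labels, κ and unit.

    Parameters
    ----------
    data
        DataFrame with one column per part (strictly positive floats) and
        one row per sample; the index is the sample id.
    kappa, unit
        Shared measurement scale.
    group
        Optional categorical label per row (species, cultivar, ...),
        aligned with ``data.index``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        kappa: float = 1.0,
        unit: str = "unitless",
        group: pd.Series | None = None,
    ):
        if data.shape[0] == 0 or data.shape[1] < 2:
            raise DimensionError(
                f"need >=1 row and >=2 part columns, got shape {data.shape}"
            )
        labels = _check_labels(data.columns, data.shape[1])
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all() or (values <= 0).any():
            rows, cols = np.where(~(values > 0) | ~np.isfinite(values))
            rid, part = data.index[rows[0]], labels[cols[0]]
            raise PositivityError(
                f"sample {rid!r}, part {part!r}: value "
                f"{values[rows[0], cols[0]]!r} is not strictly positive"
            )
        if not kappa > 0:
            raise DimensionError(f"kappa must be positive, got {kappa}")
        if group is not None:
            group = pd.Series(group)
            if not group.index.equals(data.index):
                group = pd.Series(np.asarray(group), index=data.index)
            group = group.astype("category")
        self.data = data.astype(float).copy()
        self.data.columns = list(labels)
        self.kappa = float(kappa)
        self.unit = unit
        self.group = group

    # -- basic properties ------------------------------------------------
    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def D(self) -> int:
        return self.data.shape[1]

    def __len__(self) -> int:
        return self.n

    def iter_compositions(self) -> Iterator[Composition]:
        for _, row in self.data.iterrows():
            yield Composition(row.to_numpy(), self.labels, self.kappa, self.unit)

    def composition(self, sample_id) -> Composition:
        row = self.data.loc[sample_id]
        return Composition(row.to_numpy(), self.labels, self.kappa, self.unit)

    # -- transforms of the whole table -----------------------------------
    def close(self, kappa: float | None = None) -> "CompositionTable":
        """Re-close every row to ``kappa`` (default: own κ)."""
        k = self.kappa if kappa is None else float(kappa)
        if not k > 0:
            raise DimensionError(f"kappa must be positive, got {k}")
        vals = self.data.to_numpy()
        closed = vals * (k / vals.sum(axis=1, keepdims=True))
        return CompositionTable(
            pd.DataFrame(closed, index=self.data.index, columns=self.data.columns),
            kappa=k, unit=self.unit, group=self.group,
        )

    def subcomposition(self, labels: Sequence[str]) -> "CompositionTable":
        missing = [x for x in labels if x not in self.data.columns]
        if missing:
            raise LabelError(f"unknown part labels {missing}")
        return CompositionTable(self.data[list(labels)], self.kappa, self.unit, self.group)

    def with_filling_value(self, kappa: float, label: str = "Fv") -> "CompositionTable":
        """Append per-row filling values and close to ``kappa``."""
        totals = self.data.sum(axis=1)
        if (totals >= kappa).any():
            rid = totals.index[int(np.argmax(totals.to_numpy() >= kappa))]
            raise FillingValueError(
                f"sample {rid!r} sums to {totals.loc[rid]:g} >= kappa {kappa:g}"
            )
        out = self.data.copy()
        out[label] = kappa - totals
        return CompositionTable(out, kappa=float(kappa), unit=self.unit, group=self.group)

    def select(self, mask: Sequence[bool]) -> "CompositionTable":
        mask = np.asarray(mask, dtype=bool)
        grp = self.group[mask] if self.group is not None else None
        return CompositionTable(self.data.loc[mask], self.kappa, self.unit, grp)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        kappa: float = 1.0,
        unit: str = "unitless",
        decimal: str = ".",
    ) -> "CompositionTable":
        """Read a table whose header holds part labels plus the reserved
        ``sample_id`` and ``group`` columns."""
        df = pd.read_csv(path, decimal=decimal)
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        group = None
        if "group" in df.columns:
            group = df.pop("group")
        return cls(df, kappa=kappa, unit=unit, group=group)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "sample_id", self.data.index)
        if self.group is not None:
            out.insert(1, "group", self.group.to_numpy())
        out.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g = self.group.nunique() if self.group is not None else 0
        return (f"CompositionTable(n={self.n}, D={self.D}, kappa={self.kappa:g} "
                f"{self.unit}, groups={g})")
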