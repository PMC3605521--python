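"""Sequential binary partitions and the isometric log-ratio transform.

A sequential binary partition (SBP) splits the part set hierarchically:
the first contrast involves all D parts, and every subsequent contrast
splits one of the sign-groups created earlier, until all groups are
singletons — D−1 contrasts in total. Each row yields one orthonormal
log-contrast ("balance"):

    ilr_j = sqrt(r_j s_j / (r_j + s_j)) · ln( g(+group) / g(−group) )

where r_j, s_j are the sizes of the +1 and −1 groups and g(·) is the
geometric mean. The +1 group sits in the numerator, so a positive balance
means the +1 group's geometric mean exceeds the −1 group's; this sign
convention is never flipped silently.

The D−1 balances are orthonormal coordinates of the composition, so the
Euclidean geometry of ilr space is exactly the Aitchison geometry of the
simplex, whatever valid SBP is chosen (a different SBP only rotates the
coordinates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Composition, CompositionTable, closure
from .errors import DimensionError, HierarchyViolationError, LabelError

__all__ = [
    "SBP",
    "OrthonormalBasis",
    "BalanceCoordinates",
    "sbp_validate",
    "sbp_from_csv",
    "sbp_to_csv",
    "sbp_from_json",
    "sbp_to_basis",
    "ilr",
    "ilr_inverse",
    "default_ionome_sbp",
    "balance_dendrogram",
    "BalanceNode",
    "random_sbp",
    "transform_table",
    "REPRESENTATIONS",
]

#: Data representations understood by :func:`transform_table`.
REPRESENTATIONS = ("raw", "log", "alr", "clr", "ilr")


def _row_name(row: np.ndarray, labels: Sequence[str], sep: str = ", ") -> str:
    plus = [labels[i] for i in np.flatnonzero(row > 0)]
    minus = [labels[i] for i in np.flatnonzero(row < 0)]
    return f"[{','.join(plus)} | {','.join(minus)}]"


@dataclass(frozen=True, eq=False)
class SBP:
    """A validated sequential binary partition.

    Attributes
    ----------
    matrix
        (D−1) × D array of {+1, −1, 0} contrasts, hierarchy order preserved
        as given.
    part_labels
        Ordered part names (columns).
    row_names
        Balance designations in the ``[numerator | denominator]`` style.
    """

    matrix: np.ndarray
    part_labels: tuple[str, ...]
    row_names: tuple[str, ...]

    @property
    def D(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_balances(self) -> int:
        return self.matrix.shape[0]

    def safe_row_names(self, sep: str = ".", joiner: str = "_vs_") -> tuple[str, ...]:
        """File-system-safe balance names, e.g. ``N.P.K_vs_Ca.Mg``."""
        out = []
        for row in self.matrix:
            plus = sep.join(self.part_labels[i] for i in np.flatnonzero(row > 0))
            minus = sep.join(self.part_labels[i] for i in np.flatnonzero(row < 0))
            out.append(f"{plus}{joiner}{minus}")
        return tuple(out)

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(),
                "part_labels": list(self.part_labels),
                "row_names": list(self.row_names)}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def sbp_validate(matrix, part_labels: Sequence[str]) -> SBP:
    """Validate a signed contrast matrix as a sequential binary partition.

    Checks shape, entry domain, and the hierarchy rule: the active
    (nonzero) part set of each row must be a group created by an earlier
    split (the first row activates all parts), and every group of size ≥ 2
    is split exactly once. Row order is preserved.

    Raises
    ------
    HierarchyViolationError
        Naming the first offending row and its active set.
    """
    mat = np.asarray(matrix, dtype=int)
    labels = tuple(str(x) for x in part_labels)
    if mat.ndim != 2:
        raise DimensionError(f"contrast matrix must be 2-D, got ndim={mat.ndim}")
    D = len(labels)
    if len(set(labels)) != D:
        raise LabelError(f"duplicate part labels: {list(labels)}")
    if D < 2:
        raise DimensionError("need at least 2 parts")
    if mat.shape != (D - 1, D):
        raise DimensionError(
            f"expected shape ({D - 1}, {D}) for {D} parts, got {mat.shape}"
        )
    if not np.isin(mat, (-1, 0, 1)).all():
        raise HierarchyViolationError("entries must be in {-1, 0, +1}")

    open_groups: set[frozenset[int]] = {frozenset(range(D))}
    for j, row in enumerate(mat):
        plus = frozenset(np.flatnonzero(row > 0).tolist())
        minus = frozenset(np.flatnonzero(row < 0).tolist())
        if not plus or not minus:
            raise HierarchyViolationError(
                f"row {j} ({_row_name(row, labels)}) must contain at least one "
                "+1 and one -1 entry"
            )
        active = plus | minus
        if active not in open_groups:
            names = sorted(labels[i] for i in active)
            raise HierarchyViolationError(
                f"row {j}: active set {names} is not a group created by an "
                "earlier split — the partition is not sequential"
            )
        open_groups.remove(active)
        for grp in (plus, minus):
            if len(grp) >= 2:
                open_groups.add(grp)
    if open_groups:
        leftover = [sorted(labels[i] for i in g) for g in open_groups]
        raise HierarchyViolationError(f"groups never split into singletons: {leftover}")

    names = tuple(_row_name(row, labels) for row in mat)
    return SBP(matrix=mat, part_labels=labels, row_names=names)


def sbp_from_csv(path: str | Path) -> SBP:
    """Read an SBP from CSV: rows = balances, columns = parts, cells in
    {−1, 0, 1}. An optional first unnamed column holds row names (ignored;
    names are regenerated)."""
    df = pd.read_csv(path)
    first = df.columns[0]
    if first.startswith("Unnamed") or first in ("ilr", "balance", "row"):
        df = df.set_index(first)
    return sbp_validate(df.to_numpy(dtype=int), list(df.columns))


def sbp_to_csv(sbp: SBP, path: str | Path) -> None:
    df = pd.DataFrame(sbp.matrix, columns=list(sbp.part_labels),
                      index=list(sbp.row_names))
    df.to_csv(path, index_label="balance")


def sbp_from_json(text: str) -> SBP:
    d = json.loads(text)
    return sbp_validate(np.asarray(d["matrix"], int), d["part_labels"])


@dataclass(frozen=True, eq=False)
class OrthonormalBasis:
    """Contrast-coefficient matrix Ψ of an SBP.

    Row j carries +√(r_j s_j/(r_j+s_j))/r_j on the +1 parts and
    −√(r_j s_j/(r_j+s_j))/s_j on the −1 parts; Ψ Ψᵀ = I and each row sums
    to zero.
    """

    psi: np.ndarray
    sbp: SBP


def sbp_to_basis(sbp: SBP) -> OrthonormalBasis:
    """Build the orthonormal contrast matrix Ψ from a validated SBP."""
    mat = sbp.matrix
    r = (mat > 0).sum(axis=1).astype(float)
    s = (mat < 0).sum(axis=1).astype(float)
    coef = np.sqrt(r * s / (r + s))
    psi = np.zeros(mat.shape, dtype=float)
    for j in range(mat.shape[0]):
        psi[j, mat[j] > 0] = coef[j] / r[j]
        psi[j, mat[j] < 0] = -coef[j] / s[j]
    return OrthonormalBasis(psi=psi, sbp=sbp)


@dataclass(frozen=True, eq=False)
class BalanceCoordinates:
    """Per-sample log-ratio coordinates with their balance names.

    ``values`` is (D−1,) for a single composition or (n, D−1) for a table;
    ``transform`` tags the representation (ilr/alr/log/raw).
    """

    values: np.ndarray
    balance_names: tuple[str, ...]
    transform: str = "ilr"
    index: pd.Index | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if not np.isfinite(arr).all():
            raise DimensionError("balance coordinates must be finite")
        if arr.ndim not in (1, 2) or arr.shape[-1] != len(self.balance_names):
            raise DimensionError(
                f"values shape {arr.shape} does not match "
                f"{len(self.balance_names)} balance names"
            )
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "balance_names", tuple(self.balance_names))

    def as_frame(self) -> pd.DataFrame:
        vals = np.atleast_2d(self.values)
        return pd.DataFrame(vals, columns=list(self.balance_names), index=self.index)


def _aligned_parts(labels: Sequence[str], sbp: SBP) -> list[int]:
    missing = [x for x in sbp.part_labels if x not in labels]
    extra = [x for x in labels if x not in sbp.part_labels]
    if missing or extra:
        raise LabelError(
            f"part labels do not match the SBP: missing {missing}, extra {extra}"
        )
    return [list(labels).index(x) for x in sbp.part_labels]


def ilr(comp_or_table: Composition | CompositionTable, sbp: SBP) -> BalanceCoordinates:
    """Isometric log-ratio coordinates of a composition or table.

    Equals Ψ · ln(parts) per sample (the closure constant cancels in each
    log-contrast, so the input need not be closed).
    """
    basis = sbp_to_basis(sbp)
    if isinstance(comp_or_table, Composition):
        idx = _aligned_parts(comp_or_table.labels, sbp)
        vals = basis.psi @ np.log(comp_or_table.parts[idx])
        return BalanceCoordinates(vals, sbp.row_names, "ilr")
    idx = _aligned_parts(comp_or_table.labels, sbp)
    logs = np.log(comp_or_table.data.to_numpy()[:, idx])
    vals = logs @ basis.psi.T
    return BalanceCoordinates(vals, sbp.row_names, "ilr",
                              index=comp_or_table.data.index)


def ilr_inverse(
    coords: BalanceCoordinates | np.ndarray,
    sbp: SBP,
    kappa: float = 1.0,
    unit: str = "unitless",
) -> Composition | CompositionTable:
    """Map ilr coordinates back to a composition closed to ``kappa``.

    Round trip: ``ilr_inverse(ilr(x), sbp, kappa)`` equals the closure of
    ``x`` to κ within 1e-10 relative.
    """
    vals = coords.values if isinstance(coords, BalanceCoordinates) else np.asarray(coords, float)
    psi = sbp_to_basis(sbp).psi
    if vals.shape[-1] != psi.shape[0]:
        raise DimensionError(
            f"{vals.shape[-1]} coordinates for an SBP with {psi.shape[0]} balances"
        )
    if vals.ndim == 1:
        return closure(np.exp(psi.T @ vals), kappa, labels=sbp.part_labels, unit=unit)
    raw = np.exp(vals @ psi)
    raw *= kappa / raw.sum(axis=1, keepdims=True)
    index = coords.index if isinstance(coords, BalanceCoordinates) else None
    df = pd.DataFrame(raw, columns=list(sbp.part_labels), index=index)
    return CompositionTable(df, kappa=kappa, unit=unit)


#: Leaf-ionome partition over (N, P, K, Ca, Mg): the macro-nutrient group
#: against the cations, then N,P against K, the N/P contrast, and Ca/Mg.
_IONOME_SBP = [
    [+1, +1, +1, -1, -1],
    [+1, +1, -1, 0, 0],
    [+1, -1, 0, 0, 0],
    [0, 0, 0, +1, -1],
]


def default_ionome_sbp(include_fv: bool = False) -> SBP:
    """The standard 5-nutrient leaf-ionome SBP over (N, P, K, Ca, Mg).

    With ``include_fv`` the composition is first embedded into the
    dry-matter scale: the leading contrast puts all five nutrients against
    the filling value Fv, followed by the four nutrient balances.
    """
    labels = ("N", "P", "K", "Ca", "Mg")
    if not include_fv:
        return sbp_validate(_IONOME_SBP, labels)
    rows = [[+1, +1, +1, +1, +1, -1]]
    rows += [r + [0] for r in _IONOME_SBP]
    return sbp_validate(rows, labels + ("Fv",))


@dataclass
class BalanceNode:
    """Node of a balance dendrogram: internal nodes carry a balance name
    and optional summary statistics; leaves carry a part label."""

    name: str
    parts: tuple[str, ...]
    children: list["BalanceNode"]
    stats: dict | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_dict(self) -> dict:
        d = {"name": self.name, "parts": list(self.parts)}
        if self.stats:
            d["stats"] = self.stats
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        return d

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        safe = self.name.replace(" ", "").replace(",", ".").replace("|", "_vs_")
        safe = safe.replace("[", "").replace("]", "").replace("(", "").replace(")", "")
        if self.is_leaf:
            return safe
        inner = ",".join(c._newick() for c in self.children)
        return f"({inner}){safe}"

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_labels())
        return out


def balance_dendrogram(
    sbp: SBP, summaries: dict[str, dict] | None = None
) -> BalanceNode:
    """Hierarchical layout of an SBP for plotting / export.

    Parameters
    ----------
    summaries
        Optional per-balance statistics keyed by row name (e.g. mean and
        quartiles of the coordinate across samples); attached to the
        matching internal node.
    """
    labels = sbp.part_labels
    by_active: dict[frozenset[int], int] = {}
    for j, row in enumerate(sbp.matrix):
        by_active[frozenset(np.flatnonzero(row != 0).tolist())] = j

    def build(group: frozenset[int]) -> BalanceNode:
        if len(group) == 1:
            (i,) = group
            return BalanceNode(name=labels[i], parts=(labels[i],), children=[])
        j = by_active[group]
        row = sbp.matrix[j]
        plus = frozenset(np.flatnonzero(row > 0).tolist())
        minus = frozenset(np.flatnonzero(row < 0).tolist())
        name = sbp.row_names[j]
        stats = (summaries or {}).get(name)
        parts = tuple(labels[i] for i in sorted(group))
        return BalanceNode(name=name, parts=parts,
                           children=[build(plus), build(minus)], stats=stats)

    return build(frozenset(range(sbp.D)))


def random_sbp(part_labels: Sequence[str], rng: np.random.Generator) -> SBP:
    """Draw a uniformly random valid SBP over the given parts (test and
    simulation helper)."""
    labels = tuple(part_labels)
    D = len(labels)
    rows: list[np.ndarray] = []

    def split(group: list[int]) -> None:
        if len(group) < 2:
            return
        while True:
            signs = rng.integers(0, 2, size=len(group))
            if 0 < signs.sum() < len(group):
                break
        row = np.zeros(D, dtype=int)
        plus = [g for g, s in zip(group, signs) if s == 1]
        minus = [g for g, s in zip(group, signs) if s == 0]
        row[plus] = 1
        row[minus] = -1
        rows.append(row)
        split(plus)
        split(minus)

    split(list(range(D)))
    return sbp_validate(np.array(rows), labels)


def transform_table(
    table: CompositionTable,
    representation: str,
    sbp: SBP | None = None,
    denominator: str | None = None,
) -> pd.DataFrame:
    """Express a composition table in one of the supported representations.

    raw — concentrations as stored; log — natural log of concentrations;
    alr — ln(part/denominator), default denominator is the first part;
    clr — ln(part/geometric mean); ilr — balances of ``sbp``.
    """
    if representation not in REPRESENTATIONS:
        raise LabelError(
            f"unknown representation {representation!r}; choose from {REPRESENTATIONS}"
        )
    vals = table.data.to_numpy()
    if representation == "raw":
        return table.data.copy()
    if representation == "log":
        return pd.DataFrame(np.log(vals), index=table.data.index,
                            columns=[f"ln({c})" for c in table.labels])
    if representation == "clr":
        logs = np.log(vals)
        out = logs - logs.mean(axis=1, keepdims=True)
        return pd.DataFrame(out, index=table.data.index,
                            columns=[f"clr({c})" for c in table.labels])
    if representation == "alr":
        denom = denominator or table.labels[0]
        if denom not in table.labels:
            raise LabelError(f"unknown alr denominator {denom!r}")
        d = table.labels.index(denom)
        keep = [i for i in range(table.D) if i != d]
        out = np.log(vals[:, keep] / vals[:, [d]])
        cols = [f"{table.labels[i]}/{denom}" for i in keep]
        return pd.DataFrame(out, index=table.data.index, columns=cols)
    # ilr
    if sbp is None:
        raise LabelError("the ilr representation requires an SBP")
    return ilr(table, sbp).as_frame()
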