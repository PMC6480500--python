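"""Cross-tabulated birth/case counts by maternal and paternal age.

The central data structure is a rectangular table of births ``n_jk`` and
case counts ``Y_jk`` indexed by maternal age ``j`` (default 15..49, J=35)
and paternal age ``k`` (default 15..65, K=51). One-dimensional marginal
tables (counts by a single parent's age) are used by the single-parent
models.

Canonical interchange format is long CSV with columns
``maternal_age, paternal_age, births, cases``; the OpenBUGS rectangular
dialect (``list(...)`` with ``structure(.Data=c(...), .Dim=c(J,K))``
blocks) is supported read-only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AgeCrossTab",
    "MarginalAgeTab",
    "CrossTabError",
    "load_crosstab",
    "write_crosstab",
    "marginalize",
]


class CrossTabError(ValueError):
    """Raised when a count table violates its invariants or cannot be parsed."""


def _check_ages(ages: np.ndarray, name: str) -> np.ndarray:
    ages = np.asarray(ages, dtype=np.int64)
    if ages.ndim != 1 or ages.size < 1:
        raise CrossTabError(f"{name} must be a non-empty 1-D integer vector")
    if ages.size > 1 and not np.all(np.diff(ages) == 1):
        raise CrossTabError(
            f"{name} must be strictly increasing in steps of one year; got {ages.tolist()}"
        )
    return ages


def _check_counts(births, cases, ages_desc: str):
    births = np.asarray(births)
    cases = np.asarray(cases)
    for arr, label in ((births, "births"), (cases, "cases")):
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.asarray(arr) == np.floor(arr)):
                raise CrossTabError(f"{label} must be integers")
        if np.any(arr < 0):
            idx = np.argwhere(arr < 0)[0]
            raise CrossTabError(f"negative {label} at {ages_desc} index {tuple(idx)}")
    births = births.astype(np.int64)
    cases = cases.astype(np.int64)
    bad = cases > births
    if np.any(bad):
        idx = tuple(np.argwhere(bad)[0])
        raise CrossTabError(
            f"cases ({cases[idx]}) exceed births ({births[idx]}) at {ages_desc} index {idx}"
        )
    return births, cases


@dataclass(frozen=True)
class AgeCrossTab:
    """Births and case counts cross-tabulated by maternal x paternal age.

    Parameters
    ----------
    maternal_ages, paternal_ages
        Contiguous integer ages (years), ascending.
    births, cases
        ``(J, K)`` non-negative integer arrays with ``cases <= births``
        cell-wise. Cells with zero births are legal and carry no
        likelihood information.
    outcome_label
        Free-text outcome name, e.g. ``"DS"``.
    """

    maternal_ages: np.ndarray
    paternal_ages: np.ndarray
    births: np.ndarray
    cases: np.ndarray
    outcome_label: str = ""

    def __post_init__(self):
        m = _check_ages(self.maternal_ages, "maternal_ages")
        p = _check_ages(self.paternal_ages, "paternal_ages")
        births = np.asarray(self.births)
        cases = np.asarray(self.cases)
        if births.shape != (m.size, p.size) or cases.shape != births.shape:
            raise CrossTabError(
                f"count arrays must have shape (J={m.size}, K={p.size}); "
                f"got births {births.shape}, cases {cases.shape}"
            )
        births, cases = _check_counts(births, cases, "(maternal, paternal)")
        object.__setattr__(self, "maternal_ages", m)
        object.__setattr__(self, "paternal_ages", p)
        object.__setattr__(self, "births", births)
        object.__setattr__(self, "cases", cases)

    @property
    def shape(self) -> tuple[int, int]:
        return self.births.shape

    @property
    def total_births(self) -> int:
        return int(self.births.sum())

    @property
    def total_cases(self) -> int:
        return int(self.cases.sum())

    def __eq__(self, other) -> bool:
        if not isinstance(other, AgeCrossTab):
            return NotImplemented
        return (
            np.array_equal(self.maternal_ages, other.maternal_ages)
            and np.array_equal(self.paternal_ages, other.paternal_ages)
            and np.array_equal(self.births, other.births)
            and np.array_equal(self.cases, other.cases)
            and self.outcome_label == other.outcome_label
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with one row per (maternal, paternal) cell."""
        jj, kk = np.meshgrid(self.maternal_ages, self.paternal_ages, indexing="ij")
        return pd.DataFrame(
            {
                "maternal_age": jj.ravel(),
                "paternal_age": kk.ravel(),
                "births": self.births.ravel(),
                "cases": self.cases.ravel(),
            }
        )


@dataclass(frozen=True)
class MarginalAgeTab:
    """Births and case counts by a single parent's age."""

    ages: np.ndarray
    births: np.ndarray
    cases: np.ndarray
    parent: str = "maternal"
    outcome_label: str = ""

    def __post_init__(self):
        if self.parent not in ("maternal", "paternal"):
            raise CrossTabError(f"parent must be 'maternal' or 'paternal', got {self.parent!r}")
        ages = _check_ages(self.ages, "ages")
        births = np.asarray(self.births)
        cases = np.asarray(self.cases)
        if births.shape != (ages.size,) or cases.shape != (ages.size,):
            raise CrossTabError(
                f"count arrays must have length {ages.size}; "
                f"got births {births.shape}, cases {cases.shape}"
            )
        births, cases = _check_counts(births, cases, "age")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "births", births)
        object.__setattr__(self, "cases", cases)

    @property
    def total_births(self) -> int:
        return int(self.births.sum())

    @property
    def total_cases(self) -> int:
        return int(self.cases.sum())


def marginalize(tab: AgeCrossTab, parent: str) -> MarginalAgeTab:
    """Collapse a cross-tab onto one parent's age axis.

    Grand totals of births and cases are conserved exactly.
    """
    if parent == "maternal":
        ages, axis = tab.maternal_ages, 1
    elif parent == "paternal":
        ages, axis = tab.paternal_ages, 0
    else:
        raise CrossTabError(f"parent must be 'maternal' or 'paternal', got {parent!r}")
    return MarginalAgeTab(
        ages=ages,
        births=tab.births.sum(axis=axis),
        cases=tab.cases.sum(axis=axis),
        parent=parent,
        outcome_label=tab.outcome_label,
    )


# ---------------------------------------------------------------------------
# I/O

_CSV_COLUMNS = ["maternal_age", "paternal_age", "births", "cases"]


def _load_csv(path, outcome_label: str, allow_sparse: bool) -> AgeCrossTab:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CrossTabError(f"CSV {path} lacks required columns {missing}")
    if df[_CSV_COLUMNS].isna().any().any():
        row = int(df[_CSV_COLUMNS].isna().any(axis=1).idxmax())
        raise CrossTabError(f"CSV {path} has missing values at row {row}")
    m_ages = np.arange(df["maternal_age"].min(), df["maternal_age"].max() + 1)
    p_ages = np.arange(df["paternal_age"].min(), df["paternal_age"].max() + 1)
    births = np.zeros((m_ages.size, p_ages.size), dtype=np.int64)
    cases = np.zeros_like(births)
    seen = np.zeros(births.shape, dtype=bool)
    j = df["maternal_age"].to_numpy(dtype=np.int64) - m_ages[0]
    k = df["paternal_age"].to_numpy(dtype=np.int64) - p_ages[0]
    if np.any(seen[j, k]):
        dup = np.argwhere(np.bincount(j * p_ages.size + k) > 1)
        raise CrossTabError(f"duplicate cell(s) in {path}: flat index {dup[0]}")
    seen[j, k] = True
    b = df["births"].to_numpy()
    y = df["cases"].to_numpy()
    if np.any(b != np.floor(b)) or np.any(y != np.floor(y)):
        raise CrossTabError(f"non-integer counts in {path}")
    births[j, k] = b
    cases[j, k] = y
    if not seen.all() and not allow_sparse:
        jj, kk = np.argwhere(~seen)[0]
        raise CrossTabError(
            f"cell (maternal={m_ages[jj]}, paternal={p_ages[kk]}) absent from {path}; "
            "pass allow_sparse=True to zero-fill missing cells"
        )
    return AgeCrossTab(m_ages, p_ages, births, cases, outcome_label)


_NUM = r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?"


def _parse_bugs_vector(text: str) -> np.ndarray:
    return np.array([float(x) for x in re.findall(_NUM, text)])


def _load_bugs(path, outcome_label: str) -> AgeCrossTab:
    """Read an OpenBUGS rectangular data block.

    Expects ``Y`` and ``n`` given as ``structure(.Data=c(...), .Dim=c(J,K))``;
    ``.Data`` is filled row-major over (j, k), the BUGS convention. Age grids
    are taken as 15..(15+J-1) maternal and 15..(15+K-1) paternal, the layout
    the source tables use.
    """
    text = open(path).read()
    arrays = {}
    for m in re.finditer(
        r"(\w+)\s*=\s*structure\s*\(\s*\.Data\s*=\s*c\(([^)]*)\)\s*,\s*\.Dim\s*=\s*c\(([^)]*)\)\s*\)",
        text,
        flags=re.S,
    ):
        name, data, dim = m.group(1), m.group(2), m.group(3)
        vals = _parse_bugs_vector(data)
        shape = tuple(int(float(d)) for d in re.findall(_NUM, dim))
        if vals.size != int(np.prod(shape)):
            raise CrossTabError(
                f"{path}: {name} has {vals.size} values but .Dim={shape}"
            )
        arrays[name] = vals.reshape(shape)  # row-major
    for want in ("Y", "n"):
        if want not in arrays:
            raise CrossTabError(f"{path}: no structure() block named {want!r}")
    Y, n = arrays["Y"], arrays["n"]
    if Y.shape != n.shape or Y.ndim != 2:
        raise CrossTabError(f"{path}: Y {Y.shape} and n {n.shape} must be equal 2-D shapes")
    J, K = Y.shape
    return AgeCrossTab(
        np.arange(15, 15 + J), np.arange(15, 15 + K), n, Y, outcome_label
    )


def load_crosstab(
    path,
    format: str = "csv",
    outcome_label: str = "",
    allow_sparse: bool = False,
) -> AgeCrossTab:
    """Load and validate an :class:`AgeCrossTab`.

    Parameters
    ----------
    format
        ``"csv"`` (long format, canonical) or ``"bugs_rectangular"``
        (read-only support for the OpenBUGS data dialect).
    allow_sparse
        If True, cells absent from a CSV within the age rectangle are
        zero-filled; the default is to reject such files.
    """
    if format == "csv":
        return _load_csv(path, outcome_label, allow_sparse)
    if format == "bugs_rectangular":
        return _load_bugs(path, outcome_label)
    raise CrossTabError(f"unknown format {format!r}")


def write_crosstab(tab: AgeCrossTab, path, format: str = "csv") -> None:
    """Write a cross-tab; ``load_crosstab(write_crosstab(t)) == t`` exactly."""
    if format != "csv":
        raise CrossTabError(f"only 'csv' is writable, got {format!r}")
    tab.to_frame().to_csv(path, index=False)
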