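"""Agreement evaluation: Dice overlap and the volume-agreement battery.

Validates a segmentation against reference (manually traced) lesion maps
and volume tables: the Dice similarity coefficient

    DSC(Seg, Ref) = 2 |Seg n Ref| / (|Seg| + |Ref|)

for spatial agreement (0 = no overlap, 1 = perfect; >= 0.7 is the
conventional good-agreement bar), plus paired Student's t-tests, Pearson
and Spearman correlation and ordinary least-squares regression on
per-subject lesion volumes in cm^3.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .image_core import BinaryMask, GridMismatchError

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeTable",
    "AgreementReport",
    "dice",
    "paired_t",
    "pearson",
    "spearman",
    "linear_regression",
    "agreement_report",
    "load_table1",
    "load_table2",
]


class DegenerateInputError(ValueError):
    """Raised for constant inputs or zero-variance paired differences."""


def dice(seg: BinaryMask, ref: BinaryMask) -> float:
    """Dice similarity coefficient of two binary masks on one grid.

    When both masks are empty the coefficient is defined as 1.0 (perfect
    agreement on absence) and a warning is logged; one empty mask against
    a non-empty one gives 0.
    """
    if seg.grid_shape != ref.grid_shape:
        raise GridMismatchError(
            f"mask grids differ: {seg.grid_shape} vs {ref.grid_shape}"
        )
    a = seg.data > 0
    b = ref.data > 0
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        logger.warning("both masks empty; defining DSC = 1.0 (agreement on absence)")
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _as_arrays(a: Sequence[float], b: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"inputs must be equal-length 1-D sequences, got {x.shape} vs {y.shape}")
    return x, y


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Paired two-tailed Student's t-test of a - b; returns (t, df, p), df = n - 1."""
    x, y = _as_arrays(a, b)
    if x.size < 2:
        raise DegenerateInputError("paired t-test needs at least 2 pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        raise DegenerateInputError("paired differences have zero variance")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def pearson(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation; returns (r, r^2)."""
    x, y = _as_arrays(a, b)
    if x.size < 3:
        raise DegenerateInputError("correlation needs at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("constant input to correlation")
    r = float(sps.pearsonr(x, y).statistic)
    return r, r * r


def spearman(a: Sequence[float], b: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on mid-ranks, ties averaged)."""
    x, y = _as_arrays(a, b)
    if x.size < 3:
        raise DegenerateInputError("correlation needs at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("constant input to correlation")
    return float(sps.spearmanr(x, y).statistic)


def linear_regression(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float, int, int]:
    """OLS of y on x; returns (slope, intercept, F, df1, df2).

    F = (n - 2) r^2 / (1 - r^2) with df1 = 1, df2 = n - 2; for a perfect
    fit (r^2 == 1) F is infinite.
    """
    xv, yv = _as_arrays(x, y)
    if xv.size < 3:
        raise DegenerateInputError("regression needs at least 3 points")
    if xv.std() == 0:
        raise DegenerateInputError("constant predictor in regression")
    res = sps.linregress(xv, yv)
    r2 = res.rvalue**2
    n = xv.size
    f = np.inf if r2 >= 1.0 else (n - 2) * r2 / (1.0 - r2)
    return float(res.slope), float(res.intercept), float(f), 1, int(n - 2)


@dataclass
class VolumeTable:
    """Per-subject lesion volumes (cm^3) in named columns, positionally paired.

    Subject labels need not be unique; pairing is by row position.
    """

    subject_ids: list[str]
    columns: dict[str, list[float]]

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if n < 2:
            raise ValueError("volume table needs at least 2 subjects")
        for name, col in self.columns.items():
            if len(col) != n:
                raise ValueError(f"column {name!r} has length {len(col)}, expected {n}")
            if any(v < 0 for v in col):
                raise ValueError(f"column {name!r} contains negative volumes")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, subject_col: str = "subject") -> "VolumeTable":
        cols = {c: df[c].astype(float).tolist() for c in df.columns if c != subject_col}
        return cls(df[subject_col].astype(str).tolist(), cols)

    @classmethod
    def from_csv(cls, path, subject_col: str = "subject") -> "VolumeTable":
        return cls.from_dataframe(pd.read_csv(path), subject_col)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"subject": self.subject_ids, **self.columns})


@dataclass
class AgreementReport:
    """Column summaries and pairwise agreement statistics.

    Pairwise entries are keyed ``"<a>_vs_<b>"``; paired t and regression
    use the (a, b) order as (a - b) and (x = a, y = b) respectively.
    """

    n_subjects: int
    column_mean: dict[str, float]
    column_sd: dict[str, float]
    paired_t: dict[str, tuple[float, int, float]]
    pearson: dict[str, tuple[float, float]]
    spearman_rho: dict[str, float]
    regression: dict[str, tuple[float, float, float, int, int]]
    dsc_summary: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "column_mean": self.column_mean,
            "column_sd": self.column_sd,
            "paired_t": {k: {"t": v[0], "df": v[1], "p": v[2]} for k, v in self.paired_t.items()},
            "pearson": {k: {"r": v[0], "r_squared": v[1]} for k, v in self.pearson.items()},
            "spearman_rho": self.spearman_rho,
            "regression": {
                k: {"slope": v[0], "intercept": v[1], "F": v[2], "df1": v[3], "df2": v[4]}
                for k, v in self.regression.items()
            },
            "dsc_summary": {k: {"mean": v[0], "sd": v[1]} for k, v in self.dsc_summary.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_text(self) -> str:
        """Human-readable summary, volumes/DSC to 2 decimals, statistics to 3."""
        lines = [f"Agreement report  (n = {self.n_subjects} subjects)", ""]
        lines.append("Volumes (cm^3):")
        for name in self.column_mean:
            lines.append(
                f"  {name:<18} mean {self.column_mean[name]:6.2f}  SD {self.column_sd[name]:6.2f}"
            )
        if self.paired_t:
            lines.append("\nPaired t-tests (a - b):")
            for k, (t, df, p) in self.paired_t.items():
                lines.append(f"  {k:<32} t = {t:7.3f}  df = {df}  p = {p:.3f}")
        if self.pearson:
            lines.append("\nCorrelations:")
            for k, (r, r2) in self.pearson.items():
                rho = self.spearman_rho.get(k, float("nan"))
                lines.append(
                    f"  {k:<32} r = {r:.3f}  r^2 = {r2:.3f}  rho = {rho:.3f}"
                )
        if self.regression:
            lines.append("\nLinear regression (y on x):")
            for k, (slope, intercept, f, df1, df2) in self.regression.items():
                lines.append(
                    f"  {k:<32} slope = {slope:.3f}  intercept = {intercept:.3f}"
                    f"  F({df1},{df2}) = {f:.3f}"
                )
        if self.dsc_summary:
            lines.append("\nDice similarity coefficients:")
            for k, (m, s) in self.dsc_summary.items():
                lines.append(f"  {k:<32} mean {m:.2f}  SD {s:.2f}")
        return "\n".join(lines) + "\n"


def agreement_report(
    table: VolumeTable,
    dsc_values: dict[str, Sequence[float]] | None = None,
    comparisons: Sequence[tuple[str, str]] | None = None,
) -> AgreementReport:
    """Build the full agreement battery over column pairs of a volume table.

    ``comparisons`` defaults to every unordered pair of columns in table
    order. ``dsc_values`` holds per-subject Dice coefficients aligned to
    the table rows, keyed like the report entries.
    """
    names = list(table.columns)
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    col_mean = {c: float(np.mean(table.columns[c])) for c in names}
    col_sd = {c: float(np.std(table.columns[c], ddof=1)) for c in names}
    t_res, r_res, rho_res, reg_res = {}, {}, {}, {}
    for a, b in comparisons:
        key = f"{a}_vs_{b}"
        xa, xb = table.columns[a], table.columns[b]
        t_res[key] = paired_t(xa, xb)
        r_res[key] = pearson(xa, xb)
        rho_res[key] = spearman(xa, xb)
        reg_res[key] = linear_regression(xa, xb)
    dsc_summary = {}
    if dsc_values:
        for key, vals in dsc_values.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size != table.n_subjects:
                raise ValueError(
                    f"DSC list {key!r} has {arr.size} entries for {table.n_subjects} subjects"
                )
            dsc_summary[key] = (float(arr.mean()), float(arr.std(ddof=1)))
    return AgreementReport(
        n_subjects=table.n_subjects,
        column_mean=col_mean,
        column_sd=col_sd,
        paired_t=t_res,
        pearson=r_res,
        spearman_rho=rho_res,
        regression=reg_res,
        dsc_summary=dsc_summary,
    )


def _load_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("wmhseg.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_table1() -> VolumeTable:
    """The shipped 30-subject volume table (two manual raters + semi-automated)."""
    return VolumeTable.from_dataframe(_load_packaged_csv("table1.csv"))


def load_table2() -> pd.DataFrame:
    """The shipped 30-subject per-pair Dice coefficient table."""
    return _load_packaged_csv("table2.csv")
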