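"""Peak-area tables: container, CSV IO, total-sum normalization and assay QC.

A targeted LC-MS run exports one peak area per (sample, metabolite). The
analyses downstream all operate on *relative* intracellular levels, so the
only preprocessing applied here is total-sum normalization: each sample's
areas are divided by that sample's summed area over the quantified cellular
analytes. A spiked instrument-control analyte (run-to-run QC standard) is
excluded from the denominator and dropped from the normalized matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "QCReport",
    "read_peak_table",
    "write_peak_table",
    "total_sum_normalize",
    "qc_instrument_control",
    "teer_filter",
]

#: Row-sum tolerance for a normalized table.
_NORM_TOL = 1e-9


@dataclass(frozen=True)
class PeakTable:
    """Samples x metabolites matrix of peak areas with group annotations.

    Parameters
    ----------
    areas
        DataFrame indexed by sample id with one column per metabolite.
        Values are non-negative peak areas (NaN marks a missing cell).
    groups
        Per-sample label aligned with ``areas.index`` (e.g. ``treated`` /
        ``control`` or ``KO`` / ``WT``).
    normalized
        True once :func:`total_sum_normalize` has been applied; rows of a
        normalized table sum to 1 over non-missing cells.
    """

    areas: pd.DataFrame
    groups: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        areas, groups = self.areas, self.groups
        if areas.index.has_duplicates:
            raise ValueError("duplicate sample ids in peak table")
        if areas.columns.has_duplicates:
            raise ValueError("duplicate metabolite ids in peak table")
        if not areas.index.equals(groups.index):
            raise ValueError("groups index does not match sample ids")
        vals = areas.to_numpy(dtype=float)
        neg = np.argwhere(vals < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative peak area at sample {areas.index[i]!r}, "
                f"metabolite {areas.columns[j]!r}"
            )
        if self.normalized:
            sums = np.nansum(vals, axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise ValueError("normalized flag set but rows do not sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def n_samples(self) -> int:
        return self.areas.shape[0]

    def subset_samples(self, keep: Sequence[str]) -> "PeakTable":
        """Return a table restricted to ``keep`` (order preserved)."""
        keep = [s for s in self.sample_ids if s in set(keep)]
        return replace(self, areas=self.areas.loc[keep], groups=self.groups.loc[keep])

    def binary_labels(self, positive: str = "treated") -> np.ndarray:
        """0/1 vector with 1 for samples whose group equals ``positive``."""
        return (self.groups == positive).to_numpy(dtype=int)


@dataclass(frozen=True)
class QCReport:
    """Instrument-control QC summary for one peak table."""

    control_analyte: str
    control_cv: float
    cv_limit: float
    passed: bool
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "control_analyte": self.control_analyte,
                "control_cv": self.control_cv,
                "cv_limit": self.cv_limit,
                "pass": self.passed,
                "excluded_samples": [
                    {"sample": s, "reason": r} for s, r in self.excluded_samples
                ],
            },
            indent=2,
        )


def read_peak_table(path: str | Path, dialect: str = "wide_csv") -> PeakTable:
    """Read a peak-area table from CSV.

    ``wide_csv``: first column sample id, second column group, remaining
    columns one metabolite each. ``long_csv``: columns sample, group,
    metabolite, area; pivoted to wide. Missing cells stay missing (NaN),
    never silently zero.
    """
    path = Path(path)
    if dialect == "wide_csv":
        df = pd.read_csv(path)
        if df.shape[1] < 3:
            raise ValueError(f"{path}: wide peak table needs sample, group and >=1 metabolite column")
        sample_col, group_col = df.columns[0], df.columns[1]
        if df[sample_col].duplicated().any():
            dup = df[sample_col][df[sample_col].duplicated()].iloc[0]
            raise ValueError(f"{path}: duplicate sample id {dup!r}")
        areas = df.set_index(sample_col).drop(columns=[group_col]).astype(float)
        groups = df.set_index(sample_col)[group_col].astype(str)
    elif dialect == "long_csv":
        df = pd.read_csv(path)
        required = {"sample", "group", "metabolite", "area"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: long peak table needs columns {sorted(required)}")
        if df.duplicated(subset=["sample", "metabolite"]).any():
            row = df[df.duplicated(subset=["sample", "metabolite"])].iloc[0]
            raise ValueError(
                f"{path}: duplicate (sample, metabolite) pair "
                f"({row['sample']!r}, {row['metabolite']!r})"
            )
        areas = df.pivot(index="sample", columns="metabolite", values="area").astype(float)
        areas.columns.name = None
        areas.index.name = None
        groups = df.drop_duplicates("sample").set_index("sample")["group"].astype(str)
        groups = groups.loc[areas.index]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    areas.index = areas.index.astype(str)
    groups.index = groups.index.astype(str)
    areas.index.name = None
    areas.columns.name = None
    groups.index.name = None
    vals = areas.to_numpy(dtype=float)
    neg = np.argwhere(vals < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"{path}: negative area for sample {areas.index[i]!r}, "
            f"metabolite {areas.columns[j]!r}"
        )
    return PeakTable(areas=areas, groups=groups)


def write_peak_table(table: PeakTable, path: str | Path, dialect: str = "wide_csv") -> None:
    """Write a peak table as CSV in either dialect (round-trips with read)."""
    path = Path(path)
    if dialect == "wide_csv":
        out = table.areas.copy()
        out.insert(0, "group", table.groups)
        out.index.name = "sample"
        out.to_csv(path)
    elif dialect == "long_csv":
        long = table.areas.stack(future_stack=True).rename("area").reset_index()
        long.columns = ["sample", "metabolite", "area"]
        long.insert(1, "group", table.groups.loc[long["sample"]].to_numpy())
        long.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def total_sum_normalize(table: PeakTable, control_analyte: str | None = None) -> PeakTable:
    """Divide each sample's areas by its total over quantified cellular analytes.

    The spiked instrument-control analyte, if named, is excluded from the
    denominator and dropped from the output: it tracks the instrument, not
    the cell, and would otherwise dilute every biological proportion.
    Missing cells are excluded from the denominator and propagated.
    Normalizing twice is an error, not a silent no-op.
    """
    if table.normalized:
        raise ValueError("table is already normalized")
    areas = table.areas
    if control_analyte is not None:
        if control_analyte not in areas.columns:
            raise KeyError(f"control analyte {control_analyte!r} not in table")
        areas = areas.drop(columns=[control_analyte])
    totals = areas.sum(axis=1, skipna=True)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total area")
    return replace(table, areas=areas.div(totals, axis=0), normalized=True)


def qc_instrument_control(
    table: PeakTable, control_analyte: str, cv_limit: float = 0.2
) -> QCReport:
    """Coefficient of variation of the spiked control analyte across samples.

    Computed on raw (pre-normalization) areas with the sample (n-1) standard
    deviation. The run passes when CV <= ``cv_limit``.
    """
    if table.normalized:
        raise ValueError("instrument QC must run on raw areas, before normalization")
    if control_analyte not in table.areas.columns:
        raise KeyError(f"control analyte {control_analyte!r} not in table")
    x = table.areas[control_analyte].to_numpy(dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("need >=2 control analyte measurements for a CV")
    cv = float(np.std(x, ddof=1) / np.mean(x))
    return QCReport(
        control_analyte=control_analyte,
        control_cv=cv,
        cv_limit=cv_limit,
        passed=cv <= cv_limit,
    )


def teer_filter(teer_values: Sequence[float], threshold: float = 1000.0) -> np.ndarray:
    """Monolayer-integrity mask: True where TEER (ohm*cm^2) strictly exceeds threshold.

    Intact Caco-2 monolayers sit well above 1000 ohm*cm^2; a well at or
    below the threshold is excluded from transport analysis.
    """
    values = np.asarray(list(teer_values), dtype=float)
    if values.size and values.min() < 0:
        raise ValueError("TEER values must be non-negative")
    return values > threshold
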