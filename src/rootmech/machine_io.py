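"""Reading tester traces, unit conversion, and tabular reports.

A universal tester exports one (displacement, force) trace per specimen as
delimited text.  Conversion to engineering stress-strain uses the nominal
(initial) root diameter and the gauge length:

    sigma_i = 4 * F_i / (pi * d^2)   [N, mm -> MPa]
    eps_i   = dl_i / L0              [mm / mm, dimensionless]

Writers produce the fit-results table (one row per specimen) and sample
accounting summaries (per-class effective percentages plus two aggregate
conventions: the ratio of summed counts, and the mean of per-class
percentages).  Percentages are rounded half-up to 2 decimal places.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .estimation import FitResult, StressStrainCurve

__all__ = [
    "TraceFormatError",
    "RawTensileTrace",
    "SpecimenMeta",
    "SampleSummaryRow",
    "SampleSummary",
    "round_half_up",
    "read_trace_csv",
    "write_trace_csv",
    "trace_to_curve",
    "curve_to_trace",
    "write_fit_table",
    "summarize_samples",
    "write_summary_csv",
]

FIT_TABLE_COLUMNS = [
    "specimen_id", "species", "diameter_mm", "E0_MPa", "Ep_MPa",
    "E", "x_e", "mean_abs_residual", "residual_variance", "valid",
]


class TraceFormatError(ValueError):
    """Malformed or physically inconsistent trace file."""


@dataclass(frozen=True)
class SpecimenMeta:
    """Identity and geometry of one root specimen.

    ``diameter`` is the nominal diameter in mm (mean of three measurement
    points along the piece, if triplets are supplied upstream);
    ``gauge_length`` the free length between grips in mm (50 by default,
    the standardised spacing).
    """

    species: str
    diameter: float
    gauge_length: float = 50.0

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError(f"diameter must be > 0 mm (got {self.diameter})")
        if not self.gauge_length > 0:
            raise ValueError(
                f"gauge length must be > 0 mm (got {self.gauge_length})"
            )


@dataclass
class RawTensileTrace:
    """Machine-native (displacement mm, force N) series for one pull."""

    displacement: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if len(self.displacement) != len(self.force):
            raise TraceFormatError("displacement and force lengths differ")
        if len(self.displacement) < 3:
            raise TraceFormatError("trace needs at least 3 samples")
        if self.displacement[0] < 0:
            raise TraceFormatError("displacement must start at >= 0 mm")
        d = np.diff(self.displacement)
        if np.any(d <= 0):
            row = int(np.argmax(d <= 0)) + 2  # 1-based data row of offender
            raise TraceFormatError(
                f"displacement not strictly increasing at data row {row}"
            )
        if np.any(self.force < 0):
            raise TraceFormatError("forces must be non-negative")

    def __len__(self) -> int:
        return len(self.displacement)


@dataclass(frozen=True)
class SampleSummaryRow:
    """Sample counts for one (species, diameter-class) cell."""

    species: str
    diameter_scope: str
    total: int
    effective: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError(f"total count must be positive (got {self.total})")
        if not 0 <= self.effective <= self.total:
            raise ValueError(
                f"effective count {self.effective} outside [0, {self.total}]"
            )


@dataclass
class SampleSummary:
    """Per-class percentages plus both aggregate conventions."""

    rows: pd.DataFrame
    grand_total: int
    grand_effective: int
    overall_pct: float  # 100 * sum(effective) / sum(total)
    mean_row_pct: float  # mean of per-class percentages


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), as used in printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def read_trace_csv(
    path: Union[str, Path],
    *,
    delimiter: str = ",",
    displacement_col: str = "displacement_mm",
    force_col: str = "force_N",
) -> RawTensileTrace:
    """Read one tester trace from delimited text with a header row.

    Rows with non-numeric fields are rejected with 1-based row numbers in
    the message; missing columns, empty files and non-monotone
    displacement raise :class:`TraceFormatError`.
    """
    path = Path(path)
    try:
        # round_trip parser: the default fast parser loses the last digit
        df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise TraceFormatError(f"{path}: file is empty") from None
    for col in (displacement_col, force_col):
        if col not in df.columns:
            raise TraceFormatError(
                f"{path}: missing column {col!r} (found {list(df.columns)})"
            )
    disp = pd.to_numeric(df[displacement_col], errors="coerce")
    force = pd.to_numeric(df[force_col], errors="coerce")
    bad = df.index[disp.isna() | force.isna()]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        raise TraceFormatError(f"{path}: non-numeric values at row(s) {rows}")
    try:
        return RawTensileTrace(disp.to_numpy(), force.to_numpy())
    except TraceFormatError as exc:
        raise TraceFormatError(f"{path}: {exc}") from None


def write_trace_csv(
    trace: RawTensileTrace,
    path: Union[str, Path],
    *,
    delimiter: str = ",",
    displacement_col: str = "displacement_mm",
    force_col: str = "force_N",
) -> None:
    """Write a trace in the dialect :func:`read_trace_csv` accepts.

    Full float precision is kept so a write/read round trip is exact.
    """
    df = pd.DataFrame(
        {displacement_col: trace.displacement, force_col: trace.force}
    )
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def trace_to_curve(trace: RawTensileTrace, meta: SpecimenMeta) -> StressStrainCurve:
    """Convert a machine trace to engineering stress-strain.

    Stress from the nominal initial diameter (no instantaneous-area
    correction), strain as elongation over the gauge length.
    """
    area = math.pi * meta.diameter**2 / 4.0  # mm^2
    stress = trace.force / area  # N/mm^2 == MPa
    strain = trace.displacement / meta.gauge_length
    return StressStrainCurve(strain=strain, stress=stress, meta=meta)


def curve_to_trace(curve: StressStrainCurve, meta: SpecimenMeta) -> RawTensileTrace:
    """Analytic inverse of :func:`trace_to_curve` (exact round trip)."""
    area = math.pi * meta.diameter**2 / 4.0
    return RawTensileTrace(
        displacement=curve.strain * meta.gauge_length,
        force=curve.stress * area,
    )


def _fmt(value: float, ndigits: int) -> str:
    if value != value:  # NaN
        return "NA"
    return f"{value:.{ndigits}f}"


def write_fit_table(
    results: Sequence[tuple[str, SpecimenMeta, FitResult]],
    path: Union[str, Path],
    *,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Write the per-specimen results table; returns the frame written.

    Columns (stable order): specimen_id, species, diameter_mm, E0_MPa,
    Ep_MPa, E, x_e, mean_abs_residual, residual_variance, valid.  Moduli
    are printed with 2 decimals, E and x_e with 5, residual statistics
    with 6; invalid fits carry NA in the model-dependent columns and
    valid=False.
    """
    if len(results) == 0:
        raise ValueError("no results to write")
    records = []
    for specimen_id, meta, fit in results:
        records.append({
            "specimen_id": specimen_id,
            "species": meta.species,
            "diameter_mm": _fmt(meta.diameter, 2),
            "E0_MPa": _fmt(fit.E0, 2),
            "Ep_MPa": _fmt(fit.Ep, 2),
            "E": _fmt(fit.E, 5),
            "x_e": _fmt(fit.x_e, 5),
            "mean_abs_residual": _fmt(fit.mean_abs_residual, 6),
            "residual_variance": _fmt(fit.residual_variance, 6),
            "valid": fit.valid,
        })
    df = pd.DataFrame.from_records(records, columns=FIT_TABLE_COLUMNS)
    df.to_csv(path, sep=delimiter, index=False)
    return df


def summarize_samples(rows: Sequence[SampleSummaryRow]) -> SampleSummary:
    """Effective-sample accounting across (species, diameter-class) cells.

    Reports per-class percentages (2 dp, half-up) and both aggregates:
    ``overall_pct`` is the ratio of summed counts — the convention for a
    pooled dataset — while ``mean_row_pct`` averages the per-class
    percentages, the convention used for per-gauge columns.  The two
    differ whenever class sizes are unequal.
    """
    if len(rows) == 0:
        raise ValueError("no summary rows")
    raw_pct = [100.0 * r.effective / r.total for r in rows]
    df = pd.DataFrame({
        "species": [r.species for r in rows],
        "diameter_scope": [r.diameter_scope for r in rows],
        "total": [r.total for r in rows],
        "effective": [r.effective for r in rows],
        "effective_pct": [round_half_up(p) for p in raw_pct],
    })
    grand_total = int(df["total"].sum())
    grand_effective = int(df["effective"].sum())
    return SampleSummary(
        rows=df,
        grand_total=grand_total,
        grand_effective=grand_effective,
        overall_pct=round_half_up(100.0 * grand_effective / grand_total),
        mean_row_pct=round_half_up(sum(raw_pct) / len(raw_pct)),
    )


def write_summary_csv(
    summary: SampleSummary, path: Union[str, Path], *, delimiter: str = ","
) -> None:
    """Write per-class rows followed by a total row with both aggregates."""
    df = summary.rows.copy()
    total_row = pd.DataFrame([{
        "species": "Total",
        "diameter_scope": "",
        "total": summary.grand_total,
        "effective": summary.grand_effective,
        "effective_pct": summary.overall_pct,
        "mean_row_pct": summary.mean_row_pct,
    }])
    out = pd.concat([df, total_row], ignore_index=True)
    out.to_csv(path, sep=delimiter, index=False, float_format="%.2f")
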