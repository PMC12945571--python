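"""Measurement-table CSV I/O and report rendering.

The input format is a comma-delimited, header-mandatory CSV (period
decimal separator — the dialect is fixed to avoid locale ambiguity) with
columns

    irp_id, plasma_id, pt_mean_s, sd_log_pt, n,
    mnpt_s, sd_log_mnpt, m, isi, sd_isi

and optionally a ``replicates`` column of semicolon-joined raw PT seconds;
when a row's ``replicates`` cell is non-empty it replaces pt_mean_s /
sd_log_pt / n, which are then derived (geometric mean, SD of ln with n-1).
(irp_id, plasma_id) pairs must be unique.

The rendered report mirrors the calibration-report layout: mean INR to 2
decimals, SD_logINR to 3, the 95% CI as "lower-upper" with 2 decimals and
%ru to 1 decimal.  Rounding happens only at rendering; every computation
upstream is unrounded.
"""

from __future__ import annotations

import csv
import io as _io
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import (
    INRUncertaintyResult,
    PlasmaMeasurement,
    ThromboplastinCalibration,
    evaluate_plasma,
)

__all__ = [
    "ParseError",
    "MeasurementTable",
    "read_measurement_csv",
    "write_measurement_csv",
    "compute_results",
    "render_report_csv",
    "render_report_text",
]

REQUIRED_COLUMNS = (
    "irp_id",
    "plasma_id",
    "pt_mean_s",
    "sd_log_pt",
    "n",
    "mnpt_s",
    "sd_log_mnpt",
    "m",
    "isi",
    "sd_isi",
)


class ParseError(ValueError):
    """Input-table validation failure, naming the offending row/column."""


@dataclass(frozen=True)
class MeasurementTable:
    """Validated, ordered (plasma, calibration) rows."""

    rows: tuple[tuple[PlasmaMeasurement, ThromboplastinCalibration], ...]

    def __len__(self) -> int:
        return len(self.rows)

    def irp_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, calib in self.rows:
            if calib.irp_id not in seen:
                seen.append(calib.irp_id)
        return tuple(seen)

    def for_irp(self, irp_id: str) -> "MeasurementTable":
        sel = tuple(r for r in self.rows if r[1].irp_id == irp_id)
        if not sel:
            raise KeyError(f"no rows for IRP {irp_id!r}; have {self.irp_ids()}")
        return MeasurementTable(sel)


def _cell(df: pd.DataFrame, i: int, col: str, kind: str):
    raw = df.at[i, col] if col in df.columns else None
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
        raise ParseError(f"row {i + 1}: missing value in column {col!r}")
    s = str(raw).strip()
    if kind == "str":
        return s
    try:
        if kind == "int":
            f = float(s)
            if int(f) != f:
                raise ValueError
            return int(f)
        return float(s)
    except ValueError:
        raise ParseError(f"row {i + 1}: column {col!r} is not a valid {kind}: {s!r}") from None


def read_measurement_csv(path) -> MeasurementTable:
    """Read and validate a measurement table; errors name row and column."""
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file or no header") from None
    has_replicates = "replicates" in df.columns
    for col in REQUIRED_COLUMNS:
        if col in ("pt_mean_s", "sd_log_pt", "n") and has_replicates:
            continue
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows")

    rows = []
    seen_keys: set[tuple[str, str]] = set()
    for i in range(len(df)):
        irp_id = _cell(df, i, "irp_id", "str")
        plasma_id = _cell(df, i, "plasma_id", "str")
        key = (irp_id, plasma_id)
        if key in seen_keys:
            raise ParseError(f"row {i + 1}: duplicate (irp_id, plasma_id) pair {key}")
        seen_keys.add(key)

        rep_raw = None
        if has_replicates:
            v = df.at[i, "replicates"]
            if v is not None and not (isinstance(v, float) and math.isnan(v)) and str(v).strip():
                rep_raw = str(v).strip()
        try:
            if rep_raw is not None:
                try:
                    reps = [float(x) for x in rep_raw.split(";") if x.strip()]
                except ValueError:
                    raise ParseError(
                        f"row {i + 1}: column 'replicates' is not a "
                        f"semicolon-joined list of numbers: {rep_raw!r}"
                    ) from None
                plasma = PlasmaMeasurement.from_replicates(plasma_id, reps)
            else:
                plasma = PlasmaMeasurement(
                    plasma_id=plasma_id,
                    pt_mean_seconds=_cell(df, i, "pt_mean_s", "float"),
                    sd_log_pt=_cell(df, i, "sd_log_pt", "float"),
                    n=_cell(df, i, "n", "int"),
                )
            calib = ThromboplastinCalibration(
                irp_id=irp_id,
                isi=_cell(df, i, "isi", "float"),
                sd_isi=_cell(df, i, "sd_isi", "float"),
                mnpt_seconds=_cell(df, i, "mnpt_s", "float"),
                sd_log_mnpt=_cell(df, i, "sd_log_mnpt", "float"),
                m=_cell(df, i, "m", "int"),
            )
        except ParseError:
            raise
        except ValueError as exc:
            raise ParseError(f"row {i + 1}: {exc}") from None
        rows.append((plasma, calib))
    return MeasurementTable(tuple(rows))


def write_measurement_csv(table: MeasurementTable, path) -> None:
    """Write a table back out; read_measurement_csv(write(...)) is identity."""
    any_reps = any(p.replicates_seconds is not None for p, _ in table.rows)
    cols = list(REQUIRED_COLUMNS) + (["replicates"] if any_reps else [])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for plasma, calib in table.rows:
            if plasma.replicates_seconds is not None:
                row = [calib.irp_id, plasma.plasma_id, "", "", "",
                       repr(calib.mnpt_seconds), repr(calib.sd_log_mnpt), calib.m,
                       repr(calib.isi), repr(calib.sd_isi),
                       ";".join(repr(r) for r in plasma.replicates_seconds)]
            else:
                row = [calib.irp_id, plasma.plasma_id,
                       repr(plasma.pt_mean_seconds), repr(plasma.sd_log_pt), plasma.n,
                       repr(calib.mnpt_seconds), repr(calib.sd_log_mnpt), calib.m,
                       repr(calib.isi), repr(calib.sd_isi)]
                if any_reps:
                    row.append("")
            w.writerow(row)


def compute_results(
    table: MeasurementTable, k: float = 2.0, ru_mode: str = "approximate"
) -> list[INRUncertaintyResult]:
    """Run the per-plasma uncertainty pipeline over every row."""
    return [evaluate_plasma(p, c, k=k, ru_mode=ru_mode) for p, c in table.rows]


def _format_result(r: INRUncertaintyResult) -> tuple[str, str, str, str, str, str]:
    return (
        r.irp_id,
        r.plasma_id,
        f"{r.mean_inr:.2f}",
        f"{r.sd_log_inr:.3f}",
        f"{r.ci_lower:.2f}-{r.ci_upper:.2f}",
        f"{r.ru_percent:.1f}",
    )


_HEADER = ("irp_id", "plasma_id", "mean_inr", "sd_log_inr", "ci_95", "ru_percent")


def render_report_csv(results: Sequence[INRUncertaintyResult]) -> str:
    buf = _io.StringIO()
    w = csv.writer(buf)
    w.writerow(_HEADER)
    for r in results:
        w.writerow(_format_result(r))
    return buf.getvalue()


def render_report_text(results: Sequence[INRUncertaintyResult]) -> str:
    """Aligned plain-text report."""
    rows = [_HEADER] + [_format_result(r) for r in results]
    widths = [max(len(row[c]) for row in rows) for c in range(len(_HEADER))]
    lines = []
    for i, row in enumerate(rows):
        lines.append("  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip())
        if i == 0:
            lines.append("  ".join("-" * w for w in widths))
    return "\n".join(lines) + "\n"
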