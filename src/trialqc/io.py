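"""Reading, validating and writing trial-level score tables.

The canonical interchange format is a long CSV with one row per trial:

    participant,condition,trial,value
    P1,A,1,0.5

A wide layout (one row per participant x condition, trial columns
left-to-right) is accepted as a convenience; blank wide cells mean the trial
is absent, never zero (zero is a legal amplitude).  Values are single-trial
scores in whatever unit the upstream pipeline produced (microvolts for ERP
time-window mean amplitudes, power units for spectral measures) and are
assumed already baseline-corrected.
"""

from __future__ import annotations

import csv
import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ParseError

__all__ = [
    "TrialTable",
    "ValidationIssue",
    "ValidationReport",
    "read_trial_table",
    "write_trial_table",
    "validate_trial_table",
    "write_results",
    "RESULTS_HEADER",
]

_LONG_COLUMNS = ("participant", "condition", "trial", "value")


@dataclass(frozen=True)
class TrialTable:
    """Ragged store of single-trial scores keyed by (participant, condition, trial).

    Backed by a pandas DataFrame with columns ``participant``, ``condition``,
    ``trial`` (positive integer, ordinal within participant x condition) and
    ``value`` (finite float).  Trial counts may differ across participants and
    conditions.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _LONG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"trial table missing columns: {missing}")
        df = df[list(_LONG_COLUMNS)].copy()
        df["participant"] = df["participant"].astype(str)
        df["condition"] = df["condition"].astype(str)
        df["trial"] = df["trial"].astype(np.int64)
        df["value"] = df["value"].astype(np.float64)
        if (df["trial"] < 1).any():
            raise IntegrityError("trial indices must be positive integers")
        if df.duplicated(["participant", "condition", "trial"]).any():
            dup = df[df.duplicated(["participant", "condition", "trial"], keep=False)]
            key = tuple(dup.iloc[0][["participant", "condition", "trial"]])
            raise IntegrityError(f"duplicate (participant, condition, trial): {key}")
        if not np.isfinite(df["value"]).all():
            bad = df.loc[~np.isfinite(df["value"])].iloc[0]
            raise IntegrityError(
                f"non-finite value for ({bad['participant']}, {bad['condition']}, "
                f"trial {bad['trial']})"
            )
        df = df.sort_values(["participant", "condition", "trial"], kind="mergesort")
        df = df.reset_index(drop=True)
        object.__setattr__(self, "frame", df)

    # -- accessors ---------------------------------------------------------

    def participants(self, condition: str | None = None) -> list[str]:
        df = self.frame
        if condition is not None:
            df = df[df["condition"] == condition]
        return sorted(df["participant"].unique())

    def conditions(self) -> list[str]:
        return sorted(self.frame["condition"].unique())

    def trials(self, participant: str, condition: str) -> np.ndarray:
        """Trial values for one cell, in ascending trial-index order."""
        df = self.frame
        sel = df[(df["participant"] == participant) & (df["condition"] == condition)]
        return sel["value"].to_numpy()

    def trial_indices(self, participant: str, condition: str) -> np.ndarray:
        df = self.frame
        sel = df[(df["participant"] == participant) & (df["condition"] == condition)]
        return sel["trial"].to_numpy()

    def cells(self, condition: str) -> dict[str, np.ndarray]:
        """All participants' trial-value arrays for one condition."""
        df = self.frame[self.frame["condition"] == condition]
        return {
            str(pid): g["value"].to_numpy()
            for pid, g in df.groupby("participant", sort=True)
        }

    def cell_counts(self) -> pd.DataFrame:
        """Trial count per (participant, condition) cell."""
        return (
            self.frame.groupby(["participant", "condition"], sort=True)
            .size()
            .rename("n_trials")
            .reset_index()
        )

    def n_records(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        return self.frame.equals(other.frame)


@dataclass(frozen=True)
class ValidationIssue:
    severity: Literal["error", "warning"]
    code: str
    message: str
    locus: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def ok(self) -> bool:
        return not self.issues


def read_trial_table(
    path: str | Path,
    layout: Literal["long", "wide"] = "long",
    delimiter: str = ",",
    columns: Mapping[str, str] | None = None,
) -> TrialTable:
    """Read a trial-level score table from a delimited text file.

    Parameters
    ----------
    path
        CSV file.  Long layout needs columns (participant, condition, trial,
        value); wide layout needs (participant, condition) followed by trial
        columns read left-to-right as trial indices 1..k, blank cells meaning
        the trial is absent.
    layout
        ``"long"`` (canonical) or ``"wide"``.
    delimiter
        Field delimiter, comma by default.
    columns
        Optional map from the canonical column names to the names used in the
        file, e.g. ``{"participant": "subject_id"}``.
    """
    path = Path(path)
    colmap = {c: c for c in ("participant", "condition", "trial", "value")}
    if columns:
        colmap.update(columns)
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed csv
        raise FormatError(f"could not read {path}: {exc}") from exc
    raw.columns = [str(c).strip() for c in raw.columns]

    if layout == "long":
        needed = [colmap[c] for c in _LONG_COLUMNS]
        missing = [c for c in needed if c not in raw.columns]
        if missing:
            raise FormatError(f"missing required column(s) {missing} in {path.name}")
        df = raw[needed].copy()
        df.columns = list(_LONG_COLUMNS)
        df["value"] = _parse_numeric(df["value"], colmap["value"])
        df["trial"] = _parse_numeric(df["trial"], colmap["trial"]).astype(np.int64)
        return TrialTable(df)

    if layout == "wide":
        id_cols = [colmap["participant"], colmap["condition"]]
        missing = [c for c in id_cols if c not in raw.columns]
        if missing:
            raise FormatError(f"missing required column(s) {missing} in {path.name}")
        trial_cols = [c for c in raw.columns if c not in id_cols]
        if not trial_cols:
            raise FormatError(f"wide layout needs at least one trial column in {path.name}")
        records: list[tuple[str, str, int, float]] = []
        for row_no, row in raw.iterrows():
            for j, col in enumerate(trial_cols, start=1):
                cell = row[col]
                if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                    continue
                cell = str(cell).strip()
                if cell == "":
                    continue
                try:
                    val = float(cell)
                except ValueError:
                    raise ParseError(
                        f"non-numeric value {cell!r} in column {col!r}, data row "
                        f"{row_no + 1}",
                        row=int(row_no) + 1,
                    ) from None
                records.append(
                    (str(row[id_cols[0]]), str(row[id_cols[1]]), j, val)
                )
        df = pd.DataFrame(records, columns=list(_LONG_COLUMNS))
        return TrialTable(df)

    raise ValueError(f"unknown layout {layout!r}")


def _parse_numeric(series: pd.Series, name: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(bad.idxmax()) + 1  # 1-based data row
        raise ParseError(
            f"non-numeric value {series[bad.idxmax()]!r} in column {name!r}, "
            f"data row {row}",
            row=row,
        )
    if out.isna().any():
        row = int(out.isna().idxmax()) + 1
        raise ParseError(f"empty value in column {name!r}, data row {row}", row=row)
    return out


def write_trial_table(table: TrialTable, path: str | Path) -> None:
    """Write a TrialTable as the canonical long CSV (round-trips exactly)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_LONG_COLUMNS)
        for rec in table.frame.itertuples(index=False):
            w.writerow([rec.participant, rec.condition, rec.trial, _fmt(rec.value)])


def validate_trial_table(
    table: TrialTable, min_subsample: int | None = None
) -> ValidationReport:
    """Check TrialTable invariants and announce downstream exclusions.

    Invariant violations are reported as ``error`` issues (they normally
    cannot occur through the constructor, but tables built programmatically
    from a raw frame are re-checked here).  Participants whose trial count in
    a condition falls below ``min_subsample`` — the smallest requested
    subsample size — get a ``warning`` so exclusions are announced up front.
    """
    report = ValidationReport()
    df = table.frame
    dup = df.duplicated(["participant", "condition", "trial"], keep=False)
    for _, row in df[dup].iterrows():
        report.issues.append(
            ValidationIssue(
                "error",
                "duplicate-trial",
                "duplicate (participant, condition, trial) record",
                f"{row['participant']}/{row['condition']}/trial {row['trial']}",
            )
        )
    nonfinite = ~np.isfinite(df["value"].to_numpy())
    for _, row in df[nonfinite].iterrows():
        report.issues.append(
            ValidationIssue(
                "error",
                "non-finite-value",
                f"non-finite value {row['value']!r}",
                f"{row['participant']}/{row['condition']}/trial {row['trial']}",
            )
        )
    if (df["trial"] < 1).any():
        for _, row in df[df["trial"] < 1].iterrows():
            report.issues.append(
                ValidationIssue(
                    "error",
                    "bad-trial-index",
                    "trial index must be a positive integer",
                    f"{row['participant']}/{row['condition']}/trial {row['trial']}",
                )
            )
    if min_subsample is not None:
        counts = table.cell_counts()
        short = counts[counts["n_trials"] < min_subsample]
        for _, row in short.iterrows():
            report.issues.append(
                ValidationIssue(
                    "warning",
                    "below-min-subsample",
                    f"only {row['n_trials']} trials; smallest requested "
                    f"subsample size is {min_subsample} — participant will be "
                    "excluded at that grid point",
                    f"{row['participant']}/{row['condition']}",
                )
            )
    return report


RESULTS_HEADER = (
    "metric,condition,contrast,scope,n_trials,n_iterations,"
    "n_participants,estimate,ci_low,ci_high"
)


def _fmt(x: float | int | None) -> str:
    """Render a number with >= 6 significant digits, deterministically."""
    if x is None:
        return ""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if math.isnan(x):
        return "nan"
    return format(float(x), ".8g")


def write_results(results: Sequence, path: str | Path) -> None:
    """Serialize metric result rows to the stable results CSV schema.

    Each element must provide ``to_rows()`` yielding dicts with the keys of
    :data:`RESULTS_HEADER`.  All rows must share one metric kind; output is
    byte-identical for identical inputs.
    """
    rows: list[dict] = []
    for res in results:
        rows.extend(res.to_rows())
    metrics = {r["metric"] for r in rows}
    if len(metrics) > 1:
        raise ValueError(f"results mix metric kinds: {sorted(metrics)}")
    buf = _io.StringIO()
    buf.write(RESULTS_HEADER + "\n")
    for r in rows:
        buf.write(
            ",".join(
                [
                    str(r["metric"]),
                    str(r["condition"]),
                    str(r.get("contrast", "")),
                    str(r["scope"]),
                    "" if r.get("n_trials") is None else str(int(r["n_trials"])),
                    "" if r.get("n_iterations") is None else str(int(r["n_iterations"])),
                    "" if r.get("n_participants") is None else str(int(r["n_participants"])),
                    _fmt(r.get("estimate")),
                    _fmt(r.get("ci_low")),
                    _fmt(r.get("ci_high")),
                ]
            )
            + "\n"
        )
    Path(path).write_text(buf.getvalue())
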