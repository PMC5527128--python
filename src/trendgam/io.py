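"""Readers/writers for tidy time-course tables and the absorbance utility."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("metabolite", "day", "replicate", "group", "concentration")
GROUPS = ("control", "treated")
FLOAT_FORMAT = "%.6g"


class DatasetError(ValueError):
    """Raised when a time-course table violates the format contract."""


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a long-format time-course table.

    Enforces: required columns present, numeric non-negative days, strictly
    positive numeric concentrations, groups in {control, treated}, and unique
    (metabolite, day, replicate, group) keys.  Offending rows are reported by
    position (first 20).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required column(s): {missing}")
    out = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    out["metabolite"] = out["metabolite"].astype(str)
    out["replicate"] = out["replicate"].astype(str)
    out["group"] = out["group"].astype(str)

    problems: list[str] = []
    day = pd.to_numeric(out["day"], errors="coerce")
    bad = out.index[day.isna() | (day < 0)]
    if len(bad):
        problems.append(f"non-numeric or negative day at rows {bad[:20].tolist()}")
    conc = pd.to_numeric(out["concentration"], errors="coerce")
    bad = out.index[conc.isna() | (conc <= 0)]
    if len(bad):
        problems.append(
            f"non-numeric or non-positive concentration at rows {bad[:20].tolist()}"
        )
    bad = out.index[~out["group"].isin(GROUPS)]
    if len(bad):
        problems.append(f"group not in {GROUPS} at rows {bad[:20].tolist()}")
    if not problems:
        out["day"] = day.astype(float)
        out["concentration"] = conc.astype(float)
        dup = out.duplicated(subset=["metabolite", "day", "replicate", "group"])
        if dup.any():
            problems.append(
                f"duplicate (metabolite, day, replicate, group) keys at rows "
                f"{out.index[dup][:20].tolist()}"
            )
    if problems:
        raise DatasetError("; ".join(problems))
    return out.reset_index(drop=True)


def read_timecourse_csv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a comma-delimited time-course table.

    ``column_map`` maps canonical names to the file's column names, e.g.
    ``{"metabolite": "compound", "day": "t"}``.
    """
    df = pd.read_csv(path)
    if column_map:
        rename = {src: canonical for canonical, src in column_map.items()}
        absent = [src for src in column_map.values() if src not in df.columns]
        if absent:
            raise DatasetError(f"mapped column(s) not in file: {absent}")
        df = df.rename(columns=rename)
    return validate_dataset(df)


def write_timecourse_csv(df: pd.DataFrame, path) -> None:
    """Write a validated table with fixed column order and float formatting
    (6 significant digits) so reruns are byte-identical."""
    out = validate_dataset(df)
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


@dataclass(frozen=True)
class AbsorbanceReading:
    """A 535 nm absorbance measurement for total-pigment quantification."""

    a535: float
    dilution_factor: float = 2.0
    epsilon: float = 98.2

    def __post_init__(self):
        if not np.isfinite(self.a535) or self.a535 < 0:
            raise ValueError("A535 must be finite and >= 0")
        if self.epsilon <= 0 or self.dilution_factor <= 0:
            raise ValueError("epsilon and dilution factor must be positive")


def total_anthocyanin_from_absorbance(reading: AbsorbanceReading) -> float:
    """Total pigment concentration from a 535 nm reading:
    ``A535 * dilution_factor / epsilon`` (Beer-Lambert rearrangement; the
    unit follows the epsilon convention used for the reading)."""
    return reading.a535 * reading.dilution_factor / reading.epsilon
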