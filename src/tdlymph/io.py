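"""CSV dialects shared across the pipeline.

Every numeric column carries its unit as a bracketed header suffix
(``pressure[mmHg]``, ``diameter[mm]``); a short list of inherently
dimensionless columns (stretch ratios, fractions, test statistics) is
exempt. Floats are written at 6 significant digits so that re-running a
manifest-identical pipeline reproduces files byte-for-byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pdcurves import PDCurve
from .waveforms import HemoTrace

FLOAT_FORMAT = "%.6g"

#: columns allowed without a unit suffix
BARE_COLUMNS = {
    "animal_id", "group", "phase", "state", "site", "epoch", "day", "variable",
    "unit", "row", "lambda", "fold", "tdq_fold", "n_cycles", "n",
    "retrograde_time_fraction", "retrograde_volume_fraction", "mean_ratio",
    "t", "df", "p", "significant", "degenerate", "retrograde",
    "control_mean", "control_sd", "tr_mean", "tr_sd",
}

_TRACE_SITES = sorted(
    ("artery", "jugular_vein", "right_atrium", "right_ventricle", "thoracic_duct_flow"),
    key=len, reverse=True,
)


def _parse_trace_filename(name: str) -> tuple[str, str, str]:
    """<animal>_<site>_<day>.csv; site matched against the site vocabulary
    (both site and day labels may themselves contain underscores)."""
    stem = name[:-4] if name.endswith(".csv") else None
    if stem and "_" in stem:
        animal, rest = stem.split("_", 1)
        for site in _TRACE_SITES:
            if rest.startswith(site + "_"):
                return animal, site, rest[len(site) + 1:]
    raise SchemaError(f"{name}: file name does not match <animal>_<site>_<day>.csv")


class SchemaError(ValueError):
    """A CSV that does not match its declared dialect; names file and column."""


def validate_columns(df: pd.DataFrame, path, required: list[str] | None = None) -> None:
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in df.columns:
        if col in BARE_COLUMNS or ("[" in col and col.endswith("]")):
            continue
        if pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(f"{path}: numeric column {col!r} lacks a unit suffix")


def write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_csv(path, required: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path)
    validate_columns(df, path, required)
    return df


# ---------------------------------------------------------------------------
# traces: one file per animal/site/day, pattern <animal>_<site>_<day>.csv


def trace_filename(trace: HemoTrace) -> str:
    return f"{trace.animal_id}_{trace.site}_{trace.day}.csv"


def write_trace_csv(trace: HemoTrace, directory) -> Path:
    path = Path(directory) / trace_filename(trace)
    df = pd.DataFrame({"time[s]": trace.t, f"value[{trace.unit}]": trace.v})
    write_csv(df, path)
    return path


def read_trace_csv(path) -> HemoTrace:
    path = Path(path)
    animal, site, day = _parse_trace_filename(path.name)
    df = pd.read_csv(path)
    if "time[s]" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'time[s]'")
    value_cols = [c for c in df.columns if c.startswith("value[")]
    if len(value_cols) != 1:
        raise SchemaError(f"{path}: expected exactly one 'value[<unit>]' column")
    unit = value_cols[0][6:-1]
    return HemoTrace(
        site=site, t=df["time[s]"].to_numpy(), v=df[value_cols[0]].to_numpy(),
        day=day, animal_id=animal, unit=unit,
    )


# ---------------------------------------------------------------------------
# pressure-diameter tables: animal_id, group, height[cmH2O], diameter[mm]

PD_COLUMNS = ["animal_id", "group", "height[cmH2O]", "diameter[mm]"]


def write_pd_csv(curves: list[PDCurve], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "animal_id": c.animal_id,
                "group": c.group,
                "height[cmH2O]": c.heights_cm,
                "diameter[mm]": c.diameters_mm,
            }
        )
        for c in curves
    ]
    write_csv(pd.concat(frames, ignore_index=True), path)


def read_pd_csv(path) -> list[PDCurve]:
    df = read_csv(path, required=PD_COLUMNS)
    curves = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=True):
        sub = sub.sort_values("height[cmH2O]")
        curves.append(
            PDCurve(
                heights_cm=sub["height[cmH2O]"].to_numpy(),
                diameters_mm=sub["diameter[mm]"].to_numpy(),
                group=str(group),
                animal_id=str(animal),
            )
        )
    return curves


# ---------------------------------------------------------------------------
# cohort table

COHORT_COLUMNS = [
    "animal_id", "group", "phase", "D_o[mm]", "D_i[mm]", "h[mm]", "A_o[mm2]",
    "lambda", "TDQ[ml/min]", "TDP[mmHg]", "CC[mmHg]", "RV_mass[g]", "LV_mass[g]",
]


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    write_csv(df, path)


def read_cohort_csv(path) -> pd.DataFrame:
    df = read_csv(path, required=COHORT_COLUMNS)
    bad = df[df["D_i[mm]"] > df["D_o[mm]"] + 1e-9]
    if len(bad):
        raise SchemaError(
            f"{path}: D_i exceeds D_o for animal(s) {sorted(bad['animal_id'])}"
        )
    if np.any(df["lambda"] <= 0):
        raise SchemaError(f"{path}: non-positive axial stretch in column 'lambda'")
    return df
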