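"""End-to-end orchestration: simulate -> analyze -> report.

``simulate`` writes the synthetic study inputs (cohort table, trace files,
P-D tables, lymph-flow time course). ``analyze`` consumes those inputs —
real or simulated, the CSV dialects are identical — and produces
per-animal biomechanics, waveform summaries, P-D summaries and Welch
statistics. ``report`` renders the machine-readable twins of the study's
two summary tables plus a run manifest. Re-running with an identical
manifest (same config hash and seed) reproduces every output byte-for-byte
apart from the manifest timestamp.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomech import (
    MorphometryRecord,
    analyze_record,
    per_animal_ratio_summary,
    remodeling_ratios,
)
from .io import (
    SchemaError,
    read_cohort_csv,
    read_csv,
    read_pd_csv,
    read_trace_csv,
    write_cohort_csv,
    write_csv,
    write_pd_csv,
    write_trace_csv,
)
from .pdcurves import mean_group_curve, secant_compliance
from .stats import summarize, welch_t_test
from .synth import (
    CohortConfig,
    generate_cohort,
    generate_flow_trace,
    generate_pd_curve,
    generate_pressure_cohort,
    generate_pressure_trace,
    generate_timecourse,
)
from .units import Quantity, q, round_sig
from .waveforms import summarize_trace

log = logging.getLogger("tdlymph")

PRESSURE_SITES = ("artery", "jugular_vein", "right_atrium", "right_ventricle")

#: table2 variable -> (cohort/biomech column, unit)
TABLE2_VARIABLES = {
    "D_o": "D_o[mm]",
    "D_i": "D_i[mm]",
    "h": "h[mm]",
    "TDQ": "TDQ[ml/min]",
    "TDP": "TDP[mmHg]",
    "WSS": "WSS[dyn/cm2]",
    "WSS_Pa": "WSS[Pa]",
    "sigma": "CWS[kPa]",
}


class _OutputSet:
    """Tracks files written by one stage so failures leave no partial output."""

    def __init__(self) -> None:
        self.paths: list[Path] = []

    def add(self, path) -> Path:
        p = Path(path)
        self.paths.append(p)
        return p

    def cleanup(self) -> None:
        for p in self.paths:
            if p.exists():
                p.unlink()


def _machine_log(out_dir: Path, stage: str, payload: dict) -> None:
    record = {"stage": stage, **payload}
    with open(out_dir / "run_log.jsonl", "a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")


def config_hash(config: CohortConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.raw, sort_keys=True, default=float).encode()
    ).hexdigest()


# ---------------------------------------------------------------------------
# simulate


def simulate(config: CohortConfig, out_dir, seed: int = 0) -> Path:
    """Write a full synthetic input set under ``out_dir``/inputs."""
    inputs = Path(out_dir) / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    rng_cohort, rng_press, rng_traces, rng_pd, rng_tc = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    cohort = generate_cohort(config, rng_cohort)
    write_cohort_csv(cohort, inputs / "cohort.csv")

    pressures = generate_pressure_cohort(config, rng_press)
    write_csv(pressures, inputs / "pressures.csv")

    traces_dir = inputs / "traces"
    wf = config.waveform
    for _, row in pressures.iterrows():
        trace = generate_pressure_trace(
            row["systolic[mmHg]"], row["diastolic[mmHg]"], row["mean[mmHg]"],
            site=row["site"], duration_s=wf["duration_s"],
            rate_hz=wf["sample_rate_hz"], rng=rng_traces, config=config,
            animal_id=row["animal_id"], day=row["epoch"],
        )
        write_trace_csv(trace, traces_dir)
    tr = cohort[cohort["group"] == "tr"]
    for phase, state in (("baseline", "baseline"), ("day28", "post_tr")):
        for _, row in tr[tr["phase"] == phase].iterrows():
            trace = generate_flow_trace(
                row["TDQ[ml/min]"], state=state, duration_s=max(wf["duration_s"], 10.0),
                rate_hz=wf["sample_rate_hz"], rng=rng_traces, config=config,
                animal_id=row["animal_id"],
            )
            trace.day = phase
            write_trace_csv(trace, traces_dir)

    curves = []
    for group in ("control", "tr"):
        ids = sorted(cohort.loc[cohort["group"] == group, "animal_id"].unique())
        for animal in ids:
            curves.append(generate_pd_curve(group, config, rng_pd, animal_id=animal))
    write_pd_csv(curves, inputs / "pd_curves.csv")

    tc_frames = []
    day28 = tr[tr["phase"] == "day28"].set_index("animal_id")
    base = tr[tr["phase"] == "baseline"].set_index("animal_id")
    for animal in day28.index:
        tc = generate_timecourse(
            base.loc[animal, "TDQ[ml/min]"], config, rng=rng_tc,
            plateau_fold=day28.loc[animal, "tdq_fold"],
        )
        tc.insert(0, "animal_id", animal)
        tc_frames.append(tc)
    write_csv(pd.concat(tc_frames, ignore_index=True), inputs / "timecourse.csv")

    log.info("simulated inputs for %d animals/group under %s", config.n_per_group, inputs)
    _machine_log(Path(out_dir), "simulate", {"seed": seed, "inputs": str(inputs)})
    return inputs


# ---------------------------------------------------------------------------
# analyze


def analyze(
    config: CohortConfig,
    input_dir,
    out_dir,
    mu_cp: float | None = None,
    stress_convention: str = "laplace",
) -> None:
    """Run the full analysis over an input set."""
    inputs = Path(input_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = _OutputSet()
    try:
        mu = q(mu_cp if mu_cp is not None else config.mu_cp, "cP")
        cohort = read_cohort_csv(inputs / "cohort.csv")

        biomech = _biomech_table(cohort, mu, stress_convention)
        write_csv(biomech, outputs.add(out / "biomech.csv"))

        summaries = _waveform_summaries(inputs / "traces")
        write_csv(summaries, outputs.add(out / "waveform_summaries.csv"))

        pd_summary, compliance = _pd_summaries(inputs / "pd_curves.csv")
        write_csv(pd_summary, outputs.add(out / "pd_summary.csv"))

        stats = _stats_table(cohort, biomech, compliance)
        write_csv(stats, outputs.add(out / "stats.csv"))
    except Exception:
        outputs.cleanup()
        raise
    log.info("analysis written to %s", out)
    _machine_log(out, "analyze", {"inputs": str(inputs), "mu_cP": mu.value,
                                  "stress_convention": stress_convention})


def _biomech_table(cohort: pd.DataFrame, mu: Quantity, convention: str) -> pd.DataFrame:
    rows = []
    for _, r in cohort.iterrows():
        record = MorphometryRecord(
            animal_id=str(r["animal_id"]),
            D_o=q(r["D_o[mm]"], "mm"),
            A_o=q(r["A_o[mm2]"], "mm2"),
            lam=float(r["lambda"]),
        )
        result = analyze_record(
            record, P_i=q(r["TDP[mmHg]"], "mmHg"), Q=q(r["TDQ[ml/min]"], "ml/min"),
            mu=mu, convention=convention,
        )
        rows.append(
            {
                "animal_id": r["animal_id"],
                "group": r["group"],
                "phase": r["phase"],
                "D_i[mm]": result.D_i.value,
                "h[mm]": result.h.value,
                "WSS[dyn/cm2]": result.wss_dyn_cm2.value,
                "WSS[Pa]": result.wss_pa.value,
                "CWS[kPa]": result.cws_kpa.value,
                "retrograde": result.retrograde,
            }
        )
    return pd.DataFrame(rows)


def _waveform_summaries(traces_dir: Path) -> pd.DataFrame:
    if not traces_dir.is_dir():
        raise SchemaError(f"{traces_dir}: trace directory not found")
    rows = []
    for path in sorted(traces_dir.glob("*.csv")):
        trace = read_trace_csv(path)
        s = summarize_trace(trace)
        col = "mmHg" if trace.unit == "mmHg" else "ml/min"
        row = {
            "animal_id": trace.animal_id, "site": trace.site, "day": trace.day,
            "n_cycles": s.n_cycles,
            "mean[mmHg]": s.mean if col == "mmHg" else np.nan,
            "systolic[mmHg]": s.systolic if col == "mmHg" else np.nan,
            "diastolic[mmHg]": s.diastolic if col == "mmHg" else np.nan,
            "mean[ml/min]": s.mean if col == "ml/min" else np.nan,
            "systolic[ml/min]": s.systolic if col == "ml/min" else np.nan,
            "diastolic[ml/min]": s.diastolic if col == "ml/min" else np.nan,
            "retrograde_time_fraction": s.retrograde_time_fraction,
            "retrograde_volume_fraction": s.retrograde_volume_fraction,
        }
        rows.append(row)
    if not rows:
        raise SchemaError(f"{traces_dir}: no trace files found")
    return pd.DataFrame(rows)


def _pd_summaries(path: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    curves = read_pd_csv(path)
    frames = []
    comp_rows = []
    for group in ("control", "tr"):
        group_curves = [c for c in curves if c.group == group]
        if not group_curves:
            raise SchemaError(f"{path}: no curves for group {group!r}")
        pressures, mean_d = mean_group_curve(group_curves)
        frames.append(
            pd.DataFrame(
                {
                    "group": group,
                    "height[cmH2O]": group_curves[0].heights_cm,
                    "pressure[mmHg]": pressures,
                    "mean_diameter[mm]": mean_d,
                    "mean_ratio": mean_d / mean_d[0],
                }
            )
        )
        for c in group_curves:
            p = c.pressures_mmhg
            comp_rows.append(
                {
                    "animal_id": c.animal_id, "group": group,
                    "compliance[mm/mmHg]": secant_compliance(c, p[0], p[14]),
                }
            )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(comp_rows)


def _stats_table(
    cohort: pd.DataFrame, biomech: pd.DataFrame, compliance: pd.DataFrame
) -> pd.DataFrame:
    control = cohort[(cohort["group"] == "control") & (cohort["phase"] == "terminal")]
    tr = cohort[(cohort["group"] == "tr") & (cohort["phase"] == "day28")]
    bio_c = biomech[(biomech["group"] == "control") & (biomech["phase"] == "terminal")]
    bio_t = biomech[(biomech["group"] == "tr") & (biomech["phase"] == "day28")]
    rows = []

    def add(variable, unit, x, y):
        sx, sy = summarize(x, variable, unit), summarize(y, variable, unit)
        res = welch_t_test(x, y)
        rows.append(
            {
                "variable": variable, "unit": unit,
                "control_mean": sx.mean, "control_sd": sx.sd,
                "tr_mean": sy.mean, "tr_sd": sy.sd,
                "t": res.t, "df": res.df, "p": res.p, "significant": res.significant,
            }
        )

    for var, col in (
        ("D_o", "D_o[mm]"), ("D_i", "D_i[mm]"), ("h", "h[mm]"),
        ("TDQ", "TDQ[ml/min]"), ("TDP", "TDP[mmHg]"), ("CC", "CC[mmHg]"),
        ("RV_mass", "RV_mass[g]"), ("LV_mass", "LV_mass[g]"),
    ):
        unit = col.split("[")[1][:-1]
        add(var, unit, control[col].to_numpy(), tr[col].to_numpy())
    add("WSS", "Pa", bio_c["WSS[Pa]"].to_numpy(), bio_t["WSS[Pa]"].to_numpy())
    add("sigma", "kPa", bio_c["CWS[kPa]"].to_numpy(), bio_t["CWS[kPa]"].to_numpy())
    add(
        "PD_compliance", "mm/mmHg",
        compliance.loc[compliance["group"] == "control", "compliance[mm/mmHg]"].to_numpy(),
        compliance.loc[compliance["group"] == "tr", "compliance[mm/mmHg]"].to_numpy(),
    )
    df = pd.DataFrame(rows)
    df.attrs["n_tests"] = len(df)  # no multiplicity correction; count reported
    return df


# ---------------------------------------------------------------------------
# report


def report(config: CohortConfig, out_dir, seed: int | None = None) -> None:
    """Render table twins and the manifest from an analyzed output set."""
    out = Path(out_dir)
    outputs = _OutputSet()
    try:
        summaries = read_csv(out / "waveform_summaries.csv")
        biomech = read_csv(out / "biomech.csv")
        cohort = read_cohort_csv(Path(out) / "inputs" / "cohort.csv")

        write_csv(_table1(summaries), outputs.add(out / "table1.csv"))
        write_csv(_table2(cohort, biomech), outputs.add(out / "table2.csv"))

        manifest = {
            "config_hash": config_hash(config),
            "seed": seed,
            "inputs": sorted(
                str(p.relative_to(out)) for p in (out / "inputs").rglob("*.csv")
            ),
            "outputs": ["table1.csv", "table2.csv", "stats.csv",
                        "waveform_summaries.csv", "pd_summary.csv", "biomech.csv"],
            "package_version": __version__,
            "mu_cP": config.mu_cp,
            "n_statistical_tests": int(len(read_csv(out / "stats.csv"))),
            "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        }
        path = outputs.add(out / "manifest.json")
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception:
        outputs.cleanup()
        raise
    log.info("report written to %s", out)
    _machine_log(out, "report", {"config_hash": config_hash(config)})


def _table1(summaries: pd.DataFrame) -> pd.DataFrame:
    rows = []
    press = summaries[summaries["site"].isin(PRESSURE_SITES)]
    for (day, site), sub in press.groupby(["day", "site"], sort=True):
        row = {"site": site, "epoch": day, "n": len(sub)}
        for metric in ("systolic", "diastolic", "mean"):
            s = summarize(sub[f"{metric}[mmHg]"].to_numpy(), metric, "mmHg")
            row[f"{metric}_mean[mmHg]"] = s.mean
            row[f"{metric}_sd[mmHg]"] = s.sd
        rows.append(row)
    return pd.DataFrame(rows)


def _table2(cohort: pd.DataFrame, biomech: pd.DataFrame) -> pd.DataFrame:
    merged = cohort.merge(
        biomech[["animal_id", "phase", "WSS[dyn/cm2]", "WSS[Pa]", "CWS[kPa]"]],
        on=["animal_id", "phase"],
    )
    control = merged[(merged["group"] == "control") & (merged["phase"] == "terminal")]
    tr28 = merged[(merged["group"] == "tr") & (merged["phase"] == "day28")]
    tr0 = merged[(merged["group"] == "tr") & (merged["phase"] == "baseline")]

    def group_row(label: str, sub: pd.DataFrame) -> dict:
        row: dict = {"row": label, "n": len(sub)}
        for var, col in TABLE2_VARIABLES.items():
            unit = col.split("[")[1][:-1]
            s = summarize(sub[col].to_numpy(), var, unit)
            row[f"{var}_mean[{unit}]"] = s.mean
            row[f"{var}_sd[{unit}]"] = s.sd
        return row

    c_row = group_row("control", control)
    t_row = group_row("tr", tr28)
    means_c = {v: c_row[f"{v}_mean[{c.split('[')[1][:-1]}]"] for v, c in TABLE2_VARIABLES.items()}
    means_t = {v: t_row[f"{v}_mean[{c.split('[')[1][:-1]}]"] for v, c in TABLE2_VARIABLES.items()}
    ratios = remodeling_ratios(means_c, means_t)
    ratio_row: dict = {"row": "ratio_tr_over_control", "n": len(tr28)}
    tr0_idx = tr0.set_index("animal_id")
    tr28_idx = tr28.set_index("animal_id")
    for var, col in TABLE2_VARIABLES.items():
        unit = col.split("[")[1][:-1]
        ratio_row[f"{var}_mean[{unit}]"] = ratios.display[var]
        # SD of the per-animal (day-28 / paired-baseline) ratios
        shared = tr28_idx.index.intersection(tr0_idx.index)
        base_vals = tr0_idx.loc[shared, col].to_numpy()
        if len(shared) >= 2 and np.all(base_vals != 0):
            _, sd = per_animal_ratio_summary(base_vals, tr28_idx.loc[shared, col].to_numpy())
            ratio_row[f"{var}_sd[{unit}]"] = round_sig(sd, 2)
        else:
            ratio_row[f"{var}_sd[{unit}]"] = np.nan
    return pd.DataFrame([c_row, t_row, ratio_row])


# ---------------------------------------------------------------------------


def run_pipeline(
    config: CohortConfig,
    out_dir,
    seed: int = 0,
    input_dir=None,
    do_simulate: bool = False,
    mu_cp: float | None = None,
    stress_convention: str = "laplace",
) -> Path:
    """simulate (optional) -> analyze -> report. Returns the output dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if do_simulate:
        inputs = simulate(config, out, seed=seed)
    elif input_dir is not None:
        inputs = Path(input_dir)
        if inputs != out / "inputs":
            # report() resolves the cohort through <out>/inputs
            target = out / "inputs"
            if not target.exists():
                target.symlink_to(inputs.resolve(), target_is_directory=True)
    else:
        raise SchemaError("no input directory given and --simulate not requested")
    analyze(config, out / "inputs", out, mu_cp=mu_cp, stress_convention=stress_convention)
    report(config, out, seed=seed)
    return out
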