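"""Seeded synthetic swine cohorts, traces, time courses and P-D curves.

The generator stands in for the animal data: its defaults are the
published study conditions (printed group means/SDs, the ~3-fold lymph
flow rise at one hour and ~10-fold plateau by day 2, retrograde flow
troughs after tricuspid regurgitation, and outward-shifted passive
pressure-diameter curves in the TR group).

Sampling model
--------------
Each scalar variable is drawn from a lower-bounded distribution whose
*achieved* moments are the configured ones:

* a truncated normal whose parent parameters are solved so the truncated
  distribution has the target mean/SD (plain truncation would shift the
  mean — by ~54% for baseline lymph flow, whose printed SD exceeds its
  mean);
* a moment-matched gamma when the target coefficient of variation exceeds
  what any zero-truncated normal can reach (CV >= 1);
* by default (``moment_match='sample'``) draws are then standardized so
  every cohort reproduces the configured mean/SD as exact sample moments
  — the ``mvrnorm(empirical=TRUE)`` convention — falling back to a
  moment-preserving power transform when the affine map would cross the
  lower bound. ``moment_match='population'`` keeps plain distributional
  draws.

Within-animal geometric consistency is enforced by construction: the
outer diameter and wall thickness are sampled, the inner diameter is
``D_o - 2h``, and the no-load wall area follows from incompressibility,
so the derived geometry round-trips through the biomechanics module
exactly. Variables are otherwise independent (no within-animal
correlation structure is published).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy import stats as sps
from scipy.special import gammaln

from .pdcurves import PDCurve
from .waveforms import HemoTrace

#: CV above which no zero-truncated normal can match the target moments
_TRUNCNORM_CV_LIMIT = 0.95
#: beyond this many SDs from the bound, truncation is numerically irrelevant
_NO_TRUNCATION_SDS = 8.0


class ConfigError(ValueError):
    """Invalid or infeasible generator configuration."""


@dataclass(frozen=True)
class VariableSpec:
    mean: float
    sd: float
    unit: str = "dimensionless"
    lower: Optional[float] = None
    derived: bool = False

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError("SD must be non-negative")
        if self.lower is not None and self.mean < self.lower:
            raise ConfigError(
                f"mean {self.mean} below truncation bound {self.lower}: infeasible"
            )


@dataclass
class CohortConfig:
    """Typed view over the generator configuration (see packaged defaults)."""

    n_per_group: int
    mu_cp: float
    lambda_range: tuple[float, float]
    split_factor: Optional[float]
    cohort: dict[str, dict[str, VariableSpec]]
    tdq_fold: VariableSpec
    pressure_triples: dict[str, dict[str, dict[str, tuple[float, float]]]]
    waveform: dict
    timecourse: dict
    pd_curve: dict
    reference: dict
    raw: dict = field(repr=False, default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        cohort = {
            group: {
                name: VariableSpec(**spec)
                for name, spec in variables.items()
            }
            for group, variables in d["cohort"].items()
        }
        return cls(
            n_per_group=int(d["n_per_group"]),
            mu_cp=float(d.get("mu_cP", 1.0)),
            lambda_range=tuple(d.get("lambda_range", [1.0, 1.6])),
            split_factor=d.get("split_factor"),
            cohort=cohort,
            tdq_fold=VariableSpec(**d["tdq_fold"]),
            pressure_triples=d["pressure_triples"],
            waveform=d["waveform"],
            timecourse=d["timecourse"],
            pd_curve=d["pd_curve"],
            reference=d.get("reference", {}),
            raw=d,
        )


def default_config() -> CohortConfig:
    """The packaged study-condition defaults (printed Tables 1-2)."""
    text = resources.files("tdlymph.data").joinpath("tables_1_2_defaults.yaml").read_text()
    return CohortConfig.from_dict(yaml.safe_load(text))


def load_config(path) -> CohortConfig:
    with open(path) as fh:
        return CohortConfig.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# moment-matched sampling


@lru_cache(maxsize=256)
def _truncnorm_parent(mean: float, sd: float, lower: float) -> Optional[tuple[float, float, float]]:
    """Parent (mu, sigma, alpha) of a lower-truncated normal with target moments.

    Returns None when the target CV is unreachable (handled by the gamma
    fallback).
    """
    c = sd / (mean - lower)
    if c >= _TRUNCNORM_CV_LIMIT:
        return None

    def lam(a: float) -> float:
        return math.exp(sps.norm.logpdf(a) - sps.norm.logsf(a))

    def g(a: float) -> float:
        l = lam(a)
        var_factor = 1.0 + a * l - l * l
        return math.sqrt(max(var_factor, 1e-300)) / (l - a)

    a_lo = min(-1.5 / c - 5.0, -5.0)
    a_hi = 40.0
    try:
        alpha = optimize.brentq(lambda a: g(a) - c, a_lo, a_hi, xtol=1e-12)
    except ValueError:
        return None
    sigma = (mean - lower) / (lam(alpha) - alpha)
    mu = lower - alpha * sigma
    return mu, sigma, alpha


def match_sample_moments(
    z: np.ndarray, mean: float, sd: float, lower: Optional[float]
) -> np.ndarray:
    """Map draws so the sample mean/SD equal the targets exactly.

    Affine when it respects the lower bound; otherwise a power transform
    ``lower + c*(z-lower)**p`` with (c, p) solved so both sample moments
    match on the bounded support.
    """
    n = z.size
    if n == 1:
        return np.full(1, mean)
    zbar = float(np.mean(z))
    sz = float(np.std(z, ddof=1))
    if sz == 0:
        return np.full(n, mean)
    y = mean + (z - zbar) * (sd / sz)
    if lower is None or float(np.min(y)) >= lower:
        return y
    w = np.maximum(z - lower, 0.0)
    mt = mean - lower
    target_cv = sd / mt

    def cv(p: float) -> float:
        wp = w**p
        return float(np.std(wp, ddof=1) / np.mean(wp))

    try:
        p = optimize.brentq(lambda p: cv(p) - target_cv, 0.05, 8.0, xtol=1e-10)
    except ValueError:
        return np.maximum(y, lower)  # best effort at tiny n
    wp = w**p
    return lower + wp * (mt / float(np.mean(wp)))


def draw_variable(
    spec: VariableSpec,
    n: int,
    rng: np.random.Generator,
    moment_match: str = "sample",
) -> np.ndarray:
    """n draws of one configured variable."""
    m, s, lo = spec.mean, spec.sd, spec.lower
    if s == 0:
        return np.full(n, m)
    if lo is None or (m - lo) > _NO_TRUNCATION_SDS * s:
        z = rng.normal(m, s, n)
    else:
        parent = _truncnorm_parent(m, s, lo)
        if parent is not None:
            mu, sigma, alpha = parent
            u = rng.uniform(sps.norm.cdf(alpha), 1.0, n)
            z = mu + sigma * sps.norm.ppf(u)
            z = np.maximum(z, lo)
        else:
            # CV beyond the truncated-normal limit: moment-matched gamma
            shape = ((m - lo) / s) ** 2
            scale = s**2 / (m - lo)
            z = lo + rng.gamma(shape, scale, n)
    if moment_match == "sample":
        z = match_sample_moments(z, m, s, lo)
    elif moment_match != "population":
        raise ConfigError("moment_match must be 'sample' or 'population'")
    return z


# ---------------------------------------------------------------------------
# cohort generation


_SCALARS = ("D_o", "h", "TDQ", "TDP", "CC", "RV_mass", "LV_mass")


def _triple_split(triple: dict, fallback: Optional[float]) -> float:
    """Split factor a with diastolic = mean - a*A, systolic = mean + (1-a)*A."""
    sys_m, dia_m, mean_m = triple["sys"][0], triple["dia"][0], triple["mean"][0]
    if fallback is not None:
        return float(fallback)
    amp = sys_m - dia_m
    if amp <= 0:
        return 0.35
    return (mean_m - dia_m) / amp


def _amplitude_spec(triple: dict, a: float) -> VariableSpec:
    """Pulse-amplitude distribution consistent (least-squares) with the triple."""
    sys_m, sys_s = triple["sys"]
    dia_m, dia_s = triple["dia"]
    mean_s = triple["mean"][1]
    amp_mean = max(sys_m - dia_m, 1e-6)
    denom = (1 - a) ** 2 + a**2
    var = max((sys_s**2 + dia_s**2 - 2 * mean_s**2) / denom, (0.1 * amp_mean) ** 2)
    return VariableSpec(mean=amp_mean, sd=math.sqrt(var), unit="mmHg", lower=0.0)


def generate_cohort(
    config: CohortConfig,
    seed: int | np.random.Generator | None = 0,
    n_per_group: Optional[int] = None,
    moment_match: str = "sample",
) -> pd.DataFrame:
    """Per-animal cohort table with paired baseline rows for the TR group.

    Control animals contribute one terminal row each. TR animals
    contribute a baseline row (drawn from the control parameter set, with
    lymph flow tied to the terminal value through the per-animal fold) and
    a day-28 row, so both ratio conventions — ratio of group means and
    mean of per-animal ratios — are computable downstream.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(n_per_group if n_per_group is not None else config.n_per_group)
    if n < 1:
        raise ConfigError("need at least one animal per group")

    lam_lo, lam_hi = config.lambda_range
    if not (0 < lam_lo <= lam_hi):
        raise ConfigError("invalid lambda range")

    def draw_group(group: str, n: int) -> dict[str, np.ndarray]:
        specs = config.cohort[group]
        out = {}
        for name in _SCALARS:
            out[name] = draw_variable(specs[name], n, rng, moment_match)
        out["lambda"] = rng.uniform(lam_lo, lam_hi, n)
        return out

    def geometry(d: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        D_i = d["D_o"] - 2.0 * d["h"]
        if np.any(D_i <= 0):
            raise ConfigError("configured diameters/thicknesses give D_i <= 0")
        A_o = math.pi * d["lambda"] * (d["D_o"] ** 2 - D_i**2) / 4.0
        return {**d, "D_i": D_i, "A_o": A_o}

    control = geometry(draw_group("control", n))
    tr = geometry(draw_group("tr", n))
    # paired TR baselines: control-like morphometry and pressures,
    # lymph flow tied to the terminal value via the per-animal fold
    tr_base = geometry(draw_group("control", n))
    folds = draw_variable(config.tdq_fold, n, rng, moment_match)
    tr_base["TDQ"] = tr["TDQ"] / folds

    def rows(d, ids, group, phase, masses=True):
        frame = pd.DataFrame(
            {
                "animal_id": ids,
                "group": group,
                "phase": phase,
                "D_o[mm]": d["D_o"],
                "D_i[mm]": d["D_i"],
                "h[mm]": d["h"],
                "A_o[mm2]": d["A_o"],
                "lambda": d["lambda"],
                "TDQ[ml/min]": d["TDQ"],
                "TDP[mmHg]": d["TDP"],
                "CC[mmHg]": d["CC"],
                "RV_mass[g]": d["RV_mass"] if masses else np.nan,
                "LV_mass[g]": d["LV_mass"] if masses else np.nan,
            }
        )
        return frame

    c_ids = [f"C{i + 1}" for i in range(n)]
    t_ids = [f"T{i + 1}" for i in range(n)]
    table = pd.concat(
        [
            rows(control, c_ids, "control", "terminal"),
            rows(tr_base, t_ids, "tr", "baseline", masses=False),
            rows(tr, t_ids, "tr", "day28"),
        ],
        ignore_index=True,
    )
    table.loc[table["phase"] == "day28", "tdq_fold"] = folds
    return table


def generate_pressure_cohort(
    config: CohortConfig,
    seed: int | np.random.Generator | None = 0,
    n_per_group: Optional[int] = None,
    moment_match: str = "sample",
) -> pd.DataFrame:
    """Per-animal systolic/diastolic/mean pressures per site and epoch.

    The mean level is drawn first and the pulse amplitude second;
    diastolic = mean - a*A and systolic = mean + (1-a)*A, where the split
    factor a is derived from the configured triple (so the three printed
    means are reproduced) unless an explicit ``split_factor`` overrides it.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(n_per_group if n_per_group is not None else config.n_per_group)
    ids = [f"T{i + 1}" for i in range(n)]
    frames = []
    for epoch, sites in config.pressure_triples.items():
        for site, triple in sites.items():
            a = _triple_split(triple, config.split_factor)
            mean_m, mean_s = triple["mean"]
            level = draw_variable(
                VariableSpec(mean=mean_m, sd=mean_s, unit="mmHg", lower=0.0),
                n, rng, moment_match,
            )
            amp = draw_variable(_amplitude_spec(triple, a), n, rng, moment_match)
            frames.append(
                pd.DataFrame(
                    {
                        "animal_id": ids,
                        "epoch": epoch,
                        "site": site,
                        "systolic[mmHg]": level + (1.0 - a) * amp,
                        "diastolic[mmHg]": level - a * amp,
                        "mean[mmHg]": level,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# traces


def generate_flow_trace(
    tdq_ml_min: float,
    state: str,
    duration_s: float = 60.0,
    rate_hz: float = 100.0,
    rng: np.random.Generator | int | None = 0,
    config: Optional[CohortConfig] = None,
    animal_id: str = "",
) -> HemoTrace:
    """Thoracic-duct flow trace: mean level + cardiac and respiratory
    sinusoids + noise; the post-TR state adds randomized negative troughs
    so the trace crosses zero (retrograde episodes). The trace is
    recentered so its time average equals the configured mean exactly.
    """
    if state not in ("baseline", "post_tr"):
        raise ConfigError("state must be 'baseline' or 'post_tr'")
    if rate_hz <= 0:
        raise ConfigError("sampling rate must be positive")
    if duration_s < 10:
        raise ConfigError("need at least 10 s of flow recording")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    cfg = (config or default_config()).waveform
    p = cfg["flow_baseline"] if state == "baseline" else cfg["flow_post_tr"]
    fc, fr = cfg["heart_rate_hz"], cfg["resp_rate_hz"]

    t = np.arange(0.0, duration_s, 1.0 / rate_hz)
    ph1, ph2 = rng.uniform(0, 2 * math.pi, 2)
    # pulsatility scales with the animal's mean flow: amplitudes in the
    # config are referenced to the group-mean level
    amp_ref = p.get("amp_ref")
    scale = max(tdq_ml_min, 0.0) / amp_ref if amp_ref else 1.0
    noise = rng.normal(0.0, scale * p["noise_sd"], t.size)
    base = (
        scale * p["cardiac_amp"] * np.sin(2 * math.pi * fc * t + ph1)
        + scale * p["resp_amp"] * np.sin(2 * math.pi * fr * t + ph2)
        + noise
    )
    troughs = np.zeros_like(t)
    if state == "post_tr":
        centers = np.arange(0.5 / fc, duration_s, 1.0 / fc)
        keep = rng.uniform(size=centers.size) < p["trough_prob"]
        depths = rng.normal(p["trough_depth"], 0.15 * p["trough_depth"], centers.size)
        w = p["trough_width_s"]
        for c, d_i, k in zip(centers, depths, keep):
            if k and d_i > 0:
                troughs -= d_i * np.exp(-0.5 * ((t - c) / w) ** 2)
    scale = 1.0
    for _ in range(8):
        v = tdq_ml_min + base + scale * troughs
        v = v + (tdq_ml_min - v.mean())  # exact time-average contract
        if state != "post_tr" or v.min() <= -0.5:
            break
        scale *= 1.5
    return HemoTrace(
        site="thoracic_duct_flow", t=t, v=v,
        day=state, animal_id=animal_id, unit="ml/min",
    )


def _pulse_exponent(duty_mean: float) -> float:
    """Exponent k so the time average of cos^(2k) equals the target duty."""
    duty = min(max(duty_mean, 0.08), 0.92)

    def avg(k: float) -> float:
        return math.exp(gammaln(k + 0.5) - 0.5 * math.log(math.pi) - gammaln(k + 1.0))

    return optimize.brentq(lambda k: avg(k) - duty, 1e-3, 60.0, xtol=1e-10)


def generate_pressure_trace(
    systolic: float,
    diastolic: float,
    mean: float,
    site: str,
    duration_s: float = 30.0,
    rate_hz: float = 100.0,
    rng: np.random.Generator | int | None = 0,
    config: Optional[CohortConfig] = None,
    animal_id: str = "",
    day: str = "",
) -> HemoTrace:
    """Pressure trace whose per-cycle extrema and time average reproduce a
    configured systolic/diastolic/mean triple: a cosine-power pulse with
    the exponent solved so the duty cycle hits the mean, plus respiratory
    modulation and measurement noise.
    """
    if rate_hz <= 0:
        raise ConfigError("sampling rate must be positive")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    cfg = (config or default_config()).waveform
    fc, fr = cfg["heart_rate_hz"], cfg["resp_rate_hz"]
    t = np.arange(0.0, duration_s, 1.0 / rate_hz)
    amp = systolic - diastolic
    noise = rng.normal(0.0, cfg["pressure_noise_sd"], t.size)
    if amp <= 0:
        v = mean + noise
    else:
        k = _pulse_exponent((mean - diastolic) / amp)
        ph1, ph2 = rng.uniform(0, 2 * math.pi, 2)
        pulse = np.abs(np.cos(math.pi * fc * t + ph1)) ** (2 * k)
        resp = cfg["resp_fraction"] * amp * np.sin(2 * math.pi * fr * t + ph2)
        v = diastolic + amp * pulse + resp + noise
    return HemoTrace(site=site, t=t, v=v, day=day, animal_id=animal_id, unit="mmHg")


# ---------------------------------------------------------------------------
# lymph-flow time course


def generate_timecourse(
    baseline_ml_min: float,
    config: Optional[CohortConfig] = None,
    rng: np.random.Generator | int | None = None,
    plateau_fold: Optional[float] = None,
    jitter_sd: Optional[float] = None,
) -> pd.DataFrame:
    """Mean lymph flow by study day: a saturating rise anchored at 1-fold
    (day 0) and the configured 1-hour fold, holding the plateau fold from
    the plateau day onward, with optional mean-preserving lognormal jitter.
    """
    if baseline_ml_min <= 0:
        raise ConfigError("baseline flow must be positive")
    tc = (config or default_config()).timecourse
    F = float(plateau_fold if plateau_fold is not None else tc["plateau_fold"])
    f1h = float(tc["fold_1h"])
    t_plateau = float(tc["plateau_day"])
    sd = float(jitter_sd if jitter_sd is not None else tc["jitter_sd"])
    days = np.asarray(tc["days"], dtype=float)
    if F < 1:
        raise ConfigError("plateau fold must be >= 1")
    if F == 1:
        folds = np.ones_like(days)
    else:
        if not 1 <= f1h <= F:
            raise ConfigError("1-hour fold must lie between 1 and the plateau fold")
        t1h = 1.0 / 24.0
        tau = -t1h / math.log(1.0 - (f1h - 1.0) / (F - 1.0)) if f1h > 1 else 1e-9
        folds = np.where(
            days >= t_plateau, F, 1.0 + (F - 1.0) * (1.0 - np.exp(-days / tau))
        )
        folds[np.isclose(days, t1h, rtol=1e-3)] = f1h  # exact 1-hour anchor
    if sd > 0:
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        jitter = np.exp(rng.normal(0.0, sd, days.size) - sd**2 / 2.0)
        jitter[days == 0] = 1.0  # the baseline anchor is measured, not jittered
        folds = folds * jitter
    return pd.DataFrame(
        {"day": days, "fold": folds, "TDQ[ml/min]": baseline_ml_min * folds}
    )


# ---------------------------------------------------------------------------
# pressure-diameter curves


def generate_pd_curve(
    group: str,
    config: Optional[CohortConfig] = None,
    rng: np.random.Generator | int | None = 0,
    animal_id: str = "",
    noise_sd_mm: Optional[float] = None,
) -> PDCurve:
    """Passive P-D curve on the protocol height grid (1..15, 20, 30 cm):
    D(P) = Dmax - (Dmax - D0) exp(-P/k) plus measurement noise, with the
    TR parameter set shifted outward so TR curves dominate control curves
    pointwise.
    """
    cfg = (config or default_config()).pd_curve
    if group not in cfg:
        raise ConfigError(f"no P-D parameters for group {group!r}")
    p = cfg[group]
    d0, dmax, k = float(p["d0_mm"]), float(p["dmax_mm"]), float(p["k_mmhg"])
    if not (0 < d0 < dmax) or k <= 0:
        raise ConfigError("need Dmax > D0 > 0 and k > 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    heights = np.asarray(cfg["heights_cm"], dtype=float)
    noise = float(noise_sd_mm if noise_sd_mm is not None else cfg["noise_sd_mm"])
    size_factor = 1.0 + cfg["animal_cv"] * rng.standard_normal()
    d0_i, dmax_i = d0 * size_factor, dmax * size_factor
    from .pdcurves import heights_to_pressures

    pressures = heights_to_pressures(heights)
    d = dmax_i - (dmax_i - d0_i) * np.exp(-pressures / k)
    if noise > 0:
        d = d + rng.normal(0.0, noise, d.size)
    return PDCurve(heights_cm=heights, diameters_mm=d, group=group, animal_id=animal_id)
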