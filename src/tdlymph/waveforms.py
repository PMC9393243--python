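"""Hemodynamic trace summarization.

Pressure and flow traces are reduced to the triple the field tabulates —
systolic (mean of per-cycle maxima), diastolic (mean of per-cycle minima)
and time-averaged mean — plus, for thoracic-duct flow, the fraction of
time and of transported volume that is retrograde (negative).

Cycle segmentation is deliberately parameter-light: local extrema gated
by a prominence threshold of 20% of the trace's interquartile range, with
a minimum separation of 0.25 s (a swine heart rate below 240 bpm). No ECG
gating is attempted. Constant traces degrade gracefully to a mean-only
summary; non-constant traces in which fewer than two cycles are detected
raise, instructing the caller to record a longer trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .units import Quantity, q

SITES = (
    "artery",
    "jugular_vein",
    "right_atrium",
    "right_ventricle",
    "thoracic_duct_flow",
)

#: cycle-segmentation convention
PROMINENCE_FRACTION = 0.20  # of the interquartile range
MIN_PEAK_SEPARATION_S = 0.25  # swine HR < 240 bpm

_REL_TOL = 1e-6


class TraceError(ValueError):
    """Malformed or insufficient trace."""


@dataclass
class HemoTrace:
    """A uniformly sampled pressure or flow time series at a named site."""

    site: str
    t: np.ndarray  # seconds, strictly increasing, constant step
    v: np.ndarray  # mmHg for pressures, ml/min for flow
    day: str = ""
    animal_id: str = ""
    unit: str = "mmHg"

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise TraceError(f"unknown site {self.site!r}; expected one of {SITES}")
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.v.shape or self.t.size < 2:
            raise TraceError("trace needs matching 1-D time/value arrays (n >= 2)")
        steps = np.diff(self.t)
        dt = steps[0]
        if dt <= 0 or not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
            raise TraceError("time base must be strictly increasing with constant step")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class TraceSummary:
    """Tabulated summary of one trace."""

    mean: float
    systolic: float
    diastolic: float
    n_cycles: int
    unit: str = "mmHg"
    degenerate: bool = False  # constant trace: extrema reported as the mean
    retrograde_time_fraction: Optional[float] = None
    retrograde_volume_fraction: Optional[float] = None
    flags: list = field(default_factory=list)


def summarize_trace(trace: HemoTrace) -> TraceSummary:
    """Mean / systolic / diastolic summary with prominence-gated cycles."""
    v = trace.v
    mean = float(np.mean(v))
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    span = float(np.ptp(v))
    if span <= _REL_TOL * max(1.0, abs(mean)):
        # constant trace: zero detected cycles, extrema degenerate to the mean
        summary = TraceSummary(
            mean=mean, systolic=mean, diastolic=mean, n_cycles=0,
            unit=trace.unit, degenerate=True, flags=["constant-trace"],
        )
    else:
        prominence = PROMINENCE_FRACTION * iqr if iqr > 0 else PROMINENCE_FRACTION * span
        distance = max(1, int(round(MIN_PEAK_SEPARATION_S / trace.dt)))
        peaks, _ = find_peaks(v, prominence=prominence, distance=distance)
        troughs, _ = find_peaks(-v, prominence=prominence, distance=distance)
        n_cycles = int(min(peaks.size, troughs.size))
        if n_cycles < 2:
            raise TraceError(
                "fewer than 2 cardiac cycles detected; record a longer trace "
                "(need at least 2 full cycles for systolic/diastolic extraction)"
            )
        summary = TraceSummary(
            mean=mean,
            systolic=float(np.mean(v[peaks])),
            diastolic=float(np.mean(v[troughs])),
            n_cycles=n_cycles,
            unit=trace.unit,
        )
    if trace.site == "thoracic_duct_flow":
        tf, vf, flags = _retrograde(v)
        summary.retrograde_time_fraction = tf
        summary.retrograde_volume_fraction = vf
        summary.flags.extend(flags)
    return summary


def _retrograde(v: np.ndarray) -> tuple[float, float, list]:
    flags: list = []
    if np.all(v == 0):
        flags.append("all-zero-flow")
        warnings.warn("all-zero flow trace: retrograde fractions reported as 0")
        return 0.0, 0.0, flags
    time_fraction = float(np.mean(v < 0))
    # sample-wise Riemann sums, consistent with the time-fraction definition
    neg = float(np.sum(np.abs(np.minimum(v, 0.0))))
    tot = float(np.sum(np.abs(v)))
    volume_fraction = neg / tot if tot > 0 else 0.0
    return time_fraction, volume_fraction, flags


def retrograde_metrics(trace: HemoTrace) -> tuple[float, float]:
    """(time_fraction, volume_fraction) of retrograde (negative) flow."""
    if trace.site != "thoracic_duct_flow":
        raise TraceError("retrograde metrics are defined for thoracic_duct_flow traces")
    tf, vf, _ = _retrograde(trace.v)
    return tf, vf


#: endpoint for successful tricuspid-regurgitation induction
RV_RA_ENDPOINT_MMHG = 2.0


def rv_ra_gradient(rv: HemoTrace, ra: HemoTrace) -> tuple[Quantity, bool]:
    """Mean right-ventricle minus right-atrium pressure, and the TR endpoint.

    The induction endpoint is reached when the mean gradient drops below
    2 mmHg (from the ~6 mmHg of a competent tricuspid valve).
    """
    if rv.t.size != ra.t.size or abs(rv.dt - ra.dt) > 1e-9 * rv.dt or abs(
        rv.t[0] - ra.t[0]
    ) > 1e-9:
        raise TraceError("RV and RA traces must share an identical time base")
    gradient = float(np.mean(rv.v) - np.mean(ra.v))
    return q(gradient, "mmHg"), gradient < RV_RA_ENDPOINT_MMHG
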