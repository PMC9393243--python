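"""Ex vivo pressure-diameter curve processing.

The passive test raises a fluid column in 1 cm increments to 15 cm and
then to 20 and 30 cm; intraluminal pressure is the hydrostatic head
(1 cmH2O = 98.0665 Pa), reported in mmHg. The module builds D(P) and
diameter-ratio (stretch) curves and a secant compliance over a pressure
window, with linear interpolation between measured points and no
smoothing or constitutive fitting — the relationship is reported raw,
as measured in the calcium-free (passive) bath.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import as_si

#: protocol column heights, cm of water
PROTOCOL_HEIGHTS_CM = tuple(range(1, 16)) + (20, 30)


class PDCurveError(ValueError):
    pass


def heights_to_pressures(heights_cm: np.ndarray | list) -> np.ndarray:
    """Column heights (cmH2O) to intraluminal pressures in mmHg."""
    h = np.asarray(heights_cm, dtype=float)
    if np.any(h < 0):
        raise PDCurveError("column heights must be non-negative")
    return h * as_si(1.0, "cmH2O") / as_si(1.0, "mmHg")


@dataclass
class PDCurve:
    """Ordered (column height, outer diameter) pairs for one vessel."""

    heights_cm: np.ndarray
    diameters_mm: np.ndarray
    group: str = "control"
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.heights_cm = np.asarray(self.heights_cm, dtype=float)
        self.diameters_mm = np.asarray(self.diameters_mm, dtype=float)
        if self.heights_cm.shape != self.diameters_mm.shape or self.heights_cm.ndim != 1:
            raise PDCurveError("heights and diameters must be matching 1-D arrays")
        if self.heights_cm.size < 2:
            raise PDCurveError("need at least two points")
        if np.any(np.diff(self.heights_cm) <= 0):
            raise PDCurveError("column heights must be strictly increasing")
        if np.any(self.diameters_mm <= 0):
            raise PDCurveError("diameters must be positive")

    @property
    def pressures_mmhg(self) -> np.ndarray:
        return heights_to_pressures(self.heights_cm)

    @property
    def reference_diameter(self) -> float:
        """Outer diameter at the lowest pressure."""
        return float(self.diameters_mm[0])


def diameter_ratio_curve(curve: PDCurve) -> tuple[np.ndarray, np.ndarray]:
    """(pressure mmHg, D/D_ref) pairs; the first ratio is 1 by construction."""
    return curve.pressures_mmhg, curve.diameters_mm / curve.reference_diameter


def diameter_at(curve: PDCurve, pressure_mmhg: float) -> float:
    """Linearly interpolated outer diameter (mm); no extrapolation."""
    p = curve.pressures_mmhg
    if pressure_mmhg < p[0] - 1e-12 or pressure_mmhg > p[-1] + 1e-12:
        raise PDCurveError(
            f"pressure {pressure_mmhg:g} mmHg outside measured range "
            f"[{p[0]:g}, {p[-1]:g}]; extrapolation is not performed"
        )
    return float(np.interp(pressure_mmhg, p, curve.diameters_mm))


def secant_compliance(curve: PDCurve, p_lo: float, p_hi: float) -> float:
    """Secant compliance (D(P_hi)-D(P_lo))/(P_hi-P_lo) in mm/mmHg."""
    if not p_lo < p_hi:
        raise PDCurveError("need p_lo < p_hi")
    return (diameter_at(curve, p_hi) - diameter_at(curve, p_lo)) / (p_hi - p_lo)


def mean_group_curve(curves: list[PDCurve]) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean diameter across animals sharing the protocol grid."""
    if not curves:
        raise PDCurveError("no curves")
    grid = curves[0].heights_cm
    for c in curves[1:]:
        if c.heights_cm.shape != grid.shape or not np.allclose(c.heights_cm, grid):
            raise PDCurveError("curves do not share a common height grid")
    stack = np.vstack([c.diameters_mm for c in curves])
    return heights_to_pressures(grid), stack.mean(axis=0)
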