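"""Vessel-wall biomechanics of the thoracic duct.

Three classical relations drive the remodeling analysis:

* Poiseuille wall shear stress for laminar flow in a circular tube,
  tau = 32 mu Q / (pi D_i^3);
* the incompressibility (constant wall volume) condition for a cylinder,
  D_i = sqrt(D_o^2 - 4 A_o / (pi lambda)), which recovers the loaded inner
  diameter from the loaded outer diameter, the no-load wall cross-sectional
  area and the axial stretch ratio;
* the thin-wall Laplace hoop stress, sigma = P_i r / h.

All inputs are :class:`~tdlymph.units.Quantity` values; each function
normalizes to SI on entry. Lymph viscosity is never hard-coded: the
conventional water-like default of 1 cP lives in the cohort config and is
threaded through explicitly.

The ``as-printed`` stress convention (sigma = P_i h / r) is retained only
to document a dimensionally inconsistent variant of the hoop-stress
formula that circulates in the source literature; it cannot produce
kilopascal-scale stresses at thoracic-duct geometry and is not the
default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .units import Quantity, q, round_sig


class DomainError(ValueError):
    """A physically inadmissible input (non-positive length, negative radicand...)."""


#: default lymph viscosity — water-like lymph, overridable everywhere
DEFAULT_MU = q(1.0, "cP")

STRESS_CONVENTIONS = ("laplace", "as-printed")


@dataclass
class MorphometryRecord:
    """Per-vessel geometric state at a named load state.

    ``D_i`` and ``h`` may be omitted and derived: ``D_i`` from the
    incompressibility condition (needs ``A_o`` and ``lam``) or from
    ``D_o - 2h``; ``h`` from ``(D_o - D_i)/2``.
    """

    animal_id: str
    D_o: Quantity
    D_i: Optional[Quantity] = None
    h: Optional[Quantity] = None
    A_o: Optional[Quantity] = None
    lam: float = 1.0  # axial stretch ratio l/l_o
    state: str = "loaded"

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise DomainError(f"{self.animal_id}: axial stretch must be positive")
        if self.D_i is not None and self.D_i.si_value > self.D_o.si_value + 1e-12:
            raise DomainError(f"{self.animal_id}: D_i exceeds D_o")
        if self.D_i is not None and self.h is not None:
            implied = (self.D_o.si_value - self.D_i.si_value) / 2.0
            if abs(implied - self.h.si_value) > 5e-6:  # 5e-3 mm
                raise DomainError(
                    f"{self.animal_id}: h inconsistent with (D_o - D_i)/2 "
                    f"beyond 5e-3 mm"
                )

    def resolved(self) -> "MorphometryRecord":
        """Return a copy with D_i and h filled in where derivable."""
        D_i, h = self.D_i, self.h
        if D_i is None and self.A_o is not None:
            D_i = inner_diameter(self.D_o, self.A_o, self.lam, record_id=self.animal_id)
        if D_i is None and h is not None:
            D_i = q(self.D_o.to("mm").value - 2.0 * h.to("mm").value, "mm")
        if h is None and D_i is not None:
            h = wall_thickness(self.D_o, D_i)
        return MorphometryRecord(self.animal_id, self.D_o, D_i, h, self.A_o, self.lam, self.state)


@dataclass
class BiomechResult:
    """Computed stresses for one record, with units made explicit."""

    animal_id: str
    wss_dyn_cm2: Quantity
    wss_pa: Quantity
    cws_kpa: Quantity
    P_i: Quantity
    Q: Quantity
    mu: Quantity
    r: Quantity
    D_i: Quantity
    h: Quantity
    retrograde: bool = field(default=False)


def wall_shear_stress(Q: Quantity, D_i: Quantity, mu: Quantity = DEFAULT_MU) -> Quantity:
    """Poiseuille wall shear stress, returned in Pa.

    The sign follows the flow: retrograde (negative) flow gives negative
    shear, flagged downstream.
    """
    d = D_i.si_value
    m = mu.si_value
    if d <= 0:
        raise DomainError("inner diameter must be positive")
    if m <= 0:
        raise DomainError("viscosity must be positive")
    tau = 32.0 * m * Q.si_value / (math.pi * d**3)
    return q(tau, "Pa")


def inner_diameter(
    D_o: Quantity, A_o: Quantity, lam: float, record_id: str | None = None
) -> Quantity:
    """Loaded inner diameter from the incompressibility condition.

    D_i = sqrt(D_o^2 - 4 A_o / (pi lambda)); a negative radicand flags
    physically inconsistent morphometry and raises naming the record.
    """
    if lam <= 0:
        raise DomainError("axial stretch ratio must be positive")
    do = D_o.si_value
    radicand = do**2 - 4.0 * A_o.si_value / (math.pi * lam)
    if radicand < 0:
        who = f" (record {record_id})" if record_id else ""
        raise DomainError(
            f"incompressibility radicand negative{who}: wall area too large "
            f"for the stated outer diameter and stretch"
        )
    return q(math.sqrt(radicand) / 1e-3, "mm")


def circumferential_wall_stress(
    P_i: Quantity, r: Quantity, h: Quantity, convention: str = "laplace"
) -> Quantity:
    """Mean hoop stress in the wall, returned in kPa.

    ``laplace`` (default) is the thin-wall form sigma = P_i r / h; the
    ``as-printed`` variant sigma = P_i h / r is kept only for documenting
    its inconsistency (it yields stresses below the pressure itself for
    thin walls).
    """
    if convention not in STRESS_CONVENTIONS:
        raise ValueError(f"convention must be one of {STRESS_CONVENTIONS}")
    rr = r.si_value
    hh = h.si_value
    if rr <= 0:
        raise DomainError("inner radius must be positive")
    if hh <= 0:
        raise DomainError("wall thickness must be positive")
    p = P_i.si_value
    sigma = p * rr / hh if convention == "laplace" else p * hh / rr
    return q(sigma / 1e3, "kPa")


def wall_thickness(D_o: Quantity, D_i: Quantity) -> Quantity:
    """h = (D_o - D_i)/2, in mm."""
    do = D_o.to("mm").value
    di = D_i.to("mm").value
    if do < di:
        raise DomainError("outer diameter smaller than inner diameter")
    return q((do - di) / 2.0, "mm")


def analyze_record(
    record: MorphometryRecord,
    P_i: Quantity,
    Q: Quantity,
    mu: Quantity = DEFAULT_MU,
    convention: str = "laplace",
) -> BiomechResult:
    """Full per-vessel biomechanics: derive missing geometry, then both stresses."""
    rec = record.resolved()
    if rec.D_i is None or rec.h is None:
        raise DomainError(
            f"{record.animal_id}: cannot derive inner diameter/wall thickness "
            f"(need D_i, h, or A_o with lambda)"
        )
    tau_pa = wall_shear_stress(Q, rec.D_i, mu)
    r = q(rec.D_i.to("mm").value / 2.0, "mm")
    sigma = circumferential_wall_stress(P_i, r, rec.h, convention=convention)
    return BiomechResult(
        animal_id=rec.animal_id,
        wss_dyn_cm2=tau_pa.to("dyn/cm2"),
        wss_pa=tau_pa,
        cws_kpa=sigma,
        P_i=P_i,
        Q=Q,
        mu=mu,
        r=r,
        D_i=rec.D_i,
        h=rec.h,
        retrograde=Q.si_value < 0,
    )


@dataclass
class RemodelingRatios:
    """Per-variable TR/control ratios under the ratio-of-group-means convention."""

    ratios: dict[str, float]
    display: dict[str, float]  # half-up at 2 significant figures

    def __getitem__(self, variable: str) -> float:
        return self.ratios[variable]


def remodeling_ratios(
    control: Mapping[str, float], tr: Mapping[str, float]
) -> RemodelingRatios:
    """Ratio of TR group mean to control group mean, per shared variable.

    This is the deterministic ratio-of-group-means convention. When paired
    per-animal data exist, the mean-of-per-animal-ratios convention is also
    computable (see :func:`per_animal_ratio_summary`); the two differ for
    skewed variables such as baseline lymph flow.
    """
    if set(control) != set(tr):
        raise DomainError(
            f"variable sets differ: {sorted(set(control) ^ set(tr))}"
        )
    ratios: dict[str, float] = {}
    for name, c in control.items():
        if c == 0:
            raise DomainError(f"zero control mean for {name!r}")
        ratios[name] = tr[name] / c
    display = {name: round_sig(v, 2) for name, v in ratios.items()}
    return RemodelingRatios(ratios=ratios, display=display)


def per_animal_ratio_summary(baseline: Mapping[str, float] | list, day28: list) -> tuple[float, float]:
    """Mean and SD of per-animal after/before ratios for one variable.

    Accepts two equal-length sequences of paired per-animal values.
    """
    import numpy as np

    b = np.asarray(baseline, dtype=float)
    a = np.asarray(day28, dtype=float)
    if b.shape != a.shape or b.ndim != 1 or b.size == 0:
        raise DomainError("paired value lists must be equal-length and non-empty")
    if np.any(b == 0):
        raise DomainError("zero baseline value in per-animal ratio")
    r = a / b
    sd = float(np.std(r, ddof=1)) if r.size > 1 else float("nan")
    return float(np.mean(r)), sd
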