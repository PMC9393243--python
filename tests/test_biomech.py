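"""Wall biomechanics: Poiseuille shear, incompressibility, Laplace stress."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tdlymph.biomech import (
    DomainError,
    MorphometryRecord,
    analyze_record,
    circumferential_wall_stress,
    inner_diameter,
    per_animal_ratio_summary,
    remodeling_ratios,
    wall_shear_stress,
    wall_thickness,
)
from tdlymph.units import q, round_half_up


def cgs_wss(q_ml_min: float, d_mm: float, mu_cp: float) -> float:
    """Independent oracle: evaluate 32*mu*Q/(pi*D^3) directly in cgs units."""
    q_cm3_s = q_ml_min / 60.0
    mu_poise = mu_cp / 100.0
    d_cm = d_mm / 10.0
    return 32.0 * mu_poise * q_cm3_s / (math.pi * d_cm**3)  # dyn/cm^2


class TestWallShearStress:
    def test_zero_flow(self):
        assert wall_shear_stress(q(0, "ml/min"), q(3.0, "mm"), q(1, "cP")).value == 0.0

    def test_control_group_values(self):
        # control lymph flow through the control lumen at water-like viscosity
        tau = wall_shear_stress(q(0.78, "ml/min"), q(3.23, "mm"), q(1, "cP"))
        assert tau.to("dyn/cm2").value == pytest.approx(0.0393, abs=1e-4)
        assert tau.value == pytest.approx(3.93e-3, abs=1e-5)  # Pa

    def test_cubic_diameter_scaling(self):
        t1 = wall_shear_stress(q(5, "ml/min"), q(2, "mm"), q(1, "cP")).value
        t2 = wall_shear_stress(q(5, "ml/min"), q(4, "mm"), q(1, "cP")).value
        assert t1 == pytest.approx(8 * t2, rel=1e-12)

    def test_sign_follows_flow(self):
        tau = wall_shear_stress(q(-2, "ml/min"), q(3, "mm"), q(1, "cP"))
        assert tau.value < 0

    @pytest.mark.parametrize("d, mu", [(0.0, 1.0), (-1.0, 1.0), (3.0, 0.0), (3.0, -2.0)])
    def test_domain_errors(self, d, mu):
        with pytest.raises(DomainError):
            wall_shear_stress(q(1, "ml/min"), q(d, "mm"), q(mu, "cP"))

    @given(
        flow=st.floats(-20, 20),
        d=st.floats(0.5, 6.0),
        mu=st.floats(0.5, 2.0),
    )
    def test_agrees_with_cgs_oracle(self, flow, d, mu):
        tau = wall_shear_stress(q(flow, "ml/min"), q(d, "mm"), q(mu, "cP"))
        expected = cgs_wss(flow, d, mu)
        assert tau.to("dyn/cm2").value == pytest.approx(expected, rel=1e-9, abs=1e-15)


class TestInnerDiameter:
    def test_zero_wall_area(self):
        assert inner_diameter(q(3.0, "mm"), q(0, "mm2"), 1.0).value == pytest.approx(3.0)

    def test_round_trip_from_group_diameters(self):
        a_o = math.pi * (4.32**2 - 3.81**2) / 4.0  # = 3.2565 mm^2 at lambda 1
        d_i = inner_diameter(q(4.32, "mm"), q(a_o, "mm2"), 1.0)
        assert d_i.value == pytest.approx(3.81, rel=1e-12)

    def test_monotone_in_axial_stretch(self):
        a_o = q(2.0, "mm2")
        d1 = inner_diameter(q(4.0, "mm"), a_o, 1.0).value
        d2 = inner_diameter(q(4.0, "mm"), a_o, 2.0).value
        assert d2 > d1

    def test_negative_radicand_names_record(self):
        with pytest.raises(DomainError, match="pig-7"):
            inner_diameter(q(1.0, "mm"), q(10.0, "mm2"), 1.0, record_id="pig-7")

    @given(
        d_o=st.floats(0.5, 10.0),
        ratio=st.floats(0.05, 0.99),
        lam=st.floats(0.5, 2.0),
    )
    def test_incompressibility_round_trip(self, d_o, ratio, lam):
        d_i_true = d_o * ratio
        a_o = math.pi * lam * (d_o**2 - d_i_true**2) / 4.0
        d_i = inner_diameter(q(d_o, "mm"), q(a_o, "mm2"), lam)
        assert d_i.value == pytest.approx(d_i_true, rel=1e-9)


class TestCircumferentialWallStress:
    def test_zero_pressure(self):
        assert circumferential_wall_stress(q(0, "mmHg"), q(1, "mm"), q(0.1, "mm")).value == 0

    def test_control_geometry_laplace_value(self):
        # 8.2 mmHg across a 1.615 mm lumen with a 0.06 mm wall
        sigma = circumferential_wall_stress(q(8.2, "mmHg"), q(1.615, "mm"), q(0.06, "mm"))
        assert sigma.unit == "kPa"
        assert sigma.value == pytest.approx(29.4, abs=0.05)

    def test_halving_thickness_doubles_stress(self):
        s1 = circumferential_wall_stress(q(10, "mmHg"), q(2, "mm"), q(0.2, "mm")).value
        s2 = circumferential_wall_stress(q(10, "mmHg"), q(2, "mm"), q(0.1, "mm")).value
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    @given(
        p=st.floats(0.1, 50.0), r=st.floats(0.2, 5.0), h=st.floats(0.01, 1.0)
    )
    def test_dimensional_identity(self, p, r, h):
        # sigma * h / r must recover the pressure exactly
        sigma = circumferential_wall_stress(q(p, "mmHg"), q(r, "mm"), q(h, "mm"))
        back = sigma.si_value * (h / r)
        assert back == pytest.approx(q(p, "mmHg").si_value, rel=1e-12)

    def test_as_printed_convention_is_inverted(self):
        lap = circumferential_wall_stress(q(10, "mmHg"), q(2, "mm"), q(0.2, "mm"))
        inv = circumferential_wall_stress(
            q(10, "mmHg"), q(2, "mm"), q(0.2, "mm"), convention="as-printed"
        )
        assert inv.value == pytest.approx(lap.value / 100.0, rel=1e-9)
        with pytest.raises(ValueError):
            circumferential_wall_stress(q(1, "mmHg"), q(1, "mm"), q(1, "mm"), convention="x")

    @pytest.mark.parametrize("r, h", [(0.0, 0.1), (1.0, 0.0), (-1.0, 0.1), (1.0, -0.1)])
    def test_domain_errors(self, r, h):
        with pytest.raises(DomainError):
            circumferential_wall_stress(q(5, "mmHg"), q(r, "mm"), q(h, "mm"))


class TestWallThickness:
    @pytest.mark.parametrize(
        ("d_o", "d_i", "expected_2dp"),
        [(3.35, 3.23, 0.06), (4.32, 3.81, 0.26), (2.0, 2.0, 0.0)],
    )
    def test_printed_precision(self, d_o, d_i, expected_2dp):
        h = wall_thickness(q(d_o, "mm"), q(d_i, "mm"))
        assert round_half_up(h.value, 2) == expected_2dp

    def test_rejects_inverted_diameters(self):
        with pytest.raises(DomainError):
            wall_thickness(q(3.0, "mm"), q(3.5, "mm"))


class TestRemodelingRatios:
    def test_group_mean_ratios_at_display_precision(self):
        control = {"D_o": 3.35, "D_i": 3.23, "TDP": 8.2, "sigma": 19.5}
        tr = {"D_o": 4.32, "D_i": 3.81, "TDP": 14.6, "sigma": 10.3}
        r = remodeling_ratios(control, tr)
        assert r.display == {"D_o": 1.3, "D_i": 1.2, "TDP": 1.8, "sigma": 0.53}

    def test_identical_groups_give_unity(self):
        g = {"a": 2.0, "b": 5.0}
        assert all(v == 1.0 for v in remodeling_ratios(g, dict(g)).ratios.values())

    def test_zero_control_mean_rejected(self):
        with pytest.raises(DomainError):
            remodeling_ratios({"a": 0.0}, {"a": 1.0})

    def test_mismatched_variable_sets_rejected(self):
        with pytest.raises(DomainError):
            remodeling_ratios({"a": 1.0}, {"b": 1.0})

    def test_per_animal_ratio_summary(self):
        mean, sd = per_animal_ratio_summary([1.0, 2.0], [3.0, 8.0])
        assert mean == pytest.approx(3.5)
        assert sd == pytest.approx(np.std([3.0, 4.0], ddof=1))


class TestMorphometryRecord:
    def test_inconsistent_thickness_rejected(self):
        with pytest.raises(DomainError, match="inconsistent"):
            MorphometryRecord("a1", D_o=q(4.0, "mm"), D_i=q(3.0, "mm"), h=q(0.7, "mm"))

    def test_resolution_from_wall_area(self):
        a_o = math.pi * 1.2 * (4.0**2 - 3.0**2) / 4.0
        rec = MorphometryRecord("a2", D_o=q(4.0, "mm"), A_o=q(a_o, "mm2"), lam=1.2)
        res = rec.resolved()
        assert res.D_i.value == pytest.approx(3.0, rel=1e-12)
        assert res.h.value == pytest.approx(0.5, rel=1e-12)

    def test_analyze_record_flags_retrograde(self):
        rec = MorphometryRecord("a3", D_o=q(4.0, "mm"), D_i=q(3.0, "mm"))
        result = analyze_record(rec, P_i=q(10, "mmHg"), Q=q(-1, "ml/min"))
        assert result.retrograde
        assert result.wss_pa.value < 0
        assert result.cws_kpa.value > 0
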