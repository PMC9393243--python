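"""Synthetic cohort generator: determinism, moment contracts, trace/curve shapes."""

import numpy as np
import pandas as pd
import pytest

from tdlymph.biomech import inner_diameter
from tdlymph.synth import (
    CohortConfig,
    ConfigError,
    VariableSpec,
    draw_variable,
    generate_cohort,
    generate_flow_trace,
    generate_pd_curve,
    generate_pressure_cohort,
    generate_timecourse,
)
from tdlymph.units import q

DIRECT_VARS = ("D_o", "h", "TDQ", "TDP", "CC", "RV_mass", "LV_mass")


def group_slice(cohort, group, phase):
    return cohort[(cohort["group"] == group) & (cohort["phase"] == phase)]


class TestDeterminism:
    def test_same_seed_same_table(self, cfg):
        a = generate_cohort(cfg, seed=123)
        b = generate_cohort(cfg, seed=123)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self, cfg):
        a = generate_cohort(cfg, seed=1, moment_match="population")
        b = generate_cohort(cfg, seed=2, moment_match="population")
        assert not a["TDQ[ml/min]"].equals(b["TDQ[ml/min]"])


class TestMomentContracts:
    def test_zero_sd_single_animal_reproduces_means(self, cfg_dict):
        for group in cfg_dict["cohort"].values():
            for spec in group.values():
                spec["sd"] = 0.0
        cfg_dict["tdq_fold"]["sd"] = 0.0
        cfg_dict["n_per_group"] = 1
        cohort = generate_cohort(CohortConfig.from_dict(cfg_dict), seed=0)
        row = group_slice(cohort, "control", "terminal").iloc[0]
        assert row["D_o[mm]"] == 3.35
        assert row["TDQ[ml/min]"] == 0.78
        assert row["TDP[mmHg]"] == 8.2

    def test_sample_moments_match_exactly(self, cfg):
        cohort = generate_cohort(cfg, seed=5, n_per_group=50)
        for group, phase in (("control", "terminal"), ("tr", "day28")):
            sub = group_slice(cohort, group, phase)
            for name in DIRECT_VARS:
                spec = cfg.cohort[group][name]
                col = [c for c in cohort.columns if c.startswith(f"{name}[")][0]
                assert sub[col].mean() == pytest.approx(spec.mean, rel=1e-9)
                assert sub[col].std(ddof=1) == pytest.approx(spec.sd, rel=1e-6)
                if spec.lower is not None:
                    assert sub[col].min() >= spec.lower - 1e-9

    def test_population_mode_is_unbiased_at_large_n(self, cfg):
        cohort = generate_cohort(cfg, seed=7, n_per_group=4000, moment_match="population")
        sub = group_slice(cohort, "control", "terminal")
        # distributional draws: moments agree within sampling error
        assert sub["TDQ[ml/min]"].mean() == pytest.approx(0.78, rel=0.10)
        assert sub["D_o[mm]"].mean() == pytest.approx(3.35, rel=0.01)

    def test_infeasible_config_rejected(self):
        with pytest.raises(ConfigError, match="infeasible"):
            VariableSpec(mean=-1.0, sd=0.0, lower=0.0)

    def test_bad_moment_match_mode_rejected(self, rng):
        with pytest.raises(ConfigError):
            draw_variable(VariableSpec(1.0, 0.5, lower=0.0), 5, rng, moment_match="x")


class TestGeometryConsistency:
    def test_within_animal_identities(self, cfg):
        cohort = generate_cohort(cfg, seed=3, n_per_group=40)
        np.testing.assert_allclose(
            cohort["h[mm]"], (cohort["D_o[mm]"] - cohort["D_i[mm]"]) / 2, rtol=0, atol=1e-12
        )
        assert (cohort["D_i[mm]"] > 0).all()
        assert cohort["lambda"].between(*cfg.lambda_range).all()

    def test_wall_area_round_trips_through_incompressibility(self, cfg):
        cohort = generate_cohort(cfg, seed=3, n_per_group=10)
        for _, r in cohort.iterrows():
            d_i = inner_diameter(q(r["D_o[mm]"], "mm"), q(r["A_o[mm2]"], "mm2"), r["lambda"])
            assert d_i.value == pytest.approx(r["D_i[mm]"], rel=1e-9)

    def test_flow_fold_pairing(self, cfg):
        cohort = generate_cohort(cfg, seed=9)
        base = group_slice(cohort, "tr", "baseline").set_index("animal_id")
        day28 = group_slice(cohort, "tr", "day28").set_index("animal_id")
        ratio = day28["TDQ[ml/min]"] / base.loc[day28.index, "TDQ[ml/min]"]
        np.testing.assert_allclose(ratio, day28["tdq_fold"], rtol=1e-9)


class TestPressureCohort:
    def test_triple_means_reproduced(self, cfg):
        table = generate_pressure_cohort(cfg, seed=4, n_per_group=100)
        for epoch, sites in cfg.pressure_triples.items():
            for site, triple in sites.items():
                sub = table[(table["epoch"] == epoch) & (table["site"] == site)]
                assert sub["systolic[mmHg]"].mean() == pytest.approx(triple["sys"][0], abs=1e-6)
                assert sub["diastolic[mmHg]"].mean() == pytest.approx(triple["dia"][0], abs=1e-6)
                assert sub["mean[mmHg]"].mean() == pytest.approx(triple["mean"][0], abs=1e-6)

    def test_ordering_within_animal(self, cfg):
        table = generate_pressure_cohort(cfg, seed=4, n_per_group=50)
        assert (table["systolic[mmHg]"] >= table["mean[mmHg]"]).all()
        assert (table["mean[mmHg]"] >= table["diastolic[mmHg]"]).all()


class TestTimecourse:
    def test_zero_jitter_hits_published_anchors(self, cfg):
        tc = generate_timecourse(0.78, cfg, jitter_sd=0)
        folds = tc["fold"].to_numpy()
        assert folds[0] == 1.0
        assert folds[1] == 3.0  # one hour post induction
        np.testing.assert_allclose(folds[3:], 10.0)  # plateau from day 2
        assert 3.0 < folds[2] <= 10.0  # day 1 sits on the rising limb

    def test_plateau_scaling(self, cfg):
        tc = generate_timecourse(0.78, cfg, jitter_sd=0, plateau_fold=12.0)
        assert tc["TDQ[ml/min]"].iloc[-1] == pytest.approx(9.36)

    def test_unity_plateau_is_flat(self, cfg):
        tc = generate_timecourse(1.0, cfg, jitter_sd=0, plateau_fold=1.0)
        np.testing.assert_allclose(tc["fold"], 1.0)

    def test_invalid_parameters_rejected(self, cfg):
        with pytest.raises(ConfigError):
            generate_timecourse(0.0, cfg)
        with pytest.raises(ConfigError):
            generate_timecourse(1.0, cfg, plateau_fold=0.5)

    def test_jitter_preserves_baseline_anchor(self, cfg, rng):
        tc = generate_timecourse(0.78, cfg, rng=rng, jitter_sd=0.2)
        assert tc["fold"].iloc[0] == 1.0
        assert not np.allclose(tc["fold"].iloc[3:], 10.0)


class TestFlowTraces:
    def test_quiet_trace_is_constant(self, cfg_dict, rng):
        cfg_dict["waveform"]["flow_baseline"] = {
            "cardiac_amp": 0.0, "resp_amp": 0.0, "noise_sd": 0.0,
        }
        trace = generate_flow_trace(
            0.78, "baseline", 10.0, 50.0, rng=rng, config=CohortConfig.from_dict(cfg_dict)
        )
        np.testing.assert_allclose(trace.v, 0.78)

    def test_time_average_contract(self, cfg, rng):
        for state, level in (("baseline", 0.78), ("post_tr", 9.34)):
            trace = generate_flow_trace(level, state, 60.0, 100.0, rng=rng, config=cfg)
            assert trace.v.mean() == pytest.approx(level, rel=1e-9)

    def test_post_tr_crosses_zero(self, cfg, rng):
        trace = generate_flow_trace(9.34, "post_tr", 30.0, 100.0, rng=rng, config=cfg)
        assert trace.v.min() < 0 < trace.v.max()

    def test_preconditions(self, cfg, rng):
        with pytest.raises(ConfigError, match="10 s"):
            generate_flow_trace(1.0, "baseline", 5.0, 100.0, rng=rng, config=cfg)
        with pytest.raises(ConfigError):
            generate_flow_trace(1.0, "baseline", 30.0, 0.0, rng=rng, config=cfg)
        with pytest.raises(ConfigError):
            generate_flow_trace(1.0, "mid", 30.0, 100.0, rng=rng, config=cfg)


class TestPDCurveGenerator:
    def test_noise_free_curves_are_monotone(self, cfg, rng):
        c = generate_pd_curve("control", cfg, rng, noise_sd_mm=0.0)
        assert np.all(np.diff(c.diameters_mm) > 0)

    def test_diameter_saturates_below_dmax(self, cfg, rng):
        c = generate_pd_curve("control", cfg, rng, noise_sd_mm=0.0)
        # per-animal size jitter rescales dmax; the curve must stay below it
        assert c.diameters_mm[-1] < cfg.pd_curve["control"]["dmax_mm"] * 1.3

    def test_tr_dominates_control_pointwise(self, cfg):
        rng = np.random.default_rng(0)
        c = generate_pd_curve("control", cfg, rng, noise_sd_mm=0.0)
        t = generate_pd_curve("tr", cfg, rng, noise_sd_mm=0.0)
        assert np.all(t.diameters_mm > c.diameters_mm)

    def test_invalid_parameters_rejected(self, cfg_dict, rng):
        cfg_dict["pd_curve"]["control"]["d0_mm"] = 5.0  # above dmax
        with pytest.raises(ConfigError):
            generate_pd_curve("control", CohortConfig.from_dict(cfg_dict), rng)
        with pytest.raises(ConfigError):
            generate_pd_curve("sham", CohortConfig.from_dict(cfg_dict), rng)
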