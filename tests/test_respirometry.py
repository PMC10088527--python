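"""Respirometry stage: cycle segmentation, slope fitting, solubility, MO2."""

import numpy as np
import pandas as pd
import pytest

from respicard import respirometry as resp
from respicard import synthetic_data as sd


def linear_trace(duration_s=3600.0, dt=1.0, slope=-0.01, start=100.0, rng=None, noise=0.0):
    t = np.arange(0.0, duration_s, dt)
    y = start + slope * t
    if noise:
        y = y + (rng or np.random.default_rng(0)).normal(0, noise, len(t))
    return pd.DataFrame({"time_s": t, "sat": y})


class TestSegmentCycles:
    def test_hour_long_trace_yields_six_cycles(self):
        trace = linear_trace(3600.0)
        sched = resp.make_schedule(3600.0, flush_s=240.0, measure_s=360.0)
        cycles, excluded = resp.segment_cycles(trace, sched)
        assert len(cycles) == 6
        assert excluded == []
        # flush samples are discarded: each cycle holds only its sealed window
        for c in cycles:
            assert c.time_s.min() >= c.start_s
            assert c.time_s.max() < c.end_s

    def test_empty_trace_yields_empty_list(self):
        trace = pd.DataFrame({"time_s": [], "sat": []})
        sched = resp.make_schedule(3600.0, 240.0, 360.0)
        cycles, excluded = resp.segment_cycles(trace, sched)
        assert cycles == [] and excluded == []

    def test_cycle_straddling_chase_is_excluded_and_logged(self):
        trace = linear_trace(3600.0)
        sched = resp.make_schedule(3600.0, 240.0, 360.0)
        chase = float(sched.loc[2, "measure_start_s"]) + 10.0
        cycles, excluded = resp.segment_cycles(trace, sched, chase_time_s=chase)
        assert len(cycles) == 5
        assert excluded == [{"cycle": 2, "reason": "straddles_chase"}]

    def test_malformed_schedule_raises(self):
        trace = linear_trace(600.0)
        with pytest.raises(ValueError):
            resp.segment_cycles(trace, pd.DataFrame({"foo": [1]}))


class TestFitSlope:
    def test_perfect_linear_decline(self):
        trace = linear_trace(600.0, slope=-0.01)
        sched = resp.make_schedule(600.0, 120.0, 480.0)
        (cycle,), _ = resp.segment_cycles(trace, sched)
        fit = resp.fit_slope(cycle, head_exclusion_s=45.0)
        assert fit.alpha == pytest.approx(-0.01, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0)
        assert 30.0 <= fit.excluded_head_s <= 60.0

    def test_constant_saturation_has_undefined_r2_and_is_filtered(self):
        trace = linear_trace(600.0, slope=0.0)
        sched = resp.make_schedule(600.0, 120.0, 480.0)
        (cycle,), _ = resp.segment_cycles(trace, sched)
        fit = resp.fit_slope(cycle)
        assert fit.alpha == pytest.approx(0.0)
        assert np.isnan(fit.r2)
        accepted, rejected = resp.filter_slopes([fit])
        assert accepted == [] and rejected[0][1] == "low_r2"

    def test_noisy_decline_recovers_slope(self):
        rng = np.random.default_rng(11)
        trace = linear_trace(600.0, slope=-0.008, noise=0.2, rng=rng)
        sched = resp.make_schedule(600.0, 120.0, 480.0)
        (cycle,), _ = resp.segment_cycles(trace, sched)
        fit = resp.fit_slope(cycle)
        # OLS standard error ~ noise / (sd(t) * sqrt(n)); 4 se band
        se = 0.2 / (np.std(cycle.time_s[45:]) * np.sqrt(fit.n_points))
        assert abs(fit.alpha - (-0.008)) < 4 * se

    def test_head_exclusion_outside_bounds_rejected(self):
        trace = linear_trace(600.0)
        sched = resp.make_schedule(600.0, 120.0, 480.0)
        (cycle,), _ = resp.segment_cycles(trace, sched)
        with pytest.raises(ValueError):
            resp.fit_slope(cycle, head_exclusion_s=10.0)

    def test_too_few_samples_raises(self):
        trace = linear_trace(600.0, dt=60.0)
        sched = resp.make_schedule(600.0, 120.0, 480.0)
        (cycle,), _ = resp.segment_cycles(trace, sched)
        with pytest.raises(ValueError, match="samples"):
            resp.fit_slope(cycle)

    def test_sampling_density_does_not_move_slope(self):
        sched = resp.make_schedule(600.0, 120.0, 480.0)
        fits = []
        for dt in (2.0, 1.0, 0.5):
            rng = np.random.default_rng(3)
            trace = linear_trace(600.0, dt=dt, slope=-0.012)
            (cycle,), _ = resp.segment_cycles(trace, sched)
            fits.append(resp.fit_slope(cycle).alpha)
        assert np.ptp(fits) < 1e-12


class TestFilterSlopes:
    def _fit(self, r2):
        return resp.SlopeFit(cycle=0, alpha=-0.01, r2=r2, n_points=100, excluded_head_s=45.0)

    def test_strict_threshold_rejects_exact_tie(self):
        accepted, rejected = resp.filter_slopes([self._fit(0.90)])
        assert accepted == []
        assert rejected[0][1] == "low_r2"

    def test_above_threshold_accepted(self):
        accepted, rejected = resp.filter_slopes([self._fit(0.95)])
        assert len(accepted) == 1 and rejected == []

    def test_all_rejected_warns(self):
        with pytest.warns(UserWarning, match="rejected"):
            accepted, _ = resp.filter_slopes([self._fit(0.1), self._fit(0.2)])
        assert accepted == []


class TestOxygenSolubility:
    def test_freshwater_value_at_10C(self):
        assert resp.oxygen_solubility(10.0, 0.0) == pytest.approx(11.29, abs=0.1)

    @pytest.mark.parametrize("t", [0.0, 5.0, 10.0, 20.0, 30.0])
    def test_monotone_in_salinity_and_temperature(self, t):
        assert resp.oxygen_solubility(t, 33.0) < resp.oxygen_solubility(t, 0.0)
        assert resp.oxygen_solubility(t + 1.0, 0.0) < resp.oxygen_solubility(t, 0.0)

    @pytest.mark.parametrize("t,s", [(-5.0, 0.0), (45.0, 0.0), (10.0, -1.0), (10.0, 50.0)])
    def test_out_of_range_raises(self, t, s):
        with pytest.raises(ValueError):
            resp.oxygen_solubility(t, s)


class TestComputeMo2:
    def _fit(self, alpha):
        return resp.SlopeFit(cycle=0, alpha=alpha, r2=0.99, n_points=100,
                             excluded_head_s=45.0, midpoint_s=300.0)

    def test_zero_slopes_zero_mo2(self):
        s = resp.compute_mo2(self._fit(0.0), 0.0, beta=10.0, vt=10.0, body_mass=1.0)
        assert s.mo2 == 0.0 and not s.flagged_negative

    def test_worked_example(self):
        # |alpha|=0.01 %/s, Vn=9 l, beta=10 -> 0.01*9*10/100*3600 = 32.4
        s = resp.compute_mo2(self._fit(-0.01), 0.0, beta=10.0, vt=10.0, body_mass=1.0)
        assert s.mo2 == pytest.approx(32.4)
        assert s.vn == pytest.approx(9.0)

    def test_mass_scaling_follows_formula_algebra(self):
        a, vt = -0.01, 10.0
        m1, m2 = 0.5, 1.0
        s1 = resp.compute_mo2(self._fit(a), 0.0, beta=10.0, vt=vt, body_mass=m1)
        s2 = resp.compute_mo2(self._fit(a), 0.0, beta=10.0, vt=vt, body_mass=m2)
        expected_ratio = ((vt - m2) / (vt - m1)) * (m1 / m2)
        assert s2.mo2 / s1.mo2 == pytest.approx(expected_ratio, rel=1e-12)

    def test_background_exceeding_fish_slope_is_flagged(self):
        s = resp.compute_mo2(self._fit(-0.001), -0.01, beta=10.0, vt=10.0, body_mass=1.0)
        assert s.mo2 < 0 and s.flagged_negative


class TestBackgroundSchedule:
    def test_constant_end_run(self):
        bg = resp.background_correction_schedule([-0.002, -0.001])
        assert bg(0.0) == -0.001 and bg(5000.0) == -0.001

    def test_zero_background_is_identity_correction(self):
        bg = resp.background_correction_schedule([0.0])
        fit = resp.SlopeFit(cycle=0, alpha=-0.01, r2=0.99, n_points=50, excluded_head_s=45.0)
        s = resp.compute_mo2(fit, bg(0.0), beta=10.0, vt=10.0, body_mass=1.0)
        assert s.mo2 == pytest.approx(32.4)

    def test_ramp_midpoint(self):
        bg = resp.background_correction_schedule([-0.002], mode="ramp", trace_span_s=1000.0)
        assert bg(500.0) == pytest.approx(-0.001)

    def test_missing_respirometer_policies(self):
        with pytest.raises(ValueError, match="missing background"):
            resp.background_correction_schedule({"R1": None})
        with pytest.warns(UserWarning):
            bgs = resp.background_correction_schedule({"R1": None}, missing="zero")
        assert bgs["R1"](0.0) == 0.0


class TestProcessTraceAudit:
    def test_every_cycle_audited_exactly_once(self):
        rng = np.random.default_rng(5)
        design = sd.reduced_design(seed=9, n_per_group=1)
        study = sd.simulate_study(design)
        fish = study.fish[0]
        series = resp.process_trace(
            fish.airsat, fish.schedule,
            beta=resp.oxygen_solubility(10.0, 0.0), vt=10.0,
            body_mass=fish.body_mass_kg, background_alpha=-3e-5,
        )
        assert len(series) == len(fish.schedule)
        n_acc = int(series["accepted"].sum())
        n_rej = int((~series["accepted"]).sum())
        assert n_acc + n_rej == len(fish.schedule)
        rej = series[~series["accepted"]]
        assert (rej["reason"] != "").all()

    def test_noise_free_mo2_matches_profile_mean_within_2pct(self):
        design = sd.reduced_design(seed=21, n_per_group=1)
        design.noise_sd_sat = 0.0
        study = sd.simulate_study(design)
        fish = study.fish[0]
        series = resp.process_trace(
            fish.airsat, fish.schedule,
            beta=resp.oxygen_solubility(design.temperature_c,
                                        0.0 if fish.salinity_group == "fresh" else design.salinity_sea_ppt),
            vt=design.respirometer_volume_l, body_mass=fish.body_mass_kg,
            background_alpha=fish.truth.background_alpha,
        )
        acc = series[series["accepted"]]
        truth = fish.cycle_truth_mo2[acc["cycle"].to_numpy()]
        rel = np.abs(acc["mo2"].to_numpy() - truth) / truth
        assert rel.max() < 0.02
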