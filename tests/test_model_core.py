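"""Core model tests: stimulus profiles, drift construction, the
first-passage-time solver against constant-drift closed forms, and the
Monte-Carlo simulator as a cross-oracle."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import erf

from multiddm import (ConfigurationError, ConditionSpec, ExperimentDesign,
                      SolverError, condition_summary, default_template,
                      drift_timecourse, fpt_solve, make_stimulus_profile,
                      simulate_trials)
from multiddm.params import BoundVector, SubjectParams


def ddm_choice_prob(mu, theta, bias=0.0):
    """Analytic upper-boundary probability of a constant-drift DDM."""
    if mu == 0:
        return 0.5 * (1 + bias)
    z = (bias + 1) * theta  # start relative to lower bound
    return (1 - math.exp(-2 * mu * z)) / (1 - math.exp(-4 * mu * theta))


def ddm_mean_dt(mu, theta):
    """Analytic unconditional mean decision time (unbiased start)."""
    return theta / mu * math.tanh(mu * theta)


class TestStimulusProfile:
    def test_peak_normalization_and_symmetry(self):
        prof = make_stimulus_profile(2.0, 0.001, 1 / 6)
        i_mid = np.argmin(np.abs(prof.t - 1.0))
        assert prof.velocity[i_mid] == 1.0
        assert abs(prof.acceleration[i_mid]) < 1e-6
        assert prof.velocity.min() >= 0.0
        assert prof.velocity[0] < 0.01 and prof.velocity[-1] < 0.01
        # acceleration antisymmetric about the peak (interior points;
        # the half-open grid has no sample at t = duration)
        a = prof.acceleration
        np.testing.assert_allclose(a[2:i_mid], -a[2 * i_mid - 2:i_mid:-1],
                                   atol=1e-9)

    def test_velocity_integral_matches_analytic_gaussian(self):
        prof = make_stimulus_profile(2.0, 0.001, 1 / 6)
        sd = 2.0 / 6
        # baseline-subtracted, peak-normalized Gaussian on [0, 2)
        t = prof.t
        base = math.exp(-0.5 * (1.0 / sd) ** 2)
        analytic = (np.exp(-0.5 * ((t - 1.0) / sd) ** 2) - base) / (1 - base)
        expected = np.trapezoid(analytic, t)
        got = np.trapezoid(prof.velocity, t)
        assert got == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("kwargs", [
        {"duration_s": -1.0}, {"dt_s": 0.5}, {"dt_s": 0.0},
        {"width_frac": 0.7}, {"width_frac": 0.0},
        {"duration_s": float("nan")},
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        args = {"duration_s": 2.0, "dt_s": 0.001, "width_frac": 1 / 6}
        args.update(kwargs)
        with pytest.raises(ConfigurationError):
            make_stimulus_profile(**args)


class TestDriftTimecourse:
    def test_zero_heading_gives_zero_drift(self, profile_fine):
        p = default_template()
        for cond in [ConditionSpec("vestibular"),
                     ConditionSpec("visual", 0.25),
                     ConditionSpec("combined", 0.70)]:
            mu = drift_timecourse(p, cond, 0.0, profile_fine)
            assert np.all(mu == 0.0)

    def test_combined_reduces_to_visual_without_vestibular(
            self, profile_fine):
        tpl = default_template()
        p0 = SubjectParams(k_vest=0.0, k_vis=tpl.k_vis,
                           coherences=tpl.coherences, bounds=tpl.bounds,
                           t_nd=tpl.t_nd, bias=tpl.bias)
        mu_c = drift_timecourse(p0, ConditionSpec("combined", 0.37), 8.0,
                                profile_fine)
        mu_v = drift_timecourse(p0, ConditionSpec("visual", 0.37), 8.0,
                                profile_fine)
        np.testing.assert_allclose(mu_c, mu_v, atol=1e-12)

    def test_combined_drift_is_root_sum_square(self, profile_fine):
        p = default_template()
        h = -4.0
        mu_c = drift_timecourse(p, ConditionSpec("combined", 0.70), h,
                                profile_fine)
        mu_v = drift_timecourse(p, ConditionSpec("visual", 0.70), h,
                                profile_fine)
        mu_ve = drift_timecourse(p, ConditionSpec("vestibular"), h,
                                 profile_fine)
        np.testing.assert_allclose(mu_c ** 2, mu_v ** 2 + mu_ve ** 2,
                                   rtol=1e-10)

    def test_missing_coherence_rejected(self, profile_fine):
        with pytest.raises(ConfigurationError):
            ConditionSpec("visual", None)


class TestFPTSolver:
    @pytest.mark.parametrize("mu0", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("theta", [0.5, 1.0, 1.5])
    def test_constant_drift_closed_forms(self, profile_long, mu0, theta):
        mu = np.full(profile_long.n_steps, mu0)
        dist = fpt_solve(mu, theta, 0.0, profile_long)
        assert dist.p_upper == pytest.approx(
            ddm_choice_prob(mu0, theta), abs=0.005)
        assert dist.mean_dt == pytest.approx(
            ddm_mean_dt(mu0, theta), abs=0.01)

    def test_biased_start_closed_form(self, profile_long):
        mu = np.full(profile_long.n_steps, 1.0)
        dist = fpt_solve(mu, 1.0, 0.4, profile_long)
        assert dist.p_upper == pytest.approx(
            ddm_choice_prob(1.0, 1.0, 0.4), abs=0.005)

    def test_mass_conservation_across_parameters(self, profile_coarse):
        tpl = default_template()
        rng = np.random.default_rng(42)
        for _ in range(15):
            cond = ConditionSpec("combined", 0.37)
            h = rng.uniform(-16, 16)
            mu = drift_timecourse(tpl, cond, h, profile_coarse)
            theta = rng.uniform(0.0, 3.0)
            bias = rng.uniform(-0.8, 0.8)
            dist = fpt_solve(mu, theta, bias, profile_coarse)
            assert abs(dist.total_mass - 1.0) < 1e-4
            assert np.all(dist.up >= 0) and np.all(dist.lo >= 0)
            assert dist.forced_up >= 0 and dist.forced_lo >= 0

    def test_zero_bound_immediate_decision(self, profile_coarse):
        mu = np.ones(profile_coarse.n_steps)
        dist = fpt_solve(mu, 0.0, 0.0, profile_coarse)
        assert dist.p_upper == pytest.approx(0.5)
        assert dist.mean_dt == 0.0
        assert dist.up[1:].sum() == 0.0 and dist.lo[1:].sum() == 0.0
        p, mrt, mdt = condition_summary(dist, 0.3, +1)
        assert (p, mrt, mdt) == (pytest.approx(0.5), pytest.approx(0.3),
                                 0.0)

    def test_tiny_bounds_leave_no_forced_mass(self, profile_coarse):
        mu = np.full(profile_coarse.n_steps, 2.0)
        dist = fpt_solve(mu, 0.2, 0.0, profile_coarse)
        assert dist.forced_up + dist.forced_lo < 1e-6

    def test_heading_and_bias_flip_swaps_boundaries(self, profile_coarse):
        tpl = default_template()
        mu = drift_timecourse(tpl, ConditionSpec("visual", 0.70), 8.0,
                              profile_coarse)
        d1 = fpt_solve(mu, 1.2, 0.3, profile_coarse)
        d2 = fpt_solve(-mu, 1.2, -0.3, profile_coarse)
        np.testing.assert_allclose(d1.up, d2.lo, atol=1e-10)
        np.testing.assert_allclose(d1.lo, d2.up, atol=1e-10)
        assert d1.forced_up == pytest.approx(d2.forced_lo, abs=1e-10)

    def test_monotonicity_in_bound(self, profile_long):
        mu = np.full(profile_long.n_steps, 1.0)
        thetas = np.linspace(0.2, 2.0, 8)
        p = [fpt_solve(mu, th, 0.0, profile_long).p_upper for th in thetas]
        m = [fpt_solve(mu, th, 0.0, profile_long).mean_dt for th in thetas]
        assert np.all(np.diff(p) > -1e-6)
        assert np.all(np.diff(m) > -1e-6)

    def test_invalid_inputs_rejected(self, profile_coarse):
        mu = np.zeros(profile_coarse.n_steps)
        with pytest.raises(ConfigurationError):
            fpt_solve(mu, -1.0, 0.0, profile_coarse)
        with pytest.raises(ConfigurationError):
            fpt_solve(mu, 1.0, 1.5, profile_coarse)


class TestSimulator:
    def test_symmetry_at_zero_heading(self, profile_coarse):
        tpl = default_template(coherences=(0.7,))
        design = ExperimentDesign(coherences=(0.7,), headings_deg=(0.0,),
                                  n_per_cell=1)
        p0 = SubjectParams(k_vest=tpl.k_vest, k_vis=tpl.k_vis,
                           coherences=tpl.coherences, bounds=tpl.bounds,
                           t_nd=tpl.t_nd, bias=0.0)
        df = simulate_trials(p0, design, n_per_cell=1500, seed=5,
                             profile=profile_coarse)
        p_right = (df["choice"] == 1).mean()
        se = math.sqrt(0.25 / len(df))
        assert abs(p_right - 0.5) < 3 * se

    def test_zero_bound_rts_equal_nondecision_time(self, profile_coarse):
        tpl = default_template(coherences=(0.7,))
        p0 = tpl.with_bounds(BoundVector.free(np.zeros(3)))
        design = ExperimentDesign(coherences=(0.7,),
                                  headings_deg=(-8.0, 8.0), n_per_cell=1)
        df = simulate_trials(p0, design, n_per_cell=200, seed=5,
                             profile=profile_coarse)
        for mod, sub in df.groupby("modality"):
            t_nd = p0.t_nd[mod]
            assert np.all(np.abs(sub["rt_s"] - t_nd) <= 0.0501)

    def test_simulation_matches_solver(self, profile_coarse):
        """Choice probabilities and RT deciles of the Monte-Carlo twin
        agree with the numerical solver at n = 10,000."""
        tpl = default_template(coherences=(0.7,))
        design = ExperimentDesign(coherences=(0.7,), headings_deg=(8.0,
                                                                   -8.0),
                                  n_per_cell=1)
        n = 10_000
        df = simulate_trials(tpl, design, n_per_cell=n, seed=9,
                             profile=profile_coarse)
        for cond in design.cells:
            mu = drift_timecourse(tpl, cond, 8.0, profile_coarse)
            theta = tpl.cell_bounds()[design.cell_index(
                cond.modality, cond.coherence)]
            dist = fpt_solve(mu, theta, tpl.bias, profile_coarse)
            key = (df["modality"] == cond.modality) \
                & (df["heading_deg"] == 8.0)
            sub = df[key]
            p_emp = (sub["choice"] == 1).mean()
            se = math.sqrt(dist.p_upper * (1 - dist.p_upper) / len(sub))
            assert abs(p_emp - dist.p_upper) < 3 * se + 1e-9
            # RT deciles: model CDF of dt + t_nd vs empirical quantiles
            dens = dist.up + dist.lo
            cdf = np.cumsum(dens) * dist.dt_s
            cdf_total = cdf + 0.0
            t_nd = tpl.t_nd[cond.modality]
            for q in (0.2, 0.4, 0.6):  # within decided mass
                if q < cdf_total[-1]:
                    t_q = dist.t[np.searchsorted(cdf_total, q)] + t_nd
                    emp_q = np.quantile(sub["rt_s"], q)
                    assert abs(t_q - emp_q) < 0.02 + 0.0501

    def test_deterministic_given_seed(self, profile_coarse):
        tpl = default_template(coherences=(0.7,))
        design = ExperimentDesign(coherences=(0.7,),
                                  headings_deg=(-2.0, 2.0), n_per_cell=1)
        a = simulate_trials(tpl, design, n_per_cell=30, seed=3,
                            profile=profile_coarse)
        b = simulate_trials(tpl, design, n_per_cell=30, seed=3,
                            profile=profile_coarse)
        pd.testing.assert_frame_equal(a, b)


class TestConditionSummary:
    def test_rt_decomposition_identity(self, profile_coarse):
        tpl = default_template()
        mu = drift_timecourse(tpl, ConditionSpec("visual", 0.25), 4.0,
                              profile_coarse)
        dist = fpt_solve(mu, 1.0, 0.0, profile_coarse)
        p, mrt, mdt = condition_summary(dist, 0.35, +1)
        assert mrt - mdt == pytest.approx(0.35, abs=1e-12)

    def test_constant_drift_accuracy(self, profile_long):
        mu = np.full(profile_long.n_steps, 1.0)
        dist = fpt_solve(mu, 1.0, 0.0, profile_long)
        p, _, _ = condition_summary(dist, 0.3, +1)
        assert p == pytest.approx(1 / (1 + math.exp(-2)), abs=0.005)
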