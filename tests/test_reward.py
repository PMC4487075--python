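"""Reward-rate computation, bound optimization, and bound-line analyses."""
import math

import numpy as np
import pandas as pd
import pytest

from multiddm import (ConfigurationError, ExperimentDesign,
                      ProjectionError, RewardSpec, bound_scaling_curve,
                      default_template, empirical_reward_rate,
                      model_reward_rate, optimize_bounds,
                      random_choice_rr, relative_rr, simulate_trials)
from multiddm.params import BoundVector, SubjectParams
from multiddm.reward import (RewardRateObjective, project_to_ray,
                             scaling_curve_on)
from multiddm.stats import bootstrap_rr_ci


def _zero_bound_template(coherences=(0.7,), t_nd=0.3, bias=0.0):
    tpl = default_template(coherences=coherences)
    return SubjectParams(k_vest=tpl.k_vest, k_vis=tpl.k_vis,
                         coherences=tpl.coherences,
                         bounds=BoundVector.free(
                             np.zeros(1 + 2 * len(coherences))),
                         t_nd=dict.fromkeys(tpl.t_nd, t_nd), bias=bias)


class TestModelRewardRate:
    def test_zero_bounds_arithmetic(self, profile_coarse):
        """All bounds 0 with t_nd = 0.3 s and a 6 s ITI: chance accuracy
        at zero decision time gives 0.5 / 6.3."""
        p0 = _zero_bound_template()
        design = ExperimentDesign(coherences=(0.7,),
                                  headings_deg=(-8.0, 8.0))
        rr = model_reward_rate(p0, design, RewardSpec(),
                               profile=profile_coarse, n_x=81)
        assert rr == pytest.approx(0.5 / 6.3, abs=1e-9)

    def test_cost_linearity_identity(self, small_template, small_design,
                                     profile_coarse):
        obj0 = RewardRateObjective(small_template, small_design,
                                   RewardSpec(), profile_coarse, 81)
        obj2 = RewardRateObjective(small_template, small_design,
                                   RewardSpec(cost_per_s=0.2),
                                   profile_coarse, 81)
        th = small_template.cell_bounds()
        p, mdt, mrt = obj0.summaries(th)
        w = obj0.combo_w
        expected = obj0(th) - 0.2 * float(w @ mdt) / (float(w @ mrt) + 6.0)
        assert obj2(th) == pytest.approx(expected, rel=1e-12)

    def test_constant_drift_cell_closed_form(self):
        """A single cell with constant drift mu=1, theta=1, t_nd=0.3
        reproduces the closed-form reward rate within 1%."""
        from multiddm.profiles import make_stimulus_profile
        prof = make_stimulus_profile(6.0, 0.002)
        tpl = default_template(coherences=())
        p = SubjectParams(k_vest=1.0, k_vis=np.array([]), coherences=(),
                          bounds=BoundVector.free([1.0]),
                          t_nd=dict.fromkeys(tpl.t_nd, 0.3), bias=0.0)
        design = ExperimentDesign(coherences=(),
                                  headings_deg=(-8.0, 8.0), iti_s=6.0)
        obj = RewardRateObjective(p, design, RewardSpec(), prof, 151)
        obj.mu_b = np.where(np.array(design.headings_deg)[:, None] > 0,
                            1.0, -1.0) * np.ones(prof.n_steps)
        p_corr = 1 / (1 + math.exp(-2))
        mean_dt = math.tanh(1.0)
        expected = p_corr / (mean_dt + 0.3 + 6.0)
        assert obj(np.array([1.0])) == pytest.approx(expected, rel=0.01)


class TestEmpiricalRewardRate:
    def test_all_correct_unit_rt(self):
        df = pd.DataFrame({"subject": "a", "modality": "visual",
                           "coherence": 0.7, "heading_deg": 8.0,
                           "choice": 1, "rt_s": 1.0}, index=range(20))
        assert empirical_reward_rate(df, RewardSpec()) == \
            pytest.approx(1 / 7)

    def test_half_correct_at_nondecision_time(self):
        t_nd = 0.4
        df = pd.DataFrame({
            "subject": "a", "modality": "vestibular",
            "coherence": np.nan, "heading_deg": [8.0, 8.0],
            "choice": [1, -1], "rt_s": t_nd})
        rr = empirical_reward_rate(df, RewardSpec(),
                                   dict.fromkeys(["vestibular", "visual",
                                                  "combined"], t_nd))
        assert rr == pytest.approx(0.5 / (t_nd + 6.0))

    def test_empty_table_rejected(self):
        with pytest.raises(ConfigurationError):
            empirical_reward_rate(pd.DataFrame(
                columns=["subject", "modality", "coherence",
                         "heading_deg", "choice", "rt_s"]), RewardSpec())

    def test_matches_model_reward_rate_on_simulated_trials(
            self, small_template, small_design, profile_coarse):
        """Empirical and model-predicted reward rates agree within three
        bootstrap standard errors on a large simulated table."""
        design = ExperimentDesign(coherences=small_template.coherences,
                                  headings_deg=small_design.headings_deg)
        df = simulate_trials(small_template, design, n_per_cell=700,
                             seed=21, profile=profile_coarse)
        spec = RewardSpec()
        rr_emp = empirical_reward_rate(df, spec, small_template.t_nd)
        rr_mod = model_reward_rate(small_template, design, spec,
                                   profile_coarse, 81)
        lo, hi = bootstrap_rr_ci(df, spec, n_boot=1000, seed=1,
                                 t_nd=small_template.t_nd)
        se = (hi - lo) / (2 * 1.96)
        assert abs(rr_emp - rr_mod) < 3 * se


class TestOptimizeBounds:
    def test_one_dimensional_grid_search_oracle(self, profile_coarse):
        """With a single (vestibular-only) cell the ascent optimum must
        match a brute-force grid search at 0.01 resolution."""
        tpl = default_template(coherences=())
        p = SubjectParams(k_vest=8.0, k_vis=np.array([]), coherences=(),
                          bounds=BoundVector.free([1.0]),
                          t_nd=dict.fromkeys(tpl.t_nd, 0.3), bias=0.0)
        design = ExperimentDesign(coherences=(),
                                  headings_deg=(-8.0, 8.0))
        spec = RewardSpec()
        obj = RewardRateObjective(p, design, spec, profile_coarse, 81)
        grid = np.arange(0.01, 3.0, 0.01)
        vals = [obj(np.array([g])) for g in grid]
        theta_grid = grid[int(np.argmax(vals))]
        opt = optimize_bounds(p, design, spec, n_restarts=3, seed=0,
                              profile=profile_coarse, n_x=81)
        theta_opt = opt.cell_bounds(())[0]
        assert theta_opt == pytest.approx(theta_grid, rel=0.05)
        assert opt.rr_opt >= max(vals) - 1e-6

    def test_optimum_dominates_fitted_bounds(self, small_template,
                                             small_design, small_opt,
                                             profile_coarse):
        rr_hat = model_reward_rate(small_template, small_design,
                                   RewardSpec(), profile_coarse, 81)
        assert small_opt.rr_opt >= rr_hat - 1e-12
        for rec in small_opt.restarts:
            assert small_opt.rr_opt >= rec["rr"] - 1e-12

    def test_cost_monotonicity(self, small_template, small_design,
                               profile_coarse):
        opt0 = optimize_bounds(small_template, small_design, RewardSpec(),
                               n_restarts=2, seed=3,
                               profile=profile_coarse, n_x=81)
        opt2 = optimize_bounds(small_template, small_design,
                               RewardSpec(cost_per_s=0.2), n_restarts=2,
                               seed=3, profile=profile_coarse, n_x=81)
        assert opt2.rr_opt <= opt0.rr_opt

    def test_parametric_variant_below_free_optimum(
            self, small_template, small_design, small_opt,
            profile_coarse):
        optp = optimize_bounds(small_template, small_design, RewardSpec(),
                               n_restarts=2, seed=3,
                               profile=profile_coarse, n_x=81,
                               variant="parametric")
        assert optp.theta_opt.variant == "parametric"
        assert optp.rr_opt <= small_opt.rr_opt + 1e-6


class TestRandomChoiceBaseline:
    def test_value_and_invariance(self, profile_coarse):
        p0 = _zero_bound_template()
        d1 = ExperimentDesign(coherences=(0.7,), headings_deg=(-8.0, 8.0))
        d2 = ExperimentDesign(coherences=(0.7,),
                              headings_deg=(-16.0, -2.0, 2.0, 16.0))
        rr1 = random_choice_rr(p0, d1, RewardSpec(), profile_coarse, 81)
        rr2 = random_choice_rr(p0, d2, RewardSpec(), profile_coarse, 81)
        assert rr1 == pytest.approx(0.5 / 6.3, abs=1e-9)
        assert rr1 == pytest.approx(rr2, abs=1e-12)

    def test_dominated_by_optimum(self, small_template, small_design,
                                  small_opt, profile_coarse):
        rr_rand = random_choice_rr(small_template, small_design,
                                   RewardSpec(), profile_coarse, 81)
        assert rr_rand <= small_opt.rr_opt


class TestRelativeRR:
    def test_trivial_values(self, small_opt):
        assert relative_rr(small_opt.rr_opt, small_opt) == 1.0
        assert relative_rr(0.0, small_opt) == 0.0


class TestBoundScalingCurve:
    def test_endpoints_and_optimality(self, small_template, small_design,
                                      small_opt, profile_coarse):
        s_grid = np.arange(0.0, 2.0001, 0.05)
        curve = bound_scaling_curve(small_template, small_opt,
                                    small_design, RewardSpec(), s_grid,
                                    profile=profile_coarse, n_x=81)
        rr_rand = random_choice_rr(small_template, small_design,
                                   RewardSpec(), profile_coarse, 81)
        assert curve.loc[0, "reward_rate"] == pytest.approx(rr_rand,
                                                            abs=1e-9)
        s_best = curve.loc[curve["reward_rate"].idxmax(), "s"]
        assert abs(s_best - 1.0) <= 0.05 + 1e-9

    def test_falls_off_faster_below_than_above(self, small_template,
                                               small_design, small_opt,
                                               profile_coarse):
        """The reward rate drops more steeply below the optimal bounds
        than above them."""
        obj = RewardRateObjective(small_template, small_design,
                                  RewardSpec(), profile_coarse, 81)
        to = small_opt.cell_bounds(small_design.coherences)
        for delta in (0.2, 0.3):
            assert obj((1 - delta) * to) < obj((1 + delta) * to)


class TestProjection:
    def test_isotropic_quadratic_point_on_line(self):
        center = np.array([2.0, 2.0, 2.0])

        def f(th):
            return -float(np.sum((th - center) ** 2))

        assert project_to_ray(f, 0.5 * center, center) == \
            pytest.approx(0.5, abs=1e-8)
        assert project_to_ray(f, center, center) == \
            pytest.approx(1.0, abs=1e-8)

    def test_defining_equation_residual_on_reward_surface(
            self, small_template, small_design, small_opt,
            profile_coarse):
        obj = RewardRateObjective(small_template, small_design,
                                  RewardSpec(), profile_coarse, 81)
        th_hat = 0.55 * small_opt.cell_bounds(small_design.coherences)
        to = small_opt.cell_bounds(small_design.coherences)
        s = project_to_ray(obj, th_hat, to)
        assert abs(obj(s * to) - obj(th_hat)) < 1e-6

    def test_contour_and_vector_modes_agree_on_side(
            self, small_template, small_design, small_opt,
            profile_coarse):
        obj = RewardRateObjective(small_template, small_design,
                                  RewardSpec(), profile_coarse, 81)
        to = small_opt.cell_bounds(small_design.coherences)
        for frac in (0.5, 0.8, 1.3):
            th_hat = frac * to
            s_c = project_to_ray(obj, th_hat, to)
            s_v = project_to_ray(obj, th_hat, to, mode="vector")
            assert (s_c - 1.0) * (s_v - 1.0) >= -1e-9

    def test_above_optimum_rejected(self, small_template, small_design,
                                    small_opt, profile_coarse):
        obj = RewardRateObjective(small_template, small_design,
                                  RewardSpec(), profile_coarse, 81)
        to = small_opt.cell_bounds(small_design.coherences)

        def f_shifted(th):
            return obj(th) + 1.0 if np.allclose(th, 0.9 * to) else obj(th)

        with pytest.raises(ProjectionError):
            project_to_ray(f_shifted, 0.9 * to, to)


class TestDominanceChain:
    def test_random_subject_optimal_ordering(self, small_template,
                                             small_design, small_opt,
                                             profile_coarse):
        """rr_random <= rr_subject <= rr_opt, with the empirical subject
        reward rate inside Monte-Carlo error."""
        spec = RewardSpec()
        rr_rand = random_choice_rr(small_template, small_design, spec,
                                   profile_coarse, 81)
        rr_model = model_reward_rate(small_template, small_design, spec,
                                     profile_coarse, 81)
        df = simulate_trials(small_template, small_design, n_per_cell=300,
                             seed=5, profile=profile_coarse)
        rr_emp = empirical_reward_rate(df, spec, small_template.t_nd)
        lo, hi = bootstrap_rr_ci(df, spec, n_boot=1000, seed=2,
                                 t_nd=small_template.t_nd)
        se = (hi - lo) / (2 * 1.96)
        assert rr_rand <= rr_model <= small_opt.rr_opt + 1e-12
        assert rr_rand - 3 * se <= rr_emp <= small_opt.rr_opt + 3 * se
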