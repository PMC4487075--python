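"""Reward-rate computation, bound optimization, and optimality analyses.

The reward rate of a bound setting theta is

    f(theta) = (sum_cells w * p_correct - c * sum_cells w * mean_dt)
               / (sum_cells w * mean_rt + iti)

with w the design trial proportions, c an optional evidence-accumulation
cost per second (multiplied by mean decision time and subtracted from the
numerator), and iti the mean inter-trial interval.  The optimal reward
rate is found by multi-start finite-difference gradient ascent on the
bounds with all other parameters fixed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .design import ExperimentDesign, MODALITIES, validate_trials
from .errors import ConfigurationError, OptimizationError, ProjectionError
from .model import drift_timecourse, fpt_solve_batch
from .params import BoundVector, SubjectParams
from .profiles import StimulusProfile, make_stimulus_profile

__all__ = [
    "RewardSpec", "OptimizationResult", "RewardRateObjective",
    "model_reward_rate", "empirical_reward_rate", "optimize_bounds",
    "random_choice_rr", "relative_rr", "bound_scaling_curve",
    "scaling_curve_on", "project_to_bound_line", "project_to_ray",
]


@dataclass(frozen=True)
class RewardSpec:
    """Reward-rate bookkeeping: mean inter-trial interval (s), evidence-
    accumulation cost (reward units per second of decision time), and
    reward per correct choice."""

    iti_s: float = 6.0
    cost_per_s: float = 0.0
    reward_correct: float = 1.0

    def __post_init__(self):
        if self.iti_s <= 0:
            raise ConfigurationError("iti_s must be positive")
        if self.cost_per_s < 0:
            raise ConfigurationError("cost_per_s must be >= 0")


@dataclass
class OptimizationResult:
    """Outcome of the reward-rate maximization over bounds."""

    theta_opt: BoundVector
    rr_opt: float
    restarts: list
    seed: int
    variant: str

    def cell_bounds(self, coherences) -> np.ndarray:
        return self.theta_opt.cell_bounds(coherences)


class RewardRateObjective:
    """Reward rate as a function of per-cell scaled bounds.

    Drift timecourses depend only on the fixed sensitivities and are
    precomputed once, so repeated evaluations during optimization only
    re-run the first-passage solver.
    """

    def __init__(self, params: SubjectParams, design: ExperimentDesign,
                 spec: RewardSpec,
                 profile: StimulusProfile | None = None, n_x: int = 101):
        if tuple(params.coherences) != tuple(design.coherences):
            raise ConfigurationError(
                "params and design disagree on coherence levels")
        self.params = params
        self.design = design
        self.spec = spec
        self.profile = profile or make_stimulus_profile(design.duration_s)
        self.n_x = n_x
        w_cell = design.weights()
        combos = [(ci, h) for ci in range(design.n_cells)
                  for h in design.headings_deg]
        self.combo_cell = np.array([c for c, _ in combos])
        self.combo_sign = np.sign([h for _, h in combos])
        self.combo_w = np.array(
            [w_cell[c] / len(design.headings_deg) for c, _ in combos])
        self.combo_tnd = np.array(
            [params.t_nd[design.cells[c].modality] for c, _ in combos])
        self.mu_b = np.empty((len(combos), self.profile.n_steps))
        for i, (ci, h) in enumerate(combos):
            self.mu_b[i] = drift_timecourse(params, design.cells[ci], h,
                                            self.profile)
        self.n_cells = design.n_cells

    def _raw_stats(self, idx: np.ndarray, th_b: np.ndarray):
        """(p_correct, mean_dt, mean_rt) for a subset of combos."""
        g_up, g_lo, forced = fpt_solve_batch(
            self.mu_b[idx], th_b, self.params.bias, self.profile, self.n_x)
        dt = self.profile.dt_s
        p_up = g_up.sum(axis=1) * dt + forced[:, 0]
        dens = g_up + g_lo
        mean_dt = ((self.profile.t[None, :] * dens).sum(axis=1) * dt
                   + self.profile.duration_s * forced.sum(axis=1))
        sgn = self.combo_sign[idx]
        p_correct = np.where(sgn > 0, p_up,
                             np.where(sgn < 0, 1.0 - p_up, 0.5))
        lapse = self.params.lapse
        if lapse > 0:
            p_correct = (1 - lapse) * p_correct + lapse * 0.5
            mean_dt = ((1 - lapse) * mean_dt
                       + lapse * self.profile.duration_s / 2)
        mean_rt = mean_dt + self.combo_tnd[idx]
        return p_correct, mean_dt, mean_rt

    def summaries(self, theta_cells: np.ndarray):
        """Per-combo (p_correct, mean_dt, mean_rt) arrays."""
        theta_cells = np.asarray(theta_cells, dtype=float)
        if theta_cells.shape != (self.n_cells,):
            raise ConfigurationError(
                f"expected {self.n_cells} cell bounds")
        idx = np.arange(len(self.combo_cell))
        return self._raw_stats(idx, theta_cells[self.combo_cell])

    def f_from_parts(self, p_correct, mean_dt, mean_rt) -> float:
        w = self.combo_w
        num = (self.spec.reward_correct * float(w @ p_correct)
               - self.spec.cost_per_s * float(w @ mean_dt))
        den = float(w @ mean_rt) + self.spec.iti_s
        return num / den

    def __call__(self, theta_cells: np.ndarray) -> float:
        return self.f_from_parts(*self.summaries(theta_cells))

    def grad_log(self, v: np.ndarray, fd_step: float = 1e-3) -> np.ndarray:
        """Central-difference gradient of f with respect to log bounds.

        Perturbing one cell's bound only touches that cell's combos, so
        the baseline per-combo summaries are reused for all others.
        """
        theta = np.exp(v)
        p0, d0, r0 = self.summaries(theta)
        g = np.empty(self.n_cells)
        for i in range(self.n_cells):
            idx = np.where(self.combo_cell == i)[0]
            vals = []
            for sgn in (1.0, -1.0):
                th_i = math.exp(v[i] + sgn * fd_step)
                pi, di, ri = self._raw_stats(
                    idx, np.full(len(idx), th_i))
                p, d, r = p0.copy(), d0.copy(), r0.copy()
                p[idx], d[idx], r[idx] = pi, di, ri
                vals.append(self.f_from_parts(p, d, r))
            g[i] = (vals[0] - vals[1]) / (2 * fd_step)
        return g


def model_reward_rate(params: SubjectParams, design: ExperimentDesign,
                      spec: RewardSpec,
                      profile: StimulusProfile | None = None,
                      n_x: int = 101) -> float:
    """Model-predicted reward rate at the subject's own bounds."""
    obj = RewardRateObjective(params, design, spec, profile, n_x)
    return obj(params.cell_bounds())


def empirical_reward_rate(trials: pd.DataFrame, spec: RewardSpec,
                          t_nd: dict | None = None) -> float:
    """Reward rate computed directly from behavioral trials.

    Fraction of correct choices (heading-zero trials credited 0.5 by
    convention), net of the accumulation cost times mean decision time
    (RT minus the per-modality non-decision time), divided by mean RT
    plus the inter-trial interval.
    """
    if len(trials) == 0:
        raise ConfigurationError("empty trial table")
    trials = validate_trials(trials)
    sgn = np.sign(trials["heading_deg"].to_numpy(float))
    correct = np.where(sgn == 0, 0.5,
                       (trials["choice"].to_numpy(float) * sgn > 0)
                       .astype(float))
    rt = trials["rt_s"].to_numpy(float)
    if t_nd is None:
        t_nd = dict.fromkeys(MODALITIES, 0.0)
    tnd = trials["modality"].map(t_nd).to_numpy(float)
    dt_dec = np.clip(rt - tnd, 0.0, None)
    num = (spec.reward_correct * correct.mean()
           - spec.cost_per_s * dt_dec.mean())
    return float(num / (rt.mean() + spec.iti_s))


# ---------------------------------------------------------------------
# gradient ascent on the reward rate
# ---------------------------------------------------------------------

def _central_grad(f, x, step):
    g = np.empty(len(x))
    for i in range(len(x)):
        e = np.zeros(len(x))
        e[i] = step
        g[i] = (f(x + e) - f(x - e)) / (2 * step)
    return g


def _ascend(f, x0, lo, hi, max_iter=500, grad_tol=1e-6, fd_step=1e-3,
            ftol=1e-9, grad_fn=None):
    """Projected gradient ascent with Barzilai-Borwein steps and
    backtracking; returns (x, fx, grad_norm, converged, n_iter)."""
    if grad_fn is None:
        def grad_fn(x):
            return _central_grad(f, x, fd_step)
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    fx = f(x)
    step = 0.1
    g_prev = None
    x_prev = None
    hist = [fx]
    window = 20
    for it in range(1, max_iter + 1):
        g = grad_fn(x)
        gn = float(np.linalg.norm(g))
        if gn < grad_tol:
            return x, fx, gn, True, it
        if g_prev is not None:
            s = x - x_prev
            y = g - g_prev
            sy = float(s @ y)
            if sy < 0:  # concave region: BB step for ascent
                step = float(s @ s) / (-sy)
            step = float(np.clip(step, 1e-6, 50.0))
        improved = False
        t = step
        for _ in range(30):
            cand = np.clip(x + t * g, lo, hi)
            fc = f(cand)
            if fc > fx + 1e-4 * float(g @ (cand - x)):
                improved = True
                break
            t *= 0.5
        if not improved:
            return x, fx, gn, True, it  # plateau: no ascent step exists
        x_prev, g_prev = x, g
        gain = fc - fx
        x, fx = cand, fc
        if gain < ftol:
            return x, fx, gn, True, it
        hist.append(fx)
        if len(hist) > window and fx - hist[-window - 1] < 10 * ftol:
            return x, fx, gn, True, it  # window plateau
    return x, fx, gn, False, max_iter


def optimize_bounds(params: SubjectParams, design: ExperimentDesign,
                    spec: RewardSpec, n_restarts: int = 50,
                    seed: int = 0, profile: StimulusProfile | None = None,
                    n_x: int = 101, max_iter: int = 500,
                    grad_tol: float = 1e-6, theta_min: float = 1e-3,
                    theta_max: float = 8.0,
                    variant: str | None = None) -> OptimizationResult:
    """Find the reward-rate-maximizing bounds, all other parameters fixed.

    Finite-difference gradient ascent runs in log-bound space from the
    fitted bounds plus ``n_restarts - 1`` random restarts drawn
    log-uniformly in [theta_hat/5, 5*theta_hat] per coordinate; the best
    endpoint wins.  ``variant='parametric'`` restricts the search to one
    bound per modality plus the coherence->standard-deviation slope.
    """
    if variant is None:
        variant = params.bounds.variant
    obj = RewardRateObjective(params, design, spec, profile, n_x)
    rng = np.random.default_rng(seed)
    C = len(design.coherences)
    slope_max = 0.95 / max(design.coherences) if C else 0.0
    if variant == "parametric" and C == 0:
        raise ConfigurationError(
            "parametric variant needs at least one coherence level")

    if variant == "free":
        theta_hat = np.clip(params.cell_bounds(), 0.05, theta_max)

        def to_cells(v):
            return np.exp(v)

        def make_bv(v):
            return BoundVector.free(np.exp(v))

        x_hat = np.log(theta_hat)
        dim = design.n_cells
    elif variant == "parametric":
        cells_hat = np.clip(params.cell_bounds(), 0.05, theta_max)
        tm0 = np.array([cells_hat[0], cells_hat[1:1 + C].mean(),
                        cells_hat[1 + C:].mean()])

        def to_cells(v):
            return BoundVector.parametric(
                np.exp(v[:3]), slope_max / (1 + math.exp(-v[3]))
            ).cell_bounds(design.coherences)

        def make_bv(v):
            return BoundVector.parametric(
                np.exp(v[:3]), slope_max / (1 + math.exp(-v[3])))

        x_hat = np.concatenate([np.log(tm0), [0.0]])
        dim = 4
    else:
        raise ConfigurationError(f"unknown bound variant {variant!r}")

    lo = np.full(dim, math.log(theta_min))
    hi = np.full(dim, math.log(theta_max))
    if variant == "parametric":
        lo[3], hi[3] = -6.0, 6.0

    def f(v):
        return obj(to_cells(v))

    starts = [x_hat]
    for _ in range(max(n_restarts - 1, 0)):
        jit = rng.uniform(math.log(1 / 5), math.log(5), dim)
        if variant == "parametric":
            jit[3] = rng.uniform(-2, 2)
            starts.append(np.clip(x_hat + jit, lo, hi))
        else:
            starts.append(np.clip(x_hat + jit, lo, hi))

    if variant == "free":
        grad_fn = obj.grad_log
    else:
        coh = np.array(design.coherences)

        def grad_fn(v):
            # chain rule through the parametric bound map
            cells = np.maximum(to_cells(v), 1e-12)
            dF_dc = obj.grad_log(np.log(cells)) / cells
            sig = 1.0 / (1.0 + math.exp(-v[3]))
            slope = slope_max * sig
            dslope = slope_max * sig * (1.0 - sig)
            sigma = 1.0 - slope * coh
            J = np.zeros((design.n_cells, 4))
            J[0, 0] = cells[0]
            J[1:1 + C, 1] = cells[1:1 + C]
            J[1 + C:, 2] = cells[1 + C:]
            J[1:1 + C, 3] = cells[1:1 + C] * coh * dslope / sigma
            J[1 + C:, 3] = cells[1 + C:] * coh * dslope / sigma
            return J.T @ dF_dc
    records = []
    best = None
    for si, s in enumerate(starts):
        x, fx, gn, conv, nit = _ascend(f, s, lo, hi, max_iter=max_iter,
                                       grad_tol=grad_tol, grad_fn=grad_fn)
        # stopping at the iteration cap is part of the stopping rule
        # (gradient-norm tolerance OR the iteration budget)
        ok = bool(conv) or (nit >= max_iter and np.isfinite(fx))
        records.append({"restart": si, "start": s.tolist(),
                        "end": x.tolist(), "rr": fx, "grad_norm": gn,
                        "converged": ok,
                        "status": "stationary" if conv else "max_iter",
                        "n_iter": nit})
        if np.isfinite(fx) and (best is None or fx > best[1]):
            best = (x, fx)
    if best is None or not any(r["converged"] for r in records):
        raise OptimizationError(
            f"no reward-rate ascent restart converged: {records}")
    x_best, rr_best = best
    # never return worse than the fitted bounds themselves
    f_hat = f(x_hat)
    if f_hat > rr_best:
        x_best, rr_best = x_hat, f_hat
    return OptimizationResult(theta_opt=make_bv(x_best),
                              rr_opt=float(rr_best), restarts=records,
                              seed=seed, variant=variant)


def random_choice_rr(params: SubjectParams, design: ExperimentDesign,
                     spec: RewardSpec,
                     profile: StimulusProfile | None = None,
                     n_x: int = 101) -> float:
    """Reward rate of immediate random choices: all bounds forced to 0."""
    obj = RewardRateObjective(params, design, spec, profile, n_x)
    return obj(np.zeros(design.n_cells))


def relative_rr(subject_rr: float, opt: OptimizationResult) -> float:
    """Subject reward rate as a fraction of the optimum."""
    if opt.rr_opt <= 0:
        raise ConfigurationError("optimal reward rate must be positive")
    return float(subject_rr) / float(opt.rr_opt)


def scaling_curve_on(f, theta_opt_cells: np.ndarray,
                     s_grid: np.ndarray) -> pd.DataFrame:
    """Evaluate an objective along the ray s * theta_opt."""
    theta_opt_cells = np.asarray(theta_opt_cells, dtype=float)
    rows = [{"s": float(s), "reward_rate": float(f(s * theta_opt_cells))}
            for s in np.asarray(s_grid, dtype=float)]
    return pd.DataFrame(rows)


def bound_scaling_curve(params: SubjectParams, opt: OptimizationResult,
                        design: ExperimentDesign, spec: RewardSpec,
                        s_grid, profile: StimulusProfile | None = None,
                        n_x: int = 101) -> pd.DataFrame:
    """Reward rate under a simultaneous linear scaling of all optimal
    bounds (s = 0 is immediate random choice, s = 1 the optimum)."""
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any(s_grid < 0):
        raise ConfigurationError("s_grid must be nonnegative")
    obj = RewardRateObjective(params, design, spec, profile, n_x)
    return scaling_curve_on(obj, opt.cell_bounds(design.coherences), s_grid)


def project_to_ray(f, theta_hat_cells: np.ndarray,
                   theta_opt_cells: np.ndarray, s_max: float = 3.0,
                   mode: str = "contour") -> float:
    """Position of theta_hat on the optimal-bound ray.

    ``contour`` mode follows the iso-reward contour through theta_hat to
    its intersection with the ray s * theta_opt, i.e. solves
    f(s * theta_opt) = f(theta_hat); the branch (s below or above 1) is
    chosen by the scalar projection of theta_hat onto theta_opt.
    ``vector`` mode returns the plain scalar projection.
    """
    th = np.asarray(theta_hat_cells, dtype=float)
    to = np.asarray(theta_opt_cells, dtype=float)
    s_hat = float(th @ to) / float(to @ to)
    if mode == "vector":
        return s_hat
    if mode != "contour":
        raise ConfigurationError("mode must be 'contour' or 'vector'")
    f_hat = float(f(th))
    f_opt = float(f(to))
    if f_hat > f_opt + 1e-9:
        raise ProjectionError("f(theta_hat) exceeds f(theta_opt)")

    def h(s):
        return float(f(s * to)) - f_hat

    if s_hat < 1.0:
        a, b = 0.0, 1.0
    else:
        a, b = 1.0, s_max
    ha, hb = h(a), h(b)
    if ha > 0 and hb > 0:
        raise ProjectionError(
            f"no iso-reward intersection on branch [{a}, {b}]")
    if ha <= 0 <= hb:
        lo_s, hi_s = a, b
    elif hb <= 0 <= ha:
        lo_s, hi_s = a, b
    else:  # both <= 0: contour does not cross within the branch
        raise ProjectionError(
            f"no iso-reward intersection on branch [{a}, {b}]")
    return float(brentq(h, lo_s, hi_s, xtol=1e-10, rtol=1e-12))


def project_to_bound_line(theta_hat: BoundVector, opt: OptimizationResult,
                          params: SubjectParams, design: ExperimentDesign,
                          spec: RewardSpec, s_max: float = 3.0,
                          mode: str = "contour",
                          profile: StimulusProfile | None = None,
                          n_x: int = 101) -> float:
    """Project a subject's fitted bounds onto the optimal-bound line."""
    obj = RewardRateObjective(params, design, spec, profile, n_x)
    return project_to_ray(obj, theta_hat.cell_bounds(design.coherences),
                          opt.cell_bounds(design.coherences),
                          s_max=s_max, mode=mode)
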