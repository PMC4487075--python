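"""Core multisensory diffusion model: drift timecourses, first-passage-time
distributions, forced choices at stimulus offset, and Monte-Carlo simulation.

The decision variable is a unit-variance diffusion with a time-varying
drift set by the stimulus profile and the modality sensitivities; the
decision is taken when the particle hits one of the scaled bounds
+/-theta, or — if the stimulus ends first — by the sign of the particle
(forced choice at offset).  Choices are coded -1 (left) / +1 (right), with
rightward mapped to the upper boundary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._fpt import fpt_batch
from .design import ConditionSpec, ExperimentDesign, validate_trials
from .errors import ConfigurationError, SolverError
from .params import SubjectParams
from .profiles import StimulusProfile, make_stimulus_profile

__all__ = [
    "RTDistribution", "drift_timecourse", "fpt_solve", "fpt_solve_batch",
    "condition_summary", "simulate_trials", "NDT_JITTER_S",
]

#: Half-width (s) of the uniform non-decision-time jitter used both for
#: simulation and for likelihood smoothing.
NDT_JITTER_S = 0.05

#: Default number of interior spatial grid points of the solver.
DEFAULT_NX = 201

#: Allowed defect of total probability mass before the solver errors out.
MASS_DEFECT_TOL = 1e-3


@dataclass(frozen=True)
class RTDistribution:
    """Defective first-passage densities plus forced-choice masses.

    ``up``/``lo`` are densities (1/s) over within-stimulus decision time on
    the half-open grid ``t`` (bin left edges); ``forced_up``/``forced_lo``
    are point masses at t = duration for trajectories that never crossed a
    bound.  Total mass is 1.
    """

    t: np.ndarray = field(repr=False)
    up: np.ndarray = field(repr=False)
    lo: np.ndarray = field(repr=False)
    forced_up: float
    forced_lo: float
    duration_s: float
    dt_s: float

    @property
    def total_mass(self) -> float:
        return float((self.up + self.lo).sum() * self.dt_s
                     + self.forced_up + self.forced_lo)

    @property
    def p_upper(self) -> float:
        return float(self.up.sum() * self.dt_s + self.forced_up)

    @property
    def p_lower(self) -> float:
        return float(self.lo.sum() * self.dt_s + self.forced_lo)

    @property
    def mean_dt(self) -> float:
        """Mean decision time (s), forced mass counted at the deadline."""
        dens = self.up + self.lo
        return float((self.t * dens).sum() * self.dt_s
                     + self.duration_s * (self.forced_up + self.forced_lo))


def drift_timecourse(params: SubjectParams, cond: ConditionSpec,
                     heading_deg: float,
                     profile: StimulusProfile) -> np.ndarray:
    """Drift mu(t) (1/s) for one condition and heading.

    Vestibular evidence follows the peak-normalized magnitude of the
    acceleration profile (rectified, so the informative signal keeps a
    constant sign); visual evidence follows the velocity profile; the
    combined drift is the root-sum-square reliability-weighted combination
    of the two, signed by the heading.
    """
    if abs(heading_deg) > 90:
        raise ConfigurationError("heading must lie within +/-90 degrees")
    s = math.sin(math.radians(heading_deg))
    if cond.modality == "vestibular":
        return params.k_vest * s * np.abs(profile.acceleration)
    k_vis = params.k_vis_at(cond.coherence)
    if cond.modality == "visual":
        return k_vis * s * profile.velocity
    vis = k_vis * profile.velocity
    vest = params.k_vest * np.abs(profile.acceleration)
    return s * np.sqrt(vis * vis + vest * vest)


def fpt_solve(mu: np.ndarray, bound: float, bias: float,
              profile: StimulusProfile, n_x: int = DEFAULT_NX) -> RTDistribution:
    """Numerical first-passage-time distribution for one drift timecourse.

    The particle starts at ``bias * bound`` between absorbing bounds at
    ``+/-bound``; surviving probability at the deadline is assigned to the
    forced-choice masses by the sign partition of the surviving density.
    """
    if bound < 0:
        raise ConfigurationError("bound must be >= 0")
    if not -1 < bias < 1:
        raise ConfigurationError("bias must lie in (-1, 1)")
    mu = np.ascontiguousarray(mu, dtype=float)
    if mu.shape != profile.t.shape:
        raise ConfigurationError("mu must be sampled on the profile grid")
    g_up, g_lo, forced = fpt_batch(mu[None, :], np.array([float(bound)]),
                                   np.array([float(bias)]), profile.dt_s,
                                   int(n_x))
    dist = RTDistribution(t=profile.t, up=g_up[0], lo=g_lo[0],
                          forced_up=float(forced[0, 0]),
                          forced_lo=float(forced[0, 1]),
                          duration_s=profile.duration_s, dt_s=profile.dt_s)
    defect = abs(dist.total_mass - 1.0)
    if defect > MASS_DEFECT_TOL:
        raise SolverError(f"FPT solver mass defect {defect:.2e} exceeds "
                          f"{MASS_DEFECT_TOL:g}")
    return dist


def fpt_solve_batch(mu_b: np.ndarray, theta_b: np.ndarray, bias: float,
                    profile: StimulusProfile, n_x: int = DEFAULT_NX):
    """Batched solver (shared grid); returns raw (g_up, g_lo, forced)."""
    mu_b = np.ascontiguousarray(mu_b, dtype=float)
    theta_b = np.ascontiguousarray(theta_b, dtype=float)
    bias_b = np.full(len(theta_b), float(bias))
    return fpt_batch(mu_b, theta_b, bias_b, profile.dt_s, int(n_x))


def condition_summary(dist: RTDistribution, t_nd: float,
                      heading_sign: float):
    """Summarize one cell: (p_correct, mean_rt, mean_dt).

    ``p_correct`` is the mass on the boundary matching the heading sign
    (0.5 by convention at heading zero); mean decision time includes the
    forced mass at the deadline; mean RT adds the non-decision time.
    """
    if heading_sign > 0:
        p_correct = dist.p_upper
    elif heading_sign < 0:
        p_correct = dist.p_lower
    else:
        p_correct = 0.5
    mean_dt = dist.mean_dt
    return p_correct, mean_dt + t_nd, mean_dt


def simulate_trials(params: SubjectParams, design: ExperimentDesign,
                    n_per_cell: int | None = None, seed: int = 0,
                    profile: StimulusProfile | None = None,
                    subject: str = "S01") -> pd.DataFrame:
    """Monte-Carlo twin of the solver: Euler-Maruyama paths per trial.

    A Brownian-bridge correction catches bound crossings between grid
    points, so the simulated choice/RT statistics are unbiased with
    respect to the continuum model even at coarse step sizes.  Forced
    choices at stimulus offset follow the particle's sign; lapse trials
    are replaced by a fair coin at a uniform RT.  Deterministic given the
    seed.
    """
    if n_per_cell is None:
        n_per_cell = design.n_per_cell
    if n_per_cell < 1:
        raise ConfigurationError("n_per_cell must be >= 1")
    if profile is None:
        profile = make_stimulus_profile(design.duration_s)
    rng = np.random.default_rng(seed)
    dt = profile.dt_s
    sdt = math.sqrt(dt)
    theta_cells = params.cell_bounds()
    rows = []
    for ci, cond in enumerate(design.cells):
        theta = theta_cells[ci]
        t_nd = params.t_nd[cond.modality]
        for h in design.headings_deg:
            mu = drift_timecourse(params, cond, h, profile)
            n = n_per_cell
            if theta <= 1e-12:
                choice = np.where(
                    rng.random(n) < 0.5 * (1 + params.bias), 1, -1)
                dt_dec = np.zeros(n)
            else:
                x = np.full(n, params.bias * theta)
                choice = np.zeros(n, dtype=np.int64)
                dt_dec = np.full(n, profile.duration_s)
                alive = np.arange(n)
                for step in range(profile.n_steps):
                    xn = (x + mu[step] * dt
                          + sdt * rng.standard_normal(len(alive)))
                    hit_up = xn >= theta
                    hit_lo = xn <= -theta
                    inside = ~(hit_up | hit_lo)
                    if np.any(inside):
                        # Brownian-bridge probability of an unseen crossing
                        xi, xf = x[inside], xn[inside]
                        p_up = np.exp(-2.0 * (theta - xi) * (theta - xf) / dt)
                        p_lo = np.exp(-2.0 * (theta + xi) * (theta + xf) / dt)
                        u = rng.random(inside.sum())
                        bu = u < p_up
                        bl = (u >= p_up) & (u < p_up + p_lo)
                        hit_up[inside] |= bu
                        hit_lo[inside] |= bl
                    done = hit_up | hit_lo
                    if np.any(done):
                        idx = alive[done]
                        choice[idx] = np.where(hit_up[done], 1, -1)
                        dt_dec[idx] = (step + 1) * dt
                        alive = alive[~done]
                        x = xn[~done]
                    else:
                        x = xn
                    if len(alive) == 0:
                        break
                if len(alive):  # forced choice at offset by particle sign
                    sgn = np.sign(x)
                    coin = np.where(rng.random(len(alive)) < 0.5, 1, -1)
                    choice[alive] = np.where(sgn == 0, coin,
                                             sgn).astype(np.int64)
            rt = dt_dec + t_nd + rng.uniform(-NDT_JITTER_S, NDT_JITTER_S, n)
            if params.lapse > 0:
                is_lapse = rng.random(n) < params.lapse
                n_l = int(is_lapse.sum())
                if n_l:
                    choice[is_lapse] = np.where(rng.random(n_l) < 0.5, 1, -1)
                    rt[is_lapse] = t_nd + rng.uniform(
                        0, profile.duration_s, n_l)
            rt = np.clip(rt, 1e-3, None)
            rows.append(pd.DataFrame({
                "subject": subject, "modality": cond.modality,
                "coherence": (np.nan if cond.coherence is None
                              else cond.coherence),
                "heading_deg": h, "choice": choice, "rt_s": rt}))
    df = pd.concat(rows, ignore_index=True)
    return validate_trials(df)
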