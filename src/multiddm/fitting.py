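"""Maximum-likelihood estimation of subject parameters from trial tables.

The likelihood of one trial is the defective first-passage density of the
chosen boundary at decision time rt - t_nd, convolved with the uniform
non-decision jitter; trials whose RT falls at the deadline use the
forced-choice mass; an optional lapse mixture adds a stimulus-independent
uniform component.  Fitting maximizes the summed log-likelihood with
multi-start Nelder-Mead on transformed parameters (log sensitivities,
bounds and non-decision times; atanh bias), replacing heavier sampling
schemes: downstream analyses only need the maximum-likelihood point.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .design import ExperimentDesign, MODALITIES, validate_trials
from .errors import ConfigurationError, FitError
from .model import NDT_JITTER_S, drift_timecourse, fpt_solve_batch
from .params import BoundVector, SubjectParams
from .profiles import StimulusProfile, make_stimulus_profile

__all__ = ["FitSettings", "FitResult", "trial_loglik", "table_loglik",
           "fit_subject", "predicted_psychometric"]

_DENSITY_FLOOR = 1e-12


@dataclass
class FitSettings:
    """Knobs of the maximum-likelihood fit."""

    n_restarts: int = 10
    maxiter: int = 50          # outer Powell iterations (direction sweeps)
    n_x: int = 101
    solver_dt_s: float = 0.005
    fit_lapse: bool = False
    seed: int = 0
    restart_scale: float = 0.3   # log-sd of multiplicative restart jitter
    fatol: float = 1e-6          # Powell relative ftol
    xatol: float = 1e-4


@dataclass
class FitResult:
    """Maximum-likelihood fit of one subject."""

    params: SubjectParams
    loglik: float
    n_trials: int
    n_flagged_trials: int
    convergence: list
    settings: dict
    seed: int

    def to_dict(self) -> dict:
        return {"params": self.params.to_dict(), "loglik": self.loglik,
                "n_trials": self.n_trials,
                "n_flagged_trials": self.n_flagged_trials,
                "convergence": self.convergence,
                "settings": self.settings, "seed": self.seed}


# ---------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------

def _group_trials(trials: pd.DataFrame, design: ExperimentDesign):
    """Group trials by (condition cell, heading) for batched solving."""
    trials = validate_trials(trials)
    groups = []
    key = trials["coherence"].where(trials["coherence"].notna(), -1.0)
    for (mod, coh, h), sub in trials.groupby(
            ["modality", key, "heading_deg"], sort=True, dropna=False):
        coherence = None if coh < 0 else float(coh)
        ci = design.cell_index(mod, coherence)
        groups.append({
            "cell": ci, "modality": mod, "heading": float(h),
            "rt": sub["rt_s"].to_numpy(float),
            "choice": sub["choice"].to_numpy(int)})
    return groups


def _smoothed_logdens(g_up, g_lo, forced, rt, choice, t_nd, lapse,
                      duration, dt):
    """Per-trial log density at observed (choice, rt).

    The FPT density is box-smoothed by the +/-NDT_JITTER_S non-decision
    jitter; the forced-choice point mass at the deadline is smeared over
    the same window.
    """
    w = NDT_JITTER_S
    tau = rt - t_nd
    edges = np.arange(len(g_up) + 1) * dt
    cum_up = np.concatenate(([0.0], np.cumsum(g_up) * dt))
    cum_lo = np.concatenate(([0.0], np.cumsum(g_lo) * dt))
    lo_t = np.clip(tau - w, 0.0, edges[-1])
    hi_t = np.clip(tau + w, 0.0, edges[-1])
    dens_up = (np.interp(hi_t, edges, cum_up)
               - np.interp(lo_t, edges, cum_up)) / (2 * w)
    dens_lo = (np.interp(hi_t, edges, cum_lo)
               - np.interp(lo_t, edges, cum_lo)) / (2 * w)
    in_forced = np.abs(tau - duration) < w
    dens_up = dens_up + in_forced * forced[0] / (2 * w)
    dens_lo = dens_lo + in_forced * forced[1] / (2 * w)
    dens = np.where(choice > 0, dens_up, dens_lo)
    if lapse > 0:
        in_lapse = (rt >= t_nd) & (rt <= t_nd + duration)
        dens = ((1 - lapse) * dens
                + lapse * 0.5 * in_lapse / duration)
    return dens


def _design_from_params(params: SubjectParams,
                        headings=(0.0,)) -> ExperimentDesign:
    hs = tuple(sorted(set(headings) | {-h for h in headings}))
    return ExperimentDesign(coherences=params.coherences,
                            headings_deg=hs if hs else (0.0,))


def _loglik_from_groups(params: SubjectParams, groups, design, profile,
                        n_x, floor):
    theta_cells = params.cell_bounds()
    mu_b = np.empty((len(groups), profile.n_steps))
    th_b = np.empty(len(groups))
    for i, g in enumerate(groups):
        cond = design.cells[g["cell"]]
        mu_b[i] = drift_timecourse(params, cond, g["heading"], profile)
        th_b[i] = theta_cells[g["cell"]]
    g_up, g_lo, forced = fpt_solve_batch(mu_b, th_b, params.bias, profile,
                                         n_x)
    total = 0.0
    n_flagged = 0
    for i, g in enumerate(groups):
        dens = _smoothed_logdens(g_up[i], g_lo[i], forced[i], g["rt"],
                                 g["choice"], params.t_nd[g["modality"]],
                                 params.lapse, profile.duration_s,
                                 profile.dt_s)
        bad = dens <= 0
        n_flagged += int(bad.sum())
        if floor is None:
            with np.errstate(divide="ignore"):
                total += float(np.log(dens).sum())
        else:
            total += float(np.log(np.maximum(dens, floor)).sum())
    return total, n_flagged


def table_loglik(params: SubjectParams, trials: pd.DataFrame,
                 profile: StimulusProfile | None = None,
                 n_x: int = 101, floor: float | None = _DENSITY_FLOOR):
    """Total log-likelihood of a trial table.

    Returns ``(loglik, n_flagged)`` where flagged trials have zero model
    density (impossible RT at zero lapse).  With ``floor=None`` a flagged
    trial contributes -inf; the optimizer path floors densities instead
    so the objective stays finite.
    """
    headings = trials["heading_deg"].unique()
    design = _design_from_params(params, headings)
    if profile is None:
        profile = make_stimulus_profile(design.duration_s)
    groups = _group_trials(trials, design)
    return _loglik_from_groups(params, groups, design, profile, n_x, floor)


def trial_loglik(params: SubjectParams, trial, profile: StimulusProfile):
    """Log density of a single trial (row with modality, coherence,
    heading_deg, choice, rt_s).  Returns -inf (flagged, not raised) for an
    RT outside the reachable window at zero lapse."""
    if trial["rt_s"] <= 0:
        raise ConfigurationError("trial rt_s must be positive")
    row = {k: trial[k] for k in
           ("modality", "coherence", "heading_deg", "choice", "rt_s")}
    row["subject"] = "x"
    df = pd.DataFrame([row])
    ll, _ = table_loglik(params, df, profile=profile, floor=None)
    return ll


# ---------------------------------------------------------------------
# parameter packing and moment-based initialization
# ---------------------------------------------------------------------

_LOG_FLOOR = -12.0


def _pack(params: SubjectParams, fit_lapse: bool) -> np.ndarray:
    v = [math.log(max(params.k_vest, 1e-5))]
    v += [math.log(max(k, 1e-5)) for k in params.k_vis]
    v += [math.log(max(t, 1e-5)) for t in params.cell_bounds()]
    v += [math.log(max(params.t_nd[m], 1e-4)) for m in MODALITIES]
    v += [math.atanh(np.clip(params.bias, -0.999, 0.999))]
    if fit_lapse:
        p = np.clip(params.lapse, 1e-4, 0.0999) / 0.1
        v += [math.log(p / (1 - p))]
    return np.array(v)


def _unpack(v: np.ndarray, coherences, fit_lapse: bool) -> SubjectParams:
    C = len(coherences)
    v = np.clip(v, _LOG_FLOOR, 12.0)
    i = 0
    k_vest = math.exp(v[i]); i += 1
    k_vis = np.exp(v[i:i + C]); i += C
    theta = np.exp(v[i:i + 2 * C + 1]); i += 2 * C + 1
    t_nd = {m: math.exp(v[i + j]) for j, m in enumerate(MODALITIES)}
    i += 3
    bias = math.tanh(v[i]); i += 1
    lapse = 0.0
    if fit_lapse:
        lapse = 0.1 / (1 + math.exp(-v[i]))
    return SubjectParams(k_vest=k_vest, k_vis=k_vis,
                         coherences=tuple(coherences),
                         bounds=BoundVector.free(theta), t_nd=t_nd,
                         bias=bias, lapse=lapse)


def _moments_init(trials: pd.DataFrame, design: ExperimentDesign,
                  profile: StimulusProfile) -> SubjectParams:
    """Method-of-moments starting point: non-decision time from minimum
    RTs, bounds and sensitivities from a constant-drift inversion of
    per-cell accuracy and mean decision time."""
    t_nd = {}
    for m in MODALITIES:
        sub = trials[trials["modality"] == m]
        t_nd[m] = max(float(sub["rt_s"].min()) - 0.1, 0.05) if len(sub) \
            else 0.3
    v_mean = float(profile.velocity.mean())
    mean_abs_sin = float(np.mean([abs(math.sin(math.radians(h)))
                                  for h in design.headings_deg if h != 0]))
    theta0 = np.full(design.n_cells, 1.0)
    mu_bar = np.full(design.n_cells, 1.0)
    key = trials["coherence"].where(trials["coherence"].notna(), -1.0)
    for ci, cond in enumerate(design.cells):
        coh = -1.0 if cond.coherence is None else cond.coherence
        sub = trials[(trials["modality"] == cond.modality)
                     & np.isclose(key, coh)
                     & (trials["heading_deg"] != 0)]
        if not len(sub):
            continue
        correct = (sub["choice"] * np.sign(sub["heading_deg"]) > 0)
        p = float(np.clip(correct.mean(), 0.55, 0.97))
        dtm = max(float(sub["rt_s"].mean()) - t_nd[cond.modality], 0.05)
        L = math.log(p / (1 - p))
        theta0[ci] = math.sqrt(0.5 * L * dtm / math.tanh(L / 2))
        mu_bar[ci] = L / (2 * theta0[ci])
    k_vest = mu_bar[0] / (mean_abs_sin * v_mean)
    C = len(design.coherences)
    k_vis = mu_bar[1:1 + C] / (mean_abs_sin * v_mean)
    bias0 = float(np.clip(2 * ((trials["choice"] == 1).mean() - 0.5),
                          -0.5, 0.5))
    return SubjectParams(k_vest=k_vest, k_vis=k_vis,
                         coherences=design.coherences,
                         bounds=BoundVector.free(theta0), t_nd=t_nd,
                         bias=bias0)


def fit_subject(trials: pd.DataFrame, variant: str = "free",
                settings: FitSettings | None = None,
                design: ExperimentDesign | None = None,
                init: SubjectParams | None = None) -> FitResult:
    """Fit one subject's diffusion-model parameters by maximum likelihood.

    ``variant='free'`` fits one scaled bound per modality/coherence cell
    (2C+1 bound parameters).  The parametric variant is obtained
    downstream by restricting the reward-rate optimization, not the fit.
    Requires at least one trial per modality.
    """
    if variant != "free":
        raise ConfigurationError(
            "only the free bound variant is fitted directly")
    settings = settings or FitSettings()
    trials = validate_trials(trials)
    for m in MODALITIES:
        if not (trials["modality"] == m).any():
            raise FitError(f"no trials of modality {m!r}")
    if design is None:
        coh = tuple(sorted(trials["coherence"].dropna().unique()))
        hs = tuple(sorted(trials["heading_deg"].unique()))
        design = ExperimentDesign(coherences=coh, headings_deg=hs)
    profile = make_stimulus_profile(design.duration_s, settings.solver_dt_s)
    groups = _group_trials(trials, design)

    def objective(v):
        p = _unpack(v, design.coherences, settings.fit_lapse)
        ll, _ = _loglik_from_groups(p, groups, design, profile,
                                    settings.n_x, _DENSITY_FLOOR)
        return -ll

    if init is None:
        init = _moments_init(trials, design, profile)
    x0 = _pack(init, settings.fit_lapse)
    rng = np.random.default_rng(settings.seed)
    starts = [x0]
    for _ in range(max(settings.n_restarts - 1, 0)):
        starts.append(x0 + rng.normal(0, settings.restart_scale, len(x0)))

    best = None
    convergence = []
    for si, s in enumerate(starts):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = minimize(objective, s, method="Powell",
                               options={"maxiter": settings.maxiter,
                                        "ftol": settings.fatol,
                                        "xtol": settings.xatol})
        except Exception as exc:  # pragma: no cover - defensive
            convergence.append({"restart": si, "status": f"error: {exc}"})
            continue
        convergence.append({"restart": si, "status": "converged"
                            if res.success else "maxiter",
                            "loglik": -float(res.fun),
                            "n_iter": int(res.nit)})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"all restarts failed: {convergence}")
    params = _unpack(best.x, design.coherences, settings.fit_lapse)
    ll, n_flagged = table_loglik(params, trials, profile=profile,
                                 n_x=settings.n_x)
    return FitResult(params=params, loglik=float(ll), n_trials=len(trials),
                     n_flagged_trials=n_flagged, convergence=convergence,
                     settings={"n_restarts": settings.n_restarts,
                               "maxiter": settings.maxiter,
                               "n_x": settings.n_x,
                               "solver_dt_s": settings.solver_dt_s,
                               "fit_lapse": settings.fit_lapse},
                     seed=settings.seed)


def predicted_psychometric(params: SubjectParams, design: ExperimentDesign,
                           profile: StimulusProfile | None = None,
                           n_x: int = 101) -> pd.DataFrame:
    """Model psychometric/chronometric table: per condition cell, accuracy
    and mean RT marginalized over the design's headings (equal weights)."""
    if profile is None:
        profile = make_stimulus_profile(design.duration_s)
    theta_cells = params.cell_bounds()
    combos = [(ci, h) for ci in range(design.n_cells)
              for h in design.headings_deg]
    mu_b = np.empty((len(combos), profile.n_steps))
    th_b = np.empty(len(combos))
    for i, (ci, h) in enumerate(combos):
        mu_b[i] = drift_timecourse(params, design.cells[ci], h, profile)
        th_b[i] = theta_cells[ci]
    g_up, g_lo, forced = fpt_solve_batch(mu_b, th_b, params.bias, profile,
                                         n_x)
    dt = profile.dt_s
    dens = g_up + g_lo
    p_up = g_up.sum(axis=1) * dt + forced[:, 0]
    mean_dt = ((profile.t[None, :] * dens).sum(axis=1) * dt
               + profile.duration_s * forced.sum(axis=1))
    rows = []
    for ci, cond in enumerate(design.cells):
        idx = [i for i, (c, _) in enumerate(combos) if c == ci]
        pc, mdt = [], []
        for i in idx:
            h = combos[i][1]
            if h > 0:
                p = p_up[i]
            elif h < 0:
                p = 1.0 - p_up[i]
            else:
                p = 0.5
            pc.append(p)
            mdt.append(mean_dt[i])
        pc = float(np.mean(pc))
        if params.lapse > 0:
            pc = (1 - params.lapse) * pc + params.lapse * 0.5
            mdt = ((1 - params.lapse) * float(np.mean(mdt))
                   + params.lapse * profile.duration_s / 2)
        else:
            mdt = float(np.mean(mdt))
        rows.append({"modality": cond.modality,
                     "coherence": cond.coherence, "p_correct": pc,
                     "mean_dt": mdt,
                     "mean_rt": mdt + params.t_nd[cond.modality]})
    return pd.DataFrame(rows)
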