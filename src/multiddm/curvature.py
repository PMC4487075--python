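"""Incomplete-gradient-learning diagnostics.

Gradient-based learning of decision bounds converges at a rate set by the
local curvature of the reward-rate surface: steep eigendirections of its
Hessian are learned quickly, shallow ones slowly.  A prematurely stopped
learner therefore ends near-optimal along high-curvature eigendimensions
and far from optimal along low-curvature ones.  This module estimates the
Hessian of the reward rate at the fitted bounds by finite differences,
projects the bound mismatch into its eigenspace, validates the quadratic
approximation of the reward-rate loss, and simulates the learning rule
itself (exact gradient steps theta_n = theta_{n-1} + alpha * grad f, or a
stochastic single-bound acceptance rule f(theta_n) > f(theta_{n-1}) + eps).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .errors import ConfigurationError, InstabilityError, NumericalError
from .params import SubjectParams
from .profiles import StimulusProfile
from .reward import RewardRateObjective, RewardSpec

__all__ = ["CurvatureReport", "LearningConfig", "LearningTrajectory",
           "fd_hessian", "reward_rate_hessian",
           "curvature_distance_analysis", "quadratic_loss_check",
           "simulate_learning"]

#: eigenvalues below this magnitude are tagged untestable for the
#: curvature/distance relation
DEGENERATE_EIGENVALUE = 1e-8


def fd_hessian(f, x: np.ndarray, step: float = 1e-2):
    """Central-difference Hessian of a scalar function.

    Returns ``(H, symmetry_defect)`` where H is symmetrized as
    (H + H^T)/2 and the defect is the max abs asymmetry before
    symmetrization.
    """
    x = np.asarray(x, dtype=float)
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)

    def ev(delta):
        return f(x + delta)

    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (ev(ei) - 2 * f0 + ev(-ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = (ev(ei + ej) - ev(ei - ej) - ev(-ei + ej)
                       + ev(-ei - ej)) / (4 * step**2)
            H[j, i] = H[i, j]
    defect = float(np.max(np.abs(H - H.T)))
    return 0.5 * (H + H.T), defect


@dataclass
class CurvatureReport:
    """Hessian of the reward rate at the fitted bounds and its eigensystem.

    Eigenvalues are reported signed (all non-positive at a true maximum);
    analyses use their magnitudes.  ``overlap()`` exposes |V| so the
    alignment of the eigenspace with the original bound coordinates can be
    inspected rather than assumed.
    """

    H: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray   # columns are eigenvectors
    fd_step: float
    symmetry_defect: float
    cell_labels: list
    richardson_flagged: bool = False
    richardson_rel_diff: float | None = None

    def overlap(self) -> np.ndarray:
        return np.abs(self.eigenvectors)

    def to_dict(self) -> dict:
        return {"H": self.H.tolist(),
                "eigenvalues": self.eigenvalues.tolist(),
                "eigenvectors": self.eigenvectors.tolist(),
                "fd_step": self.fd_step,
                "symmetry_defect": self.symmetry_defect,
                "cell_labels": list(self.cell_labels),
                "richardson_flagged": self.richardson_flagged,
                "richardson_rel_diff": self.richardson_rel_diff}


def reward_rate_hessian(params: SubjectParams, design: ExperimentDesign,
                        theta_hat, spec: RewardSpec,
                        fd_step: float = 1e-2,
                        profile: StimulusProfile | None = None,
                        n_x: int = 101,
                        richardson: bool = True) -> CurvatureReport:
    """Finite-difference Hessian of the reward rate at the fitted bounds.

    ``theta_hat`` may be a BoundVector or a per-cell array.  A Richardson
    consistency check recomputes the Hessian at half the step; a relative
    mismatch above 10% is flagged in the report.
    """
    obj = RewardRateObjective(params, design, spec, profile, n_x)
    if hasattr(theta_hat, "cell_bounds"):
        th = theta_hat.cell_bounds(design.coherences)
    else:
        th = np.asarray(theta_hat, dtype=float)
    H, defect = fd_hessian(obj, th, fd_step)
    if not np.all(np.isfinite(H)):
        bad = [(obj.design.cell_labels[i], obj.design.cell_labels[j])
               for i, j in zip(*np.where(~np.isfinite(H)))]
        raise NumericalError(f"non-finite Hessian entries at {bad}")
    flagged = False
    rel = None
    if richardson:
        H2, _ = fd_hessian(obj, th, fd_step / 2)
        scale = max(float(np.max(np.abs(H))), 1e-12)
        rel = float(np.max(np.abs(H - H2)) / scale)
        flagged = rel > 0.10
    evals, evecs = np.linalg.eigh(H)
    return CurvatureReport(H=H, eigenvalues=evals, eigenvectors=evecs,
                           fd_step=fd_step, symmetry_defect=defect,
                           cell_labels=design.cell_labels,
                           richardson_flagged=flagged,
                           richardson_rel_diff=rel)


def curvature_distance_analysis(report: CurvatureReport, theta_hat,
                                theta_opt) -> pd.DataFrame:
    """Per-eigendimension (|curvature|, |projected bound distance|) pairs.

    The bound mismatch theta_opt - theta_hat is projected into the
    Hessian eigenspace; each dimension is tagged by the original
    modality/coherence cell with the largest eigenvector loading.  Rows
    are sorted by decreasing |curvature|.
    """
    th = np.asarray(theta_hat, dtype=float)
    to = np.asarray(theta_opt, dtype=float)
    d = len(report.eigenvalues)
    if th.shape != (d,) or to.shape != (d,):
        raise ConfigurationError("bound vectors must match Hessian dim")
    delta_proj = report.eigenvectors.T @ (to - th)
    rows = []
    for i in range(d):
        lam = float(report.eigenvalues[i])
        rows.append({
            "dim": i,
            "eigenvalue": lam,
            "abs_curvature": abs(lam),
            "abs_distance": float(abs(delta_proj[i])),
            "dominant_cell": report.cell_labels[
                int(np.argmax(np.abs(report.eigenvectors[:, i])))],
            "testable": abs(lam) >= DEGENERATE_EIGENVALUE})
    out = pd.DataFrame(rows).sort_values(
        "abs_curvature", ascending=False, ignore_index=True)
    return out


def quadratic_loss_check(report: CurvatureReport, theta_hat, theta_opt,
                         rr_hat: float, rr_opt: float):
    """Compare the model reward-rate loss with its quadratic prediction.

    Returns ``(model_loss, quadratic_loss)`` with
    model_loss = rr_opt - rr_hat and
    quadratic_loss = 0.5 |Delta^T H Delta|, Delta = theta_opt - theta_hat.
    """
    if rr_opt < rr_hat - 1e-12:
        raise ConfigurationError("rr_opt must be >= rr_hat")
    delta = np.asarray(theta_opt, dtype=float) - np.asarray(theta_hat,
                                                            dtype=float)
    quad = 0.5 * abs(float(delta @ report.H @ delta))
    return float(rr_opt - rr_hat), quad


# ---------------------------------------------------------------------
# learning-rule simulation
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class LearningConfig:
    """Gradient-learning rule settings.

    ``deterministic`` mode applies theta += alpha * grad f with a central
    finite-difference gradient; ``stochastic-acceptance`` mode perturbs a
    single random bound per step (Gaussian, sd alpha) and accepts iff the
    noisy improvement criterion f(new) > f(old) + eps holds, with eps
    zero-mean Gaussian of sd ``eps_sd``.
    """

    alpha: float | None
    n_steps: int
    mode: str = "deterministic"
    eps_sd: float = 0.0
    seed: int = 0
    grad_fd_step: float = 1e-3

    def __post_init__(self):
        # alpha=None means "auto": callers derive it from the local
        # curvature before running the rule
        if self.alpha is not None and self.alpha <= 0:
            raise ConfigurationError("alpha must be positive")
        if self.n_steps < 0:
            raise ConfigurationError("n_steps must be >= 0")
        if self.eps_sd < 0:
            raise ConfigurationError("eps_sd must be >= 0")
        if self.mode not in ("deterministic", "stochastic-acceptance"):
            raise ConfigurationError(
                "mode must be 'deterministic' or 'stochastic-acceptance'")


@dataclass
class LearningTrajectory:
    """Sequence of bound vectors theta_0..theta_N and objective values."""

    thetas: np.ndarray   # (n_steps+1, d)
    values: np.ndarray   # (n_steps+1,)

    @property
    def endpoint(self) -> np.ndarray:
        return self.thetas[-1]


def simulate_learning(surface, theta0, config: LearningConfig,
                      lower: float | None = None) -> LearningTrajectory:
    """Run the gradient-learning rule on an objective surface.

    ``surface`` is any callable of a bound vector; ``lower`` optionally
    clips the trajectory from below (bounds are nonnegative).  Raises
    InstabilityError when the trajectory norm exceeds 1e3 times the
    starting norm.
    """
    if config.alpha is None:
        raise ConfigurationError("alpha must be resolved (not None) "
                                 "before simulating the rule")
    theta = np.array(theta0, dtype=float)
    d = len(theta)
    limit = 1e3 * max(float(np.linalg.norm(theta)), 1.0)
    rng = np.random.default_rng(config.seed)
    thetas = [theta.copy()]
    values = [float(surface(theta))]
    for _ in range(config.n_steps):
        if config.mode == "deterministic":
            g = np.empty(d)
            h = config.grad_fd_step
            for i in range(d):
                e = np.zeros(d)
                e[i] = h
                g[i] = (surface(theta + e) - surface(theta - e)) / (2 * h)
            theta = theta + config.alpha * g
        else:
            j = int(rng.integers(d))
            prop = theta.copy()
            prop[j] += rng.normal(0.0, config.alpha)
            if lower is not None:
                prop[j] = max(prop[j], lower)
            eps = rng.normal(0.0, config.eps_sd) if config.eps_sd > 0 \
                else 0.0
            if float(surface(prop)) > values[-1] + eps:
                theta = prop
        if lower is not None:
            theta = np.maximum(theta, lower)
        if np.linalg.norm(theta) > limit:
            raise InstabilityError(
                "learning trajectory diverged; use a smaller alpha")
        thetas.append(theta.copy())
        values.append(float(surface(theta)))
    return LearningTrajectory(thetas=np.array(thetas),
                              values=np.array(values))
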