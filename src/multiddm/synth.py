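"""Synthetic subjects and trial tables with the experiment's structure.

The generator stands in for the undeposited human dataset: interleaved
modality/coherence conditions, 2 s maximum stimulus, ~6 s inter-trial
interval, left/right heading choices, per-modality non-decision times, a
start-point choice bias, and coherence-dependent visual reliability.
"Truncated-learner" subjects carry bounds produced by a prematurely
stopped gradient ascent on their own reward-rate surface, embodying the
incomplete-learning hypothesis.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .curvature import LearningConfig, reward_rate_hessian, \
    simulate_learning
from .design import ExperimentDesign
from .errors import ConfigurationError
from .model import simulate_trials
from .params import BoundVector, SubjectParams
from .profiles import StimulusProfile
from .reward import OptimizationResult, RewardRateObjective, RewardSpec, \
    optimize_bounds

__all__ = ["TruthRecord", "default_template", "generate_subject",
           "make_truncated_learner", "generate_cohort"]


@dataclass
class TruthRecord:
    """Everything needed to regenerate a synthetic subject bit-exactly."""

    subject: str
    params: SubjectParams
    design: ExperimentDesign
    seed: int
    learning: dict | None = None

    def to_json(self) -> str:
        d = {"subject": self.subject, "params": self.params.to_dict(),
             "design": {"coherences": list(self.design.coherences),
                        "headings_deg": list(self.design.headings_deg),
                        "n_per_cell": self.design.n_per_cell,
                        "duration_s": self.design.duration_s,
                        "iti_s": self.design.iti_s},
             "seed": self.seed, "learning": self.learning}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "TruthRecord":
        d = json.loads(s)
        return cls(subject=d["subject"],
                   params=SubjectParams.from_dict(d["params"]),
                   design=ExperimentDesign(**d["design"]),
                   seed=d["seed"], learning=d.get("learning"))


def default_template(coherences=(0.25, 0.37, 0.70)) -> SubjectParams:
    """Template subject with plausible heading-discrimination parameters.

    Sensitivities put visual reliability at 70% coherence above the
    vestibular one (and below it at 25%), bounds near 1.2-1.5 in scaled
    units, non-decision times around 300 ms, and a small rightward bias.
    """
    coherences = tuple(coherences)
    C = len(coherences)
    k_vis = 25.0 * np.asarray(coherences)
    theta = np.concatenate([[1.3],
                            np.linspace(1.1, 1.4, C),
                            np.linspace(1.2, 1.5, C)])
    return SubjectParams(
        k_vest=8.0, k_vis=k_vis, coherences=coherences,
        bounds=BoundVector.free(theta),
        t_nd={"vestibular": 0.30, "visual": 0.35, "combined": 0.32},
        bias=0.03, lapse=0.0)


def generate_subject(truth: SubjectParams, design: ExperimentDesign,
                     seed: int = 0, subject: str = "S01",
                     profile: StimulusProfile | None = None,
                     learning: dict | None = None
                     ) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate one subject's trial table (interleaved, seeded shuffle)."""
    df = simulate_trials(truth, design, seed=seed, profile=profile,
                         subject=subject)
    shuffler = np.random.default_rng(seed + 1)
    df = df.sample(frac=1.0, random_state=np.random.RandomState(
        shuffler.integers(2**31 - 1))).reset_index(drop=True)
    record = TruthRecord(subject=subject, params=truth, design=design,
                         seed=seed, learning=learning)
    return df, record


def make_truncated_learner(base: SubjectParams, design: ExperimentDesign,
                           spec: RewardSpec,
                           config: LearningConfig | None = None,
                           opt: OptimizationResult | None = None,
                           start_frac: float = 0.1,
                           n_restarts: int = 5, seed: int = 0,
                           profile: StimulusProfile | None = None,
                           n_x: int = 101, return_info: bool = False):
    """Subject whose bounds come from prematurely stopped gradient ascent.

    The reward-rate surface of ``base`` is maximized to locate theta*;
    learning then starts at ``start_frac * theta*`` (default 0.1) and runs
    ``config.n_steps`` gradient steps.  The default step size is set to
    0.3 / |lambda|_max from the Hessian at theta*, so steep
    eigendirections close most of their gap within the truncated run
    while shallow ones barely move.  All non-bound parameters are left
    unchanged.
    """
    if not 0 <= start_frac:
        raise ConfigurationError("start_frac must be >= 0")
    if opt is None:
        opt = optimize_bounds(base, design, spec, n_restarts=n_restarts,
                              seed=seed, profile=profile, n_x=n_x)
    theta_opt = opt.cell_bounds(design.coherences)
    surface = RewardRateObjective(base, design, spec, profile, n_x)
    if config is None or config.alpha is None:
        report = reward_rate_hessian(base, design, theta_opt, spec,
                                     profile=profile, n_x=n_x,
                                     richardson=False)
        lam_max = float(np.max(np.abs(report.eigenvalues)))
        alpha = 0.3 / max(lam_max, 1e-9)
        if config is None:
            config = LearningConfig(alpha=alpha, n_steps=10, seed=seed)
        else:
            config = replace(config, alpha=alpha)
    theta0 = start_frac * theta_opt
    traj = simulate_learning(surface, theta0, config, lower=0.0)
    learned = base.with_bounds(BoundVector.free(traj.endpoint))
    if return_info:
        info = {"config": {"alpha": config.alpha,
                           "n_steps": config.n_steps,
                           "mode": config.mode, "eps_sd": config.eps_sd,
                           "seed": config.seed},
                "start_frac": start_frac,
                "theta_opt": theta_opt.tolist(),
                "rr_opt": opt.rr_opt,
                "rr_end": float(traj.values[-1])}
        return learned, info
    return learned


def generate_cohort(n_subjects: int, base_variability: float = 0.15,
                    seed: int = 0,
                    template: SubjectParams | None = None,
                    design: ExperimentDesign | None = None,
                    spec: RewardSpec | None = None,
                    truncated: bool = False,
                    learner_config: LearningConfig | None = None,
                    profile: StimulusProfile | None = None,
                    n_x: int = 101, opt_restarts: int = 5
                    ) -> list[tuple[pd.DataFrame, TruthRecord]]:
    """Generate a cohort of synthetic subjects.

    Per-subject truths perturb the template log-normally (sd
    ``base_variability``) on sensitivities and bounds; with
    ``truncated=True`` each subject's bounds are instead the endpoint of
    an incomplete gradient-ascent run on that subject's own reward-rate
    surface.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    if base_variability < 0:
        raise ConfigurationError("base_variability must be >= 0")
    if template is None:
        template = default_template()
    if design is None:
        design = ExperimentDesign(coherences=template.coherences)
    if spec is None:
        spec = RewardSpec(iti_s=design.iti_s)
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        sv = base_variability
        k_vest = template.k_vest * rng.lognormal(0, sv) if sv else \
            template.k_vest
        k_vis = template.k_vis * (rng.lognormal(0, sv, len(template.k_vis))
                                  if sv else 1.0)
        theta = template.cell_bounds() * (
            rng.lognormal(0, sv, design.n_cells) if sv else 1.0)
        bias = float(np.clip(template.bias + (rng.normal(0, 0.02)
                                              if sv else 0.0),
                             -0.5, 0.5))
        truth = SubjectParams(
            k_vest=float(k_vest), k_vis=k_vis,
            coherences=template.coherences,
            bounds=BoundVector.free(theta), t_nd=dict(template.t_nd),
            bias=bias, lapse=template.lapse)
        learning = None
        if truncated:
            truth, learning = make_truncated_learner(
                truth, design, spec, config=learner_config,
                seed=sub_seed, profile=profile, n_x=n_x,
                n_restarts=opt_restarts, return_info=True)
        name = f"S{i + 1:02d}"
        df, rec = generate_subject(truth, design, seed=sub_seed,
                                   subject=name, profile=profile,
                                   learning=learning)
        out.append((df, rec))
    return out
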