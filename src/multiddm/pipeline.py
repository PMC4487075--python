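"""End-to-end orchestration: simulate -> fit -> optimize -> diagnose -> report.

``run_full_analysis`` processes a cohort of trial tables through the
maximum-likelihood fit, the reward-rate maximization under a set of
variants (accumulation costs, parametric bounds, bias removal), the
curvature diagnostics, and the cohort-level nonparametric tests, writing
JSON/CSV report bundles.  Subject-level failures are isolated so the run
continues.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curvature import curvature_distance_analysis, quadratic_loss_check, \
    reward_rate_hessian
from .design import ExperimentDesign, MODALITIES
from .errors import ConfigurationError, MultiDDMError
from .fitting import FitSettings, fit_subject
from .params import SubjectParams
from .profiles import make_stimulus_profile
from .reward import RewardSpec, empirical_reward_rate, optimize_bounds, \
    project_to_bound_line, random_choice_rr, relative_rr
from .stats import bootstrap_rr_ci, wilcoxon_signed_rank_exact

logger = logging.getLogger("multiddm")

__all__ = ["VariantSpec", "AnalysisConfig", "default_variants",
           "run_full_analysis", "compare_subgroups", "write_report"]


@dataclass(frozen=True)
class VariantSpec:
    """One reward-rate assumption set: accumulation cost, bound variant
    for the optimum, and whether choice biases are removed before the
    maximization (the subject's own reward rate keeps the bias)."""

    name: str
    cost_per_s: float = 0.0
    bound_variant: str = "free"
    unbiased: bool = False

    def __post_init__(self):
        if self.bound_variant not in ("free", "parametric"):
            raise ConfigurationError("bound_variant must be free|parametric")
        if self.cost_per_s < 0:
            raise ConfigurationError("cost_per_s must be >= 0")


def default_variants() -> list[VariantSpec]:
    """The six standard assumption sets (box-plot columns)."""
    return [
        VariantSpec("no_cost"),
        VariantSpec("cost_0.1", cost_per_s=0.1),
        VariantSpec("cost_0.2", cost_per_s=0.2),
        VariantSpec("parametric", bound_variant="parametric"),
        VariantSpec("unbiased", unbiased=True),
        VariantSpec("unbiased_parametric", bound_variant="parametric",
                    unbiased=True),
    ]


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run."""

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    variants: list = field(default_factory=default_variants)
    iti_s: float = 6.0
    solver_dt_s: float = 0.01
    n_x: int = 81
    fit_settings: FitSettings = field(default_factory=lambda: FitSettings(
        n_restarts=1, solver_dt_s=0.01, n_x=81))
    opt_restarts: int = 5
    curvature_fd_step: float = 1e-2
    curvature_richardson: bool = True
    n_boot: int = 2000
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        if "design" in raw:
            kw["design"] = ExperimentDesign(**raw["design"])
        if "variants" in raw:
            kw["variants"] = [VariantSpec(**v) for v in raw["variants"]]
        if "fit_settings" in raw:
            kw["fit_settings"] = FitSettings(**raw["fit_settings"])
        for k in ("iti_s", "solver_dt_s", "n_x", "opt_restarts",
                  "curvature_fd_step", "curvature_richardson", "n_boot",
                  "seed", "out_dir"):
            if k in raw:
                kw[k] = raw[k]
        return cls(**kw)

    def echo(self) -> dict:
        return {
            "design": {"coherences": list(self.design.coherences),
                       "headings_deg": list(self.design.headings_deg),
                       "n_per_cell": self.design.n_per_cell,
                       "duration_s": self.design.duration_s,
                       "iti_s": self.design.iti_s},
            "variants": [{"name": v.name, "cost_per_s": v.cost_per_s,
                          "bound_variant": v.bound_variant,
                          "unbiased": v.unbiased} for v in self.variants],
            "iti_s": self.iti_s, "solver_dt_s": self.solver_dt_s,
            "n_x": self.n_x, "opt_restarts": self.opt_restarts,
            "curvature_fd_step": self.curvature_fd_step,
            "n_boot": self.n_boot, "seed": self.seed,
        }


def compare_subgroups(trials: pd.DataFrame, spec: RewardSpec,
                      t_nd: dict | None = None, n_boot: int = 2000,
                      seed: int = 0) -> pd.DataFrame:
    """Empirical reward rate with bootstrap CI per trial subgroup.

    Subgroups: combined trials, visual trials, vestibular trials, and the
    pooled unimodal trials.  Missing subgroups are flagged and omitted.
    """
    mods = set(trials["modality"])
    if len(mods & set(MODALITIES)) < 2:
        raise ConfigurationError("need trials from >= 2 modalities")
    subgroups = {
        "combined": trials["modality"] == "combined",
        "visual": trials["modality"] == "visual",
        "vestibular": trials["modality"] == "vestibular",
        "unimodal": trials["modality"].isin(["visual", "vestibular"]),
    }
    rows = []
    for name, mask in subgroups.items():
        sub = trials[mask]
        if len(sub) == 0:
            logger.warning("subgroup %s missing; omitted", name)
            continue
        rr = empirical_reward_rate(sub, spec, t_nd)
        lo, hi = bootstrap_rr_ci(sub, spec, n_boot=n_boot, seed=seed,
                                 t_nd=t_nd)
        rows.append({"subgroup": name, "rr": rr, "ci_low": lo,
                     "ci_high": hi, "n_trials": len(sub)})
    return pd.DataFrame(rows)


def _analyze_subject(name, trials, config, profile, truth=None):
    """Fit + per-variant optimization + diagnostics for one subject."""
    design = config.design
    if truth is not None:
        fitted = truth  # known-truth mode skips the ML fit
        fit_info = {"mode": "truth"}
    else:
        fit = fit_subject(trials, settings=config.fit_settings,
                          design=design)
        fitted = fit.params
        fit_info = {"mode": "ml", "loglik": fit.loglik,
                    "n_trials": fit.n_trials}
    theta_hat = fitted.cell_bounds()
    out = {"subject": name, "fit": fit_info,
           "theta_hat": theta_hat.tolist(), "variants": {}}
    for variant in config.variants:
        spec = RewardSpec(iti_s=config.iti_s,
                          cost_per_s=variant.cost_per_s)
        p_opt = fitted.with_bias(0.0) if variant.unbiased else fitted
        opt = optimize_bounds(p_opt, design, spec,
                              n_restarts=config.opt_restarts,
                              seed=config.seed, profile=profile,
                              n_x=config.n_x,
                              variant=variant.bound_variant)
        rr_subject = empirical_reward_rate(trials, spec, fitted.t_nd)
        rr_random = random_choice_rr(fitted, design, spec, profile,
                                     config.n_x)
        rec = {"rr_subject": rr_subject, "rr_opt": opt.rr_opt,
               "rr_random": rr_random,
               "relative_rr": relative_rr(rr_subject, opt),
               "relative_rr_random": relative_rr(rr_random, opt),
               "theta_opt": opt.cell_bounds(design.coherences).tolist()}
        if variant.bound_variant == "free" and not variant.unbiased:
            try:
                rec["s_projection"] = project_to_bound_line(
                    fitted.bounds, opt, p_opt, design, spec,
                    profile=profile, n_x=config.n_x)
            except MultiDDMError as exc:
                rec["s_projection"] = None
                rec["s_projection_error"] = str(exc)
            if variant.cost_per_s == 0:
                report = reward_rate_hessian(
                    p_opt, design, theta_hat, spec,
                    fd_step=config.curvature_fd_step, profile=profile,
                    n_x=config.n_x,
                    richardson=config.curvature_richardson)
                pairs = curvature_distance_analysis(
                    report, theta_hat,
                    opt.cell_bounds(design.coherences))
                from .reward import model_reward_rate
                rr_model = model_reward_rate(fitted, design, spec,
                                             profile, config.n_x)
                model_loss, quad_loss = quadratic_loss_check(
                    report, theta_hat,
                    opt.cell_bounds(design.coherences),
                    rr_model, opt.rr_opt)
                rec["curvature"] = {
                    "eigenvalues": report.eigenvalues.tolist(),
                    "pairs": pairs.to_dict(orient="records"),
                    "model_loss": model_loss,
                    "quadratic_loss": quad_loss,
                    "richardson_flagged": report.richardson_flagged}
        out["variants"][variant.name] = rec
    return out


def _five_number(x):
    x = np.asarray(x, dtype=float)
    return {"min": float(x.min()), "q25": float(np.quantile(x, 0.25)),
            "median": float(np.median(x)),
            "q75": float(np.quantile(x, 0.75)), "max": float(x.max())}


def run_full_analysis(config: AnalysisConfig, tables: list,
                      truths: list | None = None) -> dict:
    """Run the full pipeline on a cohort.

    ``tables`` is a list of (subject_name, trial DataFrame); ``truths``
    optionally supplies known generating SubjectParams per subject (same
    order), in which case the ML fit stage is skipped.  Returns the
    report bundle (also written to ``config.out_dir`` when set).
    """
    profile = make_stimulus_profile(config.design.duration_s,
                                    config.solver_dt_s)
    subjects = []
    errors = []
    for i, (name, trials) in enumerate(tables):
        truth = truths[i] if truths is not None else None
        try:
            subjects.append(_analyze_subject(name, trials, config,
                                             profile, truth))
        except MultiDDMError as exc:
            logger.error("subject %s failed: %s", name, exc)
            errors.append({"subject": name, "error": str(exc)})
    report = {"config": config.echo(), "subjects": subjects,
              "errors": errors, "cohort": {}}
    # cohort-level summaries and tests per variant
    for variant in config.variants:
        rel = [s["variants"][variant.name]["relative_rr"]
               for s in subjects if variant.name in s["variants"]]
        rel_rand = [s["variants"][variant.name]["relative_rr_random"]
                    for s in subjects if variant.name in s["variants"]]
        if not rel:
            continue
        entry = {"relative_rr": _five_number(rel),
                 "relative_rr_random": _five_number(rel_rand)}
        diffs = np.array(rel) - np.array(rel_rand)
        if 0 < len(diffs) <= 25 and np.any(diffs != 0):
            w = wilcoxon_signed_rank_exact(diffs, alternative="greater")
            entry["wilcoxon_subject_vs_random"] = w.to_dict()
        report["cohort"][variant.name] = entry
    # combined-vs-unimodal subgroup comparison (cost-free convention)
    spec0 = RewardSpec(iti_s=config.iti_s)
    sub_rows = []
    for (name, trials) in tables:
        if any(e["subject"] == name for e in errors):
            continue
        try:
            sg = compare_subgroups(trials, spec0, n_boot=config.n_boot,
                                   seed=config.seed)
        except ConfigurationError:
            continue
        sg.insert(0, "subject", name)
        sub_rows.append(sg)
    if sub_rows:
        sg_all = pd.concat(sub_rows, ignore_index=True)
        report["subgroups"] = sg_all.to_dict(orient="records")
        piv = sg_all.pivot(index="subject", columns="subgroup",
                           values="rr")
        if {"combined", "unimodal"} <= set(piv.columns):
            diffs = (piv["unimodal"] - piv["combined"]).to_numpy()
            if len(diffs) <= 25 and np.any(diffs != 0):
                w = wilcoxon_signed_rank_exact(diffs, alternative="less")
                report["cohort"]["wilcoxon_unimodal_vs_combined"] = \
                    w.to_dict()
    if config.out_dir:
        write_report(report, config.out_dir)
    return report


def write_report(report: dict, out_dir) -> None:
    """Write the JSON report and a long-format CSV twin for plotting."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    rows = []
    for s in report["subjects"]:
        for vname, rec in s["variants"].items():
            rows.append({"subject": s["subject"], "variant": vname,
                         "rr_subject": rec["rr_subject"],
                         "rr_opt": rec["rr_opt"],
                         "rr_random": rec["rr_random"],
                         "relative_rr": rec["relative_rr"],
                         "s_projection": rec.get("s_projection")})
    pd.DataFrame(rows).to_csv(out / "report_long.csv", index=False)
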