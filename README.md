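# multiddm

Do decision-makers tune their speed–accuracy trade-off to maximize
reward rate?  `multiddm` is a Python toolkit for asking that question
with a multisensory drift-diffusion model: it fits choice/reaction-time
data from a heading-discrimination task with visual (optic flow),
vestibular (inertial motion), and combined cues, finds the decision
bounds that would maximize reward rate, quantifies how close the fitted
bounds come to that optimum, and diagnoses the residual mistuning as
incomplete gradient-based learning.  It is aimed at researchers in
perceptual decision-making who want a tested, reusable implementation of
this analysis, exercised end-to-end on fully specified synthetic
subjects.

## The model and the analysis

Evidence accumulates as a unit-variance diffusion with time-varying
drift, started at `bias·θ`, until it hits a scaled bound ±θ (rightward =
upper) or the 2 s stimulus ends (forced choice by the sign of the
accumulated evidence).  Drift follows the stimulus velocity profile
v(t) for visual evidence, the magnitude of its derivative for vestibular
evidence, and their reliability-weighted root-sum-square for combined
trials:

    μ_vest(t) = k_vest · sin(h) · |a(t)|
    μ_vis(t)  = k_vis(c) · sin(h) · v(t)
    μ_comb(t) = sin(h) · sqrt(k_vis(c)² v(t)² + k_vest² a(t)²)

Each modality × coherence cell carries its own scaled bound (7 bound
parameters for three coherence levels, 13 for six), or, in the
parametric variant, one bound per modality with a linear
coherence-to-diffusion-SD map.  The reward rate of a bound setting θ is

    f(θ) = (Σ w·p_correct − c·Σ w·E[t_decision]) / (Σ w·E[RT] + t_iti)

with reward 1 per correct choice, a 6 s mean inter-trial interval, and
an optional evidence-accumulation cost c (0.1–0.2 reward/s).  The
pipeline is: maximum-likelihood fit → gradient ascent on f over bounds
(50 random restarts by default) → relative reward rate f-subject/f-optimal
→ finite-difference Hessian of f at the fitted bounds, whose eigenspace
pairs each curvature magnitude with the projected distance to the
optimal bounds — the signature of prematurely terminated gradient
learning is a negative relation between the two.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from multiddm import (ExperimentDesign, RewardSpec, default_template,
                      make_stimulus_profile, make_truncated_learner,
                      model_reward_rate, random_choice_rr,
                      reward_rate_hessian, curvature_distance_analysis)

profile = make_stimulus_profile(2.0, 0.01)   # 2 s stimulus, 10 ms grid
template = default_template()                # 3 coherences, 7 bounds
design = ExperimentDesign(coherences=template.coherences,
                          headings_deg=(-16., -8., -2., 2., 8., 16.))
spec = RewardSpec(iti_s=6.0)

# a subject whose bounds come from prematurely stopped gradient learning
subject, info = make_truncated_learner(template, design, spec, seed=2,
                                       n_restarts=3, profile=profile,
                                       n_x=81, return_info=True)
theta_opt = np.array(info["theta_opt"])
rr = model_reward_rate(subject, design, spec, profile, 81)
rr_rand = random_choice_rr(subject, design, spec, profile, 81)
print(f"learned bounds: {np.round(subject.cell_bounds(), 2)}")
print(f"optimal bounds: {np.round(theta_opt, 2)}")
print(f"reward rate {rr:.4f}/s = {100 * rr / info['rr_opt']:.1f}% of optimum"
      f" {info['rr_opt']:.4f}/s (random choice: {rr_rand:.4f}/s)")

report = reward_rate_hessian(subject, design, subject.cell_bounds(),
                             spec, profile=profile, n_x=81)
pairs = curvature_distance_analysis(report, subject.cell_bounds(),
                                    theta_opt)
print(pairs[["dominant_cell", "abs_curvature", "abs_distance"]]
      .round(4).to_string(index=False))
rho = spearmanr(pairs["abs_curvature"], pairs["abs_distance"]).statistic
print(f"curvature-distance Spearman rho = {rho:+.2f}")
```

Output:

```
learned bounds: [1.18 0.02 0.02 0.03 1.26 1.31 1.43]
optimal bounds: [1.17 1.11 1.3  1.53 1.27 1.33 1.46]
reward rate 0.0971/s = 92.7% of optimum 0.1048/s (random choice: 0.0790/s)
 dominant_cell  abs_curvature  abs_distance
    vestibular         0.0052        0.0027
combined_c0.25         0.0047        0.0099
combined_c0.37         0.0044        0.0176
   visual_c0.7         0.0040        1.5019
 combined_c0.7         0.0037        0.0310
  visual_c0.25         0.0034        1.0919
  visual_c0.37         0.0026        1.2862
curvature-distance Spearman rho = -0.79
```

Read: the learner converged along the steep eigendirections (vestibular
and combined bounds end within hundredths of their optima) but stopped
with the shallow visual bounds far below theirs, yet still collects
92.7% of the optimal reward rate — the surface is flattest along exactly
the directions that remain mistuned, which is the incomplete-learning
signature (negative curvature-distance correlation).  Random guessing at
trial onset would collect only 75% of the optimum.  Fitting the model to
this subject's simulated trials (`fit_subject`) recovers the bounds to a
few percent; see `scripts/acceptance.py` for the full cohort pipeline.

A command-line interface wraps the same pipeline
(`multiddm simulate | fit | optimize | curvature | report | all`); try
`multiddm all --subjects 3 --seed 0 --out-dir out/`.

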