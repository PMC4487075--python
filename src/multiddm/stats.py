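"""Exact nonparametric tests and bootstrap confidence intervals.

The Wilcoxon signed-rank statistic W (sum of ranks of positive paired
differences) is tested against its exact null distribution, obtained by
the generating-function recursion over rank sums — arithmetically
identical to enumerating all 2^n sign assignments, and exact up to the
n <= 25 regime this package needs (the experiments have 10 subject
datasets).  Reward-rate uncertainty is quantified by percentile bootstrap
over trial resamples.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .design import MODALITIES
from .errors import ConfigurationError
from .reward import RewardSpec

__all__ = ["WilcoxonResult", "wilcoxon_signed_rank_exact",
           "exact_null_distribution", "bootstrap_rr_ci"]

MAX_EXACT_N = 25


@dataclass(frozen=True)
class WilcoxonResult:
    """Exact signed-rank test result.

    ``W`` sums the ranks of positive differences, so it lies in
    [0, n(n+1)/2]; one-tailed p follows the stated alternative
    ('greater': P(W >= w)); the two-tailed p doubles the smaller tail.
    ``exact`` is False when tied |differences| forced mid-ranks.
    """

    W: float
    n: int
    p_one_tailed: float
    p_two_tailed: float
    alternative: str
    exact: bool
    note: str = ""

    def to_dict(self) -> dict:
        return {"W": self.W, "n": self.n,
                "p_one_tailed": self.p_one_tailed,
                "p_two_tailed": self.p_two_tailed,
                "alternative": self.alternative, "exact": self.exact,
                "note": self.note}


def exact_null_distribution(ranks) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of W for given |difference| ranks.

    Returns ``(support, pmf)`` on the doubled-rank integer grid divided
    back by 2, so mid-ranks (.5 steps) are handled exactly.
    """
    r2 = np.round(np.asarray(ranks, dtype=float) * 2).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:len(counts) - r]
        counts = counts + shifted
    pmf = counts / counts.sum()
    support = np.arange(total + 1) / 2.0
    return support, pmf


def wilcoxon_signed_rank_exact(diffs, alternative: str = "greater"
                               ) -> WilcoxonResult:
    """Exact Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped with a warning; tied magnitudes receive
    mid-ranks and mark the result approximate (exact=False).  n after
    zero-dropping must be in [1, 25].
    """
    if alternative not in ("greater", "less"):
        raise ConfigurationError("alternative must be 'greater' or 'less'")
    d = np.asarray(diffs, dtype=float)
    if np.any(~np.isfinite(d)):
        raise ConfigurationError("differences must be finite")
    nz = d != 0
    if not np.all(nz):
        warnings.warn(f"dropping {int((~nz).sum())} zero difference(s)",
                      stacklevel=2)
        d = d[nz]
    n = len(d)
    if n == 0:
        raise ConfigurationError("no nonzero differences left")
    if n > MAX_EXACT_N:
        raise ConfigurationError(
            f"exact enumeration limited to n <= {MAX_EXACT_N}")
    ranks = rankdata(np.abs(d))
    ties = len(np.unique(np.abs(d))) < n
    W = float(ranks[d > 0].sum())
    support, pmf = exact_null_distribution(ranks)
    p_ge = float(pmf[support >= W - 1e-9].sum())
    p_le = float(pmf[support <= W + 1e-9].sum())
    p_one = p_ge if alternative == "greater" else p_le
    p_two = min(1.0, 2.0 * min(p_ge, p_le))
    note = ("mid-ranks used for tied |differences|; p exact conditional "
            "on ranks" if ties else "")
    return WilcoxonResult(W=W, n=n, p_one_tailed=p_one, p_two_tailed=p_two,
                          alternative=alternative, exact=not ties,
                          note=note)


def bootstrap_rr_ci(trials: pd.DataFrame, spec: RewardSpec,
                    n_boot: int = 2000, level: float = 0.95,
                    seed: int = 0, t_nd: dict | None = None
                    ) -> tuple[float, float]:
    """Percentile bootstrap CI of the empirical reward rate.

    Trials are resampled with replacement ``n_boot`` times (>= 1000);
    returns the (lower, upper) percentile interval at the given level.
    """
    if len(trials) == 0:
        raise ConfigurationError("empty trial table")
    if n_boot < 1000:
        raise ConfigurationError("n_boot must be >= 1000")
    if not 0 < level < 1:
        raise ConfigurationError("level must be in (0, 1)")
    if t_nd is None:
        t_nd = dict.fromkeys(MODALITIES, 0.0)
    sgn = np.sign(trials["heading_deg"].to_numpy(float))
    correct = np.where(sgn == 0, 0.5,
                       (trials["choice"].to_numpy(float) * sgn > 0)
                       .astype(float))
    rt = trials["rt_s"].to_numpy(float)
    tnd = trials["modality"].map(t_nd).to_numpy(float)
    dt_dec = np.clip(rt - tnd, 0.0, None)
    n = len(rt)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    fc = correct[idx].mean(axis=1)
    mdt = dt_dec[idx].mean(axis=1)
    mrt = rt[idx].mean(axis=1)
    rr = (spec.reward_correct * fc - spec.cost_per_s * mdt) \
        / (mrt + spec.iti_s)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(rr, [alpha, 1 - alpha])
    return float(lo), float(hi)
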