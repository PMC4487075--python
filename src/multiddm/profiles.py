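"""Stimulus velocity and acceleration profiles on the solver time grid.

The heading stimulus is a smooth forward translation: velocity follows a
bell-shaped (Gaussian) time course over the trial, and the inertial
(vestibular) system senses its derivative, the acceleration.  Both profiles
are peak-normalized so that all scaling lives in the drift sensitivities.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["StimulusProfile", "make_stimulus_profile"]


@dataclass(frozen=True)
class StimulusProfile:
    """Velocity/acceleration samples on a half-open time grid [0, duration).

    Attributes
    ----------
    duration_s : float
        Stimulus duration in seconds (the forced-choice deadline).
    dt_s : float
        Solver grid step in seconds.
    t : ndarray
        Time grid, ``t[n] = n * dt_s``, half-open at ``duration_s``.
    velocity : ndarray
        Peak-normalized velocity v(t), max 1, nonnegative, ~0 at the edges.
    acceleration : ndarray
        Peak-normalized acceleration a(t) = dv/dt (of the unnormalized
        velocity), antisymmetric about the velocity peak.
    """

    duration_s: float
    dt_s: float
    t: np.ndarray = field(repr=False)
    velocity: np.ndarray = field(repr=False)
    acceleration: np.ndarray = field(repr=False)

    @property
    def n_steps(self) -> int:
        return len(self.t)


def make_stimulus_profile(duration_s: float = 2.0, dt_s: float = 0.001,
                          width_frac: float = 1.0 / 6.0) -> StimulusProfile:
    """Build a Gaussian-bell velocity profile and its acceleration.

    The raw velocity is a Gaussian centred at ``duration_s/2`` with standard
    deviation ``width_frac * duration_s``, baseline-subtracted so it reaches
    exactly zero at the trial edges, then peak-normalized.  The acceleration
    is the discrete derivative of the *unnormalized* velocity, peak-normalized
    separately.

    Parameters
    ----------
    duration_s : float
        Stimulus duration (s); 2 s in the heading-discrimination task.
    dt_s : float
        Grid step (s); must satisfy ``dt_s <= duration_s / 100``.
    width_frac : float
        Gaussian standard deviation as a fraction of the duration, in (0, 0.5).
    """
    for name, val in (("duration_s", duration_s), ("dt_s", dt_s),
                      ("width_frac", width_frac)):
        if not (isinstance(val, (int, float)) and math.isfinite(val)):
            raise ConfigurationError(f"{name} must be a finite number, got {val!r}")
    if duration_s <= 0:
        raise ConfigurationError("duration_s must be positive")
    if not (0 < dt_s <= duration_s / 100):
        raise ConfigurationError("dt_s must be in (0, duration_s/100]")
    if not (0 < width_frac < 0.5):
        raise ConfigurationError("width_frac must be in (0, 0.5)")

    n = int(round(duration_s / dt_s))
    t = np.arange(n) * dt_s
    center = duration_s / 2.0
    sd = width_frac * duration_s
    raw = np.exp(-0.5 * ((t - center) / sd) ** 2)
    raw = np.clip(raw - raw[0], 0.0, None)  # exact zero at onset/offset
    a_raw = np.gradient(raw, dt_s)
    v = raw / raw.max()
    a = a_raw / np.max(np.abs(a_raw))
    return StimulusProfile(duration_s=float(duration_s), dt_s=float(dt_s),
                           t=t, velocity=v, acceleration=a)
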