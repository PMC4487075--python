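"""Model parameters: scaled decision bounds and full subject parameter sets.

The diffusion variance is normalized to one, so all bounds are *scaled*
bounds (actual bound divided by the diffusion standard deviation) and all
coherence dependence of evidence reliability lives in the visual drift
sensitivities (free variant) or in a parametric coherence-to-standard-
deviation map (parametric variant).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .design import MODALITIES, ExperimentDesign
from .errors import ConfigurationError

__all__ = ["BoundVector", "SubjectParams"]


@dataclass(frozen=True)
class BoundVector:
    """Scaled decision bounds, in one of two variants.

    free
        One nonnegative scaled bound per condition cell, in the canonical
        cell order (vestibular, visual x C, combined x C): 2C+1 values,
        i.e. 7 bound parameters for three coherences, 13 for six.
    parametric
        Three per-modality bounds (vestibular, visual, combined) plus a
        coherence slope ``sigma_slope`` mapping coherence c to a diffusion
        standard deviation sigma(c) = 1 - sigma_slope * c (must stay
        positive); the scaled bound of a visual/combined cell is then
        theta_modality / sigma(c).
    """

    variant: str = "free"
    theta: np.ndarray | None = None
    theta_modality: np.ndarray | None = None
    sigma_slope: float = 0.0

    def __post_init__(self):
        if self.variant not in ("free", "parametric"):
            raise ConfigurationError("variant must be 'free' or 'parametric'")
        if self.variant == "free":
            if self.theta is None:
                raise ConfigurationError("free variant requires theta")
            th = np.asarray(self.theta, dtype=float)
            if th.ndim != 1 or len(th) % 2 == 0:
                raise ConfigurationError(
                    "free theta must be a 1-d vector of odd length 2C+1")
            if not np.all(np.isfinite(th)) or np.any(th < 0):
                raise ConfigurationError("bounds must be finite and >= 0")
            object.__setattr__(self, "theta", th)
        else:
            if self.theta_modality is None:
                raise ConfigurationError(
                    "parametric variant requires theta_modality")
            tm = np.asarray(self.theta_modality, dtype=float)
            if tm.shape != (3,):
                raise ConfigurationError(
                    "theta_modality must have 3 entries "
                    "(vestibular, visual, combined)")
            if not np.all(np.isfinite(tm)) or np.any(tm < 0):
                raise ConfigurationError("bounds must be finite and >= 0")
            object.__setattr__(self, "theta_modality", tm)

    @classmethod
    def free(cls, theta) -> "BoundVector":
        return cls(variant="free", theta=np.asarray(theta, dtype=float))

    @classmethod
    def parametric(cls, theta_modality, sigma_slope: float = 0.0) -> "BoundVector":
        return cls(variant="parametric",
                   theta_modality=np.asarray(theta_modality, dtype=float),
                   sigma_slope=float(sigma_slope))

    def sigma(self, coherence: float) -> float:
        """Parametric diffusion standard deviation at a coherence."""
        s = 1.0 - self.sigma_slope * coherence
        if s <= 0:
            raise ConfigurationError(
                f"sigma(c)={s:g} not positive for coherence {coherence:g}")
        return s

    def cell_bounds(self, coherences) -> np.ndarray:
        """Expand to per-cell scaled bounds in canonical cell order."""
        coherences = tuple(coherences)
        n_cells = 1 + 2 * len(coherences)
        if self.variant == "free":
            if len(self.theta) != n_cells:
                raise ConfigurationError(
                    f"free bound vector has {len(self.theta)} entries, "
                    f"design needs {n_cells}")
            return self.theta.copy()
        out = np.empty(n_cells)
        out[0] = self.theta_modality[0]
        for j, c in enumerate(coherences):
            out[1 + j] = self.theta_modality[1] / self.sigma(c)
            out[1 + len(coherences) + j] = self.theta_modality[2] / self.sigma(c)
        return out

    def to_dict(self) -> dict:
        if self.variant == "free":
            return {"variant": "free", "theta": self.theta.tolist()}
        return {"variant": "parametric",
                "theta_modality": self.theta_modality.tolist(),
                "sigma_slope": self.sigma_slope}

    @classmethod
    def from_dict(cls, d: dict) -> "BoundVector":
        if d["variant"] == "free":
            return cls.free(d["theta"])
        return cls.parametric(d["theta_modality"], d.get("sigma_slope", 0.0))


@dataclass(frozen=True)
class SubjectParams:
    """All diffusion-model parameters of one subject.

    Attributes
    ----------
    k_vest : float
        Vestibular drift sensitivity (1/s).
    k_vis : ndarray
        Visual drift sensitivity (1/s) per coherence level, aligned with
        ``coherences``.
    coherences : tuple
        The coherence levels this parameter set is defined over.
    bounds : BoundVector
        Scaled decision bounds.
    t_nd : dict
        Non-decision time (s) per modality.
    bias : float
        Start-point offset in units of the scaled bound, in (-1, 1);
        positive favors rightward (+1) choices.
    lapse : float
        Probability of a stimulus-independent random choice, in [0, 0.1].
    """

    k_vest: float
    k_vis: np.ndarray
    coherences: tuple
    bounds: BoundVector
    t_nd: dict = field(default_factory=lambda: dict.fromkeys(MODALITIES, 0.3))
    bias: float = 0.0
    lapse: float = 0.0

    def __post_init__(self):
        kv = np.asarray(self.k_vis, dtype=float)
        cs = tuple(float(c) for c in self.coherences)
        if len(kv) != len(cs):
            raise ConfigurationError("k_vis must align with coherences")
        if self.k_vest < 0 or np.any(kv < 0):
            raise ConfigurationError("drift sensitivities must be >= 0")
        if not -1 < self.bias < 1:
            raise ConfigurationError("bias must lie in (-1, 1)")
        if not 0 <= self.lapse <= 0.1:
            raise ConfigurationError("lapse must lie in [0, 0.1]")
        tnd = {m: float(self.t_nd[m]) for m in MODALITIES}
        if any(v < 0 for v in tnd.values()):
            raise ConfigurationError("non-decision times must be >= 0")
        object.__setattr__(self, "k_vis", kv)
        object.__setattr__(self, "coherences", cs)
        object.__setattr__(self, "t_nd", tnd)

    def k_vis_at(self, coherence: float) -> float:
        for c, k in zip(self.coherences, self.k_vis):
            if np.isclose(c, coherence):
                return float(k)
        raise ConfigurationError(f"coherence {coherence!r} not in "
                                 f"{self.coherences}")

    def cell_bounds(self) -> np.ndarray:
        return self.bounds.cell_bounds(self.coherences)

    def with_bounds(self, bounds: BoundVector) -> "SubjectParams":
        return replace(self, bounds=bounds)

    def with_bias(self, bias: float) -> "SubjectParams":
        return replace(self, bias=bias)

    def default_design(self, **kw) -> ExperimentDesign:
        return ExperimentDesign(coherences=self.coherences, **kw)

    def to_dict(self) -> dict:
        return {"k_vest": self.k_vest, "k_vis": self.k_vis.tolist(),
                "coherences": list(self.coherences),
                "bounds": self.bounds.to_dict(),
                "t_nd": dict(self.t_nd), "bias": self.bias,
                "lapse": self.lapse}

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectParams":
        return cls(k_vest=d["k_vest"], k_vis=np.asarray(d["k_vis"]),
                   coherences=tuple(d["coherences"]),
                   bounds=BoundVector.from_dict(d["bounds"]),
                   t_nd=d["t_nd"], bias=d.get("bias", 0.0),
                   lapse=d.get("lapse", 0.0))
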