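"""Experimental conditions, designs, and the behavioral trial-table schema.

A design interleaves three modalities — optic flow (visual), inertial motion
(vestibular), and their combination — across a set of visual motion
coherences and signed heading angles.  The universal input format is a
trial table (pandas DataFrame / CSV) with one row per behavioral trial.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "MODALITIES", "ConditionSpec", "ExperimentDesign",
    "TRIAL_COLUMNS", "read_trials", "write_trials", "validate_trials",
]

MODALITIES = ("vestibular", "visual", "combined")

#: Required trial-table columns, in canonical order.
TRIAL_COLUMNS = ("subject", "modality", "coherence", "heading_deg",
                 "choice", "rt_s")


@dataclass(frozen=True)
class ConditionSpec:
    """One stimulus condition: a modality and, if visual input is present,
    the motion coherence of the optic flow (fraction of coherent dots)."""

    modality: str
    coherence: float | None = None

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ConfigurationError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.modality == "vestibular":
            if self.coherence is not None:
                raise ConfigurationError(
                    "vestibular conditions carry no coherence")
        else:
            if self.coherence is None:
                raise ConfigurationError(
                    f"{self.modality} condition requires a coherence")
            if not (0 < self.coherence <= 1):
                raise ConfigurationError("coherence must be in (0, 1]")

    @property
    def label(self) -> str:
        if self.coherence is None:
            return self.modality
        return f"{self.modality}_c{self.coherence:g}"


@dataclass(frozen=True)
class ExperimentDesign:
    """Interleaved heading-discrimination design.

    Parameters
    ----------
    coherences : tuple of float
        Visual coherence levels (C levels -> 2C+1 condition cells).
    headings_deg : tuple of float
        Signed heading angles; must be symmetric about zero.
    n_per_cell : int
        Trials simulated per (condition cell x heading) combination.
    duration_s, iti_s : float
        Maximum stimulus duration and mean inter-trial interval (s).
    cell_weights : tuple of float or None
        Relative trial proportions per condition cell; equal if None.
    """

    coherences: tuple = (0.25, 0.37, 0.70)
    headings_deg: tuple = (-16.0, -8.0, -4.0, -2.0, -1.0,
                           1.0, 2.0, 4.0, 8.0, 16.0)
    n_per_cell: int = 100
    duration_s: float = 2.0
    iti_s: float = 6.0
    cell_weights: tuple | None = None

    def __post_init__(self):
        cs = tuple(float(c) for c in self.coherences)
        if any(not (0 < c <= 1) for c in cs):
            raise ConfigurationError("coherences must lie in (0, 1]")
        if tuple(sorted(cs)) != cs:
            raise ConfigurationError("coherences must be sorted ascending")
        hs = tuple(float(h) for h in self.headings_deg)
        nonzero = sorted(h for h in hs if h != 0)
        if sorted(-h for h in nonzero) != nonzero:
            raise ConfigurationError("headings must be symmetric about 0")
        if any(abs(h) > 90 for h in hs):
            raise ConfigurationError("headings must lie within +/-90 degrees")
        if self.n_per_cell < 1:
            raise ConfigurationError("n_per_cell must be >= 1")
        if self.iti_s <= 0 or self.duration_s <= 0:
            raise ConfigurationError("duration_s and iti_s must be positive")
        object.__setattr__(self, "coherences", cs)
        object.__setattr__(self, "headings_deg", hs)
        if self.cell_weights is not None:
            w = tuple(float(x) for x in self.cell_weights)
            if len(w) != self.n_cells or any(x <= 0 for x in w):
                raise ConfigurationError(
                    f"cell_weights needs {self.n_cells} positive entries")
            object.__setattr__(self, "cell_weights", w)

    # -- condition-cell bookkeeping ------------------------------------
    @property
    def cells(self) -> list[ConditionSpec]:
        """Condition cells in canonical order: vestibular, visual x C,
        combined x C (the order of the free bound vector)."""
        out = [ConditionSpec("vestibular")]
        out += [ConditionSpec("visual", c) for c in self.coherences]
        out += [ConditionSpec("combined", c) for c in self.coherences]
        return out

    @property
    def n_cells(self) -> int:
        return 1 + 2 * len(self.coherences)

    @property
    def n_bound_params(self) -> int:
        """Free-variant bound dimensionality: 2C+1 (7 for three coherences,
        13 for six)."""
        return self.n_cells

    @property
    def cell_labels(self) -> list[str]:
        return [c.label for c in self.cells]

    def cell_index(self, modality: str, coherence: float | None) -> int:
        for i, c in enumerate(self.cells):
            if c.modality == modality and (
                    c.coherence is None if coherence is None
                    else c.coherence is not None
                    and np.isclose(c.coherence, coherence)):
                return i
        raise ConfigurationError(
            f"no cell for modality={modality!r}, coherence={coherence!r}")

    def weights(self) -> np.ndarray:
        if self.cell_weights is None:
            w = np.ones(self.n_cells)
        else:
            w = np.asarray(self.cell_weights, dtype=float)
        return w / w.sum()


# -- trial-table I/O ---------------------------------------------------

def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table schema and return the frame in canonical
    column order."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"trial table missing columns: {missing}")
    bad_mod = set(df["modality"]) - set(MODALITIES)
    if bad_mod:
        raise ConfigurationError(f"unknown modalities: {sorted(bad_mod)}")
    vest = df["modality"] == "vestibular"
    if not df.loc[vest, "coherence"].isna().all():
        raise ConfigurationError("vestibular trials must have empty coherence")
    if df.loc[~vest, "coherence"].isna().any():
        raise ConfigurationError("visual/combined trials require a coherence")
    if not df["choice"].isin([-1, 1]).all():
        raise ConfigurationError("choice must be coded -1 (left) / +1 (right)")
    if (df["rt_s"] <= 0).any():
        raise ConfigurationError("rt_s must be positive")
    return df.loc[:, list(TRIAL_COLUMNS)]


def read_trials(path) -> pd.DataFrame:
    """Read a trial-table CSV (empty coherence field for vestibular)."""
    df = pd.read_csv(path, dtype={"subject": str})
    df["choice"] = df["choice"].astype(int)
    return validate_trials(df)


def write_trials(df: pd.DataFrame, path) -> None:
    validate_trials(df).to_csv(path, index=False)
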