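"""Containers for reflection observations and partial-wedge datasets.

The universal currency of the pipeline is the observation table: a pandas
DataFrame with one row per measured reflection and columns

    h, k, l   integer Miller indices
    intensity measured intensity (arbitrary linear scale; may be negative)
    sigma     standard deviation of the intensity (> 0)
    frame     integer frame id within the crystal's wedge (0-based)
    crystal   text crystal id

A :class:`CrystalDataset` bundles one microcrystal's observations with its
unit cell and wedge geometry.  Each microcrystal contributes only a small
rotation wedge (20° in the study design this pipeline serves), so no single
dataset is complete; completeness is achieved by merging many of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .symmetry import SpaceGroup, UnitCell

__all__ = ["OBS_COLUMNS", "Observation", "CrystalDataset", "make_observation_table", "concat_observations"]

OBS_COLUMNS = ("h", "k", "l", "intensity", "sigma", "frame", "crystal")


@dataclass(frozen=True)
class Observation:
    """A single reflection measurement."""

    h: int
    k: int
    l: int
    intensity: float
    sigma: float
    frame: int = 0
    crystal: str = ""

    def __post_init__(self) -> None:
        if (self.h, self.k, self.l) == (0, 0, 0):
            raise ValueError("(0,0,0) is not a valid reflection index")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.frame < 0:
            raise ValueError("frame id must be >= 0")


def make_observation_table(rows: Iterable[Observation] | Iterable[Mapping]) -> pd.DataFrame:
    """Build a validated observation table from Observation records or dicts."""
    recs = []
    for r in rows:
        if isinstance(r, Observation):
            recs.append((r.h, r.k, r.l, r.intensity, r.sigma, r.frame, r.crystal))
        else:
            recs.append(tuple(r[c] for c in OBS_COLUMNS))
    df = pd.DataFrame(recs, columns=list(OBS_COLUMNS))
    return validate_observation_table(df)


def validate_observation_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    df = df.loc[:, list(OBS_COLUMNS)].copy()
    for c in ("h", "k", "l", "frame"):
        df[c] = df[c].astype(int)
    for c in ("intensity", "sigma"):
        df[c] = df[c].astype(float)
    df["crystal"] = df["crystal"].astype(str)
    if ((df[["h", "k", "l"]] == 0).all(axis=1)).any():
        raise ValueError("observation table contains a (0,0,0) index")
    if (df["sigma"] <= 0).any():
        raise ValueError("observation table contains sigma <= 0")
    if (df["frame"] < 0).any():
        raise ValueError("observation table contains a negative frame id")
    return df


@dataclass
class CrystalDataset:
    """One microcrystal's partial dataset: cell, wedge geometry, observations."""

    crystal_id: str
    cell: UnitCell
    wedge_start: float = 0.0
    wedge_width: float = 20.0
    wavelength: float = 0.979
    observations: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(OBS_COLUMNS)))

    def __post_init__(self) -> None:
        if not 0.0 < self.wedge_width <= 360.0:
            raise ValueError("wedge_width must lie in (0, 360]")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if len(self.observations):
            self.observations = validate_observation_table(self.observations)
            ids = self.observations["crystal"].unique()
            if len(ids) > 1 or (len(ids) == 1 and ids[0] != self.crystal_id):
                raise ValueError(
                    f"observations carry crystal ids {ids!r}, dataset is {self.crystal_id!r}"
                )

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    @property
    def n_frames(self) -> int:
        return int(self.observations["frame"].nunique()) if len(self.observations) else 0

    def resolutions(self) -> np.ndarray:
        return self.cell.d_spacing(self.observations[["h", "k", "l"]].to_numpy())

    def d_min(self) -> float:
        return float(self.resolutions().min()) if len(self.observations) else np.inf


def concat_observations(datasets: Iterable[CrystalDataset]) -> pd.DataFrame:
    """Pool observation tables across crystals (crystal ids kept distinct)."""
    frames = [ds.observations for ds in datasets if len(ds.observations)]
    if not frames:
        return pd.DataFrame(columns=list(OBS_COLUMNS))
    return pd.concat(frames, ignore_index=True)
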