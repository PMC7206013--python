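"""Synthetic partial-wedge microcrystal data with known ground truth.

The generator reproduces the statistical structure that the assembly
procedure downstream has to cope with, without ray-tracing any diffraction
geometry:

* a single set of "true" unique intensities drawn from a Wilson model
  (acentric exponential law with resolution-dependent mean
  Σ(s) = Σ₀·exp(−B_wilson·s²/2), s = 1/d);
* many crystals, each recording only the symmetry equivalents whose
  (uniformly random) diffraction angle falls inside its rotation wedge —
  this is what makes every individual dataset incomplete and merging across
  crystals necessary;
* per-crystal multiplicative scale k and isotropic B-factor falloff;
* per-crystal unit-cell jitter on the lattice-free parameters;
* Gaussian counting noise with variance I + noise_floor;
* optionally, a Friedel-antisymmetric anomalous component;
* optionally, a minority of outlier crystals whose intensities correlate
  with the truth only at a chosen ρ and whose cell is shifted — the
  non-isomorphous datasets the rejection stages must find.

Everything is driven by one integer seed; a fixed config is bit-for-bit
reproducible.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import OBS_COLUMNS, CrystalDataset
from .symmetry import SpaceGroup, UnitCell

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "enumerate_unique_reflections",
    "sample_reference_intensities",
    "simulate_crystal",
    "simulate_collection",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic microcrystal collection.

    Defaults mirror the acquisition design the pipeline targets: 20° wedges
    from over a hundred microcrystals, with a minority of non-isomorphous
    outliers.  Intensity-scale parameters (``wilson_Sigma0``, ``wilson_B``)
    are generator choices declared here, not measured values.
    """

    n_crystals: int = 132
    cell0: UnitCell = field(default_factory=lambda: UnitCell(50.0, 60.0, 70.0))
    cell_jitter_sigma: float = 0.05
    space_group: str = "P212121"
    d_min: float = 3.0
    wilson_Sigma0: float = 1000.0
    wilson_B: float = 15.0
    scale_range: tuple[float, float] = (0.5, 2.0)
    B_range: tuple[float, float] = (0.0, 20.0)
    wedge_width: float = 20.0
    frames_per_wedge: int = 20
    noise_floor: float = 25.0
    noise_scale: float = 1.0
    n_outliers: int = 0
    outlier_corr: float = 0.5
    outlier_cell_shift: float = 0.0
    anom_fraction: float = 0.0
    friedel_merged: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_crystals < 1:
            raise ValueError("n_crystals must be >= 1")
        if not 0 <= self.n_outliers < self.n_crystals:
            raise ValueError("need 0 <= n_outliers < n_crystals")
        if not 0.0 <= self.outlier_corr <= 1.0:
            raise ValueError("outlier_corr must lie in [0, 1]")
        if self.d_min <= 0:
            raise ValueError("d_min must be > 0")
        if not 0.0 < self.wedge_width <= 360.0:
            raise ValueError("wedge_width must lie in (0, 360]")
        if self.frames_per_wedge < 1:
            raise ValueError("frames_per_wedge must be >= 1")
        if self.scale_range[0] <= 0 or self.scale_range[0] > self.scale_range[1]:
            raise ValueError("scale_range must be positive and ordered")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    def spacegroup(self) -> SpaceGroup:
        return SpaceGroup(self.space_group, friedel_merged=self.friedel_merged)

    def _generation_spacegroup(self) -> SpaceGroup:
        # truth intensities live on Friedel-merged orbits regardless of how
        # the data will be merged downstream; the anomalous component is the
        # only Friedel-antisymmetric part
        return SpaceGroup(self.space_group, friedel_merged=True)


@dataclass
class GroundTruth:
    """What was actually sampled, kept for parameter-recovery tests."""

    intensities: dict[tuple[int, int, int], float]
    anom_delta: dict[tuple[int, int, int], float]
    outlier_intensities: dict[tuple[int, int, int], float]
    scales: dict[str, float]
    b_factors: dict[str, float]
    cells: dict[str, UnitCell]
    outlier_ids: list[str]

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "intensities": {"{},{},{}".format(*k): v for k, v in self.intensities.items()},
            "anom_delta": {"{},{},{}".format(*k): v for k, v in self.anom_delta.items()},
            "outlier_intensities": {
                "{},{},{}".format(*k): v for k, v in self.outlier_intensities.items()
            },
            "scales": self.scales,
            "b_factors": self.b_factors,
            "cells": {cid: list(map(float, c.parameters())) for cid, c in self.cells.items()},
            "outlier_ids": self.outlier_ids,
        }
        with open(path, "w", encoding="ascii") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path, "r", encoding="ascii") as fh:
            payload = json.load(fh)
        dec = lambda d: {tuple(int(x) for x in k.split(",")): v for k, v in d.items()}
        return cls(
            intensities=dec(payload["intensities"]),
            anom_delta=dec(payload["anom_delta"]),
            outlier_intensities=dec(payload["outlier_intensities"]),
            scales=payload["scales"],
            b_factors=payload["b_factors"],
            cells={cid: UnitCell(*v) for cid, v in payload["cells"].items()},
            outlier_ids=list(payload["outlier_ids"]),
        )


def enumerate_unique_reflections(
    cell: UnitCell, sg: SpaceGroup, d_min: float, d_max: float = np.inf
) -> np.ndarray:
    """All non-absent canonical indices with d_min <= d < d_max (sorted).

    Brute-force sphere enumeration: every index within the resolution sphere
    is mapped to its canonical asymmetric-unit representative and
    systematically absent reflections are dropped.
    """
    hmax = int(np.floor(cell.a / d_min))
    kmax = int(np.floor(cell.b / d_min))
    lmax = int(np.floor(cell.c / d_min))
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[~np.all(hkl == 0, axis=1)]
    d = cell.d_spacing(hkl)
    # relative slack so a reflection sitting exactly on d_min (up to float
    # rounding) lands on the same side for every caller
    hkl = hkl[(d >= d_min * (1.0 - 1e-9)) & (d < d_max)]
    if len(hkl) == 0:
        raise ValueError(f"no reflections between d_min={d_min} and the cell size")
    canon, _ = sg.map_to_asu_array(hkl)
    uniq = np.unique(canon, axis=0)
    uniq = uniq[~sg.absent_array(uniq)]
    order = np.lexsort((uniq[:, 2], uniq[:, 1], uniq[:, 0]))
    return uniq[order]


def sample_reference_intensities(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[tuple[int, int, int], float]:
    """Draw true unique intensities from the acentric Wilson model."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sg = config._generation_spacegroup()
    uniq = enumerate_unique_reflections(config.cell0, sg, config.d_min)
    s = 1.0 / config.cell0.d_spacing(uniq)
    mean = config.wilson_Sigma0 * np.exp(-config.wilson_B * s**2 / 2.0)
    values = rng.exponential(mean)
    return {tuple(int(x) for x in hkl): float(v) for hkl, v in zip(uniq, values)}


def _jittered_cell(cell0: UnitCell, sg: SpaceGroup, sigma: float, rng: np.random.Generator,
                   length_shift: float = 0.0) -> UnitCell:
    params = dict(zip(("a", "b", "c", "alpha", "beta", "gamma"), cell0.parameters()))
    free = sg.free_cell_parameters()
    for name in ("a", "b", "c"):
        if name in free:
            params[name] += rng.normal(0.0, sigma) + length_shift
    for name in ("alpha", "beta", "gamma"):
        if name in free:
            params[name] += rng.normal(0.0, sigma)
    if "b" not in free and "a" in free:  # tetragonal: b follows a
        params["b"] = params["a"]
    return UnitCell(**params)


def _build_truth(config: SimulationConfig) -> GroundTruth:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    sg = config._generation_spacegroup()
    intens = sample_reference_intensities(config, rng)
    keys = list(intens)
    # anomalous differences: ΔI ~ anom_fraction · I, random sign per unique
    anom = {}
    if config.anom_fraction > 0:
        signs = rng.choice([-1.0, 1.0], size=len(keys))
        anom = {k: float(s * config.anom_fraction * intens[k]) for k, s in zip(keys, signs)}
    # decorrelated intensity set for outliers: mix normalized exponential
    # deviates so corr(I_out, I_true) ≈ outlier_corr
    outlier_intens: dict[tuple[int, int, int], float] = {}
    if config.n_outliers > 0:
        rho = config.outlier_corr
        if rho >= 1.0:
            outlier_intens = dict(intens)
        else:
            u = rho / np.sqrt(1.0 - rho**2)
            w = u / (1.0 + u)
            uniq = np.array(keys)
            s = 1.0 / config.cell0.d_spacing(uniq)
            mean = config.wilson_Sigma0 * np.exp(-config.wilson_B * s**2 / 2.0)
            z_true = np.array([intens[k] for k in keys]) / mean
            z_ind = rng.exponential(1.0, size=len(keys))
            z_out = w * z_true + (1.0 - w) * z_ind
            # restore the exponential unit mean so outliers are not dimmer
            z_out /= w + (1.0 - w)
            outlier_intens = {k: float(m * z) for k, m, z in zip(keys, mean, z_out)}
    n = config.n_crystals
    ids = [f"xtal{i:03d}" for i in range(n)]
    k_lo, k_hi = config.scale_range
    scales = dict(zip(ids, rng.uniform(k_lo, k_hi, size=n).tolist()))
    b_lo, b_hi = config.B_range
    bfac = dict(zip(ids, rng.uniform(b_lo, b_hi, size=n).tolist()))
    outlier_ids = ids[n - config.n_outliers :] if config.n_outliers else []
    cells = {}
    for cid in ids:
        shift = config.outlier_cell_shift if cid in outlier_ids else 0.0
        crng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, int(cid[4:])]))
        cells[cid] = _jittered_cell(config.cell0, sg, config.cell_jitter_sigma, crng, shift)
    return GroundTruth(
        intensities=intens,
        anom_delta=anom,
        outlier_intensities=outlier_intens,
        scales=scales,
        b_factors=bfac,
        cells=cells,
        outlier_ids=outlier_ids,
    )


# cache of expanded symmetry-equivalent tables, keyed by space group and
# the byte content of the unique-index array
_EXPANSION_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _expand_equivalents(
    sg: SpaceGroup, uniq: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distinct symmetry equivalents (incl. Friedel mates) of each unique.

    Returns ``(eq_hkl, parent_index, friedel_sign)`` flattened over all
    uniques; parent_index maps each equivalent back to its row in ``uniq``.
    """
    key = (sg.symbol, sg.friedel_merged, uniq.shape[0], hash(uniq.tobytes()))
    hit = _EXPANSION_CACHE.get(key)
    if hit is not None:
        return hit
    n = uniq.shape[0]
    rots = np.stack([op.rot for op in sg.ops])
    direct = np.einsum("nj,oji->oni", uniq, rots)  # (n_ops, n, 3)
    cand = np.concatenate([direct, -direct], axis=0)  # (2 n_ops, n, 3)
    n_cand = cand.shape[0]
    cmax = int(np.abs(cand).max())
    base = 2 * cmax + 1
    enc = (
        (cand[..., 0] + cmax) * base * base
        + (cand[..., 1] + cmax) * base
        + (cand[..., 2] + cmax)
    )
    parent = np.broadcast_to(np.arange(n), (n_cand, n))
    flat = pd.DataFrame(
        {
            "parent": parent.ravel(),
            "enc": enc.ravel(),
            "h": cand[..., 0].ravel(),
            "k": cand[..., 1].ravel(),
            "l": cand[..., 2].ravel(),
        }
    ).drop_duplicates(["parent", "enc"])
    eq_hkl = flat[["h", "k", "l"]].to_numpy()
    parent_index = flat["parent"].to_numpy()
    _, sign = sg.map_to_asu_array(eq_hkl)
    result = (eq_hkl, parent_index, sign)
    _EXPANSION_CACHE[key] = result
    return result


def simulate_crystal(
    config: SimulationConfig, truth: GroundTruth, crystal_index: int
) -> CrystalDataset:
    """Simulate one crystal's wedge of observations.

    Every symmetry equivalent (including Friedel mates) of every unique
    reflection gets an independent uniform diffraction angle on [0, 360);
    the equivalents whose angle falls inside the crystal's wedge are
    recorded, binned onto frames by angle.  The recorded intensity follows
    I = k · exp(−2·B·s²/4) · (I_true ± ΔI_anom/2) + ε with
    counting-statistics noise ε of variance |I_model| + noise_floor; sigma
    reports that model standard deviation.  Outlier crystals draw from the
    decorrelated intensity set and the shifted cell.
    """
    cid = f"xtal{crystal_index:03d}"
    if cid not in truth.scales:
        raise ValueError(f"crystal index {crystal_index} not present in ground truth")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, crystal_index]))
    sg = config._generation_spacegroup()
    is_outlier = cid in truth.outlier_ids
    source = truth.outlier_intensities if is_outlier else truth.intensities
    cell = truth.cells[cid]
    k_true = truth.scales[cid]
    b_true = truth.b_factors[cid]
    wedge_start = float(rng.uniform(0.0, 360.0))

    keys = sorted(truth.intensities)
    uniq = np.array(keys, dtype=int)
    eq_hkl, parent_index, friedel_sign = _expand_equivalents(sg, uniq)

    angles = rng.uniform(0.0, 360.0, size=len(eq_hkl))
    offsets = (angles - wedge_start) % 360.0
    seen = offsets < config.wedge_width

    eq = eq_hkl[seen]
    par = parent_index[seen]
    sign = friedel_sign[seen]
    frames = (offsets[seen] / config.wedge_width * config.frames_per_wedge).astype(int)
    frames = np.clip(frames, 0, config.frames_per_wedge - 1)

    i_true = np.array([source[k] for k in keys])[par]
    delta = np.array([truth.anom_delta.get(k, 0.0) for k in keys])[par] if truth.anom_delta else 0.0
    i_model = i_true + sign * np.asarray(delta) / 2.0 if truth.anom_delta else i_true
    s = 1.0 / cell.d_spacing(eq) if len(eq) else np.array([])
    i_model = i_model * k_true * np.exp(-2.0 * b_true * s**2 / 4.0)
    var = np.maximum(np.abs(i_model) + config.noise_floor, 1e-12)
    i_obs = i_model + config.noise_scale * rng.normal(0.0, 1.0, size=len(eq)) * np.sqrt(var)

    obs = pd.DataFrame(
        {
            "h": eq[:, 0] if len(eq) else np.array([], dtype=int),
            "k": eq[:, 1] if len(eq) else np.array([], dtype=int),
            "l": eq[:, 2] if len(eq) else np.array([], dtype=int),
            "intensity": i_obs,
            "sigma": np.sqrt(var),
            "frame": frames,
            "crystal": cid,
        },
        columns=list(OBS_COLUMNS),
    )
    return CrystalDataset(
        crystal_id=cid,
        cell=cell,
        wedge_start=wedge_start,
        wedge_width=config.wedge_width,
        observations=obs,
    )


def simulate_collection(config: SimulationConfig) -> tuple[list[CrystalDataset], GroundTruth]:
    """Simulate the full multi-crystal collection."""
    truth = _build_truth(config)
    datasets = [simulate_crystal(config, truth, i) for i in range(config.n_crystals)]
    return datasets, truth
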