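"""Cross-crystal scaling, symmetry-aware merging, and quality statistics.

Each partial dataset sits on its own arbitrary scale (crystal volume, beam
intensity, radiation damage), modelled here as a multiplicative scale k and
an isotropic temperature factor B per crystal:

    I_obs ≈ k · exp(−2·B·s²/4) · ⟨I⟩_h ,   s = 1/d .

``fit_scales`` recovers (k, B) by alternating least squares against the
current merged reference; ``merge`` applies the model, takes the
inverse-variance weighted mean over each canonical index, and tabulates the
standard per-shell quality statistics.  The absolute scale is not
identifiable, so the fit is gauged to mean log k = 0 and mean B = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .datasets import OBS_COLUMNS
from .simulate import enumerate_unique_reflections
from .symmetry import SpaceGroup, UnitCell

__all__ = [
    "ScalingConfig",
    "ScalingModel",
    "MergedSet",
    "fit_scales",
    "merge",
    "anomalous_cc",
    "prepare_observations",
]


@dataclass
class ScalingConfig:
    min_common: int = 20
    max_iter: int = 100
    tol: float = 1e-6
    b_bound: float = 100.0
    per_frame: bool = False
    n_shells: int = 10
    split_seed: int = 17


@dataclass
class ScalingModel:
    """Fitted per-crystal (k, B) with optional per-frame scale refinement."""

    scales: dict[str, float]
    b_factors: dict[str, float]
    frame_scales: dict[tuple[str, int], float] = field(default_factory=dict)
    gauge: str = "mean-log-k-zero, mean-B-zero"
    n_iterations: int = 0
    final_shift: float = np.inf
    converged: bool = False

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.scales.values()):
            raise ValueError("all fitted scales must be > 0")

    def scale_factors(self, obs: pd.DataFrame, s2: np.ndarray) -> np.ndarray:
        """Per-observation multiplicative factor g = k·exp(−2Bs²/4)."""
        k = obs["crystal"].map(self.scales).to_numpy(dtype=float)
        b = obs["crystal"].map(self.b_factors).to_numpy(dtype=float)
        g = k * np.exp(-2.0 * b * s2 / 4.0)
        if self.frame_scales:
            fk = pd.MultiIndex.from_frame(obs[["crystal", "frame"]]).map(self.frame_scales)
            g = g * np.where(pd.isna(fk), 1.0, fk.to_numpy(dtype=float))
        return g

    @classmethod
    def identity(cls, crystal_ids: Sequence[str]) -> "ScalingModel":
        return cls(
            scales={c: 1.0 for c in crystal_ids},
            b_factors={c: 0.0 for c in crystal_ids},
            n_iterations=0,
            final_shift=0.0,
            converged=True,
        )


def prepare_observations(
    obs: pd.DataFrame, sg: SpaceGroup, cells: Mapping[str, UnitCell]
) -> pd.DataFrame:
    """Attach canonical index, Friedel sign, d and s² columns to a table.

    The canonical index is encoded into a single integer ``canon`` for fast
    grouping; ``ch, ck, cl`` keep the readable form.
    """
    out = obs.copy()
    hkl = out[["h", "k", "l"]].to_numpy()
    canon, sign = sg.map_to_asu_array(hkl)
    out["ch"], out["ck"], out["cl"] = canon[:, 0], canon[:, 1], canon[:, 2]
    out["friedel_sign"] = sign
    cmax = int(np.abs(canon).max()) if len(canon) else 1
    base = 2 * cmax + 1
    out["canon"] = (
        (canon[:, 0] + cmax) * base * base + (canon[:, 1] + cmax) * base + (canon[:, 2] + cmax)
    )
    d = np.empty(len(out))
    for cid, idx in out.groupby("crystal").groups.items():
        cell = cells[cid] if not isinstance(cells, UnitCell) else cells
        d[out.index.get_indexer(idx)] = cell.d_spacing(out.loc[idx, ["h", "k", "l"]].to_numpy())
    out["d"] = d
    out["s2"] = 1.0 / d**2
    return out


def _check_connectivity(prepared: pd.DataFrame, min_common: int) -> None:
    crystals = prepared["crystal"].unique()
    if len(crystals) < 2:
        return
    cidx = {c: i for i, c in enumerate(crystals)}
    uniq = {u: i for i, u in enumerate(prepared["canon"].unique())}
    rows = prepared["crystal"].map(cidx).to_numpy()
    cols = prepared["canon"].map(uniq).to_numpy()
    inc = csr_matrix(
        (np.ones(len(prepared)), (rows, cols)), shape=(len(crystals), len(uniq))
    )
    inc.data[:] = 1.0
    adj = (inc @ inc.T).toarray()
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj > 0), directed=False)
    if n_comp > 1:
        groups = [list(crystals[labels == i]) for i in range(n_comp)]
        raise ValueError(
            f"crystal graph is disconnected ({n_comp} components): {groups}"
        )
    common = adj.max(axis=1)
    weak = [c for c, v in zip(crystals, common) if v < min_common]
    if weak:
        # weakly linked crystals are allowed but the fit may be poor
        pass


def fit_scales(
    obs: pd.DataFrame,
    sg: SpaceGroup,
    cells: Mapping[str, UnitCell],
    config: ScalingConfig | None = None,
) -> ScalingModel:
    """Alternating least-squares fit of per-crystal (k, B).

    Iterates (1) merge the currently inverse-scaled intensities into a
    reference ⟨I⟩_h, (2) per crystal, refit (k, B) minimizing
    Σ w·(I_obs − k·exp(−2Bs²/4)·⟨I⟩)² with w = 1/σ², until the largest
    relative parameter shift drops below ``tol``.  Raises if the crystals do
    not share reflections linking them into one connected component.
    """
    config = config or ScalingConfig()
    prepared = obs if "canon" in obs.columns else prepare_observations(obs, sg, cells)
    crystals = sorted(prepared["crystal"].unique())
    _check_connectivity(prepared, config.min_common)

    k = {c: 1.0 for c in crystals}
    b = {c: 0.0 for c in crystals}
    intensity = prepared["intensity"].to_numpy()
    sigma = prepared["sigma"].to_numpy()
    s2 = prepared["s2"].to_numpy()
    canon = prepared["canon"].to_numpy()
    crystal_col = prepared["crystal"].to_numpy()
    groups = {c: np.flatnonzero(crystal_col == c) for c in crystals}
    # integer codes for fast bincount-based merging
    canon_codes, canon_inverse = np.unique(canon, return_inverse=True)

    n_iter = 0
    shift = np.inf
    for n_iter in range(1, config.max_iter + 1):
        karr = np.array([k[c] for c in crystals])
        barr = np.array([b[c] for c in crystals])
        cmap = {c: i for i, c in enumerate(crystals)}
        ci = np.array([cmap[c] for c in crystal_col])
        g = karr[ci] * np.exp(-2.0 * barr[ci] * s2 / 4.0)
        icorr = intensity / g
        wcorr = (g / sigma) ** 2
        num = np.bincount(canon_inverse, weights=wcorr * icorr, minlength=len(canon_codes))
        den = np.bincount(canon_inverse, weights=wcorr, minlength=len(canon_codes))
        ref = num / np.maximum(den, 1e-300)
        ref_per_obs = ref[canon_inverse]

        shift = 0.0
        for c in crystals:
            idx = groups[c]
            y = intensity[idx]
            m = ref_per_obs[idx]
            w = 1.0 / sigma[idx] ** 2
            s2c = s2[idx]

            def sse(bval: float) -> float:
                mm = m * np.exp(-2.0 * bval * s2c / 4.0)
                denom = np.sum(w * mm * mm)
                if denom <= 0:
                    return np.inf
                kk = np.sum(w * y * mm) / denom
                r = y - kk * mm
                return float(np.sum(w * r * r))

            res = minimize_scalar(
                sse, bounds=(-config.b_bound, config.b_bound), method="bounded",
                options={"xatol": 1e-8},
            )
            b_new = float(res.x)
            mm = m * np.exp(-2.0 * b_new * s2c / 4.0)
            denom = np.sum(w * mm * mm)
            k_new = float(np.sum(w * y * mm) / denom) if denom > 0 else k[c]
            if k_new <= 0:
                k_new = max(k[c] * 0.5, 1e-6)  # guard against sign flips on junk data
            shift = max(
                shift,
                abs(k_new - k[c]) / max(abs(k[c]), 1e-12),
                abs(b_new - b[c]) / (1.0 + abs(b[c])),
            )
            k[c], b[c] = k_new, b_new

        # re-gauge: mean log k = 0, mean B = 0
        logs = np.log([k[c] for c in crystals])
        kshift = np.exp(logs.mean())
        bshift = float(np.mean([b[c] for c in crystals]))
        for c in crystals:
            k[c] /= kshift
            b[c] -= bshift
        if shift < config.tol:
            break

    model = ScalingModel(
        scales=k, b_factors=b, n_iterations=n_iter, final_shift=shift,
        converged=shift < config.tol,
    )
    if config.per_frame:
        model = _fit_frame_scales(prepared, model)
    return model


def _fit_frame_scales(prepared: pd.DataFrame, model: ScalingModel) -> ScalingModel:
    """Per-frame multiplicative refinement: frames inherit the crystal's B."""
    g = model.scale_factors(prepared, prepared["s2"].to_numpy())
    icorr = prepared["intensity"].to_numpy() / g
    wcorr = (g / prepared["sigma"].to_numpy()) ** 2
    codes, inv = np.unique(prepared["canon"].to_numpy(), return_inverse=True)
    ref = np.bincount(inv, weights=wcorr * icorr) / np.maximum(
        np.bincount(inv, weights=wcorr), 1e-300
    )
    m = ref[inv] * g
    y = prepared["intensity"].to_numpy()
    w = 1.0 / prepared["sigma"].to_numpy() ** 2
    frame_scales: dict[tuple[str, int], float] = {}
    for (cid, frame), idx in prepared.groupby(["crystal", "frame"]).indices.items():
        denom = float(np.sum(w[idx] * m[idx] ** 2))
        if denom > 0:
            fk = float(np.sum(w[idx] * y[idx] * m[idx]) / denom)
            frame_scales[(cid, int(frame))] = fk if fk > 0 else 1.0
    model.frame_scales = frame_scales
    return model


# ---------------------------------------------------------------------------
# merging and statistics


@dataclass
class MergedSet:
    """Unique merged intensities plus the per-shell quality table."""

    table: pd.DataFrame          # ch, ck, cl, intensity, sigma, multiplicity, d
    shell_table: pd.DataFrame    # d_max, d_min, n_unique, n_possible, completeness, ...
    overall: dict
    split_seed: int

    @property
    def n_unique(self) -> int:
        return len(self.table)

    @property
    def completeness(self) -> float:
        return float(self.overall["completeness"])

    @property
    def cc_half(self) -> float:
        return float(self.overall["cc_half"])


def _shell_edges(d: np.ndarray, n_shells: int, d_min: float | None, d_max: float | None) -> np.ndarray:
    """Equal-volume shells in 1/d³ covering (d_max, d_min]."""
    lo = float(d.min()) if d_min is None else d_min
    hi = float(d.max()) if d_max is None else d_max
    x = np.linspace(hi ** -3, lo ** -3, n_shells + 1)
    edges = x ** (-1.0 / 3.0)
    edges[0] = hi * (1 + 1e-9)  # include the lowest-resolution reflection
    edges[-1] = lo * (1 - 1e-9)
    return edges


def _weighted_group_means(
    inv: np.ndarray, n_groups: int, values: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    wsum = np.bincount(inv, weights=weights, minlength=n_groups)
    mean = np.bincount(inv, weights=weights * values, minlength=n_groups) / np.maximum(wsum, 1e-300)
    count = np.bincount(inv, minlength=n_groups)
    return mean, wsum, count


def _half_split_labels(n: int, inv: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random half labels, balanced within each unique-reflection group."""
    if n == 0:
        return np.empty(0, dtype=int)
    order = np.lexsort((rng.random(n), inv))
    sorted_inv = inv[order]
    new_group = np.r_[True, sorted_inv[1:] != sorted_inv[:-1]]
    starts = np.flatnonzero(new_group)
    group_start = np.repeat(starts, np.diff(np.r_[starts, n]))
    pos_in_group = np.arange(n) - group_start
    labels = np.empty(n, dtype=int)
    labels[order] = pos_in_group % 2
    return labels


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        return np.nan
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def cc_half_from_labels(
    icorr: np.ndarray, wcorr: np.ndarray, inv: np.ndarray, n_groups: int, labels: np.ndarray
) -> float:
    """CC1/2 from explicit half labels (means compared across uniques)."""
    means, counts = [], []
    for half in (0, 1):
        m = labels == half
        mean, _, count = _weighted_group_means(inv[m], n_groups, icorr[m], wcorr[m])
        means.append(mean)
        counts.append(count)
    ok = (counts[0] > 0) & (counts[1] > 0)
    return _pearson(means[0][ok], means[1][ok])


def merge(
    obs: pd.DataFrame,
    model: ScalingModel | None,
    sg: SpaceGroup,
    cells: Mapping[str, UnitCell] | UnitCell,
    n_shells: int = 10,
    d_min: float | None = None,
    d_max: float | None = None,
    split_seed: int = 17,
    reference_cell: UnitCell | None = None,
    half_labels: np.ndarray | None = None,
) -> MergedSet:
    """Merge symmetry-equivalent observations and tabulate shell statistics.

    Observations are divided by their fitted scale factors, then combined by
    inverse-variance weighted mean per canonical index.  Per shell (equal
    volume in 1/d³) the table reports n_unique, n_possible (from sphere
    enumeration on the reference cell, systematic absences excluded),
    completeness, R_merge, R_meas, R_pim, CC1/2 and mean I/σ; statistics that
    need multiplicity ≥ 2 are NaN on shells without it.
    """
    if len(obs) == 0:
        raise ValueError("cannot merge an empty observation table")
    prepared = obs if "canon" in obs.columns else prepare_observations(obs, sg, cells)
    if model is None:
        model = ScalingModel.identity(sorted(prepared["crystal"].unique()))
    g = model.scale_factors(prepared, prepared["s2"].to_numpy())
    icorr = prepared["intensity"].to_numpy() / g
    scorr = prepared["sigma"].to_numpy() / g
    wcorr = 1.0 / scorr**2

    codes, inv = np.unique(prepared["canon"].to_numpy(), return_inverse=True)
    n_groups = len(codes)
    mean, wsum, count = _weighted_group_means(inv, n_groups, icorr, wcorr)
    sigma_merged = np.sqrt(1.0 / wsum)

    first = np.zeros(n_groups, dtype=int)
    first[inv[::-1]] = np.arange(len(inv))[::-1]
    chkl = prepared.iloc[first][["ch", "ck", "cl"]].to_numpy()
    ref_cell = reference_cell
    if ref_cell is None:
        if isinstance(cells, UnitCell):
            ref_cell = cells
        else:
            params = np.mean([c.parameters() for c in dict(cells).values()], axis=0)
            ref_cell = UnitCell(*params)
    d_unique = ref_cell.d_spacing(chkl)

    table = pd.DataFrame(
        {
            "h": chkl[:, 0],
            "k": chkl[:, 1],
            "l": chkl[:, 2],
            "intensity": mean,
            "sigma": sigma_merged,
            "multiplicity": count,
            "d": d_unique,
        }
    ).sort_values(["h", "k", "l"], ascending=False, ignore_index=True)

    # shell assignment of observations and uniques by d
    d_obs = prepared["d"].to_numpy()
    edges = _shell_edges(d_obs, n_shells, d_min, d_max)
    shell_of_unique = np.clip(np.searchsorted(-edges, -d_unique) - 1, 0, n_shells - 1)
    shell_of_obs = shell_of_unique[inv]

    # possible reflections enumerated once over the full range and binned
    # with the same rule as the observed uniques, so shell-boundary
    # reflections are partitioned identically
    try:
        possible = enumerate_unique_reflections(
            ref_cell, sg, d_min=edges[-1], d_max=edges[0]
        )
        d_possible = ref_cell.d_spacing(possible)
        shell_of_possible = np.clip(
            np.searchsorted(-edges, -d_possible) - 1, 0, n_shells - 1
        )
        n_possible_by_shell = np.bincount(shell_of_possible, minlength=n_shells)
    except ValueError:
        n_possible_by_shell = np.zeros(n_shells, dtype=int)

    if half_labels is None:
        rng = np.random.default_rng(split_seed)
        half_labels = _half_split_labels(len(prepared), inv, rng)

    dev = np.abs(icorr - mean[inv])
    n_of_obs = count[inv]
    multi = n_of_obs >= 2
    shells = []
    for ishell in range(n_shells):
        sel_u = shell_of_unique == ishell
        sel_o = shell_of_obs == ishell
        row: dict = {
            "shell": ishell + 1,
            "d_max": float(edges[ishell]),
            "d_min": float(edges[ishell + 1]),
            "n_unique": int(sel_u.sum()),
        }
        n_possible = int(n_possible_by_shell[ishell])
        row["n_possible"] = n_possible
        row["completeness"] = row["n_unique"] / n_possible if n_possible else np.nan
        mo = sel_o & multi
        if mo.sum():
            denom = float(np.sum(icorr[mo]))
            nn = n_of_obs[mo]
            row["r_merge"] = float(np.sum(dev[mo])) / denom if denom != 0 else np.nan
            row["r_meas"] = float(np.sum(np.sqrt(nn / (nn - 1)) * dev[mo])) / denom if denom != 0 else np.nan
            row["r_pim"] = float(np.sum(np.sqrt(1.0 / (nn - 1)) * dev[mo])) / denom if denom != 0 else np.nan
        else:
            row["r_merge"] = row["r_meas"] = row["r_pim"] = np.nan
        if sel_u.sum() >= 2:
            gsel = np.flatnonzero(sel_u)
            remap = -np.ones(n_groups, dtype=int)
            remap[gsel] = np.arange(len(gsel))
            oin = sel_o
            row["cc_half"] = cc_half_from_labels(
                icorr[oin], wcorr[oin], remap[inv[oin]], len(gsel), half_labels[oin]
            )
        else:
            row["cc_half"] = np.nan
        row["mean_i_over_sigma"] = (
            float(np.mean(mean[sel_u] / sigma_merged[sel_u])) if sel_u.sum() else np.nan
        )
        shells.append(row)
    shell_table = pd.DataFrame(shells)

    denom = float(np.sum(icorr[multi]))
    nn = n_of_obs[multi]
    n_possible_total = int(shell_table["n_possible"].sum())
    overall = {
        "n_obs": int(len(prepared)),
        "n_unique": n_groups,
        "n_possible": n_possible_total,
        "completeness": n_groups / n_possible_total if n_possible_total else np.nan,
        "multiplicity": float(count.mean()),
        "r_merge": float(np.sum(dev[multi])) / denom if multi.any() and denom != 0 else np.nan,
        "r_meas": float(np.sum(np.sqrt(nn / (nn - 1)) * dev[multi])) / denom
        if multi.any() and denom != 0
        else np.nan,
        "r_pim": float(np.sum(np.sqrt(1.0 / (nn - 1)) * dev[multi])) / denom
        if multi.any() and denom != 0
        else np.nan,
        "cc_half": cc_half_from_labels(icorr, wcorr, inv, n_groups, half_labels),
        "mean_i_over_sigma": float(np.mean(mean / sigma_merged)),
    }
    return MergedSet(table=table, shell_table=shell_table, overall=overall, split_seed=split_seed)


def cc_half_splits(
    obs: pd.DataFrame,
    model: ScalingModel | None,
    sg: SpaceGroup,
    cells: Mapping[str, UnitCell] | UnitCell,
    n_splits: int = 20,
    base_seed: int = 17,
) -> tuple[float, float, list[float]]:
    """Overall CC1/2 over repeated seeded half splits: (mean, sd, values)."""
    values = []
    for i in range(n_splits):
        m = merge(obs, model, sg, cells, split_seed=base_seed + i)
        values.append(m.overall["cc_half"])
    arr = np.array(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)), values


def anomalous_cc(
    obs: pd.DataFrame,
    model: ScalingModel | None,
    sg: SpaceGroup,
    cells: Mapping[str, UnitCell] | UnitCell,
    n_shells: int = 10,
    min_pairs: int = 3,
    split_seed: int = 17,
) -> pd.DataFrame:
    """Half-split correlation of anomalous differences ΔI = I₊ − I₋ per shell.

    Requires a space group with ``friedel_merged=False`` (the anomalous
    objective works on unmerged Friedel mates).  Shells with fewer than
    ``min_pairs`` complete pairs in both halves report NaN.
    """
    if sg.friedel_merged:
        raise ValueError("anomalous_cc needs friedel_merged=False in the space group")
    sg_merged = SpaceGroup(sg.symbol, ops=[str(op) for op in sg.ops], friedel_merged=True)
    prepared = prepare_observations(obs, sg_merged, cells)
    if model is None:
        model = ScalingModel.identity(sorted(prepared["crystal"].unique()))
    g = model.scale_factors(prepared, prepared["s2"].to_numpy())
    icorr = prepared["intensity"].to_numpy() / g
    wcorr = (g / prepared["sigma"].to_numpy()) ** 2
    sign = prepared["friedel_sign"].to_numpy()

    codes, inv = np.unique(prepared["canon"].to_numpy(), return_inverse=True)
    n_groups = len(codes)
    rng = np.random.default_rng(split_seed)
    labels = _half_split_labels(len(prepared), inv * 2 + (sign < 0), rng)

    first = np.zeros(n_groups, dtype=int)
    first[inv[::-1]] = np.arange(len(inv))[::-1]
    chkl = prepared.iloc[first][["ch", "ck", "cl"]].to_numpy()
    if isinstance(cells, UnitCell):
        ref_cell = cells
    else:
        params = np.mean([c.parameters() for c in dict(cells).values()], axis=0)
        ref_cell = UnitCell(*params)
    d_unique = ref_cell.d_spacing(chkl)
    edges = _shell_edges(prepared["d"].to_numpy(), n_shells, None, None)
    shell_of_unique = np.clip(np.searchsorted(-edges, -d_unique) - 1, 0, n_shells - 1)

    # per (unique, sign, half) weighted means
    deltas = {}
    valid = {}
    for half in (0, 1):
        dmeans = []
        ok = []
        for sgn in (1, -1):
            m = (labels == half) & (sign == sgn)
            mean, _, count = _weighted_group_means(inv[m], n_groups, icorr[m], wcorr[m])
            dmeans.append(mean)
            ok.append(count > 0)
        deltas[half] = dmeans[0] - dmeans[1]
        valid[half] = ok[0] & ok[1]
    both = valid[0] & valid[1]

    rows = []
    for ishell in range(n_shells):
        sel = both & (shell_of_unique == ishell)
        rows.append(
            {
                "shell": ishell + 1,
                "d_max": float(edges[ishell]),
                "d_min": float(edges[ishell + 1]),
                "n_pairs": int(sel.sum()),
                "cc_anom": _pearson(deltas[0][sel], deltas[1][sel])
                if sel.sum() >= min_pairs
                else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["overall_cc_anom"] = (
        _pearson(deltas[0][both], deltas[1][both]) if both.sum() >= min_pairs else np.nan
    )
    out.attrs["n_pairs_total"] = int(both.sum())
    return out
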