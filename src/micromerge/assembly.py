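"""Multi-crystal data assembly: grouping, gating, ranking, and iterative
crystal/frame rejection.

The assembly strategy mirrors how a structure is solved from many partial
microcrystal wedges: cluster datasets by unit-cell variation, scale and
merge each group separately, keep only groups complete enough to be useful
(overall completeness above a gate, default 90%), pick the best of those,
and then polish the winning group by greedy leave-one-out rejection —
repeatedly removing the crystal (then the frame) whose omission most
improves the merging objective, as long as the improvement exceeds a
tolerance.  The objective is overall CC1/2 by default, or the half-split
correlation of anomalous differences (CC_anom) when the goal is to enhance
an anomalous substructure signal.  Every evaluation is recorded in a
replayable trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import CellGrouping, cluster_cells
from .datasets import CrystalDataset, concat_observations
from .scaling import (
    MergedSet,
    ScalingConfig,
    ScalingModel,
    _half_split_labels,
    _pearson,
    _weighted_group_means,
    cc_half_from_labels,
    fit_scales,
    merge,
    prepare_observations,
)
from .symmetry import SpaceGroup, UnitCell

__all__ = [
    "RejectionConfig",
    "RejectionTrace",
    "AssemblyConfig",
    "AssemblyReport",
    "select_groups",
    "rank_groups",
    "iterative_reject",
    "assemble",
]


@dataclass
class RejectionConfig:
    objective: str = "cc_half"          # "cc_half" or "cc_anom"
    tol: float = 0.001                  # absolute objective improvement required
    min_crystals: int = 3
    min_frames_per_crystal: int = 2
    max_removals: int = 1000
    split_seed: int = 17
    # the loop refits after every removal, so each refit can be lighter
    # than a one-shot production fit
    scaling: ScalingConfig = field(default_factory=lambda: ScalingConfig(max_iter=30, tol=1e-5))

    def __post_init__(self) -> None:
        if self.objective not in ("cc_half", "cc_anom"):
            raise ValueError("objective must be 'cc_half' or 'cc_anom'")
        if self.min_crystals < 1:
            raise ValueError("min_crystals must be >= 1")


@dataclass
class RejectionTrace:
    """Replayable record of the greedy rejection loop."""

    records: list[dict] = field(default_factory=list)
    evaluations: list[dict] = field(default_factory=list)
    convergence_reason: str = ""

    def accepted_objectives(self) -> list[tuple[float, float]]:
        return [(r["objective_before"], r["objective_after"]) for r in self.records]

    def removed_ids(self, level: str | None = None) -> list:
        return [r["removed"] for r in self.records if level is None or r["level"] == level]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


class _Objective:
    """Masked evaluation of the rejection objective on a prepared table."""

    def __init__(
        self,
        prepared: pd.DataFrame,
        objective: str,
        split_seed: int,
    ) -> None:
        self.kind = objective
        self.prepared = prepared
        self.intensity = prepared["intensity"].to_numpy()
        self.sigma = prepared["sigma"].to_numpy()
        self.s2 = prepared["s2"].to_numpy()
        self.sign = prepared["friedel_sign"].to_numpy()
        codes, inv = np.unique(prepared["canon"].to_numpy(), return_inverse=True)
        self.inv = inv
        self.n_groups = len(codes)
        rng = np.random.default_rng(split_seed)
        if objective == "cc_anom":
            split_groups = inv * 2 + (self.sign < 0)
        else:
            split_groups = inv
        self.labels = _half_split_labels(len(prepared), split_groups, rng)
        self._g = np.ones(len(prepared))

    def set_model(self, model: ScalingModel) -> None:
        self._g = model.scale_factors(self.prepared, self.s2)

    def value(self, mask: np.ndarray) -> float:
        icorr = self.intensity[mask] / self._g[mask]
        wcorr = (self._g[mask] / self.sigma[mask]) ** 2
        inv = self.inv[mask]
        labels = self.labels[mask]
        if self.kind == "cc_half":
            return cc_half_from_labels(icorr, wcorr, inv, self.n_groups, labels)
        return self._cc_anom(icorr, wcorr, inv, self.sign[mask], labels)

    def _cc_anom(self, icorr, wcorr, inv, sign, labels) -> float:
        deltas, valid = {}, {}
        for half in (0, 1):
            means, ok = [], []
            for sgn in (1, -1):
                m = (labels == half) & (sign == sgn)
                mean, _, count = _weighted_group_means(inv[m], self.n_groups, icorr[m], wcorr[m])
                means.append(mean)
                ok.append(count > 0)
            deltas[half] = means[0] - means[1]
            valid[half] = ok[0] & ok[1]
        both = valid[0] & valid[1]
        if both.sum() < 3:
            return np.nan
        return _pearson(deltas[0][both], deltas[1][both])


def iterative_reject(
    datasets: Sequence[CrystalDataset],
    sg: SpaceGroup,
    config: RejectionConfig | None = None,
) -> tuple[MergedSet, RejectionTrace]:
    """Greedy leave-one-out rejection of crystals, then frames.

    Each crystal-level iteration refits the scaling model on the surviving
    set, evaluates the objective with each crystal left out, and removes the
    crystal whose omission improves the objective most — if that improvement
    exceeds ``tol``.  After crystal-level convergence the same loop runs at
    frame level (frames inherit their crystal's scale).  Floors
    (``min_crystals``, ``min_frames_per_crystal``) stop degenerate emptying.
    Returns the final merged set and the full trace.
    """
    config = config or RejectionConfig()
    if config.objective == "cc_anom" and sg.friedel_merged:
        raise ValueError("cc_anom objective requires a space group with friedel_merged=False")
    if len(datasets) < max(config.min_crystals, 2):
        raise ValueError(
            f"need at least max(min_crystals, 2) = {max(config.min_crystals, 2)} datasets, "
            f"got {len(datasets)} (min_crystals == n floors the crystal pass entirely)"
        )
    cells = {ds.crystal_id: ds.cell for ds in datasets}
    obs = concat_observations(datasets)
    # grouping for merging always pools Friedel mates; the anomalous
    # objective separates the classes itself via the stored Friedel sign
    sg_merged = (
        sg
        if sg.friedel_merged
        else SpaceGroup(sg.symbol, ops=[str(op) for op in sg.ops], friedel_merged=True)
    )
    prepared = prepare_observations(obs, sg_merged, cells)
    objective = _Objective(prepared, config.objective, config.split_seed)

    crystal_col = prepared["crystal"].to_numpy()
    frame_col = prepared["frame"].to_numpy()
    alive = np.ones(len(prepared), dtype=bool)
    trace = RejectionTrace()

    def refit() -> ScalingModel:
        live = prepared[alive]
        model = fit_scales(live, sg_merged, cells, config.scaling)
        objective.set_model(model)
        return model

    def surviving_crystals() -> list[str]:
        return sorted(set(crystal_col[alive]))

    # ---- crystal level -----------------------------------------------------
    reason = "crystal level: converged"
    for _ in range(config.max_removals):
        survivors = surviving_crystals()
        if len(survivors) <= config.min_crystals:
            reason = "crystal level: at min_crystals floor"
            break
        model = refit()
        current = objective.value(alive)
        if np.isnan(current):
            raise ValueError("objective undefined on the current set")
        best_id, best_val = None, current
        for cid in survivors:
            trial = alive & (crystal_col != cid)
            val = objective.value(trial)
            trace.evaluations.append(
                {"level": "crystal", "candidate": cid, "objective": None if np.isnan(val) else float(val)}
            )
            if not np.isnan(val) and val > best_val:
                best_id, best_val = cid, val
        if best_id is None or best_val - current <= config.tol:
            break
        alive &= crystal_col != best_id
        trace.records.append(
            {
                "level": "crystal",
                "removed": best_id,
                "objective_before": float(current),
                "objective_after": float(best_val),
                "n_crystals": len(surviving_crystals()),
                "n_frames": int(pd.DataFrame({"c": crystal_col[alive], "f": frame_col[alive]}).drop_duplicates().shape[0]),
            }
        )

    # ---- frame level -------------------------------------------------------
    for _ in range(config.max_removals):
        live_cf = pd.DataFrame({"c": crystal_col[alive], "f": frame_col[alive]}).drop_duplicates()
        frames_per_crystal = live_cf.groupby("c").size()
        candidates = [
            (row.c, int(row.f))
            for row in live_cf.itertuples(index=False)
            if frames_per_crystal[row.c] > config.min_frames_per_crystal
        ]
        if not candidates:
            reason = "frame level: at min_frames floor"
            break
        model = refit()
        current = objective.value(alive)
        best_cf, best_val = None, current
        for cid, fid in sorted(candidates):
            trial = alive & ~((crystal_col == cid) & (frame_col == fid))
            val = objective.value(trial)
            trace.evaluations.append(
                {
                    "level": "frame",
                    "candidate": f"{cid}/frame{fid}",
                    "objective": None if np.isnan(val) else float(val),
                }
            )
            if not np.isnan(val) and val > best_val:
                best_cf, best_val = (cid, fid), val
        if best_cf is None or best_val - current <= config.tol:
            reason = "frame level: converged"
            break
        alive &= ~((crystal_col == best_cf[0]) & (frame_col == best_cf[1]))
        trace.records.append(
            {
                "level": "frame",
                "removed": f"{best_cf[0]}/frame{best_cf[1]}",
                "objective_before": float(current),
                "objective_after": float(best_val),
                "n_crystals": len(surviving_crystals()),
                "n_frames": int(
                    pd.DataFrame({"c": crystal_col[alive], "f": frame_col[alive]}).drop_duplicates().shape[0]
                ),
            }
        )
    trace.convergence_reason = reason

    final_model = fit_scales(prepared[alive], sg_merged, cells, config.scaling)
    final = merge(
        prepared[alive],
        final_model,
        sg_merged,
        cells,
        split_seed=config.split_seed,
    )
    return final, trace


# ---------------------------------------------------------------------------
# group selection, ranking, full assembly


def select_groups(group_reports: Mapping[int, MergedSet], min_completeness: float = 0.90) -> list[int]:
    """Groups whose overall completeness strictly exceeds the gate."""
    return sorted(
        gid for gid, ms in group_reports.items() if ms.overall["completeness"] > min_completeness
    )


def rank_groups(group_reports: Mapping[int, MergedSet], selected: Sequence[int]) -> int:
    """Winner among the selected groups.

    Ranked by higher overall CC1/2, then higher completeness, then more
    unique reflections; remaining ties fall back to the smaller group id.
    """
    if not selected:
        raise ValueError("cannot rank an empty group selection")

    def key(gid: int):
        ov = group_reports[gid].overall
        cc = ov["cc_half"]
        return (
            -(cc if not np.isnan(cc) else -np.inf),
            -ov["completeness"],
            -ov["n_unique"],
            gid,
        )

    return min(selected, key=key)


@dataclass
class AssemblyConfig:
    max_groups: int = 20
    reject_z: float = 3.0
    angle_weight: float = 1.0
    min_completeness: float = 0.90
    n_shells: int = 10
    split_seed: int = 17
    scaling: ScalingConfig = field(default_factory=ScalingConfig)
    rejection: RejectionConfig = field(default_factory=RejectionConfig)


@dataclass
class AssemblyReport:
    """Full record of one assembly run."""

    grouping: CellGrouping
    group_overall: dict[int, dict]
    selected_groups: list[int]
    winning_group: int | None
    final: MergedSet | None
    trace: RejectionTrace | None
    objective: str
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def clean(d: dict) -> dict:
            return {
                k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in d.items()
            }

        return {
            "grouping": {
                "assignments": self.grouping.assignments,
                "rejected": self.grouping.rejected,
                "metric": self.grouping.metric,
                "n_groups": self.grouping.n_groups,
            },
            "group_overall": {str(g): clean(ov) for g, ov in self.group_overall.items()},
            "selected_groups": self.selected_groups,
            "winning_group": self.winning_group,
            "objective": self.objective,
            "final_overall": clean(self.final.overall) if self.final else None,
            "final_shells": json.loads(self.final.shell_table.to_json(orient="records"))
            if self.final
            else None,
            "rejection_trace": self.trace.records if self.trace else None,
            "convergence_reason": self.trace.convergence_reason if self.trace else None,
            "notes": self.notes,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="ascii") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def assemble(
    datasets: Sequence[CrystalDataset],
    sg: SpaceGroup,
    config: AssemblyConfig | None = None,
) -> AssemblyReport:
    """Run the full assembly: cluster → per-group merge → gate → rank →
    iterative rejection on the winning group → final merge."""
    config = config or AssemblyConfig()
    if len(datasets) < 2:
        raise ValueError("assembly needs at least 2 datasets")
    by_id = {ds.crystal_id: ds for ds in datasets}
    cells = {ds.crystal_id: ds.cell for ds in datasets}
    notes: list[str] = []

    try:
        grouping = cluster_cells(
            cells,
            max_groups=config.max_groups,
            reject_z=config.reject_z,
            angle_weight=config.angle_weight,
        )
    except ValueError as exc:
        raise ValueError(f"cell clustering stage failed: {exc}") from exc
    if grouping.rejected:
        notes.append(f"cell-variation rejection removed {len(grouping.rejected)} crystals")

    sg_merged = (
        sg
        if sg.friedel_merged
        else SpaceGroup(sg.symbol, ops=[str(op) for op in sg.ops], friedel_merged=True)
    )
    group_reports: dict[int, MergedSet] = {}
    for gid in grouping.group_ids():
        members = grouping.members(gid)
        group_obs = concat_observations([by_id[m] for m in members])
        if not len(group_obs):
            continue
        group_cells = {m: cells[m] for m in members}
        try:
            model = (
                fit_scales(group_obs, sg_merged, group_cells, config.scaling)
                if len(members) > 1
                else ScalingModel.identity(members)
            )
        except ValueError as exc:
            notes.append(f"group {gid}: scaling failed ({exc}); merged unscaled")
            model = ScalingModel.identity(members)
        group_reports[gid] = merge(
            group_obs,
            model,
            sg_merged,
            group_cells,
            n_shells=config.n_shells,
            split_seed=config.split_seed,
        )

    selected = select_groups(group_reports, config.min_completeness)
    if not selected:
        notes.append("no group passed the completeness gate")
        return AssemblyReport(
            grouping=grouping,
            group_overall={g: ms.overall for g, ms in group_reports.items()},
            selected_groups=[],
            winning_group=None,
            final=None,
            trace=None,
            objective=config.rejection.objective,
            notes=notes,
        )
    winner = rank_groups(group_reports, selected)
    winner_sets = [by_id[m] for m in grouping.members(winner)]
    if len(winner_sets) >= max(config.rejection.min_crystals, 2):
        try:
            final, trace = iterative_reject(winner_sets, sg, config.rejection)
        except ValueError as exc:
            raise ValueError(f"rejection stage failed on group {winner}: {exc}") from exc
    else:
        notes.append(
            f"winning group {winner} too small for rejection "
            f"({len(winner_sets)} crystals); kept as merged"
        )
        final, trace = group_reports[winner], RejectionTrace(convergence_reason="skipped: group too small")
    return AssemblyReport(
        grouping=grouping,
        group_overall={g: ms.overall for g, ms in group_reports.items()},
        selected_groups=selected,
        winning_group=winner,
        final=final,
        trace=trace,
        objective=config.rejection.objective,
        notes=notes,
    )
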