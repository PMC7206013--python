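"""Grouping partial datasets by unit-cell variation.

Non-isomorphous crystals — different cell dimensions, hence different
packing — degrade merged data quality, so datasets are first classified
into groups of like cells and deviant datasets are rejected.  The metric is
Euclidean distance over mean-relative cell parameters: each of
(a, b, c, α, β, γ) is expressed as its deviation from the population mean
divided by that mean, with an optional extra weight on the angle terms.
Relative deviations keep the comparison scale-free across parameters of
different magnitude without inflating pure-noise parameters, which is what
per-parameter variance standardization would do.

Grouping is average-linkage agglomerative clustering on that distance
matrix, cut to at most ``max_groups`` groups (or at a linkage height), then
stabilized by deterministic nearest-centroid reassignment.  Rejection is
scale-free: a crystal is rejected when its distance to the group centroid
exceeds ``reject_z`` times the median centroid distance within its group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .symmetry import UnitCell

__all__ = ["CellGrouping", "cell_distance", "cluster_cells"]

METRIC_NAME = "mean-relative-euclidean"


@dataclass
class CellGrouping:
    """Result of unit-cell variation analysis."""

    assignments: dict[str, int]      # crystal_id -> group label (1-based)
    rejected: list[str]
    linkage_heights: list[float]
    metric: str = METRIC_NAME
    centroid_distance: dict[str, float] = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(set(self.assignments.values()))

    def members(self, group: int) -> list[str]:
        return sorted(c for c, g in self.assignments.items() if g == group)

    def group_ids(self) -> list[int]:
        return sorted(set(self.assignments.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "crystal_id": cid,
                "group": grp,
                "distance_to_centroid": self.centroid_distance.get(cid, np.nan),
                "rejected": False,
            }
            for cid, grp in sorted(self.assignments.items())
        ]
        rows += [
            {
                "crystal_id": cid,
                "group": -1,
                "distance_to_centroid": self.centroid_distance.get(cid, np.nan),
                "rejected": True,
            }
            for cid in sorted(self.rejected)
        ]
        return pd.DataFrame(rows)


def _relative_coords(params: np.ndarray, angle_weight: float) -> np.ndarray:
    mean = params.mean(axis=0)
    z = (params - mean) / mean
    z[:, 3:] *= angle_weight
    return z


def cell_distance(
    c1: UnitCell,
    c2: UnitCell,
    population: Sequence[UnitCell] | None = None,
    angle_weight: float = 1.0,
) -> float:
    """Mean-relative Euclidean distance between two cells.

    Each parameter enters as its deviation from the population mean divided
    by that mean; the population defaults to the pair itself.  Symmetric,
    and zero exactly when the parameters are identical.
    """
    pop = list(population) if population is not None else [c1, c2]
    params = np.array([c.parameters() for c in pop])
    mean = params.mean(axis=0)
    z1 = (c1.parameters() - mean) / mean
    z2 = (c2.parameters() - mean) / mean
    z1[3:] *= angle_weight
    z2[3:] *= angle_weight
    return float(np.linalg.norm(z1 - z2))


def _refine_nearest_centroid(z: np.ndarray, labels: np.ndarray, max_iter: int = 25) -> np.ndarray:
    """Deterministic reassignment to the nearest group centroid.

    Stabilizes tree cuts that strand a point (or split off a singleton)
    when the underlying populations are clearly separated.
    """
    labels = labels.copy()
    for _ in range(max_iter):
        groups = np.unique(labels)
        centroids = np.stack([z[labels == g].mean(axis=0) for g in groups])
        dist = np.linalg.norm(z[:, None, :] - centroids[None, :, :], axis=2)
        new = groups[np.argmin(dist, axis=1)]
        if np.array_equal(new, labels):
            break
        labels = new
    return labels


def cluster_cells(
    cells: Mapping[str, UnitCell],
    max_groups: int = 20,
    reject_z: float = 3.0,
    angle_weight: float = 1.0,
    height: float | None = None,
) -> CellGrouping:
    """Classify crystals into cell-variation groups and flag deviant cells.

    Average-linkage agglomerative clustering of mean-relative cell
    parameters, cut at ``height`` (linkage distance) when given, otherwise
    to at most ``max_groups`` groups, then refined by nearest-centroid
    reassignment.  A crystal is rejected when its centroid distance exceeds
    ``reject_z`` times the median centroid distance of its group.
    Deterministic: ties follow crystal-id order.  Raises if every crystal
    would be rejected.
    """
    ids = sorted(cells)
    if len(ids) < 2:
        raise ValueError("clustering needs at least 2 datasets")
    params = np.array([cells[c].parameters() for c in ids])
    z = _relative_coords(params, angle_weight)
    dvec = pdist(z, metric="euclidean")
    link = linkage(dvec, method="average")
    if height is not None:
        labels = fcluster(link, t=height, criterion="distance")
    else:
        labels = fcluster(link, t=max_groups, criterion="maxclust")
    labels = _refine_nearest_centroid(z, labels)
    # relabel groups 1..n in order of first appearance over sorted ids
    relabel: dict[int, int] = {}
    for lab in labels:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    labels = np.array([relabel[lab] for lab in labels])

    centroid_distance: dict[str, float] = {}
    rejected: list[str] = []
    assignments: dict[str, int] = {}
    for grp in sorted(set(labels)):
        member_idx = np.flatnonzero(labels == grp)
        centroid = z[member_idx].mean(axis=0)
        dist = np.linalg.norm(z[member_idx] - centroid, axis=1)
        scale = float(np.median(dist))
        for i, dd in zip(member_idx, dist):
            centroid_distance[ids[i]] = float(dd)
            if scale > 0 and dd > reject_z * scale:
                rejected.append(ids[i])
            else:
                assignments[ids[i]] = int(grp)
    if not assignments:
        raise ValueError(
            f"all {len(ids)} crystals rejected at reject_z={reject_z}; "
            f"centroid distances: {centroid_distance}"
        )
    return CellGrouping(
        assignments=assignments,
        rejected=sorted(rejected),
        linkage_heights=[float(h) for h in link[:, 2]],
        centroid_distance=centroid_distance,
    )
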