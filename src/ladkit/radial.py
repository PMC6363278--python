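"""Radial nuclear positioning of LAD classes in 3D bead models and 2D FISH.

Bead-on-string structures place one bead per fixed genomic tile inside a
sphere of radius ``R`` (default 5 um); radial position is the Euclidean
distance of the bead center to the nucleus center divided by ``R``
(0 = center, 1 = periphery). FISH spots live in 2D nuclei whose boundary
is an ellipse; their normalized position is the fractional distance to the
boundary along the ray from the nucleus center through the spot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Genome
from .intervals import GenomicIntervalSet
from .partition import CLASSES, ILAD, ClassPartition

DEFAULT_NUCLEUS_RADIUS_UM = 5.0


@dataclass
class BeadStructure:
    """One bead-on-string model: genomic tiles with 3D centers in a sphere."""

    model_id: str
    chrom: np.ndarray  # (N,) str
    start: np.ndarray  # (N,) int bp
    end: np.ndarray  # (N,) int bp
    centers: np.ndarray  # (N, 3) um
    bead_radius: np.ndarray  # (N,) um
    radius_um: float = DEFAULT_NUCLEUS_RADIUS_UM

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.bead_radius = np.asarray(self.bead_radius, dtype=float)
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.centers) == len(self.bead_radius) == n):
            raise ValueError("bead arrays have inconsistent lengths")
        if self.radius_um <= 0:
            raise ValueError("nucleus radius must be positive")
        if np.any(np.linalg.norm(self.centers, axis=1) >= self.radius_um):
            raise ValueError("bead center at or outside the nuclear boundary")

    @property
    def n_beads(self) -> int:
        return len(self.chrom)


def normalized_distances(structure: BeadStructure) -> np.ndarray:
    """d/R for every bead: distance to the nucleus center over the radius."""
    return np.linalg.norm(structure.centers, axis=1) / structure.radius_um


def normalized_distance(center: Sequence[float], radius_um: float) -> float:
    """d/R for one bead center; rejects centers on or outside the boundary."""
    if radius_um <= 0:
        raise ValueError("nucleus radius must be positive")
    d = float(np.linalg.norm(np.asarray(center, dtype=float)))
    if d >= radius_um:
        raise ValueError("bead center at or outside the nuclear boundary")
    return d / radius_um


def map_classes_to_beads(
    partition: ClassPartition, structure: BeadStructure, min_overlap: int = 1
) -> np.ndarray:
    """(N, 4) boolean membership of beads in each class.

    A bead carries a lamin class when at least ``min_overlap`` bp of its
    interval carries that label, so large beads may carry several classes.
    A bead is in the inter-LAD group only when it carries no lamin class.
    """
    for chrom in set(structure.chrom):
        if chrom not in partition.genome.names:
            raise ValueError(f"structure chromosome {chrom} absent from partition genome")
    member = np.zeros((structure.n_beads, len(CLASSES)), dtype=bool)
    for k in range(structure.n_beads):
        vec = partition.overlap_vector(
            str(structure.chrom[k]), int(structure.start[k]), int(structure.end[k])
        )
        for c in range(len(CLASSES)):
            if c != ILAD and vec[c] >= min_overlap:
                member[k, c] = True
        if not member[k, :ILAD].any() and not member[k, ILAD + 1 :].any():
            member[k, ILAD] = vec[ILAD] >= min_overlap
    return member


def _check_same_tiling(structures: Sequence[BeadStructure]) -> None:
    ref = structures[0]
    for s in structures[1:]:
        if (
            s.n_beads != ref.n_beads
            or not np.array_equal(s.start, ref.start)
            or not np.array_equal(s.end, ref.end)
            or not np.array_equal(s.chrom, ref.chrom)
        ):
            raise ValueError("structures in an ensemble must share the same bead tiling")


def pooled_class_distances(
    structures: Sequence[BeadStructure], partition: ClassPartition, min_overlap: int = 1
) -> dict[str, np.ndarray]:
    """Normalized distances per class, pooled over all models (per bead per model)."""
    if not structures:
        raise ValueError("need at least one structure")
    _check_same_tiling(structures)
    member = map_classes_to_beads(partition, structures[0], min_overlap=min_overlap)
    dists = np.stack([normalized_distances(s) for s in structures])  # (M, N)
    return {c: dists[:, member[:, i]].ravel() for i, c in enumerate(CLASSES)}


def class_distance_stats(
    structures: Sequence[BeadStructure],
    partition: ClassPartition,
    alpha: float = 0.01,
    min_overlap: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class pooled distance summaries and all pairwise Welch t-tests."""
    pooled = pooled_class_distances(structures, partition, min_overlap=min_overlap)
    summary = pd.DataFrame(
        [
            {
                "lad_class": c,
                "n": len(v),
                "mean": float(v.mean()) if len(v) else np.nan,
                "median": float(np.median(v)) if len(v) else np.nan,
                "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
            }
            for c, v in pooled.items()
        ]
    )
    rows = []
    for i, ci in enumerate(CLASSES):
        for cj in CLASSES[i + 1 :]:
            x, y = pooled[ci], pooled[cj]
            row = {
                "class_1": ci,
                "class_2": cj,
                "n_1": len(x),
                "n_2": len(y),
                "delta_mean": np.nan,
                "t": np.nan,
                "pvalue": np.nan,
                "significant": False,
            }
            if len(x) >= 2 and len(y) >= 2:
                res = stats.ttest_ind(x, y, equal_var=False)
                row.update(
                    delta_mean=float(x.mean() - y.mean()),
                    t=float(res.statistic),
                    pvalue=float(res.pvalue),
                    significant=bool(res.pvalue < alpha),
                )
            rows.append(row)
    return summary, pd.DataFrame(rows)


def _fate_region_sets(
    ctrl: ClassPartition, trt: ClassPartition
) -> dict[tuple[str, str], GenomicIntervalSet]:
    """Coverage set of each (control class, treated class) fate pair."""
    sets_c = {c: ctrl.class_set(c) for c in CLASSES}
    sets_t = {c: trt.class_set(c) for c in CLASSES}
    return {
        (ci, cj): sets_c[ci].intersection(sets_t[cj]) for ci in CLASSES for cj in CLASSES
    }


def transition_distance_stats(
    structures_ctrl: Sequence[BeadStructure],
    structures_trt: Sequence[BeadStructure],
    partition_ctrl: ClassPartition,
    partition_trt: ClassPartition,
    alpha: float = 0.01,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Radial shift of each fate pair between the two model ensembles.

    For each of the 16 (control class -> treated class) pairs, beads
    overlapping the fate region by >= ``min_overlap`` bp are collected in
    each ensemble and their pooled normalized distances compared by an
    unpaired Welch t-test. ``direction`` is ``periphery`` for a
    significant outward shift, ``center`` for a significant inward shift,
    else ``none``. Pairs are numbered row-major in CLASSES order.
    """
    if partition_ctrl.genome != partition_trt.genome:
        raise ValueError("partitions must share a genome")
    if not structures_ctrl or not structures_trt:
        raise ValueError("need at least one structure per condition")
    _check_same_tiling(list(structures_ctrl) + list(structures_trt))
    regions = _fate_region_sets(partition_ctrl, partition_trt)
    ref = structures_ctrl[0]
    dists_c = np.stack([normalized_distances(s) for s in structures_ctrl])
    dists_t = np.stack([normalized_distances(s) for s in structures_trt])
    rows = []
    pair = 0
    for ci in CLASSES:
        for cj in CLASSES:
            pair += 1
            region = regions[(ci, cj)]
            in_region = np.asarray(
                [
                    region.overlap_bp(str(ref.chrom[k]), int(ref.start[k]), int(ref.end[k]))
                    >= min_overlap
                    for k in range(ref.n_beads)
                ]
            )
            x = dists_c[:, in_region].ravel()
            y = dists_t[:, in_region].ravel()
            row = {
                "pair": pair,
                "control_class": ci,
                "treated_class": cj,
                "region_bp": region.total_bp,
                "n_ctrl": len(x),
                "n_trt": len(y),
                "mean_ctrl": float(x.mean()) if len(x) else np.nan,
                "mean_trt": float(y.mean()) if len(y) else np.nan,
                "delta_mean": np.nan,
                "t": np.nan,
                "pvalue": np.nan,
                "direction": "none",
            }
            if len(x) >= 2 and len(y) >= 2:
                if np.array_equal(x, y):
                    row.update(delta_mean=0.0, t=0.0, pvalue=1.0)
                else:
                    res = stats.ttest_ind(y, x, equal_var=False)
                    delta = float(y.mean() - x.mean())
                    row.update(
                        delta_mean=delta,
                        t=float(res.statistic),
                        pvalue=float(res.pvalue),
                    )
                    if res.pvalue < alpha:
                        row["direction"] = "periphery" if delta > 0 else "center"
            rows.append(row)
    return pd.DataFrame(rows)


def probe_distance(
    probe: tuple[str, int, int], structures: Sequence[BeadStructure]
) -> np.ndarray:
    """Normalized distance, per model, of the bead holding the probe midpoint."""
    if not structures:
        raise ValueError("need at least one structure")
    _check_same_tiling(structures)
    chrom, start, end = probe
    mid = (start + end) // 2
    ref = structures[0]
    hit = np.flatnonzero((ref.chrom == chrom) & (ref.start <= mid) & (mid < ref.end))
    if hit.size == 0:
        raise ValueError(f"probe midpoint {chrom}:{mid} falls in no bead")
    k = int(hit[0])
    return np.asarray([normalized_distances(s)[k] for s in structures])


# --------------------------------------------------------------------------
# 2D FISH geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SpotRecord:
    """A FISH spot inside a 2D nucleus with an elliptical boundary.

    The boundary ellipse has semi-axes ``(axis_a, axis_b)`` um rotated by
    ``angle`` radians about the nucleus center.
    """

    nucleus_id: str
    condition: str
    probe: str
    spot_xy: tuple[float, float]
    center_xy: tuple[float, float]
    axis_a: float
    axis_b: float
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.axis_a <= 0 or self.axis_b <= 0:
            raise ValueError("ellipse semi-axes must be positive")


def fish_normalized_position(spot: SpotRecord) -> float:
    """Fractional radial position of a spot: 0 = center, 1 = boundary.

    Computed as the distance from the nucleus center divided by the
    distance from the center to the boundary along the ray through the
    spot. For the rotated ellipse this reduces to
    ``sqrt((vx/a)^2 + (vy/b)^2)`` in the ellipse frame; a circle gives
    exactly ``|spot - center| / r``.
    """
    v = np.asarray(spot.spot_xy, dtype=float) - np.asarray(spot.center_xy, dtype=float)
    if spot.angle != 0.0:
        c, s = np.cos(-spot.angle), np.sin(-spot.angle)
        v = np.asarray([c * v[0] - s * v[1], s * v[0] + c * v[1]])
    pos = float(np.hypot(v[0] / spot.axis_a, v[1] / spot.axis_b))
    if pos > 1.0:
        raise ValueError(f"spot {spot.nucleus_id}/{spot.probe} lies outside the nucleus boundary")
    return pos


def fish_compare(
    spots_ctrl: Sequence[SpotRecord],
    spots_trt: Sequence[SpotRecord],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-probe comparison of normalized spot positions between conditions.

    Probes present in only one condition are skipped with a warning row
    (``pvalue`` NaN, ``n`` of the missing side 0).
    """
    def by_probe(spots):
        out: dict[str, list[float]] = {}
        for s in spots:
            out.setdefault(s.probe, []).append(fish_normalized_position(s))
        return out

    g1, g2 = by_probe(spots_ctrl), by_probe(spots_trt)
    rows = []
    for probe in sorted(set(g1) | set(g2)):
        x = np.asarray(g1.get(probe, []), dtype=float)
        y = np.asarray(g2.get(probe, []), dtype=float)
        row = {
            "probe": probe,
            "n_ctrl": len(x),
            "n_trt": len(y),
            "mean_ctrl": float(x.mean()) if len(x) else np.nan,
            "sd_ctrl": float(x.std(ddof=1)) if len(x) > 1 else np.nan,
            "mean_trt": float(y.mean()) if len(y) else np.nan,
            "sd_trt": float(y.std(ddof=1)) if len(y) > 1 else np.nan,
            "delta_mean": np.nan,
            "t": np.nan,
            "pvalue": np.nan,
            "direction": "none",
        }
        if len(x) >= 2 and len(y) >= 2:
            if np.array_equal(np.sort(x), np.sort(y)):
                row.update(delta_mean=float(y.mean() - x.mean()), t=0.0, pvalue=1.0)
            else:
                res = stats.ttest_ind(y, x, equal_var=False)
                delta = float(y.mean() - x.mean())
                row.update(delta_mean=delta, t=float(res.statistic), pvalue=float(res.pvalue))
                if res.pvalue < alpha:
                    row["direction"] = "periphery" if delta > 0 else "center"
        else:
            import warnings

            warnings.warn(f"probe {probe} missing or underpowered in one condition")
        rows.append(row)
    return pd.DataFrame(rows)
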