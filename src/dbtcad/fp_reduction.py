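"""Rule-based false-positive reduction for cluster candidates.

The cascade, applied in order:

1. *Member-voxel rule* — a cluster whose member MC candidates contribute
   fewer than ``min_member_voxels`` voxels (within the association radius of
   its seed) is eliminated; "less than N eliminates" means N itself keeps.
2. *Neighbor-seed rule* — a cluster with fewer than ``min_neighbor_seeds``
   *other* seed objects within ``neighbor_radius_mm`` of its seed is
   eliminated (corroborating seeds; the cluster's own seed does not count
   unless ``include_self`` is set).
3. *Bounding cubes* — each surviving cluster gets the tight axis-aligned box
   (mm) over its member voxels' physical extents, expanded to a cube on the
   longest side.
4. *Cube merging* — cubes with positive pairwise overlap volume are combined
   transitively; each group is replaced by the cube-expanded tight box of its
   members, repeated to a fixed point so the operation is idempotent.
5. *Cube-content rule* — a merged cube containing fewer than
   ``min_cube_mc_count`` distinct MC candidates (centroid containment) or
   less than ``min_cube_mc_volume_mm3`` of summed candidate volume is
   eliminated.

Survivors carry a score equal to the sum of their source clusters' scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .candidate_detection import ClusterCandidate, MCCandidate, SeedObject
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FPReductionParams:
    """Thresholds of the rule cascade.

    Reference-configuration defaults: 9 member voxels, 2 neighbor seeds
    within 5 mm, 80 MC candidates and 140 mm^3 per merged cube.  The cube
    content thresholds are stated in counts and physical volume so the rule
    is resolution independent.
    """

    min_member_voxels: int = 9
    min_neighbor_seeds: int = 2
    neighbor_radius_mm: float = 5.0
    min_cube_mc_count: int = 80
    min_cube_mc_volume_mm3: float = 140.0
    include_self: bool = False
    require_merged_from_gt1: bool = False

    def __post_init__(self) -> None:
        if min(self.min_member_voxels, self.min_neighbor_seeds, self.min_cube_mc_count) < 0:
            raise ValidationError("rule thresholds must be non-negative")
        if self.min_cube_mc_volume_mm3 < 0:
            raise ValidationError("min_cube_mc_volume_mm3 must be non-negative")
        if self.neighbor_radius_mm <= 0:
            raise ValidationError("neighbor_radius_mm must be positive")


@dataclass
class BoundingCube:
    """An axis-aligned cube (mm) around one or more accepted clusters."""

    bounds: np.ndarray  # (3, 2) per-axis (min, max)
    source_clusters: list[ClusterCandidate]
    mc_count: int
    mc_volume_mm3: float
    merged_from: int = 1

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float).reshape(3, 2)
        if np.any(self.bounds[:, 0] > self.bounds[:, 1]):
            raise ValidationError("cube min > max")


@dataclass
class DetectedMCC:
    """A final detection: a merged bounding cube plus a sweepable score."""

    cube: BoundingCube
    score: float


def rule_member_voxels(c: ClusterCandidate, p: FPReductionParams) -> bool:
    """True = keep. Eliminates clusters whose member voxel sum is below the
    minimum (boundary inclusive: exactly ``min_member_voxels`` keeps)."""
    return c.member_voxel_count >= p.min_member_voxels


def rule_neighbor_seeds(
    c: ClusterCandidate, all_seeds: list[SeedObject], p: FPReductionParams
) -> bool:
    """True = keep. Counts seed objects within ``neighbor_radius_mm`` of the
    cluster's seed centroid, excluding the seed itself (by identity) unless
    ``include_self``."""
    center = c.seed.centroid_mm
    n = 0
    for s in all_seeds:
        if s is c.seed and not p.include_self:
            continue
        if np.linalg.norm(s.centroid_mm - center) <= p.neighbor_radius_mm:
            n += 1
    return n >= p.min_neighbor_seeds


def _expand_to_cube(bounds: np.ndarray) -> np.ndarray:
    extent = bounds[:, 1] - bounds[:, 0]
    side = float(extent.max())
    center = bounds.mean(axis=1)
    return np.stack([center - side / 2.0, center + side / 2.0], axis=1)


def _distinct_members(clusters: list[ClusterCandidate]) -> list[MCCandidate]:
    seen: dict[int, MCCandidate] = {}
    for c in clusters:
        for m in c.members:
            seen.setdefault(id(m), m)
    return list(seen.values())


def _content_stats(
    bounds: np.ndarray, clusters: list[ClusterCandidate]
) -> tuple[int, float]:
    count, vol = 0, 0.0
    for m in _distinct_members(clusters):
        if np.all(bounds[:, 0] <= m.centroid_mm) and np.all(m.centroid_mm <= bounds[:, 1]):
            count += 1
            vol += m.volume_mm3
    return count, vol


def build_bounding_cubes(accepted: list[ClusterCandidate]) -> list[BoundingCube]:
    """One cube per accepted cluster: the tight box over all member voxels'
    physical extents (each voxel spans its center ± spacing/2 on its own
    grid), expanded to a cube on its longest side.  Memberless clusters are
    skipped with a warning."""
    cubes: list[BoundingCube] = []
    skipped = 0
    for c in accepted:
        if not c.members:
            skipped += 1
            continue
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for m in c.members:
            sp = m.grid_spacing
            mm = m.voxels * sp + m.grid_origin
            lo = np.minimum(lo, mm.min(axis=0) - sp / 2)
            hi = np.maximum(hi, mm.max(axis=0) + sp / 2)
        bounds = _expand_to_cube(np.stack([lo, hi], axis=1))
        count, vol = _content_stats(bounds, [c])
        cubes.append(BoundingCube(bounds, [c], count, vol, merged_from=1))
    if skipped:
        logger.warning("build_bounding_cubes: skipped %d memberless clusters", skipped)
    return cubes


def _overlap_positive(a: np.ndarray, b: np.ndarray) -> bool:
    lo = np.maximum(a[:, 0], b[:, 0])
    hi = np.minimum(a[:, 1], b[:, 1])
    return bool(np.all(hi > lo))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_overlapping_cubes(cubes: list[BoundingCube]) -> list[BoundingCube]:
    """Transitively combine cubes with positive pairwise overlap volume.

    Each overlap group is replaced by the cube-expanded tight box of its
    members with content statistics recomputed over the distinct MC
    candidates of all contributing clusters.  Because cube expansion can
    create fresh overlaps, merging repeats until a fixed point, which makes
    the operation idempotent.  Face- or edge-touching cubes (overlap volume
    exactly 0) are not merged.

    When candidate clusters are dense relative to the field of view the
    combined cubes can grow large (expansion inflates the short axes every
    round); see the methods note for the consequences on phantom studies.
    """
    current = list(cubes)
    while True:
        n = len(current)
        if n <= 1:
            return current
        uf = _UnionFind(n)
        any_merge = False
        for i in range(n):
            for j in range(i + 1, n):
                if _overlap_positive(current[i].bounds, current[j].bounds):
                    uf.union(i, j)
                    any_merge = True
        if not any_merge:
            return current
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(uf.find(i), []).append(i)
        merged: list[BoundingCube] = []
        for root in sorted(groups):
            members = [current[i] for i in groups[root]]
            if len(members) == 1:
                merged.append(members[0])
                continue
            lo = np.min([c.bounds[:, 0] for c in members], axis=0)
            hi = np.max([c.bounds[:, 1] for c in members], axis=0)
            bounds = _expand_to_cube(np.stack([lo, hi], axis=1))
            clusters = [cl for c in members for cl in c.source_clusters]
            count, vol = _content_stats(bounds, clusters)
            merged.append(
                BoundingCube(
                    bounds,
                    clusters,
                    count,
                    vol,
                    merged_from=sum(c.merged_from for c in members),
                )
            )
        current = merged


def rule_cube_content(cube: BoundingCube, p: FPReductionParams) -> bool:
    """True = keep. Eliminates cubes with fewer than ``min_cube_mc_count``
    contained MC candidates or less than ``min_cube_mc_volume_mm3`` of
    summed candidate volume (boundaries inclusive: equality keeps)."""
    if cube.mc_count < p.min_cube_mc_count:
        return False
    if cube.mc_volume_mm3 < p.min_cube_mc_volume_mm3:
        return False
    if p.require_merged_from_gt1 and cube.merged_from <= 1:
        return False
    return True


def reduce_false_positives(
    clusters: list[ClusterCandidate],
    seeds: list[SeedObject],
    mcs: list[MCCandidate],
    p: FPReductionParams,
) -> tuple[list[DetectedMCC], dict[str, int]]:
    """Run the full cascade; returns the surviving detections and a per-stage
    count log ``{stage: candidates remaining after it}``."""
    log: dict[str, int] = {"input_clusters": len(clusters)}
    kept = [c for c in clusters if rule_member_voxels(c, p)]
    log["after_member_voxel_rule"] = len(kept)
    kept = [c for c in kept if rule_neighbor_seeds(c, seeds, p)]
    log["after_neighbor_seed_rule"] = len(kept)
    cubes = build_bounding_cubes(kept)
    log["bounding_cubes"] = len(cubes)
    cubes = merge_overlapping_cubes(cubes)
    log["after_merge"] = len(cubes)
    survivors = [c for c in cubes if rule_cube_content(c, p)]
    log["after_cube_content_rule"] = len(survivors)
    dets = [
        DetectedMCC(cube=c, score=float(sum(cl.score for cl in c.source_clusters)))
        for c in survivors
    ]
    for stage, count in log.items():
        logger.info("fp_reduction %s: %d", stage, count)
    return dets, log


def write_detections(dets: list[DetectedMCC], path) -> None:
    """Detections as delimited text: the annotation box dialect plus
    score, mc_count, mc_volume_mm3 and merged_from columns."""
    import pandas as pd

    rows = []
    for i, d in enumerate(dets):
        b = d.cube.bounds
        rows.append(
            {
                "label": f"detection_{i}",
                "xmin_mm": b[0, 0],
                "xmax_mm": b[0, 1],
                "ymin_mm": b[1, 0],
                "ymax_mm": b[1, 1],
                "zmin_mm": b[2, 0],
                "zmax_mm": b[2, 1],
                "score": d.score,
                "mc_count": d.cube.mc_count,
                "mc_volume_mm3": d.cube.mc_volume_mm3,
                "merged_from": d.cube.merged_from,
            }
        )
    columns = [
        "label",
        "xmin_mm",
        "xmax_mm",
        "ymin_mm",
        "ymax_mm",
        "zmin_mm",
        "zmax_mm",
        "score",
        "mc_count",
        "mc_volume_mm3",
        "merged_from",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_detections(path) -> list[DetectedMCC]:
    """Inverse of :func:`write_detections` (source clusters are not
    persisted; cubes come back with empty cluster lists)."""
    import pandas as pd

    df = pd.read_csv(path)
    dets = []
    for _, row in df.iterrows():
        bounds = np.array(
            [
                [row["xmin_mm"], row["xmax_mm"]],
                [row["ymin_mm"], row["ymax_mm"]],
                [row["zmin_mm"], row["zmax_mm"]],
            ]
        )
        cube = BoundingCube(
            bounds,
            [],
            int(row["mc_count"]),
            float(row["mc_volume_mm3"]),
            int(row["merged_from"]),
        )
        dets.append(DetectedMCC(cube=cube, score=float(row["score"])))
    return dets
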