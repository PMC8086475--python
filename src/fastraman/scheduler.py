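"""Staggered three-round sampling-point planner.

Round 1 places a single point per segment (adipose screen).  Round 2
distributes up to 550 points over the retained segments in proportion to
segment area (largest-remainder rounding, at least one point each), which
keeps the sampling-point density consistent across segments.  Round 3
lays a 4 x 4 raster with 6 um step over each of the (up to three)
top-scoring segments, centred on the centroid of that segment's earlier
BCC-classified points.

Stage positions are continuous micrometres; a pixel (row, col) maps to
stage (x, y) = (col, row) * pixel pitch.  All plans are deterministic
functions of the segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import Segment

DEFAULT_ROUND2_BUDGET = 550
RASTER_SIDE = 4  # 4 x 4 raster
RASTER_STEP_UM = 6.0


@dataclass(frozen=True)
class SamplePoint:
    x_um: float
    y_um: float
    segment_id: int
    round: int  # 1, 2 or 3
    exposure_s: float


@dataclass
class SamplingPlan:
    points: list[SamplePoint]

    def __len__(self) -> int:
        return len(self.points)

    def for_segment(self, seg_id: int) -> list[SamplePoint]:
        return [p for p in self.points if p.segment_id == seg_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.x_um, p.y_um, p.segment_id, p.round, p.exposure_s) for p in self.points],
            columns=["x_um", "y_um", "segment_id", "round", "exposure_s"],
        )


def _pixel_to_stage(row: float, col: float, pitch_um: float) -> tuple[float, float]:
    return col * pitch_um, row * pitch_um


def _nearest_interior_pixel(seg: Segment, row: float, col: float) -> tuple[int, int]:
    """Segment pixel closest to a (possibly exterior) point; ties break
    toward the smaller (row, col)."""
    d2 = (seg.rows - row) ** 2 + (seg.cols - col) ** 2
    best = np.lexsort((seg.cols, seg.rows, d2))[0]
    return int(seg.rows[best]), int(seg.cols[best])


def plan_round1(
    segments: list[Segment], pitch_um: float, exposure_s: float = 2.0
) -> SamplingPlan:
    """One point per segment, at the segment pixel nearest its centroid."""
    if not segments:
        raise ValueError("round 1 needs at least one segment")
    pts = []
    for seg in segments:
        r, c = _nearest_interior_pixel(seg, *seg.centroid)
        x, y = _pixel_to_stage(r, c, pitch_um)
        pts.append(SamplePoint(x, y, seg.id, 1, exposure_s))
    return SamplingPlan(pts)


def allocate_points(areas: list[int], budget: int) -> list[int]:
    """Area-proportional largest-remainder allocation.

    Every segment gets at least one point and no more than its pixel
    count; the total is ``min(budget, sum(areas))``.  Remainder ties break
    toward the larger area, then the earlier segment.
    """
    n = len(areas)
    if budget < n:
        raise ValueError(f"budget {budget} is below the number of segments {n}")
    areas_arr = np.asarray(areas, float)
    capacity = np.asarray(areas, int)
    target = min(budget, int(capacity.sum()))
    quota = target * areas_arr / areas_arr.sum()
    alloc = np.floor(quota).astype(int)
    # largest remainders first; ties -> larger area, then lower index
    order = sorted(
        range(n), key=lambda i: (-(quota[i] - alloc[i]), -areas_arr[i], i)
    )
    for i in order:
        if alloc.sum() >= target:
            break
        alloc[i] += 1
    # floors can undershoot by more than the remainder pass fixed
    while alloc.sum() < target:
        open_idx = np.nonzero(alloc < capacity)[0]
        if open_idx.size == 0:
            break
        i = int(open_idx[np.argmin(alloc[open_idx] / areas_arr[open_idx])])
        alloc[i] += 1
    # at least one point per segment; take from the most-allocated
    for i in range(n):
        if alloc[i] == 0:
            j = int(np.argmax(alloc))
            if alloc[j] > 1:
                alloc[j] -= 1
            alloc[i] += 1
    # never more points than pixels
    over = alloc > capacity
    if over.any():
        surplus = int((alloc[over] - capacity[over]).sum())
        alloc[over] = capacity[over]
        room = capacity - alloc
        order2 = np.argsort(-areas_arr)
        while surplus > 0:
            placed = False
            for i in order2:
                if surplus == 0:
                    break
                if room[i] > 0:
                    alloc[i] += 1
                    room[i] -= 1
                    surplus -= 1
                    placed = True
            if not placed:
                break
    return alloc.tolist()


def plan_round2(
    segments: list[Segment],
    pitch_um: float,
    budget: int = DEFAULT_ROUND2_BUDGET,
    exposure_s: float = 2.0,
) -> SamplingPlan:
    """Density-consistent allocation of up to ``budget`` points.

    Within a segment the allocated points are spread evenly along the
    row-major ordering of its pixels, which approximates a uniform grid at
    the realised density.
    """
    if not segments:
        return SamplingPlan([])
    counts = allocate_points([s.area_px for s in segments], budget)
    pts = []
    for seg, k in zip(segments, counts):
        order = np.lexsort((seg.cols, seg.rows))
        take = np.floor(np.linspace(0, seg.area_px - 1, k)).astype(int) if k > 1 else [0]
        for t in take:
            r, c = int(seg.rows[order[t]]), int(seg.cols[order[t]])
            x, y = _pixel_to_stage(r, c, pitch_um)
            pts.append(SamplePoint(x, y, seg.id, 2, exposure_s))
    return SamplingPlan(pts)


def raster_offsets(side: int = RASTER_SIDE, step_um: float = RASTER_STEP_UM) -> np.ndarray:
    """Offsets of a side x side raster centred on the anchor."""
    o = (np.arange(side) - (side - 1) / 2.0) * step_um
    return np.array([(dx, dy) for dy in o for dx in o])


def plan_round3(
    segments: list[Segment],
    anchors: dict[int, tuple[float, float]],
    pitch_um: float,
    exposure_s: float = 2.0,
    step_um: float = RASTER_STEP_UM,
    side: int = RASTER_SIDE,
) -> SamplingPlan:
    """4 x 4 raster (6 um step) per selected segment, centred on its anchor.

    The anchor is the centroid of the segment's BCC-classified points from
    Rounds 1-2; if it falls outside the segment footprint it is snapped to
    the nearest segment pixel centre.  Raster corners may extend up to
    1.5 steps beyond the segment boundary, as the instrument's stage does.
    """
    if not 1 <= len(segments) <= 3:
        raise ValueError("round 3 runs on 1-3 segments")
    pts = []
    for seg in segments:
        if seg.id not in anchors:
            raise ValueError(f"segment {seg.id} has no BCC-classified anchor point")
        ax, ay = anchors[seg.id]
        # snap to segment if the anchor drifted outside its footprint
        col, row = ax / pitch_um, ay / pitch_um
        rr = np.round(row).astype(int)
        cc = np.round(col).astype(int)
        inside = np.any((seg.rows == rr) & (seg.cols == cc))
        if not inside:
            r, c = _nearest_interior_pixel(seg, row, col)
            ax, ay = _pixel_to_stage(r, c, pitch_um)
        for dx, dy in raster_offsets(side, step_um):
            pts.append(SamplePoint(ax + dx, ay + dy, seg.id, 3, exposure_s))
    return SamplingPlan(pts)
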