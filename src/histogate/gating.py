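"""Spatial gating of segmentation objects by patch-level attention.

An attention map is thresholded (inclusive, default 0.2 — the lower end of
the high-attention score interval) into an attended patch set; cells are kept
when their centroid falls in an attended patch, tissue regions are clipped to
the attended footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import box
from shapely.ops import unary_union

from .io import AttentionMap, CellInstance, TissueRegion, ValidationError

__all__ = ["AttendedMask", "build_attended_mask", "attended_fraction", "gate_objects"]

DEFAULT_ATTENTION_THRESHOLD = 0.2


@dataclass
class AttendedMask:
    """Set of attended (col, row) patches plus their union footprint."""

    slide_id: str
    threshold: float
    patches: frozenset[tuple[int, int]]
    patch_size: int
    origin: tuple[float, float]
    footprint: object = field(repr=False, default=None)  # shapely geometry

    @property
    def footprint_area(self) -> float:
        return float(self.patch_size**2 * len(self.patches))

    def contains_point(self, x: float, y: float) -> bool:
        """Membership via grid arithmetic (patches are half-open squares)."""
        col = int(np.floor((x - self.origin[0]) / self.patch_size))
        row = int(np.floor((y - self.origin[1]) / self.patch_size))
        return (col, row) in self.patches


def build_attended_mask(
    amap: AttentionMap, threshold: float = DEFAULT_ATTENTION_THRESHOLD
) -> AttendedMask:
    """Select patches with score >= threshold (missing patches never selected).

    An attention map with no present patch at all is an error; a map where no
    patch clears the threshold yields an empty mask.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must lie in [0, 1], got {threshold}")
    if amap.n_present == 0:
        raise ValidationError(f"slide {amap.slide_id}: attention map has no present patches")
    rows, cols = np.where(amap.scores >= threshold)  # NaN compares False
    patches = frozenset(zip(cols.tolist(), rows.tolist()))
    ox, oy = amap.origin
    ps = amap.patch_size
    boxes = [box(ox + c * ps, oy + r * ps, ox + (c + 1) * ps, oy + (r + 1) * ps) for c, r in patches]
    footprint = unary_union(boxes) if boxes else box(0, 0, 0, 0).buffer(0)
    return AttendedMask(
        slide_id=amap.slide_id,
        threshold=threshold,
        patches=patches,
        patch_size=ps,
        origin=amap.origin,
        footprint=footprint,
    )


def attended_fraction(mask: AttendedMask, amap: AttentionMap) -> float:
    """|attended patches| / |present patches| (missing patches excluded)."""
    if amap.n_present == 0:
        raise ValidationError("attention map has zero present patches")
    return len(mask.patches) / amap.n_present


def gate_objects(
    cells: Sequence[CellInstance],
    regions: Sequence[TissueRegion],
    mask: AttendedMask,
) -> tuple[list[CellInstance], list[TissueRegion]]:
    """Attended subset: cells by centroid membership, regions clipped.

    A region is replaced by its intersection with the footprint; empty clips
    are dropped.  Cells straddling the attended boundary are decided by their
    centroid alone, so no cell is double counted.
    """
    kept_cells = [c for c in cells if mask.contains_point(*c.centroid)]
    kept_regions: list[TissueRegion] = []
    if mask.patches:
        for r in regions:
            clip = r.polygon.intersection(mask.footprint)
            if clip.geom_type == "GeometryCollection":  # drop stray lines/points
                clip = unary_union([g for g in clip.geoms if g.area > 0])
            if not clip.is_empty and clip.area > 0:
                kept_regions.append(
                    TissueRegion(region_id=r.region_id, polygon=clip, tissue_type=r.tissue_type)
                )
    return kept_cells, kept_regions
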