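"""Stromal-architecture features.

Total stromal area, the tumor–stroma interface (TSI) partition of stroma into
a proximal band (within distance ``d`` of tumor tissue, default 100 px) and
distal stroma beyond it, and stromal ("connective" nuclear class) cell
counts.  All areas are exact shapely geometry, px^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from shapely.ops import unary_union

from .io import CellInstance, CellType, TissueRegion, TissueType

__all__ = [
    "StromaPartition",
    "total_stromal_area",
    "stroma_partition",
    "stromal_cell_stats",
    "region_features",
    "TISSUE_FEATURES",
]

DEFAULT_TSI_DISTANCE = 100.0

TISSUE_FEATURES = [
    "n_neoplastic_cells",
    "proportion_neoplastic_cells",
    "total_tumor_area",
    "n_connective_cells",
    "proportion_connective_cells",
    "total_stromal_area",
    "tsi_stromal_area",
    "distal_stromal_area",
    "n_inflammatory_cells",
    "proportion_inflammatory_cells",
    "n_macrophage_cells",
    "proportion_macrophage_cells",
    "n_dead_cells",
    "proportion_dead_cells",
    "n_tumor_regions",
    "n_stroma_regions",
    "mean_tumor_region_area",
    "total_necrosis_area",
]


@dataclass(frozen=True)
class StromaPartition:
    total_stromal_area: float
    tsi_area: float
    distal_stromal_area: float
    interface_distance_d: float
    no_tumor_warning: bool = False


def _typed(regions: Sequence[TissueRegion], ttype: TissueType):
    return [r.polygon for r in regions if r.tissue_type is ttype]


def total_stromal_area(regions: Sequence[TissueRegion]) -> float:
    """Summed area of stroma-typed regions (region interiors are disjoint)."""
    return float(sum(p.area for p in _typed(regions, TissueType.STROMA)))


def stroma_partition(
    regions: Sequence[TissueRegion], d: float = DEFAULT_TSI_DISTANCE
) -> StromaPartition:
    """Partition stroma into the TSI band (within ``d`` of tumor) and distal rest.

    The band is stroma intersected with tumor buffered outward by ``d``
    (round joins).  With no tumor region the whole stroma is distal and the
    result carries a warning flag.
    """
    if d <= 0:
        raise ValueError(f"interface distance d must be positive, got {d}")
    stroma = _typed(regions, TissueType.STROMA)
    total = float(sum(p.area for p in stroma))
    tumor = _typed(regions, TissueType.EPITHELIAL_TUMOR)
    if not tumor:
        return StromaPartition(total, 0.0, total, d, no_tumor_warning=True)
    band = unary_union(tumor).buffer(d)
    tsi = float(sum(p.intersection(band).area for p in stroma))
    return StromaPartition(total, tsi, total - tsi, d)


def stromal_cell_stats(cells: Sequence[CellInstance]) -> tuple[int, float]:
    """(connective cell count, connective fraction of all cells).

    The proportion is NaN — an explicit missing marker — when there are no
    cells at all.
    """
    n_conn = sum(1 for c in cells if c.cell_type is CellType.CONNECTIVE)
    if not cells:
        return 0, float("nan")
    return n_conn, n_conn / len(cells)


def region_features(
    cells: Sequence[CellInstance],
    regions: Sequence[TissueRegion],
    tsi_distance: float = DEFAULT_TSI_DISTANCE,
) -> dict[str, float]:
    """All tissue-architecture catalog features for one slide/ROI."""
    nan = float("nan")
    out: dict[str, float] = {}
    n_cells = len(cells)
    for ctype, short in [
        (CellType.NEOPLASTIC, "neoplastic"),
        (CellType.CONNECTIVE, "connective"),
        (CellType.INFLAMMATORY, "inflammatory"),
        (CellType.MACROPHAGE, "macrophage"),
        (CellType.DEAD, "dead"),
    ]:
        n = sum(1 for c in cells if c.cell_type is ctype)
        out[f"n_{short}_cells"] = float(n)
        out[f"proportion_{short}_cells"] = n / n_cells if n_cells else nan
    tumor = _typed(regions, TissueType.EPITHELIAL_TUMOR)
    out["total_tumor_area"] = float(sum(p.area for p in tumor))
    out["n_tumor_regions"] = float(len(tumor))
    out["mean_tumor_region_area"] = out["total_tumor_area"] / len(tumor) if tumor else nan
    stroma = _typed(regions, TissueType.STROMA)
    out["n_stroma_regions"] = float(len(stroma))
    part = stroma_partition(regions, tsi_distance)
    out["total_stromal_area"] = part.total_stromal_area
    out["tsi_stromal_area"] = part.tsi_area
    out["distal_stromal_area"] = part.distal_stromal_area
    out["total_necrosis_area"] = float(
        sum(p.area for p in _typed(regions, TissueType.NECROSIS))
    )
    return out
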