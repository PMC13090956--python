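"""Domain types and on-disk formats.

Coordinate convention: pixel units at 20x magnification, origin top-left,
y increasing downward, polygons as closed rings (first vertex repeated),
areas in px^2.

On disk, one GeoJSON FeatureCollection holds the panoptic segmentation of a
single slide.  Each feature carries ``properties.object_type`` ("cell" or
"tissue") and ``properties.classification.name`` (one of the 5 nuclear or
6 tissue class labels).  Attention grids, clinical outcomes and feature
tables are CSV; table provenance travels in a JSON sidecar.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

__all__ = [
    "CellType",
    "TissueType",
    "PFIClass",
    "CellInstance",
    "TissueRegion",
    "AttentionMap",
    "SlideRecord",
    "FeatureTable",
    "SchemaError",
    "GeometryError",
    "ValidationError",
    "classify_pfi",
    "validate_region_overlaps",
    "read_panoptic_geojson",
    "write_panoptic_geojson",
    "read_attention_table",
    "write_attention_table",
    "read_clinical_table",
    "write_clinical_table",
    "read_feature_table",
    "write_feature_table",
]

# PFI class cutoffs in days: short = platinum resistant, long = sensitive.
PFI_SHORT_MAX_DAYS = 180
PFI_LONG_MIN_DAYS = 365


class SchemaError(ValueError):
    """An input file does not follow the documented schema."""


class GeometryError(ValueError):
    """A polygon violates the geometry invariants."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


class CellType(str, enum.Enum):
    NEOPLASTIC = "neoplastic"
    CONNECTIVE = "connective"
    INFLAMMATORY = "inflammatory"
    DEAD = "dead"
    MACROPHAGE = "macrophage"


class TissueType(str, enum.Enum):
    STROMA = "stroma"
    BENIGN_OMENTAL = "benign_omental"
    EPITHELIAL_TUMOR = "epithelial_tumor"
    NECROSIS = "necrosis"
    HEMORRHAGE = "hemorrhage"
    SERUM = "serum"


class PFIClass(str, enum.Enum):
    SHORT = "short"
    LONG = "long"
    EXCLUDED = "excluded"


def classify_pfi(pfi_days: float) -> PFIClass:
    """Class label from the progression-free interval.

    long iff pfi_days > 365; short iff pfi_days < 180; in-between cases are
    excluded from classification.
    """
    if pfi_days < 0:
        raise ValidationError(f"pfi_days must be non-negative, got {pfi_days}")
    if pfi_days > PFI_LONG_MIN_DAYS:
        return PFIClass.LONG
    if pfi_days < PFI_SHORT_MAX_DAYS:
        return PFIClass.SHORT
    return PFIClass.EXCLUDED


def _as_ring(coords) -> np.ndarray:
    ring = np.asarray(coords, dtype=float)
    if ring.ndim != 2 or ring.shape[1] != 2:
        raise GeometryError(f"polygon ring must be (n, 2), got {ring.shape}")
    if not np.allclose(ring[0], ring[-1]):
        ring = np.vstack([ring, ring[0]])
    return ring


@dataclass(frozen=True)
class CellInstance:
    """One segmented nucleus: closed polygon ring, centroid and nuclear type."""

    cell_id: str
    polygon: np.ndarray  # (n, 2) closed ring, px at 20x
    cell_type: CellType
    centroid: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        ring = _as_ring(self.polygon)
        if ring.shape[0] < 5:  # closed ring: >= 4 distinct vertices
            raise GeometryError(
                f"cell {self.cell_id}: polygon needs >= 4 vertices, got {ring.shape[0] - 1}"
            )
        poly = Polygon(ring)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError(f"cell {self.cell_id}: non-simple or zero-area polygon")
        object.__setattr__(self, "polygon", ring)
        if self.centroid is None:
            c = poly.centroid
            object.__setattr__(self, "centroid", (c.x, c.y))

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass(frozen=True)
class TissueRegion:
    """One semantic tissue polygon (outer ring + optional holes)."""

    region_id: str
    polygon: Polygon  # shapely, may have interior rings
    tissue_type: TissueType

    def __post_init__(self):
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise GeometryError(f"region {self.region_id}: zero-area polygon")
        if not self.polygon.is_valid:
            raise GeometryError(f"region {self.region_id}: invalid polygon")

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass
class AttentionMap:
    """Patch-grid attention heatmap for one slide.

    ``scores`` is an (n_rows, n_cols) float grid in [0, 1]; NaN marks a patch
    the upstream patcher did not extract (background).
    """

    slide_id: str
    patch_size: int
    origin: tuple[float, float]
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or min(self.scores.shape) < 1:
            raise ValidationError("attention grid must be 2-D and non-empty")
        if self.patch_size <= 0:
            raise ValidationError("patch_size must be positive")
        present = self.scores[~np.isnan(self.scores)]
        if present.size and (present.min() < 0 or present.max() > 1):
            raise ValidationError("attention scores must lie in [0, 1]")

    @property
    def n_rows(self) -> int:
        return self.scores.shape[0]

    @property
    def n_cols(self) -> int:
        return self.scores.shape[1]

    @property
    def n_present(self) -> int:
        return int(np.sum(~np.isnan(self.scores)))


@dataclass(frozen=True)
class SlideRecord:
    """Slide/patient identifiers plus clinical outcome."""

    slide_id: str
    patient_id: str
    pfi_days: int
    os_days: int
    pfi_event: bool
    os_event: bool

    def __post_init__(self):
        if self.pfi_days < 0 or self.os_days < 0:
            raise ValidationError(
                f"slide {self.slide_id}: durations must be non-negative"
            )

    @property
    def pfi_class(self) -> PFIClass:
        return classify_pfi(self.pfi_days)


@dataclass
class FeatureTable:
    """Per-slide named feature vector with a single provenance.

    ``values`` is a DataFrame indexed by slide_id; missing entries are NaN
    (written as literal "NA").  provenance is "attended" or "whole_slide".
    """

    values: pd.DataFrame
    provenance: str

    def __post_init__(self):
        if self.provenance not in ("attended", "whole_slide"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate feature columns: {dupes}")
        self.values = self.values.astype(float)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# GeoJSON segmentation I/O


def validate_region_overlaps(
    regions: Sequence[TissueRegion], tolerance: float = 0.0
) -> None:
    """Region interiors of one slide must not overlap beyond ``tolerance`` px^2.

    Touching boundaries are fine; a pairwise interior intersection larger
    than the tolerance raises :class:`GeometryError` naming both regions.
    """
    from shapely.strtree import STRtree

    if len(regions) < 2:
        return
    tree = STRtree([r.polygon for r in regions])
    for i, r in enumerate(regions):
        for j in tree.query(r.polygon):
            if j <= i:
                continue
            other = regions[int(j)]
            inter = r.polygon.intersection(other.polygon).area
            if inter > tolerance:
                raise GeometryError(
                    f"regions {r.region_id} and {other.region_id} overlap by "
                    f"{inter:.1f} px^2 (tolerance {tolerance})"
                )


_CELL_LABELS = {t.value for t in CellType}
_TISSUE_LABELS = {t.value for t in TissueType}


def read_panoptic_geojson(
    path, overlap_tolerance: float = 0.0
) -> tuple[list[CellInstance], list[TissueRegion]]:
    """Read one slide's panoptic segmentation FeatureCollection.

    Every feature must map to exactly one cell or tissue region; unknown class
    labels raise :class:`SchemaError` naming the label; region interiors may
    overlap at most ``overlap_tolerance`` px^2 pairwise.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: malformed GeoJSON: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a FeatureCollection")
    cells: list[CellInstance] = []
    regions: list[TissueRegion] = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties", {})
        label = (props.get("classification") or {}).get("name")
        obj = props.get("object_type")
        fid = str(feat.get("id", props.get("id", i)))
        geom = shape(feat["geometry"])
        if obj == "cell":
            if label not in _CELL_LABELS:
                raise SchemaError(f"{path}: unknown cell class label {label!r}")
            ring = np.asarray(geom.exterior.coords, dtype=float)
            cells.append(CellInstance(cell_id=fid, polygon=ring, cell_type=CellType(label)))
        elif obj == "tissue":
            if label not in _TISSUE_LABELS:
                raise SchemaError(f"{path}: unknown tissue class label {label!r}")
            regions.append(TissueRegion(region_id=fid, polygon=geom, tissue_type=TissueType(label)))
        else:
            raise SchemaError(f"{path}: feature {fid} has unknown object_type {obj!r}")
    validate_region_overlaps(regions, overlap_tolerance)
    return cells, regions


def write_panoptic_geojson(
    cells: Iterable[CellInstance], regions: Iterable[TissueRegion], path
) -> None:
    features = []
    for c in cells:
        features.append(
            {
                "type": "Feature",
                "id": c.cell_id,
                "geometry": mapping(Polygon(c.polygon)),
                "properties": {
                    "object_type": "cell",
                    "classification": {"name": c.cell_type.value},
                },
            }
        )
    for r in regions:
        features.append(
            {
                "type": "Feature",
                "id": r.region_id,
                "geometry": mapping(r.polygon),
                "properties": {
                    "object_type": "tissue",
                    "classification": {"name": r.tissue_type.value},
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "metadata": {"crs": "pixel@20x", "origin": "top-left"},
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Attention grid I/O

def read_attention_table(path) -> AttentionMap:
    """Read a patch-attention CSV with ``# key=value`` header metadata.

    Columns (col, row, score); grid positions absent from the file are
    missing patches.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    import io as _io

    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])))
    required = {"col", "row", "score"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: need columns {sorted(required)}")
    if df.duplicated(subset=["col", "row"]).any():
        raise ValidationError(f"{path}: duplicate (col, row) entries")
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise ValidationError(f"{path}: attention score outside [0, 1]")
    n_rows = int(meta.get("n_rows", df["row"].max() + 1))
    n_cols = int(meta.get("n_cols", df["col"].max() + 1))
    scores = np.full((n_rows, n_cols), np.nan)
    scores[df["row"].to_numpy(int), df["col"].to_numpy(int)] = df["score"].to_numpy(float)
    origin = (float(meta.get("origin_x", 0.0)), float(meta.get("origin_y", 0.0)))
    return AttentionMap(
        slide_id=meta.get("slide_id", Path(path).stem),
        patch_size=int(meta.get("patch_size", 1)),
        origin=origin,
        scores=scores,
    )


def write_attention_table(amap: AttentionMap, path) -> None:
    rows, cols = np.where(~np.isnan(amap.scores))
    with open(path, "w") as fh:
        fh.write(f"# slide_id={amap.slide_id}\n")
        fh.write(f"# patch_size={amap.patch_size}\n")
        fh.write(f"# origin_x={amap.origin[0]}\n")
        fh.write(f"# origin_y={amap.origin[1]}\n")
        fh.write(f"# n_rows={amap.n_rows}\n")
        fh.write(f"# n_cols={amap.n_cols}\n")
        fh.write("col,row,score\n")
        for r, c in zip(rows, cols):
            fh.write(f"{c},{r},{amap.scores[r, c]:.17g}\n")


# ---------------------------------------------------------------------------
# Clinical table I/O

def read_clinical_table(path) -> list[SlideRecord]:
    df = pd.read_csv(path)
    required = {"slide_id", "patient_id", "pfi_days", "os_days", "pfi_event", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SlideRecord(
                slide_id=str(row.slide_id),
                patient_id=str(row.patient_id),
                pfi_days=int(row.pfi_days),
                os_days=int(row.os_days),
                pfi_event=bool(row.pfi_event),
                os_event=bool(row.os_event),
            )
        )
    return records


def write_clinical_table(records: Sequence[SlideRecord], path) -> None:
    df = pd.DataFrame(
        {
            "slide_id": [r.slide_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "pfi_days": [r.pfi_days for r in records],
            "os_days": [r.os_days for r in records],
            "pfi_event": [int(r.pfi_event) for r in records],
            "os_event": [int(r.os_event) for r in records],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature table I/O

def write_feature_table(table: FeatureTable, path) -> None:
    """CSV with slide_id key column plus a JSON sidecar recording provenance.

    Column order is the table's (catalog) order; floats at 17 significant
    digits so write -> read is the identity up to formatting.
    """
    path = Path(path)
    table.values.to_csv(path, index_label="slide_id", na_rep="NA", float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    with open(sidecar, "w") as fh:
        json.dump({"provenance": table.provenance, "n_features": len(table.feature_names)}, fh)


def read_feature_table(path) -> FeatureTable:
    path = Path(path)
    df = pd.read_csv(path, index_col="slide_id", na_values=["NA"])
    df.index = df.index.astype(str)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            provenance = json.load(fh)["provenance"]
    else:
        raise SchemaError(f"{path}: missing provenance sidecar {sidecar.name}")
    return FeatureTable(values=df, provenance=provenance)
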