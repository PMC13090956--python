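"""Per-cell shape descriptors and their slide-level aggregates.

Eccentricity and major-axis length come from the ellipse of equal second
moments, with the moments computed analytically on the polygon interior
(Green's theorem) so the result is resolution independent.  Boundary
complexity is the box-counting dimension of the cell outline.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .io import CellInstance, GeometryError

__all__ = [
    "polygon_moments",
    "eccentricity",
    "major_axis_length",
    "fractal_dimension",
    "cell_descriptors",
    "aggregate_morphology",
    "MORPHOMETRY_FEATURES",
]

# Slide-level aggregates emitted per cell type; the neoplastic set carries the
# pleomorphism features, the stromal/immune sets coarser summaries.
_AGGREGATE_PLAN: dict[str, dict[str, tuple[str, ...]]] = {
    "neoplastic": {
        "eccentricity": ("min", "mean", "max", "sd"),
        "major_axis_length": ("min", "mean", "max", "sd"),
        "fractal_dimension": ("min", "mean", "max", "sd"),
        "area": ("min", "mean", "max", "sd"),
    },
    "connective": {
        "eccentricity": ("mean", "sd"),
        "major_axis_length": ("mean", "sd"),
        "area": ("mean", "sd"),
    },
    "inflammatory": {
        "eccentricity": ("mean", "sd"),
        "area": ("mean", "sd"),
    },
}

MORPHOMETRY_FEATURES: list[str] = [
    f"{stat}_{desc}_{ctype}"
    for ctype, plan in _AGGREGATE_PLAN.items()
    for desc, stats in plan.items()
    for stat in stats
]


def _ring(polygon) -> np.ndarray:
    ring = np.asarray(polygon, dtype=float)
    if not np.allclose(ring[0], ring[-1]):
        ring = np.vstack([ring, ring[0]])
    return ring


def polygon_moments(polygon) -> tuple[float, np.ndarray, np.ndarray]:
    """(area, centroid, central second-moment matrix) of a simple polygon.

    The moment matrix is the per-unit-area covariance of the interior, i.e.
    [[mu_xx, mu_xy], [mu_xy, mu_yy]] with mu_xx = E[(x-cx)^2] etc.
    """
    ring = _ring(polygon)
    x0, y0 = ring[:-1, 0], ring[:-1, 1]
    x1, y1 = ring[1:, 0], ring[1:, 1]
    cross = x0 * y1 - x1 * y0
    area = 0.5 * np.sum(cross)
    if abs(area) < 1e-12:
        raise GeometryError("degenerate polygon: zero area")
    cx = np.sum((x0 + x1) * cross) / (6.0 * area)
    cy = np.sum((y0 + y1) * cross) / (6.0 * area)
    ixx = np.sum((x0 * x0 + x0 * x1 + x1 * x1) * cross) / (12.0 * area)
    iyy = np.sum((y0 * y0 + y0 * y1 + y1 * y1) * cross) / (12.0 * area)
    ixy = np.sum((x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0) * cross) / (24.0 * area)
    cov = np.array([[ixx - cx * cx, ixy - cx * cy], [ixy - cx * cy, iyy - cy * cy]])
    return abs(area), np.array([cx, cy]), cov


def _ellipse_axes(polygon) -> tuple[float, float]:
    """Semi-axes (a >= b) of the ellipse of equal second moments."""
    _, _, cov = polygon_moments(polygon)
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 0.0, None)
    b, a = 2.0 * np.sqrt(lam)  # ellipse with semi-axis s has variance s^2/4
    return float(a), float(b)


def eccentricity(polygon) -> float:
    """Fit-ellipse eccentricity e = sqrt(1 - (b/a)^2), in [0, 1)."""
    a, b = _ellipse_axes(polygon)
    if a <= 0:
        raise GeometryError("degenerate polygon: zero spread")
    return math.sqrt(max(0.0, 1.0 - (b / a) ** 2))


def major_axis_length(polygon) -> float:
    """Full major axis (2a) of the moments-fit ellipse, in pixels."""
    a, _ = _ellipse_axes(polygon)
    return 2.0 * a


def _densify(ring: np.ndarray, step: float) -> np.ndarray:
    """Resample the closed polyline so no segment exceeds ``step``."""
    p, q = ring[:-1], ring[1:]
    seg = np.hypot(q[:, 0] - p[:, 0], q[:, 1] - p[:, 1])
    n = np.maximum(1, np.ceil(seg / step).astype(int))
    reps = np.repeat(np.arange(len(p)), n)
    # fractional position along each segment: 1/n, 2/n, ..., 1
    idx_in_seg = np.arange(len(reps)) - np.repeat(np.cumsum(n) - n, n)
    t = ((idx_in_seg + 1) / n[reps])[:, None]
    return np.vstack([ring[:1], p[reps] * (1 - t) + q[reps] * t])


def fractal_dimension(
    polygon,
    k_min: int = 2,
    k_max: int = 7,
    n_jitter: int = 4,
    rng_seed: int = 0,
) -> float:
    """Box-counting dimension of the polygon boundary.

    Boxes on a geometric ladder s_k = L / 2^k, k = k_min..k_max (default six
    scales spanning 1.5 decades relative to the bounding-box side L).  Counts
    from one grid-aligned and ``n_jitter - 1`` jittered grid origins are
    averaged in log to damp grid-phase bias; the dimension is the
    least-squares slope of log N(s) vs log(1/s).  Boxes are half-open, so
    points on the far bounding edge are nudged inward rather than opening a
    spurious box.
    """
    ring = _ring(polygon)
    if ring.shape[0] - 1 < 8:
        raise GeometryError("fractal dimension needs a boundary with >= 8 vertices")
    lo = ring.min(axis=0)
    span = ring.max(axis=0) - lo
    L = float(span.max())
    if L <= 0:
        raise GeometryError("degenerate boundary: zero extent")
    scales = L / (2.0 ** np.arange(k_min, k_max + 1))
    if len(scales) < 3:
        raise GeometryError("fewer than 3 valid box-counting scales")
    pts = _densify(ring, step=scales[-1] / 2.0) - lo
    pts = np.minimum(pts, np.maximum(span - 1e-9 * L, 0.0))
    rng = np.random.default_rng(rng_seed)
    log_n = np.empty(len(scales))
    for i, s in enumerate(scales):
        n_boxes = int(np.ceil(L / s)) + 2  # row stride for the composite key
        offs = np.vstack([np.zeros(2), rng.uniform(0.0, s, size=(n_jitter - 1, 2))])
        idx = np.floor((pts[None, :, :] + offs[:, None, :]) / s)
        key = idx[:, :, 0] * n_boxes + idx[:, :, 1]
        key.sort(axis=1)
        counts = 1 + np.count_nonzero(np.diff(key, axis=1), axis=1)
        log_n[i] = np.mean(np.log(counts))
    slope, _ = np.polyfit(np.log(1.0 / scales), log_n, 1)
    return float(slope)


def cell_descriptors(cell: CellInstance, with_fractal: bool = True) -> dict[str, float]:
    """Shape descriptors for one cell.

    Fractal dimension is only computed where the aggregate plan uses it
    (neoplastic nuclei) unless requested explicitly.
    """
    area, _, _ = polygon_moments(cell.polygon)
    a, b = _ellipse_axes(cell.polygon)
    out = {
        "eccentricity": math.sqrt(max(0.0, 1.0 - (b / a) ** 2)),
        "major_axis_length": 2.0 * a,
        "area": area,
    }
    if with_fractal:
        out["fractal_dimension"] = fractal_dimension(cell.polygon)
    return out


_STAT_FUNCS = {
    "min": np.min,
    "mean": np.mean,
    "max": np.max,
    "sd": lambda v: float(np.std(v, ddof=0)),
}


def aggregate_morphology(
    cells: Sequence[CellInstance],
    descriptors: Mapping[str, Mapping[str, float]] | None = None,
) -> dict[str, float]:
    """Slide/ROI-level morphometry aggregates over typed cells.

    Returns every catalog morphometry feature; a feature whose cell type is
    absent gets NaN (explicit missing), never 0.  ``descriptors`` may carry
    precomputed per-cell descriptors (keyed by cell_id) so gated and
    whole-slide aggregation share one computation.
    """
    out: dict[str, float] = {name: float("nan") for name in MORPHOMETRY_FEATURES}
    by_type: dict[str, list[CellInstance]] = {}
    for c in cells:
        by_type.setdefault(c.cell_type.value, []).append(c)
    for ctype, plan in _AGGREGATE_PLAN.items():
        members = by_type.get(ctype, [])
        if not members:
            continue
        needs_fractal = "fractal_dimension" in plan
        descs = []
        for c in members:
            if descriptors is not None and c.cell_id in descriptors:
                descs.append(descriptors[c.cell_id])
            else:
                descs.append(cell_descriptors(c, with_fractal=needs_fractal))
        for desc_name, stats in plan.items():
            vals = np.array([d[desc_name] for d in descs], dtype=float)
            for stat in stats:
                out[f"{stat}_{desc_name}_{ctype}"] = float(_STAT_FUNCS[stat](vals))
    return out
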