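"""Graph-based cell–cell proximity features.

A radius graph (edge iff centroid distance <= bandwidth, default 112 px — the
midpoint of the 100–128 px bandwidth range) supports per-cell neighborhood
composition profiles: type counts, fractions and Simpson diversity over the
*closed* neighborhood (the cell plus its graph neighbors, so denominators are
never empty).  Slide-level summaries cover the interaction of neoplastic
cells with connective, inflammatory and macrophage partners, and immune
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import CellInstance, CellType, FeatureTable, ValidationError

__all__ = [
    "SpatialGraph",
    "NeighborhoodProfile",
    "build_radius_graph",
    "neighborhood_profile",
    "proximity_features",
    "assemble_feature_table",
    "NEIGHBORHOOD_FEATURES",
    "DEFAULT_BANDWIDTH",
]

DEFAULT_BANDWIDTH = 112.0

_TYPES = [t.value for t in CellType]  # fixed 5-type order
_TYPE_INDEX = {t: i for i, t in enumerate(_TYPES)}

_PARTNERS = ("connective", "inflammatory", "macrophage")

NEIGHBORHOOD_FEATURES: list[str] = (
    [
        f"{stat}_{kind}_{p}_near_neoplastic"
        for p in _PARTNERS
        for kind in ("count", "fraction")
        for stat in ("mean", "sd")
    ]
    + [
        "mean_simpson_neoplastic",
        "sd_simpson_neoplastic",
        "mean_degree_neoplastic",
        "sd_degree_neoplastic",
    ]
    + [
        "mean_count_inflammatory_near_inflammatory",
        "sd_count_inflammatory_near_inflammatory",
        "mean_fraction_inflammatory_near_inflammatory",
        "sd_fraction_inflammatory_near_inflammatory",
        "majority_inflammatory_fraction",
        "mean_simpson_inflammatory",
        "sd_simpson_inflammatory",
        "mean_degree_inflammatory",
        "sd_degree_inflammatory",
    ]
)


@dataclass
class SpatialGraph:
    """Undirected radius graph over cell centroids."""

    cell_ids: list[str]
    centroids: np.ndarray  # (n, 2)
    types: np.ndarray  # (n,) int index into the 5-type order
    neighbors: list[np.ndarray]  # adjacency lists (no self)
    bandwidth: float

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def degree(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])


@dataclass(frozen=True)
class NeighborhoodProfile:
    cell_id: str
    counts: np.ndarray  # per 5 types, closed neighborhood
    fractions: np.ndarray
    simpson: float


def build_radius_graph(
    cells: Sequence[CellInstance], bandwidth: float = DEFAULT_BANDWIDTH
) -> SpatialGraph:
    """Radius graph via a k-d tree (no all-pairs scan)."""
    if bandwidth <= 0:
        raise ValidationError(f"bandwidth must be positive, got {bandwidth}")
    n = len(cells)
    centroids = np.array([c.centroid for c in cells], dtype=float).reshape(n, 2)
    types = np.array([_TYPE_INDEX[c.cell_type.value] for c in cells], dtype=int)
    neighbors: list[list[int]] = [[] for _ in range(n)]
    if n > 1:
        tree = cKDTree(centroids)
        for i, j in tree.query_pairs(bandwidth):
            neighbors[i].append(j)
            neighbors[j].append(i)
    return SpatialGraph(
        cell_ids=[c.cell_id for c in cells],
        centroids=centroids,
        types=types,
        neighbors=[np.array(sorted(nb), dtype=int) for nb in neighbors],
        bandwidth=bandwidth,
    )


def _closed_counts(graph: SpatialGraph) -> np.ndarray:
    """(n, 5) type counts over each cell's closed neighborhood."""
    n = graph.n_cells
    onehot = np.zeros((n, len(_TYPES)))
    onehot[np.arange(n), graph.types] = 1.0
    counts = onehot.copy()
    for i, nb in enumerate(graph.neighbors):
        if len(nb):
            counts[i] += onehot[nb].sum(axis=0)
    return counts


def _simpson(fractions: np.ndarray) -> np.ndarray:
    return 1.0 - np.sum(fractions**2, axis=-1)


def neighborhood_profile(graph: SpatialGraph, cell_id: str) -> NeighborhoodProfile:
    """Composition of one cell's closed neighborhood."""
    try:
        i = graph.cell_ids.index(cell_id)
    except ValueError:
        raise KeyError(f"unknown cell_id {cell_id!r}") from None
    counts = _closed_counts(graph)[i]
    fractions = counts / counts.sum()
    return NeighborhoodProfile(
        cell_id=cell_id,
        counts=counts,
        fractions=fractions,
        simpson=float(_simpson(fractions)),
    )


def proximity_features(
    cells: Sequence[CellInstance],
    bandwidth: float = DEFAULT_BANDWIDTH,
    graph: SpatialGraph | None = None,
) -> dict[str, float]:
    """Slide-level proximity/diversity summaries.

    Anchored on neoplastic cells (partner counts/fractions, Simpson, degree)
    and on inflammatory cells (immune clustering: inflammatory–inflammatory
    counts/fractions, fraction of inflammatory cells whose neighborhood
    plurality type is inflammatory).  Features are NaN when the anchor type
    is absent.
    """
    out = {name: float("nan") for name in NEIGHBORHOOD_FEATURES}
    if not cells:
        return out
    g = graph if graph is not None else build_radius_graph(cells, bandwidth)
    counts = _closed_counts(g)
    fractions = counts / counts.sum(axis=1, keepdims=True)
    simpson = _simpson(fractions)
    degree = g.degree().astype(float)

    def _stats(prefix: str, vals: np.ndarray):
        out[f"mean_{prefix}"] = float(np.mean(vals))
        out[f"sd_{prefix}"] = float(np.std(vals, ddof=0))

    neo = g.types == _TYPE_INDEX["neoplastic"]
    if neo.any():
        for p in _PARTNERS:
            pi = _TYPE_INDEX[p]
            _stats(f"count_{p}_near_neoplastic", counts[neo, pi])
            _stats(f"fraction_{p}_near_neoplastic", fractions[neo, pi])
        _stats("simpson_neoplastic", simpson[neo])
        _stats("degree_neoplastic", degree[neo])

    inf = g.types == _TYPE_INDEX["inflammatory"]
    if inf.any():
        ii = _TYPE_INDEX["inflammatory"]
        # closed neighborhood includes the anchor; report neighbors only
        _stats("count_inflammatory_near_inflammatory", counts[inf, ii] - 1.0)
        _stats("fraction_inflammatory_near_inflammatory", fractions[inf, ii])
        others = np.delete(counts[inf], ii, axis=1)
        plurality = counts[inf, ii] > others.max(axis=1)
        out["majority_inflammatory_fraction"] = float(np.mean(plurality))
        _stats("simpson_inflammatory", simpson[inf])
        _stats("degree_inflammatory", degree[inf])
    return out


def assemble_feature_table(
    per_slide: Mapping[str, Mapping[str, float]],
    provenance: str,
    catalog: Sequence[str] | None = None,
) -> FeatureTable:
    """One row per slide over the fixed 69-name catalog, in catalog order.

    Raises an assembly error when a slide carries a feature outside the
    catalog or misses a catalog entry.
    """
    from .catalog import feature_catalog

    names = list(catalog) if catalog is not None else feature_catalog()
    rows = {}
    for slide_id, feats in per_slide.items():
        extra = set(feats) - set(names)
        missing = set(names) - set(feats)
        if extra or missing:
            raise ValidationError(
                f"slide {slide_id}: features outside catalog {sorted(extra)}; "
                f"missing catalog entries {sorted(missing)}"
            )
        rows[str(slide_id)] = [feats[n] for n in names]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    df.index.name = "slide_id"
    return FeatureTable(values=df, provenance=provenance)
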