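"""Radius graph, neighborhood composition, Simpson diversity, catalog."""

import math

import numpy as np
import pytest

from histogate.catalog import N_FEATURES, catalog_table, feature_catalog
from histogate.io import CellInstance, CellType, ValidationError
from histogate.neighborhood import (
    NEIGHBORHOOD_FEATURES,
    assemble_feature_table,
    build_radius_graph,
    neighborhood_profile,
    proximity_features,
)


def _cell(cid, x, y, ctype=CellType.NEOPLASTIC):
    ring = np.array(
        [[x - 3, y - 3], [x + 3, y - 3], [x + 3, y + 3], [x - 3, y + 3], [x - 3, y - 3]],
        float,
    )
    return CellInstance(cid, ring, ctype)


def test_edges_respect_bandwidth():
    g = build_radius_graph([_cell("a", 0, 0), _cell("b", 50, 0)], 112.0)
    assert len(g.neighbors[0]) == 1
    g = build_radius_graph([_cell("a", 0, 0), _cell("b", 200, 0)], 112.0)
    assert len(g.neighbors[0]) == 0


def test_graph_equals_brute_force():
    """k-d-tree edge set equals the all-pairs oracle on 500 random cells."""
    rng = np.random.default_rng(4)
    pts = rng.uniform(0, 1000, size=(500, 2))
    cells = [_cell(f"c{i}", *pts[i]) for i in range(500)]
    bw = 112.0
    g = build_radius_graph(cells, bw)
    centroids = np.array([c.centroid for c in cells])
    d2 = ((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
    brute = {
        (i, j)
        for i in range(500)
        for j in range(i + 1, 500)
        if d2[i, j] <= bw * bw
    }
    ours = {(min(i, j), max(i, j)) for i in range(500) for j in g.neighbors[i]}
    assert ours == brute


def test_bandwidth_monotonicity():
    rng = np.random.default_rng(9)
    cells = [_cell(f"c{i}", *rng.uniform(0, 400, 2)) for i in range(80)]
    prev = None
    for bw in (50, 100, 128, 250):
        deg = build_radius_graph(cells, bw).degree()
        if prev is not None:
            assert np.all(deg >= prev)
        prev = deg


@pytest.mark.parametrize(
    "counts,expected",
    [
        ((4, 0, 0), 0.0),
        ((3, 3, 0), 0.5),
        ((2, 3, 5), 0.62),
    ],
)
def test_simpson_closed_form(counts, expected):
    """Simpson = 1 - sum p_i^2 on enumerated count vectors."""
    cells = []
    types = [CellType.NEOPLASTIC, CellType.CONNECTIVE, CellType.INFLAMMATORY]
    k = 0
    for n, t in zip(counts, types):
        for _ in range(n):
            cells.append(_cell(f"c{k}", 10 * k, 0, t))
            k += 1
    g = build_radius_graph(cells, bandwidth=10_000.0)  # complete graph
    prof = neighborhood_profile(g, "c0")
    assert prof.simpson == pytest.approx(expected, abs=1e-9)


def test_simpson_bounded_for_five_types():
    assert all(0 <= 1 - sum(p * p for p in f) <= 1 - 1 / 5 for f in [[0.2] * 5])


def test_profile_closed_neighborhood_fraction():
    """Anchor + 4 neighbors, 2 connective -> connective fraction 2/5."""
    cells = [_cell("anchor", 0, 0)]
    cells += [_cell(f"n{i}", 20 + 10 * i, 0, CellType.CONNECTIVE) for i in range(2)]
    cells += [_cell(f"m{i}", -20 - 10 * i, 0, CellType.NEOPLASTIC) for i in range(2)]
    g = build_radius_graph(cells, 112.0)
    prof = neighborhood_profile(g, "anchor")
    assert prof.counts.sum() == 5
    out = proximity_features(cells, 112.0)
    assert out["mean_fraction_connective_near_neoplastic"] <= 0.4 + 1e-9
    with pytest.raises(KeyError):
        neighborhood_profile(g, "ghost")


def test_missing_when_anchor_absent():
    cells = [_cell("a", 0, 0, CellType.CONNECTIVE)]
    out = proximity_features(cells, 112.0)
    assert math.isnan(out["mean_simpson_neoplastic"])
    assert math.isnan(out["majority_inflammatory_fraction"])


def test_clustered_inflammatory_raises_majority_fraction():
    """Planted immune clusters push the plurality-inflammatory fraction up."""
    rng = np.random.default_rng(2)
    scatter = [
        _cell(f"s{i}", *rng.uniform(0, 2000, 2), CellType.INFLAMMATORY) for i in range(12)
    ] + [_cell(f"b{i}", *rng.uniform(0, 2000, 2), CellType.CONNECTIVE) for i in range(60)]
    clustered = [
        _cell(f"s{i}", 500 + 15 * i, 500, CellType.INFLAMMATORY) for i in range(12)
    ] + [_cell(f"b{i}", *rng.uniform(0, 2000, 2), CellType.CONNECTIVE) for i in range(60)]
    lo = proximity_features(scatter, 112.0)["majority_inflammatory_fraction"]
    hi = proximity_features(clustered, 112.0)["majority_inflammatory_fraction"]
    assert hi > lo


class TestCatalog:
    def test_catalog_is_69_and_closed(self):
        names = feature_catalog()
        assert len(names) == N_FEATURES == 69
        assert len(set(names)) == 69
        assert set(NEIGHBORHOOD_FEATURES) <= set(names)
        tbl = catalog_table()
        assert list(tbl.columns) == ["name", "family", "units", "aggregation", "module"]

    def test_assemble_matches_catalog_order(self):
        names = feature_catalog()
        row = {n: 1.0 for n in names}
        table = assemble_feature_table({"s1": row, "s2": row}, "attended")
        assert table.feature_names == names
        assert table.values.shape == (2, 69)

    def test_assemble_rejects_unknown_or_missing(self):
        names = feature_catalog()
        row = {n: 1.0 for n in names}
        bad = dict(row)
        bad["mystery_feature"] = 1.0
        with pytest.raises(ValidationError, match="mystery_feature"):
            assemble_feature_table({"s": bad}, "attended")
        short = dict(row)
        short.pop(names[0])
        with pytest.raises(ValidationError):
            assemble_feature_table({"s": short}, "attended")


from hypothesis import given, settings
from hypothesis import strategies as st


@given(st.lists(st.integers(min_value=0, max_value=6), min_size=5, max_size=5).filter(lambda c: sum(c) > 0))
@settings(max_examples=40, deadline=None)
def test_simpson_profile_matches_closed_form(counts):
    """Profile Simpson equals 1 - sum p^2 of the composition; it lies in
    [0, 0.8] for 5 types and is 0 iff the neighborhood is monotypic."""
    cells, k = [], 0
    for n, t in zip(counts, CellType):
        for _ in range(n):
            cells.append(_cell(f"c{k}", 10 * k, 0, t))
            k += 1
    g = build_radius_graph(cells, bandwidth=10_000.0)  # complete graph
    simpson = neighborhood_profile(g, cells[0].cell_id).simpson
    total = sum(counts)
    expected = 1.0 - sum((n / total) ** 2 for n in counts)
    assert simpson == pytest.approx(expected, abs=1e-12)
    assert -1e-12 <= simpson <= 1 - 1 / 5 + 1e-12
    assert (simpson < 1e-12) == (max(counts) == total)
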