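"""Shared fixtures: small geometric shapes and synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from histogate import CohortConfig, PipelineConfig
from histogate.pipeline import (
    _filter_labelled,
    cohort_feature_tables,
    load_cohort,
)


def ellipse_ring(a: float, b: float, n: int = 64, theta: float = 0.0) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    ct, st = np.cos(theta), np.sin(theta)
    ring = np.c_[ct * x - st * y, st * x + ct * y]
    return np.vstack([ring, ring[:1]])


def koch_polyline(depth: int = 5, length: float = 729.0) -> np.ndarray:
    """Koch curve as a closed thin polygon (the flat return edge is 1 px below)."""

    def rec(p, q, d):
        p, q = np.asarray(p, float), np.asarray(q, float)
        if d == 0:
            return [p]
        dd = (q - p) / 3.0
        a, b = p + dd, p + 2 * dd
        rot = np.array([[0.5, -np.sqrt(3) / 2], [np.sqrt(3) / 2, 0.5]])
        c = a + rot @ dd
        out = []
        for s, e in [(p, a), (a, c), (c, b), (b, q)]:
            out += rec(s, e, d - 1)
        return out

    pts = np.array(rec([0.0, 0.0], [length, 0.0], depth) + [[length, 0.0]])
    return np.vstack([pts, [[length, -1.0], [0.0, -1.0], [0.0, 0.0]]])


def straight_segment_ring(length: float = 100.0, n: int = 300) -> np.ndarray:
    seg = np.c_[np.linspace(0.0, length, n), np.zeros(n)]
    return np.vstack([seg, seg[::-1][1:]])


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small attended-signal cohort: 6 patients/class x 2 slides."""
    cfg = PipelineConfig(
        synthetic=CohortConfig(seed=7, n_patients_per_class=6),
        seed=42,
    )
    slides, records = load_cohort(cfg)
    tables, fractions = cohort_feature_tables(slides, cfg)
    tables, records = _filter_labelled(tables, records)
    return {
        "config": cfg,
        "slides": slides,
        "records": records,
        "tables": tables,
        "fractions": fractions,
    }
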