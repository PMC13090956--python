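"""Synthetic cohorts with known planted class effects.

Each synthetic slide emulates the geometry a panoptic-segmentation +
attention pipeline would hand downstream: a contiguous high-attention block
(~10% of patches, matching the reported high-attention share), tissue
regions (epithelial tumor, a tumor–stroma interface band, distal stroma,
necrosis, ...) and typed nuclei drawn as perturbed ellipses.  Class effects
(short vs long progression-free interval) are planted in the seven headline
features — tumor-cell eccentricity/major axis/fractal dimension, stromal
cell count and proportion, total and distal stromal area — and, by default,
only inside the attended region, so whole-slide features dilute the signal.
Everything is a pure function of the config (seed included).

Cell boundary roughness is radial Fourier noise over harmonics 6..48 with a
mild spectral decay; its amplitude maps monotonically to box-counting
fractal dimension through a calibration table measured once with the
package's own estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    AttentionMap,
    CellInstance,
    CellType,
    SlideRecord,
    TissueRegion,
    TissueType,
    ValidationError,
    write_attention_table,
    write_clinical_table,
    write_panoptic_geojson,
)

__all__ = [
    "EffectSpec",
    "CohortConfig",
    "SlideBundle",
    "CohortBundle",
    "GenerationError",
    "default_effects",
    "generate_slide",
    "generate_cohort",
    "write_cohort",
    "planted_truth",
]


class GenerationError(RuntimeError):
    """Requested geometry cannot be realized (e.g. cell density too high)."""


@dataclass(frozen=True)
class EffectSpec:
    """Class-conditional generative target for one catalog feature."""

    feature_name: str
    short_mean: float
    long_mean: float
    noise_sd: float

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def standardized_effect(self) -> float:
        return abs(self.long_mean - self.short_mean) / self.noise_sd if self.noise_sd else float("inf")


# Planted features and their class-conditional targets.  Per-feature
# standardized effects are ~1 so that no single feature separates the classes
# alone but the seven jointly do; all effects point "higher in long PFI".
# proportion_connective_cells and total_stromal_area are induced by the
# primary draws (stromal cell count / distal area + the class-independent
# interface band); their specs record the implied targets.
def default_effects() -> list[EffectSpec]:
    return [
        EffectSpec("max_eccentricity_neoplastic", 0.78, 0.865, 0.058),
        EffectSpec("max_major_axis_length_neoplastic", 48.0, 57.5, 6.0),
        EffectSpec("mean_fractal_dimension_neoplastic", 1.12, 1.20, 0.05),
        EffectSpec("n_connective_cells", 38.0, 56.0, 11.5),
        EffectSpec("proportion_connective_cells", 0.42, 0.52, 0.095),
        EffectSpec("total_stromal_area", 2.10e5, 2.75e5, 4.8e4),
        EffectSpec("distal_stromal_area", 1.45e5, 2.10e5, 3.2e4),
    ]


_PRIMARY_EFFECTS = {
    "max_eccentricity_neoplastic",
    "max_major_axis_length_neoplastic",
    "mean_fractal_dimension_neoplastic",
    "n_connective_cells",
    "distal_stromal_area",
}
_INDUCED_EFFECTS = {"proportion_connective_cells", "total_stromal_area"}


@dataclass
class CohortConfig:
    n_patients_per_class: int = 25
    slides_per_patient: int = 2
    slide_extent: int = 4000
    patch_size: int = 100
    attended_target_fraction: float = 0.10
    effects: list[EffectSpec] = field(default_factory=default_effects)
    n_nuisance_features: int | None = None  # informational: unplanted catalog features
    signal_scope: str = "attended"  # or "slide_wide" (control cohorts)
    censoring_rate: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.attended_target_fraction <= 1:
            raise ValidationError("attended_target_fraction must lie in (0, 1]")
        if self.signal_scope not in ("attended", "slide_wide"):
            raise ValidationError(f"unknown signal_scope {self.signal_scope!r}")
        known = _PRIMARY_EFFECTS | _INDUCED_EFFECTS
        for e in self.effects:
            if e.feature_name not in known:
                raise ValidationError(
                    f"no generative mechanism for effect feature {e.feature_name!r}"
                )

    def effect(self, name: str) -> EffectSpec:
        for e in self.effects:
            if e.feature_name == name:
                return e
        raise KeyError(name)


@dataclass
class SlideBundle:
    slide_id: str
    cells: list[CellInstance]
    regions: list[TissueRegion]
    attention: AttentionMap
    record: SlideRecord


@dataclass
class CohortBundle:
    slides: list[SlideBundle]
    records: list[SlideRecord]
    manifest: dict


# ---------------------------------------------------------------------------
# Roughness -> box-counting dimension calibration (measured once with
# morphometry.fractal_dimension on 96-vertex perturbed ellipses).

_FD_CAL_AMP = np.array([0.0, 0.005, 0.01, 0.02, 0.03, 0.05, 0.08, 0.12, 0.16])
_FD_CAL_FD = np.array([0.9885, 1.0082, 1.050, 1.129, 1.179, 1.255, 1.336, 1.391, 1.407])

# Per-cell mixture endpoints for planting a slide-mean fractal dimension:
# smooth baseline nuclei vs rough nuclei.
_FD_BASE, _FD_ROUGH = 1.08, 1.26


def _amp_for_fd(fd: float) -> float:
    return float(np.interp(fd, _FD_CAL_FD, _FD_CAL_AMP))


_ROUGH_KS = np.arange(6, 49)
_ROUGH_SIG = (_ROUGH_KS / _ROUGH_KS[0]) ** -0.3


def _cell_ring(
    rng: np.random.Generator,
    center: np.ndarray,
    major_axis: float,
    ecc: float,
    amp: float,
    n_vert: int,
) -> np.ndarray:
    a = major_axis / 2.0
    b = a * np.sqrt(max(1e-6, 1.0 - ecc**2))
    phi = np.linspace(0.0, 2.0 * np.pi, n_vert, endpoint=False)
    r = np.ones(n_vert)
    if amp > 0:
        sig = amp * _ROUGH_SIG
        cc = rng.normal(0.0, sig)
        ss = rng.normal(0.0, sig)
        r = r + np.cos(np.outer(phi, _ROUGH_KS)) @ cc + np.sin(np.outer(phi, _ROUGH_KS)) @ ss
        r = np.clip(r, 0.15, None)
    theta = rng.uniform(0.0, np.pi)
    x, y = a * r * np.cos(phi), b * r * np.sin(phi)
    ct, st = np.cos(theta), np.sin(theta)
    ring = np.c_[ct * x - st * y, st * x + ct * y] + center
    return np.vstack([ring, ring[:1]])


_TYPE_GEOM = {
    # (axis_lo, axis_hi, ecc_lo, ecc_hi, amp, n_vert)
    CellType.CONNECTIVE: (10.0, 22.0, 0.75, 0.90, 0.01, 32),
    CellType.INFLAMMATORY: (7.0, 11.0, 0.20, 0.45, 0.01, 32),
    CellType.MACROPHAGE: (12.0, 18.0, 0.40, 0.60, 0.02, 32),
    CellType.DEAD: (6.0, 10.0, 0.30, 0.70, 0.04, 32),
}

# px^2 bounding-box budget per nucleus for the density sanity check
_CELL_FOOTPRINT = {"neoplastic": 1100.0, "default": 420.0}


def _check_capacity(n: int, area: float, what: str, kind: str = "default") -> None:
    if n * _CELL_FOOTPRINT.get(kind, 420.0) > 0.85 * area:
        raise GenerationError(
            f"{what}: {n} cells exceed region capacity ({area:.0f} px^2); "
            "reduce the density or enlarge the region"
        )


def _scatter(rng, n, x0, y0, w, h, margin=14.0):
    xs = rng.uniform(x0 + margin, x0 + max(w - margin, margin), n)
    ys = rng.uniform(y0 + margin, y0 + max(h - margin, margin), n)
    return np.c_[xs, ys]


def _simple_cells(rng, ctype: CellType, positions: np.ndarray, id_prefix: str) -> list[CellInstance]:
    lo, hi, elo, ehi, amp, nv = _TYPE_GEOM[ctype]
    out = []
    for i, pos in enumerate(positions):
        ring = _cell_ring(
            rng, pos, rng.uniform(lo, hi), rng.uniform(elo, ehi), amp, nv
        )
        out.append(CellInstance(cell_id=f"{id_prefix}_{i}", polygon=ring, cell_type=ctype))
    return out


def _neoplastic_cells(
    rng,
    positions: np.ndarray,
    ecc_max: float,
    axis_max: float,
    fd_target: float,
    id_prefix: str,
) -> list[CellInstance]:
    """Tumor nuclei: bulk draws plus one cell forced to each planted maximum.

    The bulk-draw upper bounds vary per slide (class-independently), so the
    forced maxima dominate the max aggregates without tying the mean/sd
    aggregates to the class.  Per-cell fractal dimension is a two-point
    mixture (smooth vs rough, endpoints jittered per slide) whose mixing
    fraction realizes the slide-level mean target.
    """
    n = len(positions)
    eccs = rng.uniform(0.30, rng.uniform(0.55, 0.72), n)
    axes = rng.uniform(18.0, rng.uniform(30.0, 44.0), n)
    if n:
        eccs[0] = min(ecc_max, 0.97)
        j = min(1, n - 1)
        axes[j] = axis_max
        # keep the longest cell's area in the bulk range so the area
        # aggregates stay uninformative about the class
        target_ab = rng.uniform(1400.0, 2000.0)  # (axis/2)*(minor/2) * 4
        ratio = min(target_ab / axis_max**2, 0.9)
        eccs[j] = float(np.clip(np.sqrt(1.0 - ratio**2), 0.30, max(ecc_max - 0.03, 0.35)))
    fd_base = _FD_BASE + rng.normal(0.0, 0.03)
    fd_rough = _FD_ROUGH + rng.normal(0.0, 0.045)
    p_rough = np.clip((fd_target - fd_base) / max(fd_rough - fd_base, 0.05), 0.02, 0.95)
    rough = rng.random(n) < p_rough
    fds = np.where(rough, fd_rough, fd_base) + rng.normal(0.0, 0.015, n)
    out = []
    for i, pos in enumerate(positions):
        ring = _cell_ring(rng, pos, axes[i], eccs[i], _amp_for_fd(fds[i]), 96)
        out.append(
            CellInstance(cell_id=f"{id_prefix}_{i}", polygon=ring, cell_type=CellType.NEOPLASTIC)
        )
    return out


# ---------------------------------------------------------------------------
# Slide generation


# split of the per-slide noise_sd into patient-level and slide-level parts
# (0.87^2 + 0.5^2 = 1): most heterogeneity sits between patients, and slides
# of one patient stay similar
_PATIENT_SD, _SLIDE_SD = 0.87, 0.5


def _patient_targets(class_label: str, config: CohortConfig, rng) -> dict[str, float]:
    """Patient-level draws of the planted targets (shared by the patient's slides)."""
    t = {}
    for name in sorted(_PRIMARY_EFFECTS):
        e = config.effect(name)
        mean = e.long_mean if class_label == "long" else e.short_mean
        t[name] = rng.normal(mean, _PATIENT_SD * e.noise_sd)
    return t


def _cohort_patient_targets(
    class_label: str, config: CohortConfig, rng, n_patients: int
) -> list[dict[str, float]]:
    """Patient targets for a whole class arm, with class-standardized z-draws.

    The z-scores behind the patient-level effects are standardized within the
    arm (mean 0, sd 1), so the realized cohort effect matches the configured
    class-conditional means instead of fluctuating with the draw — the
    cohort-level analogue of stratified sampling.
    """
    names = sorted(_PRIMARY_EFFECTS)
    z = rng.normal(size=(n_patients, len(names)))
    if n_patients > 1:
        z = (z - z.mean(axis=0)) / np.where(z.std(axis=0) > 0, z.std(axis=0), 1.0)
    out = []
    for i in range(n_patients):
        t = {}
        for j, name in enumerate(names):
            e = config.effect(name)
            mean = e.long_mean if class_label == "long" else e.short_mean
            t[name] = mean + _PATIENT_SD * e.noise_sd * z[i, j]
        out.append(t)
    return out


def _slide_targets(patient_targets: dict[str, float], config: CohortConfig, rng) -> dict[str, float]:
    t = {}
    for name, val in patient_targets.items():
        sd = config.effect(name).noise_sd
        t[name] = val + rng.normal(0.0, _SLIDE_SD * sd)
    t["max_eccentricity_neoplastic"] = float(np.clip(t["max_eccentricity_neoplastic"], 0.70, 0.945))
    t["max_major_axis_length_neoplastic"] = float(
        np.clip(t["max_major_axis_length_neoplastic"], 40.0, 76.0)
    )
    t["mean_fractal_dimension_neoplastic"] = float(
        np.clip(t["mean_fractal_dimension_neoplastic"], 1.05, 1.30)
    )
    t["n_connective_cells"] = float(np.clip(t["n_connective_cells"], 8.0, 90.0))
    t["distal_stromal_area"] = float(np.clip(t["distal_stromal_area"], 3.0e4, 3.1e5))
    return t


def _survival(class_label: str, config: CohortConfig, rng) -> tuple[int, int, bool, bool]:
    """Class-consistent Weibull PFI (short < 180 d, long > 365 d) and OS."""
    shape = 1.6
    if class_label == "short":
        scale, lo, hi = 110.0, 0.0, 179.0
    else:
        scale, lo, hi = 700.0, 366.0, 3000.0
    for _ in range(1000):
        pfi = scale * rng.weibull(shape)
        if lo <= pfi <= hi:
            break
    else:  # pragma: no cover - vanishingly unlikely
        pfi = (lo + min(hi, scale)) / 2.0
    os_days = pfi + 500.0 * rng.weibull(1.5)
    pfi_event = rng.random() >= config.censoring_rate
    os_event = rng.random() < 0.6
    return int(round(pfi)), int(round(os_days)), bool(pfi_event), bool(os_event)


def generate_slide(
    class_label: str,
    config: CohortConfig,
    slide_seed,
    patient_targets: dict[str, float] | None = None,
    slide_id: str = "slide",
    patient_id: str = "patient",
    clinical: tuple[int, int, bool, bool] | None = None,
) -> tuple[list[CellInstance], list[TissueRegion], AttentionMap, SlideRecord]:
    """Generate one synthetic slide.

    ``slide_seed`` may be an int or a sequence of ints (seed path).  When
    ``patient_targets`` is omitted they are drawn here, so a standalone call
    is still a pure function of (class_label, config, slide_seed).
    """
    if class_label not in ("short", "long"):
        raise ValidationError(f"class_label must be short/long, got {class_label!r}")
    rng = np.random.default_rng(np.random.SeedSequence(slide_seed))
    if patient_targets is None:
        patient_targets = _patient_targets(class_label, config, rng)
    t = _slide_targets(patient_targets, config, rng)

    ps = config.patch_size
    n_grid = config.slide_extent // ps
    if n_grid < 20:
        raise GenerationError("slide_extent must cover at least a 20x20 patch grid")

    # --- attention grid: contiguous attended block + scattered missing patches
    n_missing = max(1, int(round(0.02 * n_grid * n_grid)))
    n_present = n_grid * n_grid - n_missing
    n_att = int(round(config.attended_target_fraction * n_present))
    block_w = int(np.ceil(np.sqrt(n_att)))
    block_h = int(np.ceil(n_att / block_w))
    col0 = int(rng.integers(0, n_grid - block_w + 1))
    row0 = int(rng.integers(0, n_grid - block_h + 1))
    attended = [
        (col0 + (i % block_w), row0 + (i // block_w)) for i in range(n_att)
    ]
    att_set = set(attended)
    scores = rng.uniform(0.0, 0.15, size=(n_grid, n_grid))
    for c, r in attended:
        scores[r, c] = rng.uniform(0.5, 1.0)
    non_att = [(c, r) for r in range(n_grid) for c in range(n_grid) if (c, r) not in att_set]
    miss_idx = rng.choice(len(non_att), size=n_missing, replace=False)
    for k in miss_idx:
        c, r = non_att[k]
        scores[r, c] = np.nan
    amap = AttentionMap(slide_id=slide_id, patch_size=ps, origin=(0.0, 0.0), scores=scores)

    # --- attended geometry inside the full-rows part of the block
    bx, by = col0 * ps, row0 * ps
    s = rng.uniform(0.9, 1.1)  # tumor size jitter
    tw, th = 500.0 * s, 400.0 * s
    regions: list[TissueRegion] = []
    cells: list[CellInstance] = []

    def rect(x0, y0, w, h):
        from shapely.geometry import box as _box

        return _box(x0, y0, x0 + w, y0 + h)

    tx = 110.0  # tumor x-offset inside the block leaves room for a left band
    tumor_att = rect(bx + tx, by + 10, tw, th)
    regions.append(TissueRegion("att_tumor", tumor_att, TissueType.EPITHELIAL_TUMOR))

    # U-shaped interface band along the tumor's left, right and bottom edges,
    # fully within d=100 of the tumor boundary; its area varies independently
    # of the distal block so total and distal stroma are not near-duplicates
    near_area = float(np.clip(rng.normal(6.5e4, 3.6e4), 1.2e4, 1.25e5))
    shares = rng.dirichlet(np.ones(3) * 6.0)
    band_wl = min(near_area * shares[0] / th, 95.0)
    band_wr = min(near_area * shares[1] / th, 95.0)
    band_left = rect(bx + tx - band_wl, by + 10, band_wl, th)
    band_right = rect(bx + tx + tw, by + 10, band_wr, th)
    bottom_span = band_wl + tw + band_wr
    band_wb = min(near_area * shares[2] / bottom_span, 95.0)
    band_bottom = rect(bx + tx - band_wl, by + 10 + th, bottom_span, band_wb)
    from shapely.ops import unary_union as _uu

    regions.append(
        TissueRegion("att_stroma_band", _uu([band_left, band_right, band_bottom]), TissueType.STROMA)
    )

    # distal stroma block, >= 150 px from tumor (all beyond the interface);
    # it must stay inside the fully attended rows of the block, so overflow
    # goes into width rather than height
    distal_area = t["distal_stromal_area"]
    full_rows_h = (n_att // block_w) * ps
    distal_y = 10 + th + band_wb + 155.0
    avail_h = full_rows_h - distal_y - 10.0
    if avail_h < 80.0:
        raise GenerationError("attended block too small for the distal stroma layout")
    distal_h = min(distal_area / 600.0, avail_h)
    distal_w = min(distal_area / distal_h, block_w * ps - 20.0)
    distal_y = 10 + th + band_wb + 155.0
    distal = rect(bx + 10, by + distal_y, distal_w, distal_h)
    regions.append(TissueRegion("att_stroma_distal", distal, TissueType.STROMA))

    necro_area = float(np.clip(rng.normal(2.4e4, 0.6e4), 1.0e4, 4.0e4))
    necro_side = np.sqrt(necro_area)
    regions.append(
        TissueRegion(
            "att_necrosis",
            rect(bx + 10 + max(tx + tw + 160, distal_w + 40), by + distal_y, necro_side, necro_side),
            TissueType.NECROSIS,
        )
    )

    n_neo = int(np.clip(round(rng.normal(34, 18)), 10, 72))
    _check_capacity(n_neo, tumor_att.area, "attended tumor", "neoplastic")
    cells += _neoplastic_cells(
        rng,
        _scatter(rng, n_neo, bx + tx, by + 10, tw, th, margin=20),
        t["max_eccentricity_neoplastic"],
        t["max_major_axis_length_neoplastic"],
        t["mean_fractal_dimension_neoplastic"],
        "att_neo",
    )
    n_conn = int(round(t["n_connective_cells"]))
    _check_capacity(n_conn, distal.area, "attended distal stroma")
    cells += _simple_cells(
        rng,
        CellType.CONNECTIVE,
        _scatter(rng, n_conn, bx + 10, by + distal_y, distal_w, distal_h),
        "att_conn",
    )
    n_inf = int(np.clip(round(rng.normal(12, 5)), 2, 30))
    inf_pos = _scatter(rng, n_inf, bx + tx, by + 10, tw + band_wr, th)
    if rng.random() < 0.5:  # occasional immune cluster (inside the tumor bed)
        center = _scatter(rng, 1, bx + tx + 50, by + 60, tw - 100, th - 100)[0]
        inf_pos = np.vstack([inf_pos, center + rng.uniform(-40, 40, size=(5, 2))])
    cells += _simple_cells(rng, CellType.INFLAMMATORY, inf_pos, "att_inf")
    n_mac = int(np.clip(round(rng.normal(4, 2)), 0, 12))
    cells += _simple_cells(
        rng, CellType.MACROPHAGE, _scatter(rng, n_mac, bx + tx, by + 10, tw, th), "att_mac"
    )
    n_dead = int(np.clip(round(rng.normal(3, 2)), 0, 10))
    cells += _simple_cells(
        rng, CellType.DEAD, _scatter(rng, n_dead, bx + tx, by + 10, tw, th), "att_dead"
    )

    # --- outside geometry on a site grid avoiding the attended block
    slide_wide = config.signal_scope == "slide_wide"
    site = 800
    n_sites = config.slide_extent // site
    bx1, by1 = bx + block_w * ps, by + block_h * ps
    free = []
    for i in range(n_sites):
        for j in range(n_sites):
            sx, sy = i * site, j * site
            if sx + site <= bx or sx >= bx1 or sy + site <= by or sy >= by1:
                free.append((sx, sy))
    rng.shuffle(free)
    if len(free) < 9:
        raise GenerationError("slide extent too small to place outside tissue sites")

    def take_site():
        return free.pop()

    # outside tumor regions with baseline (class-independent) morphology that
    # masks the attended maxima in whole-slide aggregates
    if slide_wide:
        e_out = t["max_eccentricity_neoplastic"]
        l_out = t["max_major_axis_length_neoplastic"]
        f_out = t["mean_fractal_dimension_neoplastic"]
    else:
        e_out = float(np.clip(rng.normal(0.955, 0.01), 0.935, 0.985))
        l_out = float(rng.normal(80.0, 4.0))
        f_out = float(np.clip(rng.normal(1.145, 0.05), 1.05, 1.30))
    n_tum_out = int(rng.integers(2, 4))
    out_tumors = []
    for k in range(n_tum_out):
        sx, sy = take_site()
        w, h = rng.uniform(450, 700), rng.uniform(400, 650)
        poly = rect(sx + 40, sy + 40, w, h)
        out_tumors.append((sx, sy, w, h))
        regions.append(TissueRegion(f"out_tumor_{k}", poly, TissueType.EPITHELIAL_TUMOR))
    n_neo_out_total = int(np.clip(round(rng.normal(44, 10)), 24, 90))
    areas = np.array([w * h for _, _, w, h in out_tumors])
    shares = areas / areas.sum()
    for k, (sx, sy, w, h) in enumerate(out_tumors):
        nk = int(round(n_neo_out_total * shares[k]))
        _check_capacity(nk, w * h, f"outside tumor {k}", "neoplastic")
        cells += _neoplastic_cells(
            rng, _scatter(rng, nk, sx + 40, sy + 40, w, h, margin=20), e_out, l_out, f_out,
            f"out_neo_{k}",
        )

    # outside stroma: class-independent baseline (or scaled signal in
    # slide_wide control cohorts)
    base_area = float(np.clip(rng.normal(1.1e6, 2.2e5), 5.0e5, 1.7e6))
    if slide_wide:
        e_tot = config.effect("total_stromal_area")
        mid = 0.5 * (e_tot.short_mean + e_tot.long_mean)
        base_area *= (near_area + distal_area) / mid
    n_str_out = int(rng.integers(3, 6))
    shares = rng.dirichlet(np.ones(n_str_out) * 4.0)
    out_stroma = []
    for k in range(n_str_out):
        sx, sy = take_site()
        area_k = base_area * shares[k]
        h = float(np.clip(area_k / 650.0, 90.0, 720.0))
        w = min(area_k / h, 720.0)
        out_stroma.append((sx, sy, w, h))
        regions.append(
            TissueRegion(f"out_stroma_{k}", rect(sx + 40, sy + 40, w, h), TissueType.STROMA)
        )
    n_conn_out = int(np.clip(round(rng.normal(230, 60)), 80, 400))
    if slide_wide:
        e_cc = config.effect("n_connective_cells")
        mid = 0.5 * (e_cc.short_mean + e_cc.long_mean)
        n_conn_out = int(np.clip(round(230.0 * t["n_connective_cells"] / mid + rng.normal(0, 20)), 40, 500))
    areas = np.array([w * h for _, _, w, h in out_stroma])
    shares = areas / areas.sum()
    for k, (sx, sy, w, h) in enumerate(out_stroma):
        nk = int(round(n_conn_out * shares[k]))
        _check_capacity(nk, w * h, f"outside stroma {k}")
        cells += _simple_cells(
            rng, CellType.CONNECTIVE, _scatter(rng, nk, sx + 40, sy + 40, w, h), f"out_conn_{k}"
        )

    # minor tissue classes for taxonomy coverage
    for ttype, name, lo_, hi_ in [
        (TissueType.BENIGN_OMENTAL, "out_benign", 250, 400),
        (TissueType.NECROSIS, "out_necrosis", 200, 320),
        (TissueType.HEMORRHAGE, "out_hemorrhage", 120, 220),
        (TissueType.SERUM, "out_serum", 120, 220),
    ]:
        sx, sy = take_site()
        regions.append(
            TissueRegion(name, rect(sx + 40, sy + 40, rng.uniform(lo_, hi_), rng.uniform(lo_, hi_)), ttype)
        )

    n_inf_out = int(np.clip(round(rng.normal(25, 8)), 5, 60))
    sx, sy, w, h = out_stroma[0]
    inf_pos = _scatter(rng, n_inf_out, sx + 40, sy + 40, w, h)
    cells += _simple_cells(rng, CellType.INFLAMMATORY, inf_pos, "out_inf")
    n_mac_out = int(np.clip(round(rng.normal(8, 3)), 0, 20))
    cells += _simple_cells(
        rng, CellType.MACROPHAGE, _scatter(rng, n_mac_out, sx + 40, sy + 40, w, h), "out_mac"
    )
    n_dead_out = int(np.clip(round(rng.normal(6, 3)), 0, 16))
    sx, sy, w, h = out_tumors[0][0], out_tumors[0][1], out_tumors[0][2], out_tumors[0][3]
    cells += _simple_cells(
        rng, CellType.DEAD, _scatter(rng, n_dead_out, sx + 40, sy + 40, w, h), "out_dead"
    )

    if clinical is None:
        clinical = _survival(class_label, config, rng)
    pfi, osd, pev, oev = clinical
    record = SlideRecord(
        slide_id=slide_id,
        patient_id=patient_id,
        pfi_days=pfi,
        os_days=osd,
        pfi_event=pev,
        os_event=oev,
    )
    return cells, regions, amap, record


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Full two-class cohort; slides of one patient share patient-level effects."""
    slides: list[SlideBundle] = []
    records: list[SlideRecord] = []
    for ci, class_label in enumerate(("short", "long")):
        arm_rng = np.random.default_rng(np.random.SeedSequence((config.seed, ci)))
        arm_targets = _cohort_patient_targets(
            class_label, config, arm_rng, config.n_patients_per_class
        )
        for p in range(config.n_patients_per_class):
            prng = np.random.default_rng(np.random.SeedSequence((config.seed, ci, p)))
            targets = arm_targets[p]
            clinical = _survival(class_label, config, prng)
            patient_id = f"P{class_label[0].upper()}{p:03d}"
            for si in range(config.slides_per_patient):
                slide_id = f"{patient_id}_S{si}"
                cells, regions, amap, record = generate_slide(
                    class_label,
                    config,
                    (config.seed, ci, p, si + 1),
                    patient_targets=targets,
                    slide_id=slide_id,
                    patient_id=patient_id,
                    clinical=clinical,
                )
                slides.append(SlideBundle(slide_id, cells, regions, amap, record))
                records.append(record)
    manifest = {
        "planted_features": planted_truth(config),
        "directions": {
            e.feature_name: ("higher_in_long" if e.long_mean > e.short_mean else "higher_in_short")
            for e in config.effects
        },
        "signal_scope": config.signal_scope,
        "n_slides": len(slides),
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "effects"},
            "effects": [asdict(e) for e in config.effects],
        },
    }
    return CohortBundle(slides=slides, records=records, manifest=manifest)


def write_cohort(bundle: CohortBundle, out_dir) -> None:
    """Write per-slide GeoJSON + attention CSV, one clinical CSV and the manifest."""
    out = Path(out_dir)
    (out / "segmentation").mkdir(parents=True, exist_ok=True)
    (out / "attention").mkdir(parents=True, exist_ok=True)
    for sb in bundle.slides:
        write_panoptic_geojson(sb.cells, sb.regions, out / "segmentation" / f"{sb.slide_id}.geojson")
        write_attention_table(sb.attention, out / "attention" / f"{sb.slide_id}.csv")
    write_clinical_table(bundle.records, out / "clinical.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)


def planted_truth(config: CohortConfig) -> list[str]:
    """Informative feature names, strongest standardized effect first.

    Only features whose class means actually differ count as planted; ties
    break lexicographically.
    """
    informative = [e for e in config.effects if e.long_mean != e.short_mean]
    return [
        e.feature_name
        for e in sorted(informative, key=lambda e: (-e.standardized_effect, e.feature_name))
    ]
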