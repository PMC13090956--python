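"""End-to-end orchestration: gate -> features -> CV -> importance -> selection
-> survival -> report.

A run is a pure function of its :class:`PipelineConfig` — every stochastic
stage derives its randomness from the config seeds — and either consumes a
synthetic cohort config or reads segmentation/attention/clinical files from
disk (exactly one of the two).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, gating, importance, morphometry, neighborhood, stroma, survival
from .io import (
    CellType,
    FeatureTable,
    PFIClass,
    SlideRecord,
    ValidationError,
    read_attention_table,
    read_clinical_table,
    read_panoptic_geojson,
    write_feature_table,
)
from .synthetic import CohortConfig, SlideBundle, generate_cohort

__all__ = [
    "PipelineConfig",
    "RunReport",
    "compute_slide_features",
    "cohort_feature_tables",
    "run_pipeline",
    "compare_provenances",
]


@dataclass
class PipelineConfig:
    # exactly one input source
    synthetic: CohortConfig | None = None
    segmentation_dir: str | None = None
    attention_dir: str | None = None
    clinical_table: str | None = None

    attention_threshold: float = gating.DEFAULT_ATTENTION_THRESHOLD
    tsi_distance: float = stroma.DEFAULT_TSI_DISTANCE
    bandwidth: float = neighborhood.DEFAULT_BANDWIDTH
    model_set: tuple[str, ...] = classify.DEFAULT_MODEL_SET
    n_folds: int = 3
    seed: int = 42
    auc_min: float = 0.8
    f1_min: float = 0.8
    elbow_epsilon: float = 0.005
    provenance: str = "both"  # attended | whole_slide | both
    shap_orderings: int = 16
    lime_perturbations: int = 150
    # distance-based learner for the feature-addition curve: its performance
    # visibly degrades once uninformative features are added, which makes the
    # elbow well defined
    curve_model: str | None = "nearest_neighbors"
    output_dir: str | None = None

    def __post_init__(self):
        real = [self.segmentation_dir, self.attention_dir, self.clinical_table]
        if self.synthetic is not None and any(v is not None for v in real):
            raise ValidationError("config must set either synthetic or real inputs, not both")
        if self.synthetic is None and not all(v is not None for v in real):
            raise ValidationError(
                "config needs a synthetic cohort config or all three real input paths"
            )
        if self.provenance not in ("attended", "whole_slide", "both"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")


@dataclass
class RunReport:
    config: dict
    attended_fractions: dict[str, float]
    cv_summaries: dict[str, list[dict]]  # per provenance
    retained_models: list[str]
    ranking: list[str]
    rra_p: dict[str, float]
    selected_features: list[str]
    elbow_k: int
    curve: dict
    survival_results: dict
    provenance_deltas: dict | None = None


# ---------------------------------------------------------------------------
# Feature extraction


def compute_slide_features(
    cells,
    regions,
    mask=None,
    bandwidth: float = neighborhood.DEFAULT_BANDWIDTH,
    tsi_distance: float = stroma.DEFAULT_TSI_DISTANCE,
    descriptors=None,
) -> dict[str, float]:
    """All 69 catalog features for one slide (gated when a mask is given)."""
    if mask is not None:
        cells, regions = gating.gate_objects(cells, regions, mask)
    return {
        **morphometry.aggregate_morphology(cells, descriptors),
        **stroma.region_features(cells, regions, tsi_distance),
        **neighborhood.proximity_features(cells, bandwidth),
    }


def _shared_descriptors(cells) -> dict:
    needs = {
        CellType.NEOPLASTIC: True,
        CellType.CONNECTIVE: False,
        CellType.INFLAMMATORY: False,
    }
    out = {}
    for c in cells:
        if c.cell_type in needs:
            out[c.cell_id] = morphometry.cell_descriptors(c, with_fractal=needs[c.cell_type])
    return out


def cohort_feature_tables(
    slides: Sequence[SlideBundle], config: PipelineConfig
) -> tuple[dict[str, FeatureTable], dict[str, float]]:
    """Attended and/or whole-slide feature tables plus per-slide attended fraction."""
    provenances = (
        ("attended", "whole_slide") if config.provenance == "both" else (config.provenance,)
    )
    rows: dict[str, dict[str, dict[str, float]]] = {p: {} for p in provenances}
    fractions: dict[str, float] = {}
    for sb in slides:
        mask = gating.build_attended_mask(sb.attention, config.attention_threshold)
        fractions[sb.slide_id] = gating.attended_fraction(mask, sb.attention)
        descs = _shared_descriptors(sb.cells)
        for p in provenances:
            rows[p][sb.slide_id] = compute_slide_features(
                sb.cells,
                sb.regions,
                mask if p == "attended" else None,
                config.bandwidth,
                config.tsi_distance,
                descriptors=descs,
            )
    tables = {
        p: neighborhood.assemble_feature_table(rows[p], provenance=p) for p in provenances
    }
    return tables, fractions


def _load_real_cohort(config: PipelineConfig) -> list[SlideBundle]:
    records = read_clinical_table(config.clinical_table)
    by_slide = {r.slide_id: r for r in records}
    slides = []
    for geo in sorted(Path(config.segmentation_dir).glob("*.geojson")):
        sid = geo.stem
        if sid not in by_slide:
            raise ValidationError(f"slide {sid} has no clinical record")
        cells, regions = read_panoptic_geojson(geo)
        amap = read_attention_table(Path(config.attention_dir) / f"{sid}.csv")
        slides.append(SlideBundle(sid, cells, regions, amap, by_slide[sid]))
    if not slides:
        raise ValidationError(f"no .geojson slides under {config.segmentation_dir}")
    return slides


def load_cohort(config: PipelineConfig) -> tuple[list[SlideBundle], list[SlideRecord]]:
    if config.synthetic is not None:
        bundle = generate_cohort(config.synthetic)
        return bundle.slides, bundle.records
    slides = _load_real_cohort(config)
    return slides, [sb.record for sb in slides]


# ---------------------------------------------------------------------------
# Importance stage


def importance_stage(
    table: FeatureTable,
    records: Sequence[SlideRecord],
    retained: Sequence[classify.CVResult],
    config: PipelineConfig,
) -> importance.AggregatedRanking:
    """Pool native / Shapley / surrogate importances over retained models x folds."""
    X, y, _, _ = classify._label_arrays(table, records)
    feats = table.feature_names
    columns: dict[tuple, np.ndarray] = {}
    pooled = {"native": [], "shapley": [], "surrogate": []}
    for res in retained:
        for fi, ((tr, te), model) in enumerate(zip(res.folds, res.fitted)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nat = importance.native_importance(model, X[tr], y[tr], seed=config.seed)
                sha = importance.shapley_attribution(
                    model,
                    X[te],
                    background=X[tr],
                    n_samples=config.shap_orderings,
                    seed=config.seed + fi,
                )
                sur = importance.local_surrogate_attribution(
                    model,
                    X[te],
                    n_perturb=config.lime_perturbations,
                    seed=config.seed + fi,
                )
            for method, vec in (("native", nat), ("shapley", sha), ("surrogate", sur)):
                columns[(res.model_name, fi, method)] = vec
                pooled[method].append(vec)
    rank_matrix = importance.rank_matrix_from_scores(columns, feats)
    means = {m: np.mean(v, axis=0) for m, v in pooled.items()}
    return importance.aggregate_ranking(
        dict(zip(feats, means["native"])),
        dict(zip(feats, means["shapley"])),
        dict(zip(feats, means["surrogate"])),
        rank_matrix,
    )


# ---------------------------------------------------------------------------
# Survival stage


def _survival_stage(
    best: classify.CVResult,
    table: FeatureTable,
    records: Sequence[SlideRecord],
    selected: Sequence[str],
) -> dict:
    X, y, _, slide_ids = classify._label_arrays(table, records)
    by_slide = {r.slide_id: r for r in records}
    # out-of-fold predicted class vs overall survival
    pred = np.empty(len(y), dtype=int)
    for (tr, te), model in zip(best.folds, best.fitted):
        pred[te] = model.predict(X[te])
    os_days = np.array([by_slide[s].os_days for s in slide_ids], dtype=float)
    os_event = np.array([by_slide[s].os_event for s in slide_ids], dtype=bool)
    groups = np.where(pred == 1, "pred_short", "pred_long")
    out = {"predicted_class_vs_os": None, "features_vs_pfi": {}, "km_curves": []}
    if len(np.unique(groups)) == 2:
        chi2, p = survival.logrank_test(os_days, os_event, groups)
        out["predicted_class_vs_os"] = {"chi2": chi2, "p": p}
        for curve in survival.km_estimate(os_days, os_event, groups):
            out["km_curves"].append(
                {
                    "group": curve.group,
                    "times": curve.times.tolist(),
                    "survival": curve.survival.tolist(),
                    "at_risk": curve.at_risk.tolist(),
                    "events": curve.events.tolist(),
                }
            )
    pfi_days = np.array([by_slide[s].pfi_days for s in slide_ids], dtype=float)
    pfi_event = np.array([by_slide[s].pfi_event for s in slide_ids], dtype=bool)
    for feat in selected:
        try:
            glab, info = survival.feature_dichotomize(table, feat, "median")
        except ValidationError:
            out["features_vs_pfi"][feat] = {"error": "degenerate split"}
            continue
        chi2, p = survival.logrank_test(pfi_days, pfi_event, glab)
        out["features_vs_pfi"][feat] = {"chi2": chi2, "p": p, **info}
    return out


# ---------------------------------------------------------------------------
# Pipeline


def _filter_labelled(
    tables: dict[str, FeatureTable], records: Sequence[SlideRecord]
) -> tuple[dict[str, FeatureTable], list[SlideRecord]]:
    ok = {r.slide_id for r in records if r.pfi_class is not PFIClass.EXCLUDED}
    tables = {
        p: FeatureTable(values=t.values.loc[sorted(ok & set(t.values.index))], provenance=p)
        for p, t in tables.items()
    }
    return tables, [r for r in records if r.slide_id in ok]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; returns the run report (and writes artifacts when
    ``output_dir`` is set)."""
    slides, records = load_cohort(config)
    tables, fractions = cohort_feature_tables(slides, config)
    tables, records = _filter_labelled(tables, records)
    primary = "attended" if config.provenance in ("attended", "both") else "whole_slide"

    cv_by_prov: dict[str, list[classify.CVResult]] = {}
    X0, y0, groups0, _ = classify._label_arrays(tables[primary], records)
    folds = classify.make_folds(y0, groups0, config.n_folds, config.seed)
    for p, t in tables.items():
        cv_by_prov[p] = classify.run_cv(
            t, records, config.model_set, config.n_folds, config.seed, folds=folds
        )
    results = cv_by_prov[primary]
    retained = classify.retain_models(results, config.auc_min, config.f1_min)

    ranking = importance_stage(tables[primary], records, retained, config)
    curve_model = config.curve_model or max(retained, key=lambda r: r.mean_auc).model_name
    curve = classify.progressive_curve(
        tables[primary], records, ranking.features, curve_model, config.n_folds, config.seed
    )
    k = classify.elbow_select(curve, config.elbow_epsilon)
    selected = ranking.features[:k]

    best = max(retained, key=lambda r: r.mean_auc)
    surv = _survival_stage(best, tables[primary], records, selected)

    deltas = None
    if config.provenance == "both":
        att = {r.model_name: r.mean_auc for r in cv_by_prov["attended"]}
        whole = {r.model_name: r.mean_auc for r in cv_by_prov["whole_slide"]}
        retained_names = [r.model_name for r in retained]
        deltas = {
            "per_model": {m: att[m] - whole[m] for m in att},
            "retained_mean_attended": float(np.mean([att[m] for m in retained_names])),
            "retained_mean_whole_slide": float(np.mean([whole[m] for m in retained_names])),
        }
        deltas["retained_mean_delta"] = (
            deltas["retained_mean_attended"] - deltas["retained_mean_whole_slide"]
        )

    report = RunReport(
        config=_config_dict(config),
        attended_fractions=fractions,
        cv_summaries={p: [r.summary() for r in res] for p, res in cv_by_prov.items()},
        retained_models=[r.model_name for r in retained],
        ranking=ranking.features,
        rra_p=ranking.rra_p,
        selected_features=selected,
        elbow_k=k,
        curve={"k": curve.ks, "auc": curve.auc, "f1": curve.f1},
        survival_results=surv,
        provenance_deltas=deltas,
    )
    if config.output_dir:
        _write_artifacts(report, tables, ranking, config)
    return report


def compare_provenances(config: PipelineConfig) -> dict:
    """Paired attended vs whole-slide CV with identical folds; per-model deltas."""
    if config.provenance != "both":
        raise ValidationError("compare_provenances requires provenance='both'")
    report = run_pipeline(config)
    return report.provenance_deltas


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _write_artifacts(report, tables, ranking, config) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p, t in tables.items():
        write_feature_table(t, out / f"features_{p}.csv")
    rows = []
    for f in ranking.features:
        rows.append(
            {
                "feature": f,
                "rra_p": ranking.rra_p[f],
                "composite": ranking.composite[f],
                **{k: float(v) for k, v in ranking.method_means.loc[f].items()},
            }
        )
    pd.DataFrame(rows).to_csv(out / "ranking.csv", index=False)
    cv_rows = []
    for p, summaries in report.cv_summaries.items():
        for s in summaries:
            cv_rows.append({"provenance": p, **s})
    pd.DataFrame(cv_rows).to_csv(out / "cv_metrics.csv", index=False)
    km_rows = [
        {"group": c["group"], "time": t, "survival": s, "at_risk": r, "events": e}
        for c in report.survival_results.get("km_curves", [])
        for t, s, r, e in zip(c["times"], c["survival"], c["at_risk"], c["events"])
    ]
    if km_rows:
        pd.DataFrame(km_rows).to_csv(out / "survival_curves.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
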