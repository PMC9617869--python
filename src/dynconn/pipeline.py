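"""End-to-end orchestration: configuration, staged pipeline, run manifest.

``run_pipeline`` executes the full analysis on an in-memory cohort:
sliding-window dFC -> k selection and state fit -> state temporal metrics
-> dynamic topology -> permutation group statistics with FDR -> symptom
correlations -> LOOCV classification.  All seeds and parameters are
echoed into a manifest so a run is reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .atlas_io import SubjectTimeSeries
from .classification import (
    ClassificationReport,
    build_feature_table,
    loocv_svc,
    permutation_significance,
    sweep_fraction,
)
from .dfc import DfcSeries, WindowParams, sliding_window_fc
from .dyn_topology import DEFAULT_SPARSITY_GRID, subject_topo_dynamics, topo_table
from .group_stats import compare_groups, demographics_table, spearman_partial
from .state_analysis import (
    StateModel,
    fit_states,
    occurrence_frequency,
    select_k,
    stack_window_vectors,
    state_metrics,
    state_metrics_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_outputs"]

STATE_FEATURES = (
    "fractional_time_state1",
    "fractional_time_state2",
    "mean_dwell_state1",
    "mean_dwell_state2",
    "n_transitions",
)


@dataclass
class RunConfig:
    """Stage parameters for a full run; serializable to YAML/JSON."""

    window_width_tr: int = 22
    window_step_tr: int = 1
    taper: str = "rectangular"
    k_range: tuple[int, int] = (2, 10)
    fixed_k: int | None = None  # skip model selection when set
    sparsity_grid: tuple[float, ...] = DEFAULT_SPARSITY_GRID
    n_perm_group: int = 10_000
    n_perm_classifier: int = 1000
    fdr_alpha: float = 0.05
    feature_fractions: tuple[float, ...] | None = None  # default 1%..100%
    fixed_fraction: float | None = None  # skip the sweep when set
    svc_cost: float = 1.0
    silhouette_sample_size: int | None = None
    seed: int = 0

    def window_params(self) -> WindowParams:
        return WindowParams(
            width_tr=self.window_width_tr,
            step_tr=self.window_step_tr,
            taper=self.taper,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("k_range", "sparsity_grid", "feature_fractions"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    config: RunConfig
    dfc_by_subject: dict[str, DfcSeries]
    k_selection: object | None
    state_model: StateModel
    state_table: pd.DataFrame
    occurrence: np.ndarray
    topo: pd.DataFrame
    feature_table: object
    group_comparisons: pd.DataFrame
    correlations: pd.DataFrame
    demographics: pd.DataFrame | None
    classification: ClassificationReport
    manifest: dict


def _metadata_frame(subjects: Sequence[SubjectTimeSeries]) -> pd.DataFrame:
    rows = []
    for ts in subjects:
        row = {"subject_id": ts.subject_id, "group": ts.group}
        row.update(ts.covariates)
        for k, v in (ts.panss or {}).items():
            row[f"panss_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _symptom_correlations(
    feature_df: pd.DataFrame,
    comparisons: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float,
) -> pd.DataFrame:
    """Spearman partial correlations (age/sex/education covariates) of
    PANSS ratings with the features surviving the group comparison at the
    FDR threshold, patients only."""
    pat = metadata[metadata["group"] == "patient"].set_index("subject_id")
    panss_cols = [c for c in pat.columns if c.startswith("panss_")]
    covar_cols = [c for c in ("age", "sex", "education") if c in pat.columns]
    surviving = comparisons.loc[comparisons["p_fdr"] < alpha, "feature"]
    rows = []
    if len(pat) == 0 or not panss_cols:
        return pd.DataFrame(
            columns=["feature", "rating", "rho", "p", "n", "significant"]
        )
    feats = feature_df.loc[feature_df.index.intersection(pat.index)]
    for feat in surviving:
        x = feats[feat]
        for rating in panss_cols:
            yv = pat.loc[feats.index, rating]
            ok = np.isfinite(x.to_numpy(float)) & np.isfinite(yv.to_numpy(float))
            if ok.sum() <= len(covar_cols) + 2:
                continue
            res = spearman_partial(
                x[ok], yv[ok], pat.loc[feats.index[ok], covar_cols]
            )
            rows.append(
                {
                    "feature": feat,
                    "rating": rating,
                    "rho": res.rho,
                    "p": res.p,
                    "n": res.n,
                    "significant": bool(res.p < alpha) if np.isfinite(res.p) else False,
                }
            )
    return pd.DataFrame(rows, columns=["feature", "rating", "rho", "p", "n", "significant"])


def run_pipeline(
    subjects: Sequence[SubjectTimeSeries], config: RunConfig | None = None
) -> PipelineResult:
    """Run every analysis stage on an in-memory cohort."""
    cfg = config or RunConfig()
    params = cfg.window_params()
    logger.info("dFC: %d subjects, window %d TR step %d TR",
                len(subjects), params.width_tr, params.step_tr)
    dfc_by_subject = {ts.subject_id: sliding_window_fc(ts, params) for ts in subjects}
    group_by_subject = {ts.subject_id: ts.group for ts in subjects}

    X, sids = stack_window_vectors(dfc_by_subject.values())
    if cfg.fixed_k is not None:
        k_sel = None
        k = cfg.fixed_k
    else:
        k_sel = select_k(
            X,
            k_range=range(cfg.k_range[0], cfg.k_range[1] + 1),
            seed=cfg.seed,
            silhouette_sample_size=cfg.silhouette_sample_size,
        )
        k = k_sel.k_star
    logger.info("state model: k = %d", k)
    model = fit_states(X, k, seed=cfg.seed, subject_ids=sids)
    state_df = state_metrics_table(model)
    occurrence = occurrence_frequency(model)

    topo_by_subject = {
        sid: subject_topo_dynamics(dfc, cfg.sparsity_grid)
        for sid, dfc in dfc_by_subject.items()
    }
    topo_df = topo_table(topo_by_subject.values())

    table = build_feature_table(
        {sid: state_metrics(model.labels_for(sid), k) for sid in dfc_by_subject},
        topo_by_subject,
        group_by_subject,
    )
    feature_df = pd.DataFrame(
        table.X, columns=list(table.feature_names), index=list(table.subject_ids)
    )

    # FDR families: state characteristics together; each nodal map its own
    families: dict[str, list[str]] = {
        "state_characteristics": [
            f for f in STATE_FEATURES if f in feature_df.columns
        ],
        "nodal_efficiency": [
            f for f in feature_df.columns if f.startswith("cv_nodal_efficiency_")
        ],
        "eigenvector_centrality": [
            f for f in feature_df.columns
            if f.startswith("cv_eigenvector_centrality_")
        ],
        "global": ["cv_global_efficiency", "cv_clustering_coefficient"],
    }
    groups = [group_by_subject[s] for s in table.subject_ids]
    comparisons = compare_groups(
        feature_df, groups, families=families,
        n_perm=cfg.n_perm_group, seed=cfg.seed,
    )

    metadata = _metadata_frame(subjects)
    correlations = _symptom_correlations(
        feature_df, comparisons, metadata, cfg.fdr_alpha
    )
    demo = None
    if {"age", "sex", "education"} & set(metadata.columns):
        try:
            demo = demographics_table(metadata)
        except (ValueError, KeyError):
            demo = None

    if cfg.fixed_fraction is not None:
        curve, fraction = None, cfg.fixed_fraction
    else:
        curve, fraction = sweep_fraction(
            table, fractions=cfg.feature_fractions, svc_cost=cfg.svc_cost
        )
    report = loocv_svc(table, fraction, svc_cost=cfg.svc_cost)
    report.fraction_curve = curve
    report.perm_p = permutation_significance(
        table, fraction, n_perm=cfg.n_perm_classifier, seed=cfg.seed,
        svc_cost=cfg.svc_cost, observed_accuracy=report.accuracy,
    )

    manifest = {
        "config": cfg.to_dict(),
        "n_subjects": len(subjects),
        "n_patients": int(sum(g == "patient" for g in groups)),
        "n_controls": int(sum(g == "control" for g in groups)),
        "n_windows_per_subject": int(
            next(iter(dfc_by_subject.values())).n_windows
        ),
        "k": k,
        "occurrence_by_state": occurrence.tolist(),
        "classifier_fraction": fraction,
        "classifier_accuracy": report.accuracy,
        "seed": cfg.seed,
    }
    return PipelineResult(
        config=cfg,
        dfc_by_subject=dfc_by_subject,
        k_selection=k_sel,
        state_model=model,
        state_table=state_df,
        occurrence=occurrence,
        topo=topo_df,
        feature_table=table,
        group_comparisons=comparisons,
        correlations=correlations,
        demographics=demo,
        classification=report,
        manifest=manifest,
    )


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write all stage outputs as TSV/JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.state_table.to_csv(out / "state_metrics.tsv", sep="\t", index=False)
    result.topo.to_csv(out / "topo_dynamics.tsv", sep="\t", index=False)
    result.group_comparisons.to_csv(
        out / "group_comparisons.tsv", sep="\t", index=False
    )
    result.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
    if result.demographics is not None:
        result.demographics.to_csv(out / "demographics.tsv", sep="\t", index=False)
    rep = result.classification
    rep.to_json(out / "classification_report.json")
    rep.predictions.to_csv(out / "per_fold_predictions.tsv", sep="\t", index=False)
    rep.weight_table().to_csv(out / "consensus_features.tsv", sep="\t", index=False)
    if rep.fraction_curve is not None:
        rep.fraction_curve.to_csv(out / "fraction_curve.tsv", sep="\t", index=False)
    if result.k_selection is not None:
        sel = result.k_selection
        (out / "k_selection.json").write_text(
            json.dumps(
                {
                    "k_star": sel.k_star,
                    "elbow_k": sel.elbow_k,
                    "sse_by_k": sel.sse_by_k,
                    "silhouette_by_k": sel.silhouette_by_k,
                },
                indent=1,
            )
        )
    (out / "run_manifest.json").write_text(json.dumps(result.manifest, indent=1))
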