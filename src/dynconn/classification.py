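"""Case-control classification from dynamic features.

A linear support vector classifier (C = 1) distinguishes patients from
controls using per-subject dynamic features: the five state
characteristics (fractional time and mean dwell of each state, number of
transitions), the CV of nodal efficiency and of nodal eigenvector
centrality at every node, and the CVs of global efficiency and mean
clustering coefficient.

Evaluation is leave-one-out cross-validation.  Inside every fold, and
using the training fold only: undefined (NaN) CVs are imputed with the
training median, features are ranked by one-way ANOVA F score and the top
``ceil(fraction * n_features)`` retained, then z-scored by training-fold
statistics before fitting.  This keeps feature selection strictly
fold-local (no leakage from the held-out subject).  The feature fraction
is swept from 1% to 100%; significance of the observed accuracy comes
from rerunning the whole selection + LOOCV under permuted labels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .dyn_topology import TopoDynamics
from .state_analysis import StateMetrics

__all__ = [
    "FeatureTable",
    "ClassificationReport",
    "build_feature_table",
    "f_scores",
    "loocv_svc",
    "sweep_fraction",
    "permutation_significance",
]

_F_EPS = 1e-12


@dataclass
class FeatureTable:
    """Complete per-subject feature matrix with fixed column order:
    state characteristics first (fractional time x2, mean dwell x2,
    transitions), then CV of nodal efficiency per node, CV of nodal
    eigenvector centrality per node, CV of global efficiency, CV of
    clustering coefficient."""

    X: np.ndarray  # (n_subjects, n_features), may hold NaN (imputed per fold)
    y: np.ndarray  # 1 = patient, 0 = control
    feature_names: tuple[str, ...]
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y, int)
        if self.X.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("feature table dimensions are inconsistent")
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError("labels must be 0 (control) / 1 (patient)")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def build_feature_table(
    state_metrics_by_subject: Mapping[str, StateMetrics],
    topo_by_subject: Mapping[str, TopoDynamics],
    group_by_subject: Mapping[str, str],
) -> FeatureTable:
    sids = sorted(state_metrics_by_subject)
    if sorted(topo_by_subject) != sids:
        raise ValueError("state metrics and topology cover different subjects")
    first = topo_by_subject[sids[0]]
    n = len(first.cv_nodal_efficiency)
    node_ids = list(first.node_ids) or [f"node{j:03d}" for j in range(n)]
    names = (
        ["fractional_time_state1", "fractional_time_state2",
         "mean_dwell_state1", "mean_dwell_state2", "n_transitions"]
        + [f"cv_nodal_efficiency_{nid}" for nid in node_ids]
        + [f"cv_eigenvector_centrality_{nid}" for nid in node_ids]
        + ["cv_global_efficiency", "cv_clustering_coefficient"]
    )
    rows = []
    for sid in sids:
        m = state_metrics_by_subject[sid]
        t = topo_by_subject[sid]
        rows.append(
            np.concatenate(
                [
                    [m.fractional_time[0], m.fractional_time[1],
                     m.mean_dwell[0], m.mean_dwell[1], m.n_transitions],
                    t.cv_nodal_efficiency,
                    t.cv_eigenvector_centrality,
                    [t.cv_global_efficiency, t.cv_clustering_coefficient],
                ]
            )
        )
    y = np.array([1 if group_by_subject[s] == "patient" else 0 for s in sids])
    return FeatureTable(
        X=np.vstack(rows), y=y, feature_names=tuple(names), subject_ids=tuple(sids)
    )


def f_scores(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic per feature (between-group over
    within-group variance).

    A feature with zero within-group variance scores 0 when the group
    means are equal, and a large finite value (epsilon-guarded
    denominator) when they differ.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    n = X.shape[0]
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    grand = X.mean(axis=0)
    for c in classes:
        Xc = X[y == c]
        nc = Xc.shape[0]
        if nc < 2:
            raise ValueError("each class needs at least 2 samples")
        mu = Xc.mean(axis=0)
        ssb += nc * (mu - grand) ** 2
        ssw += ((Xc - mu) ** 2).sum(axis=0)
    msb = ssb / (len(classes) - 1)
    msw = ssw / (n - len(classes))
    scale = np.maximum(msb, 1.0)
    return msb / np.maximum(msw, _F_EPS * scale)


@dataclass
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    fraction: float
    n_selected: int
    per_fold_selected: list[list[str]]
    consensus_features: list[str]
    #: consensus feature -> mean standardized SVC weight across folds
    weights: dict[str, float]
    predictions: pd.DataFrame  # subject_id, y_true, y_pred, decision_value
    perm_p: float | None = None
    fraction_curve: pd.DataFrame | None = None

    def weight_table(self) -> pd.DataFrame:
        """Consensus features with mean weights, ranked by |weight|."""
        df = pd.DataFrame(
            {"feature": list(self.weights), "mean_weight": list(self.weights.values())}
        )
        df["abs_rank"] = (
            df["mean_weight"].abs().rank(ascending=False, method="min").astype(int)
        )
        return df.sort_values("abs_rank").reset_index(drop=True)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "fraction": self.fraction,
            "n_selected": self.n_selected,
            "perm_p": self.perm_p,
            "consensus_features": self.consensus_features,
            "weights": self.weights,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _fold_fit(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    n_keep: int,
    svc_cost: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Impute, select, standardize and fit on the training fold only.
    Returns (selected indices, test predictions, test decision values,
    weight vector over selected features)."""
    med = np.nanmedian(X_tr, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    X_tr = np.where(np.isfinite(X_tr), X_tr, med)
    X_te = np.where(np.isfinite(X_te), X_te, med)
    scores = f_scores(X_tr, y_tr)
    # stable ranking: ties broken by feature order
    order = np.lexsort((np.arange(len(scores)), -scores))
    sel = np.sort(order[:n_keep])
    mu = X_tr[:, sel].mean(axis=0)
    sd = X_tr[:, sel].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z_tr = (X_tr[:, sel] - mu) / sd
    Z_te = (X_te[:, sel] - mu) / sd
    clf = SVC(kernel="linear", C=svc_cost)
    clf.fit(Z_tr, y_tr)
    return sel, clf.predict(Z_te), clf.decision_function(Z_te), clf.coef_.ravel()


def loocv_svc(
    table: FeatureTable, fraction: float, svc_cost: float = 1.0
) -> ClassificationReport:
    """Leave-one-out evaluation of the linear SVC at one feature fraction.

    Patients (label 1) are the positive class for sensitivity; AUC is
    computed from the per-fold decision values.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    X, y = table.X, table.y
    n, p = X.shape
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    n_keep = math.ceil(fraction * p)
    if n_keep == 0:
        raise ValueError("selected feature count is zero")

    preds = np.empty(n, int)
    decisions = np.empty(n)
    selected: list[list[str]] = []
    weight_sum: dict[str, float] = {}
    weight_cnt: dict[str, int] = {}
    for i in range(n):
        tr = np.ones(n, bool)
        tr[i] = False
        sel, yhat, dec, w = _fold_fit(X[tr], y[tr], X[[i]], n_keep, svc_cost)
        preds[i] = yhat[0]
        decisions[i] = dec[0]
        names = [table.feature_names[j] for j in sel]
        selected.append(names)
        for nm, wj in zip(names, w):
            weight_sum[nm] = weight_sum.get(nm, 0.0) + float(wj)
            weight_cnt[nm] = weight_cnt.get(nm, 0) + 1

    consensus = sorted(set(selected[0]).intersection(*selected[1:]))
    weights = {nm: weight_sum[nm] / weight_cnt[nm] for nm in consensus}
    tp = int(((preds == 1) & (y == 1)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    acc = (tp + tn) / n
    sens = tp / (y == 1).sum()
    spec = tn / (y == 0).sum()
    auc = float(roc_auc_score(y, decisions))
    return ClassificationReport(
        accuracy=float(acc),
        sensitivity=float(sens),
        specificity=float(spec),
        auc=auc,
        fraction=float(fraction),
        n_selected=n_keep,
        per_fold_selected=selected,
        consensus_features=consensus,
        weights=weights,
        predictions=pd.DataFrame(
            {
                "subject_id": table.subject_ids,
                "y_true": y,
                "y_pred": preds,
                "decision_value": decisions,
            }
        ),
    )


def sweep_fraction(
    table: FeatureTable,
    fractions: Sequence[float] | None = None,
    svc_cost: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Accuracy across feature fractions (default 1%..100% in 1% steps).

    The chosen fraction is the smallest whose accuracy is within one
    LOOCV-fold error (1/n) of the maximum — the most parsimonious model
    statistically indistinguishable from the best.
    """
    if fractions is None:
        fractions = [f / 100 for f in range(1, 101)]
    rows = []
    for f in fractions:
        rep = loocv_svc(table, f, svc_cost=svc_cost)
        rows.append({"fraction": f, "n_selected": rep.n_selected,
                     "accuracy": rep.accuracy, "auc": rep.auc})
    curve = pd.DataFrame(rows)
    n = len(table.y)
    best = curve["accuracy"].max()
    ok = curve[curve["accuracy"] >= best - 1.0 / n]
    chosen = float(ok["fraction"].min())
    return curve, chosen


def permutation_significance(
    table: FeatureTable,
    fraction: float,
    n_perm: int = 1000,
    seed: int = 0,
    svc_cost: float = 1.0,
    observed_accuracy: float | None = None,
) -> float:
    """p-value of the LOOCV accuracy under label permutation.

    The complete pipeline (fold-local imputation, F-score selection,
    standardization, SVC) is rerun for every permuted label vector;
    p = (#{perm accuracy >= observed} + 1) / (n_perm + 1).
    """
    if observed_accuracy is None:
        observed_accuracy = loocv_svc(table, fraction, svc_cost).accuracy
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        yp = rng.permutation(table.y)
        if yp.sum() < 2 or (1 - yp).sum() < 2:
            continue
        perm_table = FeatureTable(
            X=table.X, y=yp, feature_names=table.feature_names,
            subject_ids=table.subject_ids,
        )
        acc = loocv_svc(perm_table, fraction, svc_cost).accuracy
        if acc >= observed_accuracy - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
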