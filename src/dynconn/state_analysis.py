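"""Recurring dFC brain states by k-means, and state temporal metrics.

Windowed connectivity matrices from all subjects are pooled (vectorized
upper triangles, Euclidean distance) and clustered with k-means.  Model
order is chosen by the maximum mean silhouette coefficient over k = 2..10,
with the elbow of the sum of squared errors (largest discrete second
difference) reported alongside.  States are relabeled so that state 1 is
always the centroid with the lowest mean connectivity (the hypoconnected
state), making state identity invariant to initialization.

Per-subject temporal metrics: fractional time (proportion of windows in
each state), mean dwell time (average consecutive-run length, in windows)
and number of transitions (label switches).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import groupby
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .dfc import DfcSeries, vectorize_upper, matrix_from_upper

__all__ = [
    "StateModel",
    "StateMetrics",
    "KSelection",
    "stack_window_vectors",
    "select_k",
    "fit_states",
    "group_centroids",
    "state_metrics",
    "occurrence_frequency",
    "state_metrics_table",
]

logger = logging.getLogger(__name__)

_KMEANS_KW = dict(n_init=20, max_iter=500, tol=1e-6, init="k-means++")


@dataclass
class KSelection:
    k_star: int
    silhouette_k: int
    elbow_k: int
    sse_by_k: dict[int, float]
    silhouette_by_k: dict[int, float]


@dataclass
class StateModel:
    """Fitted k-means state model over pooled window vectors."""

    k: int
    centroids: np.ndarray  # (k, N(N-1)/2), state order = ascending mean edge
    labels: np.ndarray  # per pooled window, 1..k
    subject_ids: np.ndarray  # per pooled window
    seed: int
    inertia: float

    def labels_for(self, subject_id: str) -> np.ndarray:
        """Window-ordered state labels for one subject."""
        return self.labels[self.subject_ids == subject_id]

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(str(s), None)
        return list(seen)

    def centroid_matrix(self, state: int) -> np.ndarray:
        """N x N centroid connectivity matrix for a state (1-based)."""
        return matrix_from_upper(self.centroids[state - 1])


@dataclass(frozen=True)
class StateMetrics:
    fractional_time: np.ndarray  # per state, sums to 1
    mean_dwell: np.ndarray  # per state, in windows; 0 if never visited
    n_transitions: int


def stack_window_vectors(
    dfc_list: Iterable[DfcSeries],
) -> tuple[np.ndarray, np.ndarray]:
    """Pool all subjects' windows: (X of shape (sum W, N(N-1)/2),
    subject_id per row)."""
    vecs, sids = [], []
    for dfc in dfc_list:
        iu = np.triu_indices(dfc.n_nodes, k=1)
        vecs.append(dfc.windows[:, iu[0], iu[1]])
        sids.extend([dfc.subject_id] * dfc.n_windows)
    return np.vstack(vecs), np.asarray(sids)


def select_k(
    window_vectors: np.ndarray,
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
    silhouette_sample_size: int | None = None,
) -> KSelection:
    """Choose the number of states.

    The silhouette-maximizing k is selected; the SSE elbow (argmax of the
    discrete second difference) is computed alongside, with a warning
    logged when the two criteria disagree.
    """
    X = np.asarray(window_vectors, float)
    ks = sorted(k_range)
    if X.shape[0] < max(ks) + 1:
        raise ValueError(
            f"need more than {max(ks)} samples to evaluate k up to {max(ks)}"
        )
    sse: dict[int, float] = {}
    sil: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, random_state=seed, **_KMEANS_KW).fit(X)
        sse[k] = float(km.inertia_)
        kwargs = {}
        if silhouette_sample_size and silhouette_sample_size < X.shape[0]:
            kwargs = dict(sample_size=silhouette_sample_size, random_state=seed)
        sil[k] = float(silhouette_score(X, km.labels_, **kwargs))
    sil_k = max(sil, key=sil.get)
    if len(ks) >= 3:
        d2 = {
            ks[i]: sse[ks[i - 1]] - 2 * sse[ks[i]] + sse[ks[i + 1]]
            for i in range(1, len(ks) - 1)
        }
        elbow_k = max(d2, key=d2.get)
    else:
        elbow_k = sil_k
    if elbow_k != sil_k:
        logger.warning(
            "elbow criterion (k=%d) and silhouette criterion (k=%d) disagree; "
            "using the silhouette k",
            elbow_k,
            sil_k,
        )
    return KSelection(
        k_star=sil_k, silhouette_k=sil_k, elbow_k=elbow_k,
        sse_by_k=sse, silhouette_by_k=sil,
    )


def fit_states(
    window_vectors: np.ndarray,
    k: int,
    seed: int = 0,
    subject_ids: Sequence[str] | None = None,
    max_retries: int = 3,
) -> StateModel:
    """k-means fit on pooled window vectors with hypoconnected-first
    relabeling.

    Centroids are ordered by ascending mean edge value, so state 1 is the
    weakest-connectivity state.  If the fit leaves a cluster empty (fewer
    distinct windows than k), the fit is retried with a fresh seed and an
    error raised if the degeneracy persists.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.asarray(window_vectors, float)
    if subject_ids is None:
        subject_ids = ["pooled"] * X.shape[0]
    subject_ids = np.asarray([str(s) for s in subject_ids])
    if len(subject_ids) != X.shape[0]:
        raise ValueError("subject_ids must align with window vectors")

    last_exc: Exception | None = None
    for attempt in range(max_retries):
        km = KMeans(n_clusters=k, random_state=seed + attempt, **_KMEANS_KW).fit(X)
        if len(np.unique(km.labels_)) == k:
            break
        last_exc = RuntimeError(
            f"k-means produced an empty cluster for k={k} "
            f"(only {len(np.unique(km.labels_))} distinct clusters)"
        )
    else:
        raise last_exc
    order = np.argsort(km.cluster_centers_.mean(axis=1))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return StateModel(
        k=k,
        centroids=km.cluster_centers_[order],
        labels=relabel[km.labels_],
        subject_ids=subject_ids,
        seed=seed,
        inertia=float(km.inertia_),
    )


def group_centroids(
    model: StateModel,
    group_by_subject: Mapping[str, str],
    window_vectors: np.ndarray,
) -> dict[tuple[str, int], np.ndarray | None]:
    """Per (group, state) mean window vector; None when a group has no
    windows in a state (flagged undefined, never fabricated)."""
    X = np.asarray(window_vectors, float)
    groups = np.asarray([group_by_subject[str(s)] for s in model.subject_ids])
    out: dict[tuple[str, int], np.ndarray | None] = {}
    for g in sorted(set(groups)):
        for s in range(1, model.k + 1):
            mask = (groups == g) & (model.labels == s)
            out[(g, s)] = X[mask].mean(axis=0) if mask.any() else None
    return out


def state_metrics(label_sequence: Sequence[int], k: int) -> StateMetrics:
    """Fractional time, mean dwell (windows) and transition count for one
    subject's window-ordered label sequence."""
    seq = np.asarray(label_sequence, int)
    if seq.size == 0:
        raise ValueError("empty label sequence")
    if seq.min() < 1 or seq.max() > k:
        raise ValueError(f"labels must be in 1..{k}")
    W = seq.size
    frac = np.array([(seq == s).mean() for s in range(1, k + 1)])
    runs = [(s, sum(1 for _ in grp)) for s, grp in groupby(seq)]
    dwell = np.zeros(k)
    for s in range(1, k + 1):
        lengths = [ln for lab, ln in runs if lab == s]
        dwell[s - 1] = float(np.mean(lengths)) if lengths else 0.0
    return StateMetrics(
        fractional_time=frac, mean_dwell=dwell, n_transitions=len(runs) - 1
    )


def occurrence_frequency(model: StateModel) -> np.ndarray:
    """Per-state proportion of all windows across all subjects."""
    return np.array([(model.labels == s).mean() for s in range(1, model.k + 1)])


def state_metrics_table(model: StateModel) -> pd.DataFrame:
    """Tidy per-subject state metrics: one row per (subject, state)."""
    rows = []
    for sid in model.subjects:
        m = state_metrics(model.labels_for(sid), model.k)
        for s in range(1, model.k + 1):
            rows.append(
                {
                    "subject_id": sid,
                    "state": s,
                    "fractional_time": m.fractional_time[s - 1],
                    "mean_dwell": m.mean_dwell[s - 1],
                    "n_transitions": m.n_transitions,
                }
            )
    return pd.DataFrame(rows)
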