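"""Dynamic graph topology: proportional thresholding, weighted metrics,
AUC over sparsity, and temporal variability (CV).

Each windowed correlation matrix is reduced to a sparse weighted graph by
keeping the strongest K% of positive connections (K = 5, 10, 15, 20 by
default; edge budget defined against all N(N-1)/2 pairs).  Four metrics
follow Brain Connectivity Toolbox conventions for weighted graphs:

* global / nodal efficiency — inverse shortest-path distances with edge
  length 1/weight (unreachable pairs contribute 0);
* mean clustering coefficient — Onnela's weighted formulation, weights
  normalized by the matrix maximum;
* eigenvector centrality — leading eigenvector by power iteration,
  nonnegative, unit Euclidean norm.

Per metric, values across the sparsity grid are integrated by the
trapezoid rule (AUC), and the coefficient of variation of the AUC across
windows (SD/mean, SD with denominator W-1) summarizes temporal
variability.  A CV whose temporal mean is below 1e-12 in magnitude is
undefined and reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .dfc import DfcSeries

__all__ = [
    "DEFAULT_SPARSITY_GRID",
    "TopoDynamics",
    "threshold_topk",
    "global_efficiency",
    "nodal_efficiency",
    "clustering_coefficient",
    "eigenvector_centrality",
    "auc_over_sparsity",
    "cv_over_windows",
    "subject_topo_dynamics",
    "topo_table",
]

DEFAULT_SPARSITY_GRID: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)

_MEAN_EPS = 1e-12


def threshold_topk(
    corr_matrix: np.ndarray, k_percent: float
) -> tuple[np.ndarray, bool]:
    """Keep the strongest K% positive connections as a weighted graph.

    The edge budget is m = round(K/100 * N(N-1)/2); the m largest strictly
    positive off-diagonal weights are retained unchanged (ties broken by
    lexicographic node-pair order).  Returns (adjacency, short_flag): the
    flag is True when fewer than m positive edges existed and all were
    kept.
    """
    C = np.asarray(corr_matrix, float)
    n = C.shape[0]
    if C.shape != (n, n):
        raise ValueError("expected a square matrix")
    if not 0 < k_percent <= 100:
        raise ValueError("K must be in (0, 100]")
    iu, ju = np.triu_indices(n, k=1)
    w = C[iu, ju]
    m = int(round(k_percent / 100.0 * len(w)))
    pos = w > 0
    # sort by (-weight, i, j): strongest first, lexicographic tie-break
    order = np.lexsort((ju[pos], iu[pos], -w[pos]))
    keep = order[:m]
    short = keep.size < m
    A = np.zeros((n, n))
    ki, kj = iu[pos][keep], ju[pos][keep]
    A[ki, kj] = w[pos][keep]
    A[kj, ki] = w[pos][keep]
    return A, short


def _check_adjacency(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("expected a square adjacency matrix")
    if np.any(W < 0):
        raise ValueError(
            "negative edge weight; apply positive thresholding first"
        )
    return W


def _inverse_distances(W: np.ndarray) -> np.ndarray:
    """1/d(i,j) matrix over shortest paths with length 1/weight; 0 for
    unreachable pairs and on the diagonal."""
    n = W.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
    d = dijkstra(csr_matrix(lengths), directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv


def nodal_efficiency(W: np.ndarray) -> np.ndarray:
    """Per node: mean over other nodes of 1/shortest-path distance."""
    W = _check_adjacency(W)
    n = W.shape[0]
    if n < 2:
        return np.zeros(n)
    return _inverse_distances(W).sum(axis=1) / (n - 1)


def global_efficiency(W: np.ndarray) -> float:
    """Mean of 1/d(i,j) over all ordered pairs (= mean nodal efficiency)."""
    W = _check_adjacency(W)
    if W.shape[0] < 2:
        return 0.0
    return float(nodal_efficiency(W).mean())


def clustering_coefficient(W: np.ndarray) -> float:
    """Network mean of Onnela's weighted clustering coefficient.

    Weights are normalized by the matrix maximum; c(i) = sum over pairs of
    neighbours of the geometric mean of the triangle's weights, divided by
    deg_i(deg_i - 1); nodes with degree < 2 contribute 0.
    """
    W = _check_adjacency(W)
    n = W.shape[0]
    wmax = W.max()
    if wmax <= 0:
        return 0.0
    Wn = (W / wmax) ** (1.0 / 3.0)
    triangles = np.diag(Wn @ Wn @ Wn)  # 2 * sum of triangle geometric means
    deg = (W > 0).sum(axis=1)
    denom = deg * (deg - 1)
    c = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return float(c.mean())


def eigenvector_centrality(
    W: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000
) -> np.ndarray:
    """Leading eigenvector by power iteration: nonnegative, unit Euclidean
    norm.  Computed on the full matrix, so on a disconnected graph the
    mass concentrates on the dominant component.  An all-zero matrix
    yields the all-zero vector."""
    W = _check_adjacency(W)
    n = W.shape[0]
    if not np.any(W > 0):
        return np.zeros(n)
    # Shift by the largest row sum: same eigenvectors, but the shifted
    # matrix is diagonally dominant (PSD), so the leading eigenvalue is
    # well separated and the iteration cannot oscillate between +/- pairs.
    shift = float(W.sum(axis=1).max())
    W = W + shift * np.eye(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = W @ x
        lam = float(x @ y)
        # residual-based stop: |Wx - lam*x| <= tol*lam bounds the
        # eigenvector error by tol / relative-spectral-gap
        if np.linalg.norm(y - lam * x) <= tol * lam:
            x = y / np.linalg.norm(y)
            break
        x = y / np.linalg.norm(y)
    x = np.abs(x)
    return x / np.linalg.norm(x)


def auc_over_sparsity(
    metric_values: Sequence[float] | np.ndarray,
    k_values: Sequence[float] = DEFAULT_SPARSITY_GRID,
) -> float | np.ndarray:
    """Trapezoidal integral of a metric across the sparsity grid (percent
    units).  Accepts a vector per K (shape (len(K), ...)) and integrates
    along the first axis."""
    v = np.asarray(metric_values, float)
    k = np.asarray(k_values, float)
    if v.shape[0] != k.shape[0]:
        raise ValueError("metric values and K values must align")
    out = np.trapezoid(v, x=k, axis=0)
    return float(out) if np.ndim(out) == 0 else out


def cv_over_windows(auc_series: np.ndarray) -> float | np.ndarray:
    """Coefficient of variation across windows: SD (denominator W-1) over
    mean; NaN where |mean| < 1e-12 (undefined)."""
    a = np.asarray(auc_series, float)
    if a.shape[0] < 2:
        raise ValueError("CV needs at least 2 windows")
    mean = a.mean(axis=0)
    sd = a.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(np.abs(mean) < _MEAN_EPS, np.nan, sd / mean)
    return float(cv) if np.ndim(cv) == 0 else cv


@dataclass
class TopoDynamics:
    """Per-subject temporal variability of the four topological metrics
    (CV across windows of the AUC across sparsity)."""

    subject_id: str
    cv_global_efficiency: float
    cv_clustering_coefficient: float
    cv_nodal_efficiency: np.ndarray  # (N,)
    cv_eigenvector_centrality: np.ndarray  # (N,)
    node_ids: tuple[str, ...] = ()


def subject_topo_dynamics(
    dfc: DfcSeries,
    k_values: Sequence[float] = DEFAULT_SPARSITY_GRID,
) -> TopoDynamics:
    """Full dynamic-topology pipeline for one subject's windowed matrices."""
    W_count, n = dfc.n_windows, dfc.n_nodes
    nk = len(k_values)
    geff = np.empty((W_count, nk))
    clus = np.empty((W_count, nk))
    neff = np.empty((W_count, nk, n))
    ecen = np.empty((W_count, nk, n))
    for wdx in range(W_count):
        for kdx, K in enumerate(k_values):
            A, _ = threshold_topk(dfc.windows[wdx], K)
            ne = nodal_efficiency(A)
            neff[wdx, kdx] = ne
            geff[wdx, kdx] = ne.mean()
            clus[wdx, kdx] = clustering_coefficient(A)
            ecen[wdx, kdx] = eigenvector_centrality(A)
    auc_geff = np.array([auc_over_sparsity(geff[w], k_values) for w in range(W_count)])
    auc_clus = np.array([auc_over_sparsity(clus[w], k_values) for w in range(W_count)])
    auc_neff = np.stack([auc_over_sparsity(neff[w], k_values) for w in range(W_count)])
    auc_ecen = np.stack([auc_over_sparsity(ecen[w], k_values) for w in range(W_count)])
    return TopoDynamics(
        subject_id=dfc.subject_id,
        cv_global_efficiency=cv_over_windows(auc_geff),
        cv_clustering_coefficient=cv_over_windows(auc_clus),
        cv_nodal_efficiency=np.asarray(cv_over_windows(auc_neff)),
        cv_eigenvector_centrality=np.asarray(cv_over_windows(auc_ecen)),
        node_ids=dfc.node_ids,
    )


def topo_table(dynamics: Iterable[TopoDynamics]) -> pd.DataFrame:
    """Tidy export: (subject_id, metric, node_id-or-GLOBAL, cv_value,
    undefined_flag)."""
    rows = []
    for td in dynamics:
        node_ids = td.node_ids or tuple(
            f"node{j:03d}" for j in range(len(td.cv_nodal_efficiency))
        )
        rows.append(
            dict(subject_id=td.subject_id, metric="global_efficiency",
                 node_id="GLOBAL", cv_value=td.cv_global_efficiency)
        )
        rows.append(
            dict(subject_id=td.subject_id, metric="clustering_coefficient",
                 node_id="GLOBAL", cv_value=td.cv_clustering_coefficient)
        )
        for name, values in (
            ("nodal_efficiency", td.cv_nodal_efficiency),
            ("eigenvector_centrality", td.cv_eigenvector_centrality),
        ):
            for nid, v in zip(node_ids, values):
                rows.append(
                    dict(subject_id=td.subject_id, metric=name,
                         node_id=nid, cv_value=v)
                )
    df = pd.DataFrame(rows)
    df["undefined_flag"] = ~np.isfinite(df["cv_value"])
    return df
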