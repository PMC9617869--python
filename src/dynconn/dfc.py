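"""Sliding-window dynamic functional connectivity (dFC).

Each subject's T x N ROI series is segmented into overlapping windows of
``width_tr`` volumes sliding by ``step_tr``; the window covering volumes
[j*s, j*s + w) yields an N x N Pearson correlation matrix.  Windows are
rectangular by default; a Gaussian taper applies observation weights
inside the window.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atlas_io import SubjectTimeSeries

__all__ = [
    "WindowParams",
    "DfcSeries",
    "count_windows",
    "sliding_window_fc",
    "vectorize_upper",
    "matrix_from_upper",
    "save_dfc",
    "load_dfc",
]


@dataclass(frozen=True)
class WindowParams:
    """Sliding-window parameters (units of TR)."""

    width_tr: int = 22
    step_tr: int = 1
    taper: str = "rectangular"  # or "gaussian"
    gaussian_sigma_tr: float | None = None
    #: Fisher r-to-z transform of window correlations (off by default:
    #: states are clustered on raw correlation matrices)
    fisher_z: bool = False
    #: linear detrend within each window (off by default)
    detrend: bool = False

    def __post_init__(self) -> None:
        if self.width_tr < 2:
            raise ValueError("window width must be >= 2 TR")
        if not 1 <= self.step_tr <= self.width_tr:
            raise ValueError("step must satisfy 1 <= step <= width")
        if self.taper not in ("rectangular", "gaussian"):
            raise ValueError("taper must be 'rectangular' or 'gaussian'")
        if self.taper == "gaussian" and not (
            self.gaussian_sigma_tr and self.gaussian_sigma_tr > 0
        ):
            raise ValueError("gaussian taper requires gaussian_sigma_tr > 0")

    def weights(self) -> np.ndarray:
        w = self.width_tr
        if self.taper == "rectangular":
            return np.ones(w)
        t = np.arange(w) - (w - 1) / 2.0
        return np.exp(-0.5 * (t / self.gaussian_sigma_tr) ** 2)


@dataclass
class DfcSeries:
    """Ordered windowed correlation matrices for one subject."""

    subject_id: str
    windows: np.ndarray  # (W, N, N)
    params: WindowParams
    window_starts: np.ndarray  # (W,) start volume of each window
    node_ids: tuple[str, ...] = ()
    n_zero_variance: int = 0

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.windows.shape[1]


def count_windows(n_volumes: int, width_tr: int, step_tr: int = 1) -> int:
    """Number of windows: W = floor((T - w) / s) + 1."""
    if width_tr > n_volumes:
        raise ValueError(
            f"window width {width_tr} exceeds series length {n_volumes}"
        )
    if step_tr < 1:
        raise ValueError("step must be >= 1")
    return (n_volumes - width_tr) // step_tr + 1


def _weighted_corr(X: np.ndarray, wts: np.ndarray) -> tuple[np.ndarray, int]:
    """Weighted Pearson correlation of columns; zero-variance columns get
    zero correlations (unit diagonal kept).  Returns (R, n_zero_cols)."""
    p = wts / wts.sum()
    mu = p @ X
    Xc = X - mu
    cov = (Xc * p[:, None]).T @ Xc
    var = np.diag(cov).copy()
    zero = var <= 1e-30
    sd = np.sqrt(np.where(zero, 1.0, var))
    R = cov / np.outer(sd, sd)
    if zero.any():
        R[zero, :] = 0.0
        R[:, zero] = 0.0
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return R, int(zero.sum())


def sliding_window_fc(
    ts: SubjectTimeSeries | np.ndarray,
    params: WindowParams = WindowParams(),
    subject_id: str | None = None,
) -> DfcSeries:
    """Windowed Pearson correlation matrices for one subject.

    Zero-variance columns within a window have their correlations set to 0
    (with a warning counter on the result) rather than aborting the subject.
    """
    if isinstance(ts, SubjectTimeSeries):
        data = ts.data
        sid = subject_id or ts.subject_id
        node_ids = tuple(ts.node_ids)
    else:
        data = np.asarray(ts, float)
        sid = subject_id or "subject"
        node_ids = tuple(f"node{j:03d}" for j in range(data.shape[1]))
    T = data.shape[0]
    w, s = params.width_tr, params.step_tr
    W = count_windows(T, w, s)
    wts = params.weights()
    out = np.empty((W, data.shape[1], data.shape[1]))
    starts = np.arange(W) * s
    n_zero = 0
    for j, start in enumerate(starts):
        X = data[start : start + w]
        if params.detrend:
            t = np.arange(w, dtype=float)
            t = (t - t.mean()) / t.std()
            X = X - np.outer(t, (t @ X) / w) - X.mean(axis=0)
        R, nz = _weighted_corr(X, wts)
        if params.fisher_z:
            R = np.arctanh(np.clip(R, -1 + 1e-15, 1 - 1e-15))
            np.fill_diagonal(R, 1.0)
        out[j] = R
        n_zero += nz
    if n_zero:
        warnings.warn(
            f"{sid}: {n_zero} zero-variance node-window(s); correlations set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return DfcSeries(
        subject_id=sid,
        windows=out,
        params=params,
        window_starts=starts,
        node_ids=node_ids,
        n_zero_variance=n_zero,
    )


# ---------------------------------------------------------------------------
# Upper-triangle vectorization
# ---------------------------------------------------------------------------


def vectorize_upper(matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Strict upper triangle in row-major order: length N(N-1)/2."""
    M = np.asarray(matrix, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("expected a square matrix")
    if np.max(np.abs(M - M.T)) > tol:
        raise ValueError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def matrix_from_upper(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; unit diagonal."""
    v = np.asarray(vector, float)
    m = len(v)
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise ValueError(f"vector length {m} is not N(N-1)/2 for integer N")
    M = np.eye(n)
    iu = np.triu_indices(n, k=1)
    M[iu] = v
    M[(iu[1], iu[0])] = v
    return M


# ---------------------------------------------------------------------------
# Persistence: compressed array container + JSON sidecar
# ---------------------------------------------------------------------------


def save_dfc(dfc: DfcSeries, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), windows=dfc.windows,
                        window_starts=dfc.window_starts)
    sidecar = {
        "subject_id": dfc.subject_id,
        "n_windows": dfc.n_windows,
        "n_nodes": dfc.n_nodes,
        "node_ids": list(dfc.node_ids),
        "n_zero_variance": dfc.n_zero_variance,
        "params": {
            "width_tr": dfc.params.width_tr,
            "step_tr": dfc.params.step_tr,
            "taper": dfc.params.taper,
            "gaussian_sigma_tr": dfc.params.gaussian_sigma_tr,
            "fisher_z": dfc.params.fisher_z,
            "detrend": dfc.params.detrend,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_dfc(path: str | Path) -> DfcSeries:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    params = WindowParams(**sidecar["params"])
    return DfcSeries(
        subject_id=sidecar["subject_id"],
        windows=arrays["windows"],
        params=params,
        window_starts=arrays["window_starts"],
        node_ids=tuple(sidecar["node_ids"]),
        n_zero_variance=sidecar["n_zero_variance"],
    )
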