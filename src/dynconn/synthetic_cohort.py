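"""Synthetic two-group cohorts with a planted connectivity-state process.

Each subject's BOLD matrix is a piecewise-stationary Gaussian process: a
latent state sequence follows a group-specific Markov chain at volume (TR)
resolution, and volume ``t`` is drawn from a zero-mean multivariate normal
with the covariance of the active state plus isotropic observation noise.

The default configuration plants the structure a sliding-window state
analysis assumes for a case-control psychosis cohort:

* two latent states — a hypoconnected state 1 (weak within-network
  coupling, negative coupling between the default-mode network and other
  networks) and a hyperconnected state 2 (strong, mostly positive coupling,
  strongest within and between sensorimotor and visual networks);
* patients persist longer in state 1 than controls (transition matrices
  are parameterized by the target stationary occupancy and mean dwell time
  of state 1, in volumes);
* one designated default-mode node carries a subject-specific dynamic
  range in patients: with planted variability v in [0, 1], the node's
  state-1 coupling profile is interpolated toward its strong state-2
  profile as v shrinks, so at v = 0 the node keeps its hub profile in
  both states (it is "locked in" and its graph metrics barely fluctuate)
  while at v = 1 it has the full between-state contrast.  Symptom
  severity scores are generated to correlate negatively with v.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .atlas_io import SubjectTimeSeries, write_cohort_metadata, write_timeseries_tsv

__all__ = [
    "StateStrength",
    "SynthConfig",
    "GroundTruth",
    "build_state_covariances",
    "transition_matrix_from_occupancy",
    "stationary_distribution",
    "simulate_subject",
    "simulate_cohort",
    "default_config",
    "write_cohort",
]

_EIG_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateStrength:
    """Target correlation levels for one latent state.

    ``within``/``between`` are the default within- and between-network
    correlations; ``blocks`` overrides specific (unordered) network pairs,
    e.g. ``{("DMN", "VN"): -0.2}``.  All targets must lie in (-1, 1).
    """

    within: float = 0.0
    between: float = 0.0
    blocks: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def level(self, net_a: str, net_b: str) -> float:
        for key in ((net_a, net_b), (net_b, net_a)):
            if key in self.blocks:
                return float(self.blocks[key])
        return float(self.within if net_a == net_b else self.between)


def _default_networks(n_nodes: int) -> list[str]:
    nets = ["DMN", "SMN_hand", "VN", "FPN"]
    return [nets[(j * len(nets)) // n_nodes] for j in range(n_nodes)]


#: Hypoconnected state: weak within-network coupling, negative DMN-other
#: and FPN-sensory coupling.
STATE1_STRENGTH = StateStrength(
    within=0.15,
    between=0.0,
    blocks={
        ("DMN", "SMN_hand"): -0.2,
        ("DMN", "VN"): -0.2,
        ("DMN", "FPN"): -0.2,
        ("FPN", "SMN_hand"): -0.15,
        ("FPN", "VN"): -0.15,
    },
)

#: Hyperconnected state: strong mostly-positive coupling, strongest within
#: and between sensorimotor and visual networks.
STATE2_STRENGTH = StateStrength(
    within=0.5,
    between=0.25,
    blocks={
        ("SMN_hand", "SMN_hand"): 0.6,
        ("VN", "VN"): 0.6,
        ("SMN_hand", "VN"): 0.5,
    },
)


def transition_matrix_from_occupancy(occupancy_state1: float, dwell_state1: float) -> np.ndarray:
    """2-state row-stochastic matrix with the given stationary occupancy of
    state 1 and its mean dwell time (volumes).

    For a 2-state chain, mean dwell of state 1 is 1/p12 and the stationary
    occupancy is p21/(p12+p21).
    """
    if not 0 < occupancy_state1 < 1:
        raise ValueError("occupancy must be in (0, 1)")
    if dwell_state1 <= 1:
        raise ValueError("mean dwell must exceed 1 volume")
    p12 = 1.0 / dwell_state1
    p21 = p12 * occupancy_state1 / (1.0 - occupancy_state1)
    if p21 >= 1:
        raise ValueError("infeasible occupancy/dwell combination (p21 >= 1)")
    return np.array([[1 - p12, p12], [p21, 1 - p21]])


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults define the study conditions."""

    n_patients: int = 20
    n_controls: int = 20
    n_nodes: int = 20
    network_assignment: tuple[str, ...] | None = None
    n_volumes: int = 190
    tr_seconds: float = 2.0
    state_strengths: tuple[StateStrength, ...] = (STATE1_STRENGTH, STATE2_STRENGTH)
    #: per-group k x k row-stochastic transition matrices (volume resolution)
    transition_matrix_by_group: Mapping[str, np.ndarray] | None = None
    #: target Pearson/Spearman correlation between symptom severity and the
    #: designated node's planted variability (negative in the study pattern)
    symptom_effect: float = -0.5
    #: index of the designated symptom-linked (default-mode) node
    symptom_node: int = 0
    #: range of the per-patient state contrast v of the designated node;
    #: controls always have v = 1 (full contrast)
    node_contrast_range: tuple[float, float] = (0.0, 1.0)
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ValueError("need at least 4 nodes")
        if self.network_assignment is None:
            object.__setattr__(
                self, "network_assignment", tuple(_default_networks(self.n_nodes))
            )
        if len(self.network_assignment) != self.n_nodes:
            raise ValueError("network_assignment length must equal n_nodes")
        if self.transition_matrix_by_group is None:
            # Patients: higher state-1 occupancy (0.756) and dwell (61.5
            # volumes) than controls (0.672, 41.0) — the planted group effect.
            object.__setattr__(
                self,
                "transition_matrix_by_group",
                {
                    "patient": transition_matrix_from_occupancy(0.756, 61.5),
                    "control": transition_matrix_from_occupancy(0.672, 41.0),
                },
            )
        k = len(self.state_strengths)
        for g, P in self.transition_matrix_by_group.items():
            P = np.asarray(P, float)
            if P.shape != (k, k):
                raise ValueError(f"transition matrix for '{g}' must be {k}x{k}")
            if np.any(P < 0) or np.max(np.abs(P.sum(axis=1) - 1)) > 1e-12:
                raise ValueError(f"transition matrix for '{g}' is not row-stochastic")
        if not 0 <= self.symptom_node < self.n_nodes:
            raise ValueError("symptom_node out of range")
        if not -1 < self.symptom_effect < 1:
            raise ValueError("symptom_effect must be in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_states(self) -> int:
        return len(self.state_strengths)

    def state_covariances(self) -> list[np.ndarray]:
        return build_state_covariances(
            self.n_nodes, self.network_assignment, self.state_strengths
        )


def default_config(**overrides) -> SynthConfig:
    """The default study conditions, with keyword overrides."""
    return SynthConfig(**overrides)


@dataclass
class GroundTruth:
    """Planted quantities recorded for parameter-recovery checks."""

    state_sequences: dict[str, np.ndarray]
    group_by_subject: dict[str, str]
    stationary_by_group: dict[str, np.ndarray]
    symptom_node: int
    #: per-patient planted nodal variability (the node's state contrast v)
    node_variability: dict[str, float]
    #: planted effect sizes: per-state difference in stationary occupancy
    #: (patient minus control)
    occupancy_effect: np.ndarray
    seed: int

    def occupancy(self, subject_id: str) -> np.ndarray:
        """Empirical per-state fraction of volumes for one subject."""
        seq = self.state_sequences[subject_id]
        k = len(self.occupancy_effect)
        return np.array([(seq == s).mean() for s in range(1, k + 1)])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "state_sequences": {k: v.tolist() for k, v in self.state_sequences.items()},
            "group_by_subject": self.group_by_subject,
            "stationary_by_group": {
                k: v.tolist() for k, v in self.stationary_by_group.items()
            },
            "symptom_node": self.symptom_node,
            "node_variability": self.node_variability,
            "occupancy_effect": self.occupancy_effect.tolist(),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Covariance construction
# ---------------------------------------------------------------------------


def build_state_covariances(
    n_nodes: int,
    network_assignment: Sequence[str],
    strength_params: Sequence[StateStrength],
) -> list[np.ndarray]:
    """Block-structured correlation matrices, one per latent state.

    Off-diagonal targets are set per network pair; the matrix is then
    repaired to be positive-definite by diagonal loading (smallest
    eigenvalue floored at 1e-6) and rescaled to unit diagonal, which
    preserves the block structure up to a uniform shrinkage.
    """
    if len(network_assignment) != n_nodes:
        raise ValueError("network_assignment length must equal n_nodes")
    nets = [str(n) for n in network_assignment]
    covs = []
    for s, strength in enumerate(strength_params):
        C = np.eye(n_nodes)
        for a in range(n_nodes):
            for b in range(a + 1, n_nodes):
                rho = strength.level(nets[a], nets[b])
                if not -1 < rho < 1:
                    raise ValueError(
                        f"state {s + 1}: correlation target {rho} for block "
                        f"({nets[a]}, {nets[b]}) outside (-1, 1)"
                    )
                C[a, b] = C[b, a] = rho
        covs.append(_repair_pd(C, state_index=s, networks=nets, strength=strength))
    return covs


def _repair_pd(
    C: np.ndarray, state_index: int, networks: Sequence[str], strength: StateStrength
) -> np.ndarray:
    eigmin = float(np.linalg.eigvalsh(C).min())
    if eigmin >= _EIG_FLOOR:
        return C
    # (C + lam*I) / (1 + lam) keeps unit diagonal; eigenvalues map to
    # (e + lam) / (1 + lam) >= floor for the loading below.
    lam = (_EIG_FLOOR - eigmin) / (1.0 - _EIG_FLOOR)
    shrink = 1.0 / (1.0 + lam)
    if shrink < 0.5:
        offenders = {
            (a, b): v
            for (a, b), v in strength.blocks.items()
        } or {"within": strength.within, "between": strength.between}
        raise ValueError(
            f"state {state_index + 1}: correlation structure not repairable "
            f"to positive-definite without distorting targets by more than "
            f"50% (smallest eigenvalue {eigmin:.3g}); offending block "
            f"targets: {offenders}"
        )
    out = shrink * C + (1 - shrink) * np.eye(C.shape[0])
    return out


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left Perron
    eigenvector, normalized to sum 1)."""
    P = np.asarray(P, float)
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _simulate_chain(P: np.ndarray, T: int, rng: np.random.Generator) -> np.ndarray:
    """Latent state sequence (labels 1..k), started from the stationary
    distribution."""
    pi = stationary_distribution(P)
    k = P.shape[0]
    states = np.empty(T, dtype=int)
    cum = np.cumsum(P, axis=1)
    states[0] = rng.choice(k, p=pi)
    u = rng.random(T - 1)
    for t in range(1, T):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t - 1], side="right")
    return states + 1


def _mix_node_profile(
    C_base: np.ndarray, C_ref: np.ndarray, node: int, contrast: float
) -> np.ndarray:
    """Interpolate one node's coupling row in ``C_base`` toward its row in
    ``C_ref``: contrast 1 leaves ``C_base`` unchanged, contrast 0 gives
    the node its ``C_ref`` profile.  Repaired to positive-definite by
    diagonal loading when the row edit breaks it."""
    out = C_base.copy()
    row = contrast * C_base[node, :] + (1.0 - contrast) * C_ref[node, :]
    out[node, :] = row
    out[:, node] = row
    np.fill_diagonal(out, np.diag(C_base))
    eigmin = float(np.linalg.eigvalsh(out).min())
    if eigmin < _EIG_FLOOR:
        lam = (_EIG_FLOOR - eigmin) / (1.0 - _EIG_FLOOR)
        out = (out + lam * np.eye(out.shape[0])) / (1.0 + lam)
    return out


def simulate_subject(
    config: SynthConfig,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "sub-000",
    node_contrast: float = 1.0,
) -> tuple[SubjectTimeSeries, np.ndarray]:
    """One subject's T x N matrix and the latent state sequence (1..k).

    ``node_contrast`` < 1 pulls the designated node's hypoconnected-state
    coupling profile toward its hyperconnected-state profile, shrinking
    that node's dynamic range (requires at least 2 states).
    """
    if group not in config.transition_matrix_by_group:
        raise ValueError(f"unknown group '{group}'")
    P = np.asarray(config.transition_matrix_by_group[group], float)
    T, N = config.n_volumes, config.n_nodes
    states = _simulate_chain(P, T, rng)

    covs = config.state_covariances()
    if node_contrast != 1.0 and len(covs) >= 2:
        covs = [
            _mix_node_profile(covs[0], covs[1], config.symptom_node, node_contrast)
        ] + covs[1:]
    chols = [np.linalg.cholesky(C) for C in covs]
    z = rng.standard_normal((T, N))
    data = np.empty((T, N))
    for s in range(config.n_states):
        mask = states == s + 1
        if mask.any():
            data[mask] = z[mask] @ chols[s].T
    if config.noise_sd > 0:
        data = data + config.noise_sd * rng.standard_normal((T, N))

    ts = SubjectTimeSeries(
        subject_id=subject_id,
        data=data,
        node_ids=[f"node{j:03d}" for j in range(N)],
        group=group,
        tr_seconds=config.tr_seconds,
    )
    return ts, states


def _symptom_scores(
    variability: np.ndarray, effect: float, rng: np.random.Generator
) -> np.ndarray:
    """Standardized severity scores with target correlation ``effect`` to
    the planted variability.

    Uses a linear-in-rank link: the variability is rank-transformed before
    mixing, so the Spearman and Pearson correlations agree in expectation.
    """
    n = len(variability)
    if n == 0:
        return np.empty(0)
    from scipy.stats import rankdata

    r = rankdata(variability)
    zx = (r - r.mean()) / (r.std() if r.std() > 0 else 1.0)
    noise = rng.standard_normal(n)
    if n > 1 and noise.std() > 0:
        noise = (noise - noise.mean()) / noise.std()
    return effect * zx + np.sqrt(1.0 - effect**2) * noise


def simulate_cohort(
    config: SynthConfig,
) -> tuple[list[SubjectTimeSeries], GroundTruth]:
    """Full two-group cohort; bit-reproducible given (config, config.seed)."""
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectTimeSeries] = []
    sequences: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    gains: dict[str, float] = {}

    lo, hi = config.node_contrast_range
    plan = [("patient", i) for i in range(config.n_patients)] + [
        ("control", i) for i in range(config.n_controls)
    ]
    patient_ids: list[str] = []
    for group, i in plan:
        sid = f"sub-{'P' if group == 'patient' else 'C'}{i:03d}"
        gain = float(rng.uniform(lo, hi)) if group == "patient" else 1.0
        ts, states = simulate_subject(
            config, group, rng, subject_id=sid, node_contrast=gain
        )
        ts.covariates = {
            "age": float(np.clip(rng.normal(25.0, 7.4), 18, 50)),
            "sex": int(rng.integers(0, 2)),
            "education": float(np.clip(rng.normal(12.9, 3.0), 6, 22)),
        }
        subjects.append(ts)
        sequences[sid] = states
        groups[sid] = group
        if group == "patient":
            gains[sid] = gain
            patient_ids.append(sid)

    # PANSS ratings for patients: severity correlates (negatively, by
    # default) with the planted nodal variability.
    var = np.array([gains[s] for s in patient_ids])
    z = _symptom_scores(var, config.symptom_effect, rng)
    panss_scale = {"total": (89.1, 16.8), "positive": (25.6, 6.4),
                   "negative": (17.6, 7.6), "general": (45.9, 10.0)}
    for sid, zi in zip(patient_ids, z):
        ts = next(t for t in subjects if t.subject_id == sid)
        ts.panss = {
            name: float(mu + sd * zi) for name, (mu, sd) in panss_scale.items()
        }

    pi_by_group = {
        g: stationary_distribution(P)
        for g, P in config.transition_matrix_by_group.items()
    }
    occ_effect = pi_by_group["patient"] - pi_by_group["control"]
    gt = GroundTruth(
        state_sequences=sequences,
        group_by_subject=groups,
        stationary_by_group=pi_by_group,
        symptom_node=config.symptom_node,
        node_variability=gains,
        occupancy_effect=occ_effect,
        seed=config.seed,
    )
    return subjects, gt


# ---------------------------------------------------------------------------
# Cohort export
# ---------------------------------------------------------------------------


def write_cohort(
    subjects: Sequence[SubjectTimeSeries],
    ground_truth: GroundTruth,
    out_dir: str | Path,
) -> None:
    """One TSV per subject, a cohort metadata TSV, and a ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ts in subjects:
        write_timeseries_tsv(ts, out / f"{ts.subject_id}_timeseries.tsv")
    write_cohort_metadata(subjects, out / "cohort_metadata.tsv")
    ground_truth.to_json(out / "ground_truth.json")
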