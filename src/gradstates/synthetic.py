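"""Synthetic multi-subject parcellated BOLD cohorts with known ground truth.

The generative model plants, by construction, every structure the analysis
pipeline is meant to recover:

* a latent 1-D connectivity hierarchy ``g`` in [-1, 1] (unimodal ->
  transmodal axis): baseline parcel-parcel coupling decays with distance
  along the axis, with an extra within-network block elevation;
* ``K`` recurrent connectivity states: each state adds a rank-one
  network-level coupling mode (a tapered Hadamard sign pattern) to the
  baseline covariance, and subjects switch states according to a per-group
  Markov chain simulated at epoch (not timepoint) resolution so dwell
  structure survives sliding-window estimation;
* group effects: target parcels of one group are re-wired toward the
  opposite end of the axis, shifting their emergent gradient scores;
* clinical covariates linearly linked (plus noise) to a per-subject
  severity scalar that scales the planted re-wiring.

Every stochastic draw flows from a single seed, so cohorts are reproducible
bit-for-bit. Analytic expectations (stationary occupancy, mean dwell) are
provided for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .prep import CANONICAL_NETWORKS, ParcelTimeSeries, write_parcel_timeseries

_GROUPS = ("HC", "AD")

# Baseline covariance structure: coupling decays with distance along the
# latent axis; the within-network elevation is kept small so the smooth
# axis, not network-block membership, dominates the leading gradient.
_AXIS_GAIN = 0.55
_AXIS_LENGTH = 0.75
_NETWORK_BLOCK = 0.10
_PSD_FLOOR = 1e-8

# Recurrent states are rank-one network-level coupling modes: state k adds
# _STATE_COUPLING * v_k v_k^T to the baseline, where v_k is a +-1 Hadamard
# sign pattern over the 7 networks, tapered to zero at network boundaries
# so the local (axis-neighbour) couplings that carry the gradient are left
# untouched. The construction is positive semi-definite without repair and
# every pair of states is separated by the same large block signature.
_STATE_COUPLING = 0.6
_DEFAULT_STICKINESS = 0.6  # fast mixing: states average out over a scan


def default_network_labels(n_parcels: int) -> tuple[str, ...]:
    """Assign the seven canonical networks to contiguous parcel blocks."""
    edges = np.linspace(0, n_parcels, len(CANONICAL_NETWORKS) + 1).astype(int)
    labels = []
    for i, name in enumerate(CANONICAL_NETWORKS):
        labels.extend([name] * (edges[i + 1] - edges[i]))
    return tuple(labels)


def sticky_transition_matrix(stationary: np.ndarray,
                             stickiness: float = _DEFAULT_STICKINESS
                             ) -> np.ndarray:
    """Row-stochastic chain ``(1-s)*I + s*1 pi^T`` with stationary ``pi``.

    ``stickiness`` is the self-coupling weight ``1 - s``; larger values give
    longer dwells. The stationary distribution is exactly ``stationary``.
    """
    pi = np.asarray(stationary, dtype=float)
    if pi.ndim != 1 or abs(pi.sum() - 1) > 1e-10 or (pi < 0).any():
        raise ValueError("stationary must be a probability vector")
    if not 0 <= stickiness < 1:
        raise ValueError("stickiness must be in [0, 1)")
    k = len(pi)
    return stickiness * np.eye(k) + (1 - stickiness) * np.tile(pi, (k, 1))


@dataclass
class EffectSpec:
    """Planted group effect: re-wire ``parcels`` of ``group`` toward the
    opposite end of the latent axis with blend weight ``magnitude``."""

    parcels: tuple[int, ...]
    magnitude: float
    group: str = "AD"


@dataclass
class CovariateSpec:
    """Clinical covariate linearly linked to a planted per-subject feature.

    ``feature`` currently supports ``"severity"`` (the subject's planted
    effect multiplier). The covariate is ``slope * feature + N(0, noise_sd)``.
    """

    name: str
    feature: str = "severity"
    slope: float = 1.0
    noise_sd: float = 0.1


@dataclass
class SyntheticCohortConfig:
    """Full generative specification for one synthetic cohort."""

    n_per_group: int = 20
    n_parcels: int = 60
    network_labels: tuple[str, ...] | None = None
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    n_states: int = 4
    state_signatures: np.ndarray | None = None  # K x 7 network sign patterns
    transition_matrices: dict[str, np.ndarray] | None = None
    latent_axis: np.ndarray | None = None
    effect_spec: tuple[EffectSpec, ...] = ()
    covariate_spec: tuple[CovariateSpec, ...] = ()
    ar1_coefficient: float = 0.2
    noise_sd: float = 0.25
    epoch_length: int = 10
    min_window_length: int = 50  # downstream sliding-window length guard
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parcels < 10:
            raise ValueError("n_parcels must be at least 10")
        if self.n_states < 1:
            raise ValueError("n_states must be at least 1")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must be in [0, 1)")
        if self.n_timepoints <= self.min_window_length:
            raise ValueError(
                f"n_timepoints ({self.n_timepoints}) must exceed the "
                f"sliding-window length used downstream ({self.min_window_length})"
            )
        if self.network_labels is None:
            self.network_labels = default_network_labels(self.n_parcels)
        if len(self.network_labels) != self.n_parcels:
            raise ValueError("network_labels length must equal n_parcels")
        unknown = set(self.network_labels) - set(CANONICAL_NETWORKS)
        if unknown:
            raise ValueError(f"unknown network name(s): {sorted(unknown)}")
        if self.latent_axis is None:
            self.latent_axis = np.linspace(-1.0, 1.0, self.n_parcels)
        self.latent_axis = np.asarray(self.latent_axis, dtype=float)
        if self.latent_axis.shape != (self.n_parcels,):
            raise ValueError("latent_axis must have one value per parcel")
        if self.transition_matrices is None:
            uniform = np.full(self.n_states, 1.0 / self.n_states)
            tm = sticky_transition_matrix(uniform)
            self.transition_matrices = {g: tm.copy() for g in _GROUPS}
        for g, tm in self.transition_matrices.items():
            _validate_transition_matrix(np.asarray(tm, float), self.n_states, g)
        for eff in self.effect_spec:
            bad = [p for p in eff.parcels if not 0 <= p < self.n_parcels]
            if bad:
                raise ValueError(f"effect parcels out of range: {bad}")
            if eff.group not in self.transition_matrices:
                raise ValueError(f"effect group {eff.group!r} not a cohort group")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.transition_matrices)


@dataclass
class GroundTruth:
    """Planted truth for parameter-recovery tests."""

    epoch_labels: dict[str, np.ndarray]       # subject -> per-epoch state
    timepoint_labels: dict[str, np.ndarray]   # subject -> per-TR state
    stationary: dict[str, np.ndarray]         # group -> pi
    expected_dwell: dict[str, np.ndarray]     # group -> 1/(1-p_ss), chain steps
    gradient_offsets: list[dict]              # echoed effect spec + severities
    covariate_links: list[dict]               # echoed covariate spec
    latent_axis: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_json(self, path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, (np.integer,)):
                return int(x)
            if isinstance(x, (np.floating,)):
                return float(x)
            return x

        payload = {
            "epoch_labels": conv(self.epoch_labels),
            "timepoint_labels": conv(self.timepoint_labels),
            "stationary": conv(self.stationary),
            "expected_dwell": conv(self.expected_dwell),
            "gradient_offsets": conv(self.gradient_offsets),
            "covariate_links": conv(self.covariate_links),
            "latent_axis": conv(self.latent_axis),
        }
        Path(path).write_text(json.dumps(payload))


def _validate_transition_matrix(tm: np.ndarray, k: int, name: str = "") -> None:
    if tm.shape != (k, k):
        raise ValueError(f"transition matrix {name} must be {k}x{k}, got {tm.shape}")
    if (tm < -1e-12).any():
        raise ValueError(f"transition matrix {name} has negative entries")
    if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError(f"transition matrix {name} rows must sum to 1")


def _floor_psd(mat: np.ndarray, floor: float = _PSD_FLOOR) -> np.ndarray:
    """Symmetrize and clip eigenvalues at ``floor``."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.maximum(vals, floor)
    out = (vecs * vals) @ vecs.T
    out = (out + out.T) / 2.0
    if np.linalg.eigvalsh(out).min() < -1e-10:
        raise ValueError("covariance not positive semi-definite after flooring")
    return out


def default_state_signatures(n_states: int) -> np.ndarray:
    """K x 7 network-level sign patterns (Hadamard codewords).

    Rows 1..K of the order-8 Hadamard matrix, truncated to the 7 canonical
    networks: every pair of states disagrees on about half the networks, so
    all pairwise state separations are comparable. Supports K <= 7.
    """
    if n_states > 7:
        raise ValueError("default signatures support at most 7 states")
    from scipy.linalg import hadamard
    return hadamard(8)[1: n_states + 1, :7].astype(float)


def _boundary_taper(net_idx: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Per-parcel triangular weight: 0 at a network's boundary parcels,
    1 at its centre (ordered along the latent axis)."""
    w = np.zeros(len(net_idx), dtype=float)
    for nid in np.unique(net_idx):
        idx = np.where(net_idx == nid)[0]
        idx = idx[np.argsort(g[idx])]
        m = len(idx)
        pos = (np.arange(m) + 0.5) / m
        w[idx] = 1.0 - np.abs(2.0 * pos - 1.0)
    return w


def build_generative_model(config: SyntheticCohortConfig
                           ) -> tuple[list[np.ndarray], np.ndarray]:
    """Construct the K state covariance matrices and the latent axis.

    The baseline covariance decays with axis distance ``|g_p - g_q|`` plus
    a within-network elevation. State k adds the rank-one coupling mode
    ``_STATE_COUPLING * v v^T`` with ``v`` its network sign pattern tapered
    to zero at block boundaries, and the result is renormalized to unit
    variance (a congruence, so positive semi-definiteness is preserved;
    the eigenvalue floor is a guard, not a repair step).
    """
    g = config.latent_axis
    net_idx = np.array([CANONICAL_NETWORKS.index(n) for n in config.network_labels])
    dist = np.abs(g[:, None] - g[None, :])
    base = _AXIS_GAIN * np.exp(-dist / _AXIS_LENGTH)
    base = base + _NETWORK_BLOCK * (net_idx[:, None] == net_idx[None, :])
    np.fill_diagonal(base, 1.0)

    sigs = config.state_signatures
    if sigs is None:
        sigs = default_state_signatures(config.n_states)
    sigs = np.asarray(sigs, dtype=float)
    if sigs.shape != (config.n_states, len(CANONICAL_NETWORKS)):
        raise ValueError(
            f"state_signatures must be ({config.n_states}, 7), got {sigs.shape}"
        )

    taper = _boundary_taper(net_idx, g)
    covs = []
    for k in range(config.n_states):
        v = sigs[k][net_idx] * taper
        cov = base + _STATE_COUPLING * np.outer(v, v)
        scale = np.sqrt(1.0 + _STATE_COUPLING * v**2)
        cov = cov / np.outer(scale, scale)
        np.fill_diagonal(cov, 1.0)
        covs.append(_floor_psd(cov))
    return covs, g


def apply_axis_rewiring(covs: list[np.ndarray], latent_axis: np.ndarray,
                        parcels, magnitude: float) -> list[np.ndarray]:
    """Blend target parcels' coupling profiles toward the parcel at the
    opposite axis extreme (weight ``magnitude`` in [0, 1])."""
    if not 0 <= magnitude <= 1:
        raise ValueError("rewiring magnitude must be in [0, 1]")
    lo, hi = int(np.argmin(latent_axis)), int(np.argmax(latent_axis))
    out = []
    for cov in covs:
        new = cov.copy()
        for p in parcels:
            opp = lo if latent_axis[p] > 0 else hi
            row = (1 - magnitude) * cov[p, :] + magnitude * cov[opp, :]
            new[p, :] = row
            new[:, p] = row
            new[p, p] = cov[p, p]
        out.append(_floor_psd(new))
    return out


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Solve pi T = pi with sum(pi) = 1."""
    tm = np.asarray(transition_matrix, dtype=float)
    _validate_transition_matrix(tm, tm.shape[0])
    k = tm.shape[0]
    a = np.vstack([tm.T - np.eye(k), np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def analytic_expectations(transition_matrix: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Stationary occupancy and expected dwell (chain steps) per state.

    Dwell of state ``s`` is ``1/(1 - p_ss)``; an absorbing state
    (``p_ss = 1``) is flagged unbounded with ``inf``.
    """
    tm = np.asarray(transition_matrix, dtype=float)
    pi = stationary_distribution(tm)
    p_stay = np.diag(tm)
    with np.errstate(divide="ignore"):
        dwell = np.where(p_stay >= 1 - 1e-15, np.inf, 1.0 / (1.0 - p_stay))
    return pi, dwell


def simulate_state_sequence(transition_matrix: np.ndarray, n_steps: int,
                            seed: int | np.random.Generator) -> np.ndarray:
    """Simulate a Markov chain started from its stationary distribution."""
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    tm = np.asarray(transition_matrix, dtype=float)
    _validate_transition_matrix(tm, tm.shape[0])
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pi = stationary_distribution(tm)
    labels = np.empty(n_steps, dtype=int)
    labels[0] = rng.choice(tm.shape[0], p=pi)
    cum = np.cumsum(tm, axis=1)
    u = rng.random(n_steps - 1)
    for t in range(1, n_steps):
        labels[t] = np.searchsorted(cum[labels[t - 1]], u[t - 1], side="right")
    return labels


def simulate_subject(config: SyntheticCohortConfig, group: str,
                     seed: int | np.random.Generator,
                     state_covs: list[np.ndarray] | None = None,
                     subject_id: str = "sub",
                     ) -> tuple[ParcelTimeSeries, np.ndarray]:
    """Simulate one subject; returns the series and per-timepoint true state.

    States switch at epoch resolution (``config.epoch_length`` timepoints);
    within an epoch, timepoints are i.i.d. draws from the active state's
    zero-mean multivariate normal, then AR(1)-smoothed (variance-preserving)
    and corrupted with white noise of sd ``config.noise_sd``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if state_covs is None:
        state_covs, _ = build_generative_model(config)
    chols = []
    for k, cov in enumerate(state_covs):
        try:
            chols.append(np.linalg.cholesky(cov + 1e-9 * np.eye(cov.shape[0])))
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"cannot sample from state {k} covariance") from exc

    T, P = config.n_timepoints, config.n_parcels
    n_epochs = -(-T // config.epoch_length)
    epoch_labels = simulate_state_sequence(
        config.transition_matrices[group], n_epochs, rng
    )
    tp_labels = np.repeat(epoch_labels, config.epoch_length)[:T]

    innov = rng.standard_normal((T, P))
    raw = np.empty((T, P))
    for k in range(len(state_covs)):
        mask = tp_labels == k
        if mask.any():
            raw[mask] = innov[mask] @ chols[k].T

    phi = config.ar1_coefficient
    if phi > 0:
        scale = np.sqrt(1 - phi**2)
        smooth = np.empty_like(raw)
        smooth[0] = raw[0]
        for t in range(1, T):
            smooth[t] = phi * smooth[t - 1] + scale * raw[t]
        raw = smooth
    if config.noise_sd > 0:
        raw = raw + config.noise_sd * rng.standard_normal((T, P))

    parcels = pd.DataFrame({
        "parcel_id": [f"p{i:03d}" for i in range(P)],
        "network": list(config.network_labels),
    })
    ts = ParcelTimeSeries(subject_id=subject_id, data=raw,
                          tr_seconds=config.tr_seconds, parcels=parcels)
    return ts, tp_labels


def simulate_cohort(config: SyntheticCohortConfig
                    ) -> tuple[list[ParcelTimeSeries], pd.DataFrame, GroundTruth]:
    """Simulate the full cohort: series, subject table, and ground truth.

    Subjects of a group named in ``effect_spec`` have their state
    covariances re-wired (axis-opposite blending scaled by a per-subject
    severity around 1); covariates are linear in severity plus noise. Age
    and sex are drawn independently of group (matched design).
    """
    rng = np.random.default_rng(config.seed)
    base_covs, g = build_generative_model(config)

    series: list[ParcelTimeSeries] = []
    rows = []
    epoch_labels: dict[str, np.ndarray] = {}
    tp_labels: dict[str, np.ndarray] = {}
    offsets: list[dict] = []

    for group in config.groups:
        effects = [e for e in config.effect_spec if e.group == group]
        for i in range(config.n_per_group):
            sid = f"{group}{i:03d}"
            severity = float(rng.normal(1.0, 0.15)) if effects else 0.0
            covs = base_covs
            for eff in effects:
                covs = apply_axis_rewiring(
                    covs, g, eff.parcels,
                    float(np.clip(eff.magnitude * severity, 0.0, 1.0)),
                )
                offsets.append({"subject_id": sid, "parcels": list(eff.parcels),
                                "magnitude": eff.magnitude, "severity": severity})
            ts, labels = simulate_subject(config, group, rng, state_covs=covs,
                                          subject_id=sid)
            series.append(ts)
            tp_labels[sid] = labels
            epoch_labels[sid] = labels[::config.epoch_length]
            row = {"subject_id": sid, "group": group,
                   "age": float(np.round(rng.uniform(55, 85), 1)),
                   "sex": "F" if rng.random() < 0.5 else "M",
                   "severity": severity}
            for cov_spec in config.covariate_spec:
                if cov_spec.feature != "severity":
                    raise ValueError(
                        f"unsupported covariate feature {cov_spec.feature!r}"
                    )
                row[cov_spec.name] = (cov_spec.slope * severity
                                      + cov_spec.noise_sd * rng.standard_normal())
            rows.append(row)

    subjects = pd.DataFrame(rows)
    stationary = {}
    dwell = {}
    for group, tm in config.transition_matrices.items():
        pi, dw = analytic_expectations(tm)
        stationary[group] = pi
        dwell[group] = dw
    truth = GroundTruth(
        epoch_labels=epoch_labels, timepoint_labels=tp_labels,
        stationary=stationary, expected_dwell=dwell,
        gradient_offsets=offsets,
        covariate_links=[vars(c).copy() for c in config.covariate_spec],
        latent_axis=g.copy(),
    )
    return series, subjects, truth


def true_window_labels(timepoint_labels: np.ndarray, length: int,
                       step: int = 1) -> np.ndarray:
    """Ground-truth label per sliding window: the state occupying the
    majority of the window's timepoints (earliest state on ties)."""
    labels = np.asarray(timepoint_labels)
    T = len(labels)
    n_win = (T - length) // step + 1
    out = np.empty(n_win, dtype=int)
    for w in range(n_win):
        seg = labels[w * step: w * step + length]
        vals, counts = np.unique(seg, return_counts=True)
        out[w] = vals[np.argmax(counts)]
    return out


def write_cohort(series: list[ParcelTimeSeries], subjects: pd.DataFrame,
                 truth: GroundTruth, out_dir) -> None:
    """Write one TSV per subject, parcel metadata TSV, subjects TSV, and
    ground-truth JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ts in series:
        write_parcel_timeseries(ts, out / f"{ts.subject_id}_timeseries.tsv")
    meta = series[0].parcels.copy()
    for col in ("x", "y", "z"):
        if col not in meta.columns:
            meta[col] = 0.0
    meta.to_csv(out / "parcels.tsv", sep="\t", index=False)
    subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
    truth.to_json(out / "ground_truth.json")
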