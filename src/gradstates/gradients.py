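"""Functional-connectivity gradients via diffusion map embedding.

The pipeline follows the standard gradient-mapping recipe: Pearson
connectivity (optionally Fisher r-to-z), row-sparsified cosine-similarity
affinity, anisotropic diffusion-map embedding of the resulting Markov
operator (anisotropy exponent ``alpha``, diffusion time ``t``), Procrustes
alignment of individual embeddings to a group template, per-component
z-scoring, and network centroid dispersion in the aligned gradient space.

Units of analysis are parcels. ``network_profile_matrix`` supports the
per-network mode (units = parcels of one network, profiles against all
parcels); the whole-cortex mode simply uses the full connectivity matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from .prep import CANONICAL_NETWORKS, ParcelTimeSeries


@dataclass
class ConnectivityMatrix:
    """Parcel x parcel connectivity, either raw Pearson r or Fisher z."""

    values: np.ndarray
    kind: str  # "pearson_r" | "fisher_z"
    parcel_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if np.abs(v - v.T).max() > 1e-10:
            raise ValueError("connectivity matrix must be symmetric")
        if self.kind == "pearson_r":
            if np.abs(np.diag(v) - 1).max() > 1e-10:
                raise ValueError("pearson_r diagonal must be 1")
            if np.abs(v).max() > 1 + 1e-10:
                raise ValueError("|r| must be <= 1")
        elif self.kind != "fisher_z":
            raise ValueError(f"unknown kind {self.kind!r}")
        self.values = v


@dataclass
class EmbeddingConfig:
    """Diffusion-embedding parameters.

    ``alpha`` = 0.5 balances local and global geometry; ``diffusion_time``
    0 leaves components unscaled by eigenvalue powers; ``row_sparsity`` is
    the fraction of strongest profile entries retained per row before
    cosine similarity.
    """

    alpha: float = 0.5
    diffusion_time: int = 0
    n_components: int = 10
    row_sparsity: float = 0.10

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.diffusion_time < 0:
            raise ValueError("diffusion_time must be >= 0")
        if not 0 < self.row_sparsity <= 1:
            raise ValueError("row_sparsity must be in (0, 1]")


@dataclass
class GradientEmbedding:
    """Eigenvector components (units x n_components) with eigenvalues."""

    components: np.ndarray
    eigenvalues: np.ndarray
    unit_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lam = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(lam) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")
        self.eigenvalues = lam
        self.components = np.asarray(self.components, dtype=float)

    @property
    def variance_explained(self) -> np.ndarray:
        lam2 = self.eigenvalues**2
        return lam2 / lam2.sum()


@dataclass
class DispersionSummary:
    """Within-network dispersion and between-network centroid distances."""

    networks: list[str]
    within: dict[str, float]
    between: pd.DataFrame  # symmetric, zero diagonal
    centroids: dict[str, np.ndarray]


def compute_fc(ts: ParcelTimeSeries, fisher: bool = False) -> ConnectivityMatrix:
    """Pairwise Pearson connectivity; Fisher z = atanh(r) with zero diagonal.

    Off-diagonal r is clipped to ``1 - 1e-7`` in magnitude before atanh so
    duplicated parcels do not produce infinities.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    sd = ts.data.std(axis=0)
    if (sd < 1e-14).any():
        bad = ts.parcel_ids[int(np.argmin(sd))]
        raise ValueError(f"constant parcel time series: {bad}")
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    if not fisher:
        return ConnectivityMatrix(r, "pearson_r", ts.parcel_ids)
    z = np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, "fisher_z", ts.parcel_ids)


def network_profile_matrix(ts: ParcelTimeSeries, network: str) -> np.ndarray:
    """Connectivity profiles of one network's parcels against all parcels.

    Rows are the network's parcels, columns all parcels, values Fisher z.
    Each row's self-connectivity entry is set to 0 (self-column excluded
    from the similarity computation).
    """
    if network not in CANONICAL_NETWORKS:
        raise ValueError(f"unknown network {network!r}")
    members = np.where(ts.networks == network)[0]
    if len(members) < 5:
        raise ValueError(
            f"network {network!r} has {len(members)} parcels; need at least 5"
        )
    z = compute_fc(ts, fisher=True).values
    return z[members, :]


def whole_cortex_profiles(ts: ParcelTimeSeries) -> np.ndarray:
    """Whole-cortex mode: full Fisher-z matrix (diagonal 0) as profiles."""
    return compute_fc(ts, fisher=True).values


def cosine_affinity(profiles: np.ndarray,
                    config: EmbeddingConfig | None = None) -> np.ndarray:
    """Row-sparsified cosine-similarity affinity between profile rows.

    Per row, only the strongest ``ceil(row_sparsity * n_cols)`` entries are
    retained (others zeroed); cosine similarity is computed between the
    sparsified rows, negatives are clipped to 0 and the matrix is
    symmetrized as ``(A + A^T)/2``.
    """
    if config is None:
        config = EmbeddingConfig()
    prof = np.asarray(profiles, dtype=float)
    n_keep = math.ceil(config.row_sparsity * prof.shape[1])
    sparse = np.zeros_like(prof)
    for i, row in enumerate(prof):
        keep = np.argsort(row)[-n_keep:]
        sparse[i, keep] = row[keep]
    norms = np.linalg.norm(sparse, axis=1)
    if (norms < 1e-14).any():
        raise ValueError(
            f"zero-norm profile row(s) after sparsification: "
            f"{np.where(norms < 1e-14)[0].tolist()}"
        )
    aff = (sparse / norms[:, None]) @ (sparse / norms[:, None]).T
    aff = np.clip(aff, 0.0, 1.0)
    return (aff + aff.T) / 2.0


def diffusion_embedding(affinity: np.ndarray,
                        config: EmbeddingConfig | None = None,
                        unit_ids: list[str] | None = None) -> GradientEmbedding:
    """Diffusion-map embedding of a nonnegative symmetric affinity.

    The affinity is anisotropically normalized, ``W' = D^-a W D^-a`` with
    ``D`` the degree diagonal, then row-normalized into a Markov operator
    ``M``. Eigenvectors of ``M`` are obtained through the conjugate
    symmetric operator (dense ``eigh``), the trivial constant eigenvector
    is dropped, and components are scaled by ``lambda^t`` (no-op at t=0).
    """
    if config is None:
        config = EmbeddingConfig()
    w = np.asarray(affinity, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("affinity must be square")
    if np.abs(w - w.T).max() > 1e-10:
        raise ValueError("affinity must be symmetric")
    if (w < 0).any():
        raise ValueError("affinity must be nonnegative")
    n = w.shape[0]
    if config.n_components >= n:
        raise ValueError("n_components must be smaller than the number of units")

    deg = w.sum(axis=1)
    if (deg < 1e-14).any():
        raise ValueError(
            f"disconnected affinity: zero-degree unit(s) "
            f"{np.where(deg < 1e-14)[0].tolist()}"
        )
    w_alpha = w / np.outer(deg**config.alpha, deg**config.alpha)
    deg2 = w_alpha.sum(axis=1)
    if (deg2 < 1e-14).any():
        raise ValueError("disconnected affinity after anisotropic normalization")

    # M = D2^-1 W' is similar to S = D2^-1/2 W' D2^-1/2 (symmetric):
    # eigvecs(M) = D2^-1/2 eigvecs(S), same eigenvalues.
    d_isqrt = 1.0 / np.sqrt(deg2)
    s = w_alpha * np.outer(d_isqrt, d_isqrt)
    s = (s + s.T) / 2.0
    vals, vecs = np.linalg.eigh(s)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    psi = d_isqrt[:, None] * vecs
    # drop the trivial stationary component (eigenvalue 1, constant vector)
    lam = vals[1: config.n_components + 1]
    comps = psi[:, 1: config.n_components + 1]
    if config.diffusion_time > 0:
        comps = comps * lam[None, :] ** config.diffusion_time
    ids = unit_ids if unit_ids is not None else [str(i) for i in range(n)]
    return GradientEmbedding(components=comps, eigenvalues=lam, unit_ids=ids)


def build_group_template(matrices: list[np.ndarray],
                         config: EmbeddingConfig | None = None,
                         unit_ids: list[str] | None = None) -> GradientEmbedding:
    """Embed the elementwise mean of subject connectivity/profile matrices."""
    if not matrices:
        raise ValueError("need at least one subject matrix")
    shapes = {m.shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"subject matrices have mismatched shapes: {shapes}")
    mean = np.mean(np.stack(matrices), axis=0)
    return diffusion_embedding(cosine_affinity(mean, config), config, unit_ids)


def procrustes_align(embedding: GradientEmbedding,
                     template: GradientEmbedding) -> tuple[np.ndarray, float]:
    """Orthogonally align embedding components to the template.

    Columns of both are centered; a rotation/reflection (no scaling)
    minimizing the Frobenius distance to the template is applied. Returns
    the aligned components and the residual Frobenius disparity.
    """
    src = np.asarray(embedding.components, dtype=float)
    tgt = np.asarray(template.components, dtype=float)
    if src.shape != tgt.shape:
        raise ValueError(f"shape mismatch: {src.shape} vs {tgt.shape}")
    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    if np.linalg.matrix_rank(src_c) < src.shape[1]:
        raise ValueError("rank-deficient embedding cannot be aligned")
    rot, _ = orthogonal_procrustes(src_c, tgt_c)
    aligned = src_c @ rot
    disparity = float(np.linalg.norm(aligned - tgt_c))
    return aligned, disparity


def standardize_components(components: np.ndarray) -> np.ndarray:
    """Z-score each gradient component across units (mean 0, sd 1)."""
    comp = np.asarray(components, dtype=float)
    sd = comp.std(axis=0, ddof=0)
    if (sd < 1e-14).any():
        raise ValueError(
            f"constant component(s): {np.where(sd < 1e-14)[0].tolist()}"
        )
    return (comp - comp.mean(axis=0)) / sd


def orient_principal_gradient(components: np.ndarray,
                              networks: np.ndarray) -> np.ndarray:
    """Fix the sign of gradient 1 so the somatomotor mean score is negative
    (deterministic reporting convention); other components untouched."""
    comp = np.asarray(components, dtype=float).copy()
    mask = np.asarray(networks) == "somatomotor"
    if mask.any() and comp[mask, 0].mean() > 0:
        comp[:, 0] = -comp[:, 0]
    return comp


def network_dispersion(components: np.ndarray, networks,
                       n_components_used: int = 3) -> DispersionSummary:
    """Centroid geometry of networks in gradient space.

    Within-network dispersion is the sum of squared Euclidean distances of
    member units to their network centroid; between-network values are
    pairwise centroid Euclidean distances. Empty networks are excluded.
    """
    comp = np.asarray(components, dtype=float)[:, :n_components_used]
    networks = np.asarray(networks)
    names = [n for n in CANONICAL_NETWORKS if (networks == n).any()]
    centroids = {}
    within = {}
    for name in names:
        pts = comp[networks == name]
        c = pts.mean(axis=0)
        centroids[name] = c
        within[name] = float(((pts - c) ** 2).sum())
    between = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = float(np.linalg.norm(centroids[a] - centroids[b]))
            between.loc[a, b] = between.loc[b, a] = d
    return DispersionSummary(networks=names, within=within, between=between,
                             centroids=centroids)
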