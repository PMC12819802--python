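"""Sliding-window dynamic functional connectivity and k-means brain states.

Windows of ``length`` timepoints (default 50 TR, step 1) slide over each
subject's cleaned series; per window the Pearson connectivity is computed,
Fisher z-transformed, and its upper triangle vectorized. Windows are pooled
across subjects and clustered with k-means into recurrent connectivity
states; the cluster number is chosen by the elbow rule on the SSE curve
refined by silhouette and Calinski-Harabasz diagnostics. Per-subject state
sequences yield fractional occupancy (FO), mean dwell time (MDT) and
number of transitions (NT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

import numpy as np
import pandas as pd
from scipy import signal as _signal
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .prep import ParcelTimeSeries


@dataclass
class WindowSpec:
    """Sliding-window parameters (length and step in timepoints)."""

    length: int = 50
    step: int = 1
    taper: str = "rectangular"  # or "gaussian"

    def __post_init__(self) -> None:
        if self.length < 10:
            raise ValueError("window length must be at least 10 timepoints")
        if self.step < 1:
            raise ValueError("step must be at least 1")
        if self.taper not in ("rectangular", "gaussian"):
            raise ValueError(f"unknown taper {self.taper!r}")

    def n_windows(self, n_timepoints: int) -> int:
        if n_timepoints < self.length:
            raise ValueError(
                f"series of {n_timepoints} timepoints shorter than "
                f"window length {self.length}"
            )
        return (n_timepoints - self.length) // self.step + 1


@dataclass
class DynamicConnectivitySeries:
    """Per-subject sequence of vectorized windowed z-connectivity.

    ``edges`` is windows x E with E = P(P-1)/2 (upper triangle, Fisher z).
    """

    subject_id: str
    edges: np.ndarray
    n_parcels: int
    spec: WindowSpec
    tr_seconds: float
    parcel_ids: list[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.edges.shape[0]


@dataclass
class StateModel:
    """Fitted k-means state solution over pooled windows."""

    k: int
    centroids: np.ndarray            # k x E
    labels: dict[str, np.ndarray]    # subject -> per-window state in 0..k-1
    sse: float
    seed: int
    n_restarts: int


@dataclass
class StateQualityScan:
    """Cluster-number diagnostics over a range of k."""

    k_values: list[int]
    sse: list[float]
    silhouette: list[float]
    calinski_harabasz: list[float]
    chosen_k: int
    rule: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k_values, "sse": self.sse,
            "silhouette": self.silhouette,
            "calinski_harabasz": self.calinski_harabasz,
        })


def sliding_window_fc(ts: ParcelTimeSeries,
                      spec: WindowSpec | None = None) -> DynamicConnectivitySeries:
    """Windowed Pearson connectivity, Fisher z, vectorized upper triangle.

    With a Gaussian taper the demeaned segment is weighted by a Gaussian
    window (sd = length/6) before correlation.
    """
    if spec is None:
        spec = WindowSpec()
    n_win = spec.n_windows(ts.n_timepoints)
    P = ts.n_parcels
    iu = np.triu_indices(P, k=1)
    taper_w = None
    if spec.taper == "gaussian":
        taper_w = _signal.windows.gaussian(spec.length, std=spec.length / 6.0)
    edges = np.empty((n_win, len(iu[0])))
    for w in range(n_win):
        seg = ts.data[w * spec.step: w * spec.step + spec.length]
        sd = seg.std(axis=0)
        if (sd < 1e-14).any():
            bad = ts.parcel_ids[int(np.argmin(sd))]
            raise ValueError(f"parcel {bad} constant within window {w}")
        if taper_w is not None:
            seg = (seg - seg.mean(axis=0)) * taper_w[:, None]
        r = np.corrcoef(seg, rowvar=False)
        z = np.arctanh(np.clip(r[iu], -1 + 1e-7, 1 - 1e-7))
        edges[w] = z
    return DynamicConnectivitySeries(
        subject_id=ts.subject_id, edges=edges, n_parcels=P, spec=spec,
        tr_seconds=ts.tr_seconds, parcel_ids=ts.parcel_ids,
    )


def dfc_variability(series: DynamicConnectivitySeries) -> np.ndarray:
    """Per-edge standard deviation of z across windows (denominator W-1)."""
    if series.n_windows < 2:
        raise ValueError("need at least 2 windows for variability")
    return series.edges.std(axis=0, ddof=1)


def pool_windows(series_list: list[DynamicConnectivitySeries]
                 ) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Stack windows across subjects; returns the pooled matrix and
    (subject_id, n_windows) bookkeeping for mapping labels back."""
    mats = [s.edges for s in series_list]
    counts = [(s.subject_id, s.n_windows) for s in series_list]
    return np.vstack(mats), counts


def fit_states(pooled: np.ndarray, counts: list[tuple[str, int]], k: int,
               seed: int = 0, n_restarts: int = 50) -> StateModel:
    """K-means (k-means++ init, best of ``n_restarts`` runs by SSE) over
    pooled windows; labels are mapped back per subject."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if pooled.shape[0] < k:
        raise ValueError(f"{pooled.shape[0]} windows cannot support k={k}")
    km = KMeans(n_clusters=k, n_init=n_restarts, init="k-means++",
                max_iter=300, random_state=seed)
    flat = km.fit_predict(pooled)
    labels = {}
    start = 0
    for sid, n in counts:
        labels[sid] = flat[start:start + n].copy()
        start += n
    return StateModel(k=k, centroids=km.cluster_centers_.copy(), labels=labels,
                      sse=float(km.inertia_), seed=seed, n_restarts=n_restarts)


def _elbow_silhouette_choice(k_values, sse, sil, ch,
                             sse_below: float | None = None) -> tuple[int, str]:
    """Elbow candidates (positive second difference of SSE) refined by
    silhouette; ties by larger Calinski-Harabasz, then smaller k.

    ``sse_below`` is the SSE at ``min(k_values) - 1`` (the k=1 total
    scatter when the scan starts at 2) so the first scanned k can itself
    be an elbow candidate.
    """
    k_values = list(k_values)
    ext = ([sse_below] if sse_below is not None else []) + list(sse)
    off = 1 if sse_below is not None else 0
    candidates = []
    for i in range(len(k_values) - 1):
        j = i + off
        if j - 1 < 0:
            continue
        d2 = ext[j - 1] - 2 * ext[j] + ext[j + 1]
        if d2 > 0:
            candidates.append(i)
    if not candidates:
        candidates = list(range(len(k_values)))
    best = max(candidates,
               key=lambda i: (sil[i], ch[i], -k_values[i]))
    return k_values[best], ("elbow candidates (positive SSE second difference)"
                            " -> max silhouette, ties by Calinski-Harabasz"
                            " then smaller k")


def cluster_quality_scan(pooled: np.ndarray, counts: list[tuple[str, int]],
                         k_range: tuple[int, int] = (2, 20), seed: int = 0,
                         n_restarts: int = 10,
                         silhouette_sample_size: int | None = 2000
                         ) -> StateQualityScan:
    """Fit k-means over a k range and select k by elbow + silhouette.

    For large window pools the silhouette is evaluated on a seeded
    subsample of ``silhouette_sample_size`` windows (pass ``None`` for the
    exact all-pairs computation).
    """
    lo, hi = k_range
    n = pooled.shape[0]
    if lo < 2 or hi > n - 1:
        import warnings
        warnings.warn(f"k_range {k_range} clipped to [2, {n - 1}]")
        lo, hi = max(2, lo), min(hi, n - 1)
    ks, sses, sils, chs = [], [], [], []
    sil_kwargs = {}
    if silhouette_sample_size is not None and silhouette_sample_size < n:
        sil_kwargs = {"sample_size": silhouette_sample_size,
                      "random_state": seed}
    for k in range(lo, hi + 1):
        model = fit_states(pooled, counts, k, seed=seed, n_restarts=n_restarts)
        flat = np.concatenate([model.labels[sid] for sid, _ in counts])
        ks.append(k)
        sses.append(model.sse)
        sils.append(float(silhouette_score(pooled, flat, **sil_kwargs)))
        chs.append(float(calinski_harabasz_score(pooled, flat)))
    # closed-form k=1 SSE anchors the elbow at the low end of the scan
    sse_below = None
    if lo == 2:
        sse_below = float(((pooled - pooled.mean(axis=0)) ** 2).sum())
    chosen, rule = _elbow_silhouette_choice(ks, sses, sils, chs, sse_below)
    return StateQualityScan(k_values=ks, sse=sses, silhouette=sils,
                            calinski_harabasz=chs, chosen_k=chosen, rule=rule)


def temporal_metrics(labels: np.ndarray, k: int, spec: WindowSpec | None = None,
                     tr_seconds: float = 2.0) -> dict:
    """FO, MDT and NT for one subject's window-label sequence.

    FO_s = fraction of windows in state s; MDT_s = mean run length in
    windows (NaN for unvisited states) and in seconds (windows x step x TR);
    NT = number of label changes between consecutive windows.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"label outside 0..{k - 1}")
    if spec is None:
        spec = WindowSpec()
    W = len(labels)
    fo = np.array([(labels == s).mean() for s in range(k)])
    runs = [(s, sum(1 for _ in grp)) for s, grp in groupby(labels)]
    mdt = np.full(k, np.nan)
    for s in range(k):
        lens = [ln for st, ln in runs if st == s]
        if lens:
            mdt[s] = float(np.mean(lens))
    nt = int((np.diff(labels) != 0).sum())
    return {
        "fo": fo,
        "mdt_windows": mdt,
        "mdt_seconds": mdt * spec.step * tr_seconds,
        "nt": nt,
        "n_windows": W,
    }


def metrics_table(model: StateModel, spec: WindowSpec,
                  tr_seconds: float = 2.0) -> pd.DataFrame:
    """Long-format FO/MDT/NT table, one row per subject per state."""
    rows = []
    for sid, lab in model.labels.items():
        m = temporal_metrics(lab, model.k, spec, tr_seconds)
        for s in range(model.k):
            rows.append({
                "subject_id": sid, "state": s + 1, "fo": m["fo"][s],
                "mdt_windows": m["mdt_windows"][s],
                "mdt_seconds": m["mdt_seconds"][s], "nt": m["nt"],
            })
    return pd.DataFrame(rows)


def match_states(centroids: np.ndarray, reference_edges: np.ndarray) -> dict[int, int]:
    """Match fitted cluster centroids to reference state edge vectors.

    Solves the assignment maximizing the total Pearson correlation between
    centroids and references (Hungarian algorithm); returns a
    cluster-index -> reference-index mapping. Used to compare recovered
    states against a known generative model or another fitted solution.
    """
    from scipy.optimize import linear_sum_assignment

    k, r = centroids.shape[0], reference_edges.shape[0]
    corr = np.zeros((k, r))
    for i in range(k):
        for j in range(r):
            corr[i, j] = np.corrcoef(centroids[i], reference_edges[j])[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    return dict(zip(rows.tolist(), cols.tolist()))


def state_mean_edges(series_list: list[DynamicConnectivitySeries],
                     model: StateModel, state: int
                     ) -> tuple[np.ndarray, list[str], list[str]]:
    """Per-subject mean edge vector over windows assigned to ``state``.

    Subjects with no window in the state are excluded; their ids are
    returned separately so callers can log the exclusions.
    """
    feats, kept, excluded = [], [], []
    for s in series_list:
        mask = model.labels[s.subject_id] == state
        if mask.any():
            feats.append(s.edges[mask].mean(axis=0))
            kept.append(s.subject_id)
        else:
            excluded.append(s.subject_id)
    return np.array(feats), kept, excluded


def state_edge_contrast(series_list: list[DynamicConnectivitySeries],
                        model: StateModel, state: int,
                        subjects: pd.DataFrame, group_col: str = "group",
                        covariate_cols: tuple[str, ...] = (),
                        alpha: float = 0.05,
                        baseline: str | None = None) -> pd.DataFrame:
    """Covariate-adjusted per-edge group contrast of state-mean connectivity.

    Delegates the per-edge linear-model contrast and BH-FDR to the group
    statistics module; returns one row per edge with t, p and q plus the
    exclusion count in ``attrs``.
    """
    from .stats import adjusted_group_contrast, fdr_bh

    feats, kept, excluded = state_mean_edges(series_list, model, state)
    sub = subjects.set_index("subject_id").loc[kept]
    for g, cnt in sub[group_col].value_counts().items():
        if cnt < 3:
            raise ValueError(
                f"group {g!r} has {cnt} subjects with windows in state "
                f"{state}; need at least 3"
            )
    covs = sub[list(covariate_cols)].to_numpy(float) if covariate_cols else None
    res = adjusted_group_contrast(feats, sub[group_col].to_numpy(),
                                  covariates=covs, baseline=baseline)
    res["q"] = fdr_bh(res["p"].to_numpy())
    res["significant"] = res["q"] < alpha
    res.attrs["excluded_subjects"] = excluded
    res.attrs["state"] = state
    return res
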