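"""Parcellated BOLD time-series container, TSV I/O, and temporal cleaning.

Cleaning operates at the parcel level on an already-extracted timepoints x
parcels matrix. Volume-space preprocessing (slice timing, realignment,
spatial normalisation, smoothing) is assumed done upstream; the synthetic
cohort generator bypasses it entirely.

The fixed cleaning order is: discard initial volumes -> polynomial
detrend -> confound regression -> zero-phase band-pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

#: The seven canonical resting-state networks used to label parcels.
CANONICAL_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal attention",
    "ventral attention",
    "limbic",
    "frontoparietal",
    "default",
)


@dataclass
class ParcelTimeSeries:
    """One subject's timepoints x parcels BOLD signal matrix.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    data : ndarray of shape (n_timepoints, n_parcels)
        BOLD signal in arbitrary units.
    tr_seconds : float
        Repetition time (sampling interval) in seconds; must be positive.
    parcels : DataFrame
        One row per parcel, columns ``parcel_id`` and ``network`` (one of
        :data:`CANONICAL_NETWORKS`), optional ``x``/``y``/``z`` coordinates.
        Row order matches the columns of ``data``.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    parcels: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D timepoints x parcels matrix")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if len(self.parcels) != self.data.shape[1]:
            raise ValueError(
                f"parcel table has {len(self.parcels)} rows but data has "
                f"{self.data.shape[1]} columns"
            )
        if np.isnan(self.data).any():
            raise ValueError("data contains missing values; imputation is not supported")
        unknown = set(self.parcels["network"]) - set(CANONICAL_NETWORKS)
        if unknown:
            raise ValueError(f"unknown network label(s): {sorted(unknown)}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    @property
    def parcel_ids(self) -> list[str]:
        return [str(p) for p in self.parcels["parcel_id"]]

    @property
    def networks(self) -> np.ndarray:
        return self.parcels["network"].to_numpy()


@dataclass
class CleaningConfig:
    """Temporal-cleaning parameters.

    ``band`` is the retained frequency range in Hz; the default 0.01-0.08 Hz
    is the conventional resting-state low-frequency band. ``detrend_order``
    1 removes a linear trend, 2 additionally a quadratic one.
    """

    n_discard: int = 10
    detrend_order: int = 1
    confounds: np.ndarray | None = None
    band: tuple[float, float] | None = (0.01, 0.08)  # None skips filtering
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.detrend_order not in (0, 1, 2):
            raise ValueError("detrend_order must be 0, 1 or 2")
        if self.n_discard < 0:
            raise ValueError("n_discard must be non-negative")


def read_parcel_metadata(path) -> pd.DataFrame:
    """Read a parcel metadata TSV (parcel_id, network, optional x/y/z)."""
    meta = pd.read_csv(path, sep="\t", dtype={"parcel_id": str})
    for col in ("parcel_id", "network"):
        if col not in meta.columns:
            raise ValueError(f"metadata file missing required column {col!r}")
    return meta


def read_parcel_timeseries(path, metadata_path, subject_id: str | None = None,
                           tr_seconds: float = 2.0) -> ParcelTimeSeries:
    """Read one subject's time series from TSV plus a parcel metadata TSV.

    The data TSV has a header row of parcel ids and one row per timepoint.
    Every parcel id in the data must appear in the metadata; metadata rows
    are reordered to match the data columns.
    """
    frame = pd.read_csv(path, sep="\t")
    bad = frame.columns[~frame.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        col = bad[0]
        row = int(pd.to_numeric(frame[col], errors="coerce").isna().idxmax())
        raise ValueError(f"non-numeric value in column {col!r}, row {row}")
    meta = read_parcel_metadata(metadata_path).set_index("parcel_id")
    missing = [c for c in frame.columns if str(c) not in meta.index]
    if missing:
        raise ValueError(f"parcel(s) missing from metadata: {missing}")
    parcels = meta.loc[[str(c) for c in frame.columns]].reset_index()
    if subject_id is None:
        import os
        subject_id = os.path.splitext(os.path.basename(str(path)))[0]
    return ParcelTimeSeries(subject_id=subject_id, data=frame.to_numpy(dtype=float),
                            tr_seconds=tr_seconds, parcels=parcels)


def write_parcel_timeseries(ts: ParcelTimeSeries, path) -> None:
    """Write the signal matrix as TSV with parcel ids as the header."""
    pd.DataFrame(ts.data, columns=ts.parcel_ids).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def discard_initial_volumes(ts: ParcelTimeSeries, n_discard: int = 10) -> ParcelTimeSeries:
    """Drop the first ``n_discard`` timepoints (signal-equilibration volumes)."""
    if not 0 <= n_discard < ts.n_timepoints:
        raise ValueError(
            f"n_discard must be in [0, {ts.n_timepoints}), got {n_discard}"
        )
    return replace(ts, data=ts.data[n_discard:].copy())


def _detrend(data: np.ndarray, order: int) -> np.ndarray:
    # least-squares removal of a polynomial trend (incl. intercept), per column
    t = np.linspace(-1.0, 1.0, data.shape[0])
    design = np.vander(t, order + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    return data - design @ beta


def _regress_confounds(data: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != data.shape[0]:
        confounds = confounds.T
    if confounds.shape[0] != data.shape[0]:
        raise ValueError(
            f"confound length {confounds.shape[0]} does not match "
            f"series length {data.shape[0]}"
        )
    design = np.column_stack([np.ones(data.shape[0]), confounds])
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    return data - design @ beta


def clean_timeseries(ts: ParcelTimeSeries, config: CleaningConfig | None = None
                     ) -> ParcelTimeSeries:
    """Detrend, regress confounds, and band-pass filter each parcel series.

    The band-pass is a zero-phase (forward-backward) Butterworth filter, so
    the output is not phase-shifted relative to in-band input. Initial-volume
    discard is *not* applied here; call :func:`discard_initial_volumes`
    first (the pipeline drivers do).
    """
    if config is None:
        config = CleaningConfig()
    if config.band is not None:
        low, high = config.band
        nyquist = 1.0 / (2.0 * ts.tr_seconds)
        if not 0 <= low < high < nyquist:
            raise ValueError(
                f"band ({low}, {high}) Hz invalid for Nyquist {nyquist:.4g} Hz"
            )
    data = _detrend(ts.data, config.detrend_order)
    logger.info("detrended (order %d)", config.detrend_order)
    if config.confounds is not None:
        data = _regress_confounds(data, config.confounds)
        logger.info("confounds regressed out")
    if config.band is not None:
        if low > 0:
            sos = signal.butter(config.filter_order, [low, high],
                                btype="bandpass", fs=1.0 / ts.tr_seconds,
                                output="sos")
        else:
            sos = signal.butter(config.filter_order, high, btype="lowpass",
                                fs=1.0 / ts.tr_seconds, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=0)
        logger.info("band-pass %.3g-%.3g Hz applied (zero-phase)", low, high)
    flat = np.where(data.std(axis=0) < 1e-12)[0]
    for p in flat:
        logger.warning("parcel %s is constant after cleaning", ts.parcel_ids[p])
    return replace(ts, data=np.ascontiguousarray(data))
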