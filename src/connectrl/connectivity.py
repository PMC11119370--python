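"""Functional connectivity from ROI time series.

Functional connectivity (FC) is the region-by-region Pearson correlation of
the ROI signals; the resulting symmetric matrix is the adjacency from which
the linear system matrix is built downstream. An optional zero-phase
Butterworth band-pass (default 0.01-0.08 Hz, the standard resting-state
band) can precede the correlation step.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .synthetic import RoiTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "bandpass_filter",
    "compute_fc",
    "fc_for_cohort",
    "read_timeseries_tsv",
    "write_fc_tsv",
    "read_fc_tsv",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric signed correlation matrix with zero diagonal."""

    values: np.ndarray
    region_labels: list[str]
    subject_id: str
    group_label: int

    def validate(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix contains non-finite entries")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("connectivity matrix must be symmetric to 1e-12")
        if np.any(np.diag(v) != 0):
            raise ValueError("connectivity diagonal must be exactly zero")
        if np.abs(v).max(initial=0.0) > 1.0 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")
        if len(self.region_labels) != v.shape[0]:
            raise ValueError("region_labels length must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def bandpass_filter(ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass (order 2, forward-backward).

    The band must sit strictly inside (0, Nyquist) for the series' sampling
    interval. Filtering is applied independently to each region's signal.
    """
    ts.validate()
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz {high_hz} must be below the Nyquist frequency {nyquist}")
    sos = butter(2, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos")
    try:
        filtered = sosfiltfilt(sos, ts.values, axis=0)
    except ValueError as exc:  # series shorter than the filter's padding need
        raise ValueError(f"time series too short for zero-phase filtering: {exc}") from exc
    return RoiTimeSeries(
        subject_id=ts.subject_id,
        group_label=ts.group_label,
        values=filtered,
        tr_seconds=ts.tr_seconds,
        region_labels=list(ts.region_labels),
    )


def compute_fc(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation matrix of the ROI signals, diagonal zeroed.

    Raises if any region has zero variance (its correlation is undefined);
    the error names the offending region.
    """
    ts.validate()
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints to estimate correlations")
    variances = ts.values.var(axis=0)
    zero_var = np.flatnonzero(variances == 0)
    if zero_var.size:
        names = ", ".join(ts.region_labels[i] for i in zero_var[:5])
        raise ValueError(f"zero-variance region(s): {names}")
    corr = np.corrcoef(ts.values, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    fc = ConnectivityMatrix(
        values=corr,
        region_labels=list(ts.region_labels),
        subject_id=ts.subject_id,
        group_label=ts.group_label,
    )
    fc.validate()
    return fc


def fc_for_cohort(
    cohort: list[RoiTimeSeries],
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    apply_bandpass: bool = False,
    absolute: bool = False,
) -> list[ConnectivityMatrix]:
    """One connectivity matrix per subject, order preserved.

    ``apply_bandpass`` runs the temporal filter first; ``absolute`` replaces
    signed correlations with their magnitudes (both conventions appear in
    the connectome literature; signed is the default).
    """
    out: list[ConnectivityMatrix] = []
    for ts in cohort:
        try:
            if apply_bandpass:
                ts = bandpass_filter(ts, low_hz, high_hz)
            fc = compute_fc(ts)
        except ValueError as exc:
            raise ValueError(f"subject {ts.subject_id}: {exc}") from exc
        if absolute:
            vals = np.abs(fc.values)
            np.fill_diagonal(vals, 0.0)
            fc = ConnectivityMatrix(vals, fc.region_labels, fc.subject_id, fc.group_label)
        out.append(fc)
    return out


def read_timeseries_tsv(path: str | Path, subject_id: str, group_label: int, tr_seconds: float) -> RoiTimeSeries:
    """Read a timepoints x regions TSV with a region-name header row."""
    df = pd.read_csv(path, sep="\t")
    ts = RoiTimeSeries(
        subject_id=subject_id,
        group_label=group_label,
        values=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        region_labels=[str(c) for c in df.columns],
    )
    ts.validate()
    return ts


def write_fc_tsv(fc: ConnectivityMatrix, path: str | Path) -> None:
    """Write a connectivity matrix as TSV with labeled rows and columns."""
    pd.DataFrame(fc.values, index=fc.region_labels, columns=fc.region_labels).to_csv(path, sep="\t")


def read_fc_tsv(path: str | Path, subject_id: str, group_label: int) -> ConnectivityMatrix:
    """Read a labeled square connectivity TSV back into a ConnectivityMatrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is {df.shape[0]} x {df.shape[1]}, expected square")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row labels do not match column labels")
    values = df.to_numpy(dtype=float)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    fc = ConnectivityMatrix(values, [str(c) for c in df.columns], subject_id, group_label)
    fc.validate()
    return fc
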