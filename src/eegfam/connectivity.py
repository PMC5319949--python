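"""Functional-connectivity indices between electrode pairs.

Three per-band indices are computed over whole recordings (one value
per subject-stimulus pair, not per window):

correlation
    zero-lag Pearson correlation of the band-filtered series — the
    normalized cross-covariance C_xy / sqrt(C_xx C_yy) with the
    frequency restriction supplied by the band filter.  Range [-1, 1].
coherence
    magnitude-squared coherence |P_xy(f)|² / (P_xx(f) P_yy(f)) from
    Welch cross-spectra (1 s Hann segments, 50% overlap), averaged
    over the frequency bins inside [lo, hi).  Range [0, 1].
psi
    phase synchronization index |mean_t exp(i [φ_x(t) - φ_y(t)])|
    where φ is the Hilbert (analytic-signal) phase of the
    band-filtered series.  Range [0, 1].

Aggregation across stimuli uses the arithmetic mean for coherence and
PSI and the quadratic (root-mean-square) mean for correlation, whose
sign would otherwise cancel.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .core import Recording
from .montage import familiarity_group
from .preprocess import BandSpec, bandpass_array

__all__ = [
    "METHODS",
    "band_correlation",
    "band_coherence",
    "phase_sync_index",
    "connectivity_matrix",
    "aggregate_indices",
]

METHODS = ("correlation", "coherence", "psi")


class DegenerateSignalWarning(UserWarning):
    """Zero-variance or zero input where an index is undefined."""


def band_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Zero-lag Pearson correlation of two band-filtered series.

    Returns NaN (with a :class:`DegenerateSignalWarning`) when either
    input has zero variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        warnings.warn("zero-variance input: correlation undefined",
                      DegenerateSignalWarning, stacklevel=2)
        return float("nan")
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.dot(xc, yc) / (np.sqrt(np.dot(xc, xc)) * np.sqrt(np.dot(yc, yc))))


def band_coherence(
    x: np.ndarray,
    y: np.ndarray,
    rate: float,
    band: BandSpec,
    nperseg: int | None = None,
) -> float:
    """Band-averaged magnitude-squared coherence of two series.

    Welch segments default to 1 s with 50% overlap; at least two
    segments are required (single-segment coherence is identically 1).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    nperseg = int(nperseg or round(rate))
    if x.size < nperseg + nperseg // 2:
        raise ValueError(
            f"{x.size} samples give fewer than 2 Welch segments of {nperseg}"
        )
    f, cxy = signal.coherence(
        x, y, fs=rate, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    mask = (f >= band.lo) & (f < band.hi)
    if not mask.any():
        raise ValueError(f"no spectral bins inside [{band.lo}, {band.hi}) Hz")
    return float(cxy[mask].mean())


def hilbert_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians) of the analytic signal of ``x``."""
    return np.angle(signal.hilbert(np.asarray(x, float)))


def phase_sync_index(
    x: np.ndarray,
    y: np.ndarray,
    rate: float | None = None,
    edge_seconds: float = 0.5,
) -> float:
    """Phase synchronization index of two band-filtered series.

    PSI = |(1/L) Σ_t exp(i [φ_x(t) − φ_y(t)])| over the L retained
    samples.  Because the Hilbert phase is unreliable at the ends of a
    finite record, the first and last ``edge_seconds`` are excluded
    when ``rate`` is given (pass ``edge_seconds=0`` to evaluate the
    bare definition).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    if not x.any() or not y.any():
        warnings.warn("zero signal: phase undefined", DegenerateSignalWarning,
                      stacklevel=2)
        return float("nan")
    dphi = hilbert_phase(x) - hilbert_phase(y)
    if rate is not None and edge_seconds > 0:
        trim = int(round(edge_seconds * rate))
        if 2 * trim < dphi.size:
            dphi = dphi[trim : dphi.size - trim]
    return float(np.abs(np.exp(1j * dphi).mean()))


def connectivity_matrix(
    rec: Recording,
    bands: tuple[BandSpec, ...],
    methods: tuple[str, ...] = METHODS,
    pairs: tuple[tuple[str, str], ...] | None = None,
    geometry: str | None = None,
    order: int = 5,
) -> pd.DataFrame:
    """All-pairs connectivity of one recording, one row per index.

    The recording is band-filtered once per band (fifth-order
    zero-phase Butterworth) and every unordered electrode pair (or the
    explicit ``pairs`` subset) is scored with every requested method.
    Returns a long-format frame with columns ``subject_id,
    stimulus_id, familiarity, familiarity_group, electrode_1,
    electrode_2, band, method, value``.
    """
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    if pairs is None:
        pairs = tuple(itertools.combinations(rec.channels, 2))
    group = familiarity_group(rec.familiarity, geometry) if geometry else None
    rows = []
    for band in bands:
        filt = bandpass_array(rec.samples, rec.rate, band.lo, band.hi, order)
        series = {ch: filt[i] for i, ch in enumerate(rec.channels)}
        for e1, e2 in pairs:
            x, y = series[e1], series[e2]
            for method in methods:
                if method == "correlation":
                    value = band_correlation(x, y)
                elif method == "coherence":
                    value = band_coherence(x, y, rec.rate, band)
                else:
                    value = phase_sync_index(x, y, rec.rate)
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "stimulus_id": rec.stimulus_id,
                        "familiarity": rec.familiarity,
                        "familiarity_group": group,
                        "electrode_1": e1,
                        "electrode_2": e2,
                        "band": band.name,
                        "method": method,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def aggregate_indices(values, method: str) -> float:
    """Overall index across stimuli for one method.

    Arithmetic mean for coherence and PSI (both bounded in [0, 1]);
    quadratic mean (RMS) for correlation so that opposite signs do not
    cancel.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty list")
    if method == "correlation":
        return float(np.sqrt(np.mean(values**2)))
    if method in ("coherence", "psi"):
        return float(np.mean(values))
    raise ValueError(f"unknown method {method!r}")
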