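"""Filtering, band decomposition and non-overlapping window segmentation.

All filters are applied forward–backward (zero phase) so that the phase
structure used by the connectivity indices is not distorted by filter
group delay.  The notch is a narrow second-order IIR band-stop
(quality factor 30); band-pass filters are Butterworth (order 5 by
default, matching the connectivity pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import Recording
from .montage import GEOMETRIES, MUSIC12

__all__ = [
    "BandSpec",
    "MUSIC12_BANDS",
    "VIDEO32_BANDS",
    "bands_for",
    "band_by_name",
    "notch_filter",
    "bandpass_filter",
    "band_decompose",
    "Window",
    "segment_windows",
    "notch_array",
    "bandpass_array",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency interval in Hz, treated as [lo, hi) in spectra."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"invalid band edges ({self.lo}, {self.hi})")


#: Canonical EEG bands for the 250 Hz music geometry.
MUSIC12_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 40.0),
)

#: The 128 Hz video geometry is pre-filtered at 4–45 Hz, so delta is absent.
VIDEO32_BANDS: tuple[BandSpec, ...] = MUSIC12_BANDS[1:]


def bands_for(geometry: str) -> tuple[BandSpec, ...]:
    """Canonical band set of a geometry (5 bands music12, 4 video32)."""
    if geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}")
    return MUSIC12_BANDS if geometry == MUSIC12 else VIDEO32_BANDS


def band_by_name(name: str, geometry: str = MUSIC12) -> BandSpec:
    for b in bands_for(geometry):
        if b.name == name:
            return b
    raise KeyError(f"band {name!r} not defined for {geometry}")


# ---------------------------------------------------------------------------
# array-level filters (also used by the synthetic generator)


def notch_array(x: np.ndarray, rate: float, freq: float, q: float = 30.0) -> np.ndarray:
    """Zero-phase narrow band-stop at ``freq`` Hz along the last axis."""
    if freq >= rate / 2:
        raise ValueError(f"notch frequency {freq} Hz >= Nyquist {rate / 2} Hz")
    b, a = signal.iirnotch(freq, q, fs=rate)
    return signal.filtfilt(b, a, x, axis=-1)


def butter_bandpass_sos(lo: float, hi: float, rate: float, order: int = 5) -> np.ndarray:
    if not 0 < lo < hi < rate / 2:
        raise ValueError(f"band edges ({lo}, {hi}) invalid for rate {rate} Hz")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")


def bandpass_array(
    x: np.ndarray, rate: float, lo: float, hi: float, order: int = 5
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    sos = butter_bandpass_sos(lo, hi, rate, order)
    return signal.sosfiltfilt(sos, x, axis=-1)


# ---------------------------------------------------------------------------
# Recording-level operations


def notch_filter(rec: Recording, freq: float = 60.0, q: float = 30.0) -> Recording:
    """Remove power-line interference with a narrow band-stop filter."""
    return rec.copy_with(samples=notch_array(rec.samples, rec.rate, freq, q))


def bandpass_filter(rec: Recording, lo: float, hi: float, order: int = 5) -> Recording:
    """Zero-phase Butterworth band-pass of every channel."""
    return rec.copy_with(samples=bandpass_array(rec.samples, rec.rate, lo, hi, order))


def band_decompose(
    rec: Recording, bands: tuple[BandSpec, ...], order: int = 5
) -> dict[str, Recording]:
    """Return one band-filtered copy of the recording per band."""
    return {b.name: bandpass_filter(rec, b.lo, b.hi, order) for b in bands}


@dataclass
class Window:
    """A half-open ``[start, start+length)`` slice of a recording."""

    recording_id: str
    start_sample: int
    length: int
    samples: np.ndarray  # (channels, length) view
    rate: float
    channels: tuple[str, ...]

    @property
    def start_time(self) -> float:
        return self.start_sample / self.rate

    @property
    def duration(self) -> float:
        return self.length / self.rate

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channels.index(label)]


def segment_windows(rec: Recording, window_samples: int) -> list[Window]:
    """Cut a recording into consecutive disjoint windows.

    ``floor(n / window_samples)`` windows are produced; the trailing
    remainder is discarded.  A window longer than the recording yields
    an empty list.
    """
    if window_samples < 2:
        raise ValueError("window_samples must be >= 2")
    n_windows = rec.n_samples // window_samples
    out = []
    for i in range(n_windows):
        start = i * window_samples
        out.append(
            Window(
                recording_id=rec.recording_id,
                start_sample=start,
                length=window_samples,
                samples=rec.samples[:, start : start + window_samples],
                rate=rec.rate,
                channels=rec.channels,
            )
        )
    return out
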