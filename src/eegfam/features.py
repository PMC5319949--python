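"""Window-level feature extraction for emotion classification.

Produces the classification feature table: per-window band power
spectral densities (Welch, μV²/Hz), Higuchi fractal dimensions, and
left-minus-right differential asymmetry features, together with
bad-channel screening and majority-vote emotion labeling.

Column naming
-------------
``PSD:<electrode>:<band>``
    mean Welch spectral density over the band interval [lo, hi).
``FD:<electrode>``
    Higuchi fractal dimension of the broadband window.
``dASYM:<left>-<right>``
    FD asymmetry (left minus right) of a symmetric pair.
``dASYM:<left>-<right>:<band>``
    PSD asymmetry of a symmetric pair in one band.

The *FD feature set* is ``FD:*`` plus the band-less ``dASYM`` columns
(electrodes + pairs columns); the *PSD feature set* is ``PSD:*`` plus
the per-band ``dASYM`` columns ((electrodes + pairs) × bands columns).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import Recording
from .montage import familiarity_group, pairs_for
from .preprocess import BandSpec, Window, bands_for, notch_filter, bandpass_filter, segment_windows

log = logging.getLogger(__name__)

__all__ = [
    "DegenerateSeriesWarning",
    "FeatureConfig",
    "META_COLUMNS",
    "band_psd",
    "window_band_psd",
    "higuchi_fd",
    "screen_bad_psd",
    "apply_exclusions",
    "asymmetry_augment",
    "label_windows",
    "assemble_feature_table",
    "fd_feature_columns",
    "psd_feature_columns",
    "feature_columns",
]

#: Non-feature columns of the assembled table.
META_COLUMNS = (
    "subject_id",
    "stimulus_id",
    "window_index",
    "familiarity",
    "familiarity_group",
    "arousal_class",
    "valence_class",
)


class DegenerateSeriesWarning(UserWarning):
    """Raised (as a warning) for constant input or out-of-range FD."""


class LabelingError(ValueError):
    """A window has no annotation coverage."""


# ---------------------------------------------------------------------------
# power spectral density


def _welch(samples: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch density estimate along the last axis, Hann taper.

    Segment length is ``min(n, rate)`` (1 s segments for >=1 s windows)
    with 50% overlap, density scaling so units are μV²/Hz.
    """
    n = samples.shape[-1]
    nperseg = int(min(n, round(rate)))
    return signal.welch(
        samples,
        fs=rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        scaling="density",
        axis=-1,
    )


def band_psd(samples: np.ndarray, rate: float, band: BandSpec) -> float | np.ndarray:
    """Mean spectral density over ``[band.lo, band.hi)`` in μV²/Hz.

    ``samples`` may be 1-D (one electrode window) or N-D with time on
    the last axis, in which case one value per leading index is
    returned.  Frequency bins are assigned half-open so adjacent bands
    sharing an edge never double count.
    """
    samples = np.asarray(samples, dtype=float)
    if not np.isfinite(samples).all():
        raise ValueError("non-finite samples")
    if samples.shape[-1] < rate / band.lo:
        raise ValueError(
            f"window of {samples.shape[-1]} samples is shorter than one "
            f"period of {band.lo} Hz at {rate} Hz"
        )
    f, pxx = _welch(samples, rate)
    mask = (f >= band.lo) & (f < band.hi)
    if not mask.any():
        raise ValueError(f"no spectral bins inside [{band.lo}, {band.hi}) Hz")
    out = pxx[..., mask].mean(axis=-1)
    return float(out) if out.ndim == 0 else out


def window_band_psd(window: Window, electrode: str, band: BandSpec) -> float:
    """`band_psd` of one electrode of a segmentation window."""
    return float(band_psd(window.channel(electrode), window.rate, band))


# ---------------------------------------------------------------------------
# Higuchi fractal dimension


def higuchi_fd(series: np.ndarray, kmax: int = 8) -> float:
    """Higuchi fractal dimension of a 1-D series, nominally in [1, 2].

    For each scale ``k`` in 1..kmax and offset ``m`` in 0..k-1, the
    normalized curve length is

        L_m(k) = (1/k) * [ sum_i |x[m+ik] - x[m+(i-1)k]| ] * (N-1)/(n_m k)

    with ``n_m = floor((N-1-m)/k)`` increments.  The FD is the least
    squares slope of ``log L(k)`` against ``log (1/k)`` where ``L(k)``
    is the mean over offsets.

    A constant series has zero curve length at every scale; it is
    reported as 1.0 with a :class:`DegenerateSeriesWarning`.  An
    estimate falling outside [1, 2] is returned as computed but also
    flagged with a warning rather than silently clamped.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if n < 10 * kmax:
        raise ValueError(f"series length {n} < 10*kmax = {10 * kmax}")
    if not np.isfinite(x).all():
        raise ValueError("non-finite samples")
    if np.ptp(x) == 0.0:
        warnings.warn("constant series: curve length is zero, reporting FD=1.0",
                      DegenerateSeriesWarning, stacklevel=2)
        return 1.0

    log_lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            sub = x[m::k]
            n_m = sub.size - 1
            if n_m < 1:
                continue
            dist = np.abs(np.diff(sub)).sum()
            lengths.append(dist * (n - 1) / (n_m * k) / k)
        log_lk[k - 1] = np.log(np.mean(lengths))

    log_inv_k = -np.log(np.arange(1, kmax + 1))
    slope = np.polyfit(log_inv_k, log_lk, 1)[0]
    fd = float(slope)
    if not 1.0 <= fd <= 2.0:
        warnings.warn(f"FD estimate {fd:.4f} outside [1, 2]",
                      DegenerateSeriesWarning, stacklevel=2)
    return fd


# ---------------------------------------------------------------------------
# bad-channel screening and exclusion


def screen_bad_psd(table: pd.DataFrame, threshold: float = 100.0) -> pd.DataFrame:
    """Flag PSD entries strictly above ``threshold`` μV²/Hz.

    Returns one row per (table row, electrode, band) whose
    ``PSD:<electrode>:<band>`` value exceeds the threshold, with
    columns ``subject_id, electrode, band, row, psd_value``.  A value
    exactly at the threshold is not flagged.
    """
    records = []
    for col in table.columns:
        if not col.startswith("PSD:"):
            continue
        _, electrode, band = col.split(":")
        vals = table[col]
        bad = vals > threshold
        for row in table.index[bad]:
            records.append(
                {
                    "subject_id": table.at[row, "subject_id"],
                    "electrode": electrode,
                    "band": band,
                    "row": row,
                    "psd_value": float(vals.at[row]),
                }
            )
    return pd.DataFrame(
        records, columns=["subject_id", "electrode", "band", "row", "psd_value"]
    )


def apply_exclusions(
    flags: pd.DataFrame,
    table: pd.DataFrame,
    subject_fraction: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the bad-channel exclusion rules to a feature table.

    Subjects whose flagged fraction of PSD entries *strictly* exceeds
    ``subject_fraction`` are dropped entirely (a fraction exactly at
    the threshold is retained).  For the remaining subjects, an
    electrode flagged in any band has all of its PSD columns (every
    band) masked to NaN for that subject, so the electrode contributes
    no spectral data to downstream statistics.

    Returns ``(table, exclusion_log)`` where the log has columns
    ``kind`` (``subject``/``electrode``), ``subject_id``, ``electrode``
    and ``flagged_fraction``.
    """
    if not 0 < subject_fraction <= 1:
        raise ValueError("subject_fraction must be in (0, 1]")
    psd_cols = [c for c in table.columns if c.startswith("PSD:")]
    log_rows = []
    if flags.empty or not psd_cols:
        return table.copy(), pd.DataFrame(
            log_rows, columns=["kind", "subject_id", "electrode", "flagged_fraction"]
        )

    out = table.copy()
    dropped = []
    for subject, sub in out.groupby("subject_id"):
        total = len(sub) * len(psd_cols)
        n_flagged = int((flags["subject_id"] == subject).sum())
        frac = n_flagged / total if total else 0.0
        if frac > subject_fraction:
            dropped.append(subject)
            log_rows.append(
                {"kind": "subject", "subject_id": subject, "electrode": None,
                 "flagged_fraction": frac}
            )
    out = out[~out["subject_id"].isin(dropped)].reset_index(drop=True)

    kept_flags = flags[~flags["subject_id"].isin(dropped)]
    for (subject, electrode), grp in kept_flags.groupby(["subject_id", "electrode"]):
        cols = [c for c in psd_cols if c.split(":")[1] == electrode]
        out.loc[out["subject_id"] == subject, cols] = np.nan
        log_rows.append(
            {"kind": "electrode", "subject_id": subject, "electrode": electrode,
             "flagged_fraction": float("nan")}
        )
    return out, pd.DataFrame(
        log_rows, columns=["kind", "subject_id", "electrode", "flagged_fraction"]
    )


# ---------------------------------------------------------------------------
# asymmetry features


def asymmetry_augment(
    table: pd.DataFrame, pairs: tuple[tuple[str, str], ...]
) -> pd.DataFrame:
    """Append left-minus-right differential features per symmetric pair.

    For every pair ``(L, R)`` a ``dASYM:L-R`` column is added from the
    FD features and a ``dASYM:L-R:<band>`` column per band from the
    PSD features.
    """
    out = table.copy()
    bands: list[str] = []
    for c in table.columns:
        if c.startswith("PSD:"):
            b = c.split(":")[2]
            if b not in bands:
                bands.append(b)
    new = {}
    for left, right in pairs:
        if f"FD:{left}" in table.columns:
            if f"FD:{right}" not in table.columns:
                raise KeyError(f"electrode {right!r} missing from FD features")
            new[f"dASYM:{left}-{right}"] = table[f"FD:{left}"] - table[f"FD:{right}"]
        for band in bands:
            lcol, rcol = f"PSD:{left}:{band}", f"PSD:{right}:{band}"
            if lcol in table.columns:
                if rcol not in table.columns:
                    raise KeyError(f"electrode {right!r} missing from PSD features")
                new[f"dASYM:{left}-{right}:{band}"] = table[lcol] - table[rcol]
        if f"FD:{left}" not in table.columns and not any(
            c.startswith(f"PSD:{left}:") for c in table.columns
        ):
            raise KeyError(f"electrode {left!r} unknown to the feature table")
    return pd.concat([out, pd.DataFrame(new, index=out.index)], axis=1)


# ---------------------------------------------------------------------------
# emotion labeling


def label_windows(
    annotations,
    windows: list[Window],
    scheme: str,
) -> pd.DataFrame:
    """Per-window binary (arousal, valence) labels.

    Continuous annotations (``scheme='positivity'``): the annotation
    stream is piecewise constant from each timestamp to the next; each
    window takes the class covering the largest fraction of its time
    span, ties broken toward the class of the chronologically earlier
    annotation.  Single trial ratings (``scheme='deap45'``): every
    window inherits the trial's rating binarized at 4.5.

    Returns a DataFrame with ``arousal_class`` in {low, high} and
    ``valence_class`` in {negative, positive}.
    """
    from .classify import binarize_labels  # local import: classify is downstream

    if isinstance(annotations, pd.DataFrame):
        t = np.asarray(annotations["t"], dtype=float)
        if t.size == 0:
            raise LabelingError("empty annotation stream")
        aro = binarize_labels(np.asarray(annotations["arousal"], float), scheme)
        val = binarize_labels(np.asarray(annotations["valence"], float), scheme)
        ends = np.append(t[1:], np.inf)
        rows = []
        for w in windows:
            ws, we = w.start_time, w.start_time + w.duration
            overlap = np.minimum(ends, we) - np.maximum(t, ws)
            covered = overlap > 0
            if not covered.any():
                raise LabelingError(
                    f"window [{ws}, {we}) s has no annotation coverage"
                )
            rows.append(
                {
                    "arousal_class": _majority(aro, overlap, covered, "high", "low"),
                    "valence_class": _majority(val, overlap, covered, "positive", "negative"),
                }
            )
        return pd.DataFrame(rows)

    valence, arousal = annotations
    aro = "high" if binarize_labels(np.array([arousal]), scheme)[0] else "low"
    val = "positive" if binarize_labels(np.array([valence]), scheme)[0] else "negative"
    return pd.DataFrame(
        {"arousal_class": [aro] * len(windows), "valence_class": [val] * len(windows)}
    )


def _majority(pos: np.ndarray, overlap: np.ndarray, covered: np.ndarray,
              pos_name: str, neg_name: str) -> str:
    dur_pos = overlap[covered & pos].sum()
    dur_neg = overlap[covered & ~pos].sum()
    if dur_pos > dur_neg:
        return pos_name
    if dur_neg > dur_pos:
        return neg_name
    # exact tie: class of the earliest annotation overlapping the window
    first = int(np.flatnonzero(covered)[0])
    return pos_name if pos[first] else neg_name


# ---------------------------------------------------------------------------
# table assembly


@dataclass
class FeatureConfig:
    """Extraction settings, defaulted from the recording geometry.

    ``window_samples`` defaults to 4 s of samples (1000 at 250 Hz, 512
    at 128 Hz); ``broad_band`` is the geometry's broad band-pass
    (0.5–60 Hz music, 4–45 Hz video); ``scheme`` is the label
    binarization rule (``positivity`` for continuous [-1, 1]
    annotations, ``deap45`` for 1–9 ratings).
    """

    geometry: str
    bands: tuple[BandSpec, ...] | None = None
    pairs: tuple[tuple[str, str], ...] | None = None
    window_samples: int | None = None
    kmax: int = 8
    notch_hz: float | None = None
    broad_band: tuple[float, float] | None = None
    scheme: str | None = None
    bandpass_order: int = 5

    def __post_init__(self) -> None:
        if self.bands is None:
            self.bands = bands_for(self.geometry)
        if self.pairs is None:
            self.pairs = pairs_for(self.geometry)
        if self.broad_band is None:
            self.broad_band = (0.5, 60.0) if self.geometry == "music12" else (4.0, 45.0)
        if self.scheme is None:
            self.scheme = "positivity" if self.geometry == "music12" else "deap45"


def assemble_feature_table(
    recordings: list[Recording], config: FeatureConfig
) -> pd.DataFrame:
    """Build the full windows × features table for a set of recordings.

    Each recording is (optionally) notch filtered, broad band-pass
    filtered, and cut into non-overlapping windows.  Per window and
    electrode, one FD feature and one PSD feature per band are
    extracted from the broadband signal, asymmetry features are
    appended, emotion labels are assigned, and the familiarity stratum
    is derived from the recording's familiarity score.
    """
    if not recordings:
        raise ValueError("no recordings")
    montage = recordings[0].channels
    frames = []
    for rec in recordings:
        if rec.channels != montage:
            raise ValueError(
                f"mixed montages: {rec.recording_id} has {rec.channels[:3]}..., "
                f"expected {montage[:3]}..."
            )
        proc = rec
        if config.notch_hz is not None:
            proc = notch_filter(proc, config.notch_hz)
        lo, hi = config.broad_band
        proc = bandpass_filter(proc, lo, hi, config.bandpass_order)
        wlen = config.window_samples or int(round(4 * rec.rate))
        windows = segment_windows(proc, wlen)
        if not windows:
            log.warning("recording %s shorter than one window; skipped", rec.recording_id)
            continue
        labels = label_windows(rec.annotations, windows, config.scheme)

        stacked = np.stack([w.samples for w in windows])  # (W, C, L)
        f, pxx = _welch(stacked, rec.rate)
        cols: dict[str, np.ndarray] = {}
        for band in config.bands:
            mask = (f >= band.lo) & (f < band.hi)
            band_mean = pxx[:, :, mask].mean(axis=-1)  # (W, C)
            for ci, ch in enumerate(montage):
                cols[f"PSD:{ch}:{band.name}"] = band_mean[:, ci]
        fd = np.empty((len(windows), len(montage)))
        for wi, w in enumerate(windows):
            for ci in range(len(montage)):
                fd[wi, ci] = higuchi_fd(w.samples[ci], config.kmax)
        for ci, ch in enumerate(montage):
            cols[f"FD:{ch}"] = fd[:, ci]

        frame = pd.DataFrame(cols)
        frame.insert(0, "subject_id", rec.subject_id)
        frame.insert(1, "stimulus_id", rec.stimulus_id)
        frame.insert(2, "window_index", np.arange(len(windows)))
        frame.insert(3, "familiarity", rec.familiarity)
        frame.insert(
            4, "familiarity_group", familiarity_group(rec.familiarity, config.geometry)
        )
        frame["arousal_class"] = labels["arousal_class"].to_numpy()
        frame["valence_class"] = labels["valence_class"].to_numpy()
        frames.append(frame)
    if not frames:
        raise ValueError("all recordings shorter than one window")
    table = pd.concat(frames, ignore_index=True)
    return asymmetry_augment(table, config.pairs)


# ---------------------------------------------------------------------------
# feature-set selectors


def fd_feature_columns(table: pd.DataFrame) -> list[str]:
    """FD feature set: per-electrode FD plus band-less asymmetries."""
    return [
        c for c in table.columns
        if c.startswith("FD:") or (c.startswith("dASYM:") and c.count(":") == 1)
    ]


def psd_feature_columns(table: pd.DataFrame) -> list[str]:
    """PSD feature set: per-electrode band PSDs plus per-band asymmetries."""
    return [
        c for c in table.columns
        if c.startswith("PSD:") or (c.startswith("dASYM:") and c.count(":") == 2)
    ]


def feature_columns(table: pd.DataFrame, feature_set: str) -> list[str]:
    if feature_set == "FD":
        return fd_feature_columns(table)
    if feature_set == "PSD":
        return psd_feature_columns(table)
    raise ValueError(f"unknown feature set {feature_set!r}; expected 'FD' or 'PSD'")
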