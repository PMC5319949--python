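"""Electrode montages and recording geometries.

Two study geometries are supported:

``music12``
    12 frontally weighted 10–20 electrodes sampled at 250 Hz during
    ~2 min music-listening sessions, with continuous arousal/valence
    annotation in [-1, 1] and familiarity scored 1–6.

``video32``
    The standard 32-channel layout of 1 min music-video trials sampled
    at 128 Hz, with a single per-trial arousal/valence rating on 1–9 and
    familiarity scored 1–5.
"""

from __future__ import annotations

MUSIC12 = "music12"
VIDEO32 = "video32"
GEOMETRIES = (MUSIC12, VIDEO32)

MUSIC12_RATE = 250.0
VIDEO32_RATE = 128.0

MUSIC12_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz", "C3", "C4", "T3", "T4", "Pz",
)

#: Left/right homologous pairs used for differential asymmetry features.
MUSIC12_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("F3", "F4"), ("F7", "F8"), ("C3", "C4"), ("T3", "T4"),
)

VIDEO32_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7", "CP5", "CP1",
    "P3", "P7", "PO3", "O1", "Oz", "Pz", "Fp2", "AF4", "Fz", "F4",
    "F8", "FC6", "FC2", "Cz", "C4", "T8", "CP6", "CP2", "P4", "P8",
    "PO4", "O2",
)

VIDEO32_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("AF3", "AF4"), ("F3", "F4"), ("F7", "F8"),
    ("FC1", "FC2"), ("FC5", "FC6"), ("C3", "C4"), ("T7", "T8"),
    ("CP1", "CP2"), ("CP5", "CP6"), ("P3", "P4"), ("P7", "P8"),
    ("PO3", "PO4"), ("O1", "O2"),
)


def channels_for(geometry: str) -> tuple[str, ...]:
    """Return the ordered channel labels of a geometry."""
    _check(geometry)
    return MUSIC12_CHANNELS if geometry == MUSIC12 else VIDEO32_CHANNELS


def pairs_for(geometry: str) -> tuple[tuple[str, str], ...]:
    """Return the symmetric (left, right) electrode pairs of a geometry."""
    _check(geometry)
    return MUSIC12_PAIRS if geometry == MUSIC12 else VIDEO32_PAIRS


def rate_for(geometry: str) -> float:
    """Return the nominal sampling rate in Hz of a geometry."""
    _check(geometry)
    return MUSIC12_RATE if geometry == MUSIC12 else VIDEO32_RATE


def familiarity_group(score: int, geometry: str) -> str:
    """Map a familiarity score to the ``low``/``high`` stratum.

    Music sessions score familiarity 1–6 and split 1–3 vs 4–6; video
    trials score 1–5 and split 1–2 vs 3–5.
    """
    _check(geometry)
    if geometry == MUSIC12:
        if not 1 <= score <= 6:
            raise ValueError(f"music12 familiarity must be 1..6, got {score}")
        return "high" if score >= 4 else "low"
    if not 1 <= score <= 5:
        raise ValueError(f"video32 familiarity must be 1..5, got {score}")
    return "high" if score >= 3 else "low"


def _check(geometry: str) -> None:
    if geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}; expected one of {GEOMETRIES}")
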