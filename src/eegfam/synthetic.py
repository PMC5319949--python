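"""Synthetic affective-EEG session generator with known ground truth.

Signal model
------------
Each channel is the sum of a 1/f-shaped broadband floor and one
narrowband oscillator per canonical EEG band (fifth-order Butterworth
filtered Gaussian noise, scaled to a per-band RMS amplitude).  This
minimal model keeps band PSD and phase structure analytically
controllable:

* **Familiarity band-power effects** — a ``BandEffect`` multiplies the
  oscillator amplitude of one electrode/band by ``sqrt(power_ratio)``
  for high-familiarity stimuli, so the measured band PSD ratio
  (high/low) approaches ``power_ratio``.
* **Familiarity phase coupling** — a ``CouplingEffect`` mixes a shared
  narrowband source into both electrodes of a pair,
  ``z_i = λ s + sqrt(1−λ²) n_i``; the mixing coefficient λ is read off
  a pre-computed monotone lookup of phase-synchronization index (PSI)
  versus λ, since PSI has no closed form under this model.  Targets
  ``psi_high``/``psi_low`` apply to high/low-familiarity stimuli.
* **Emotion coupling** — latent arousal/valence trajectories modulate
  band-oscillator amplitude multiplicatively (arousal drives a band's
  power on a set of electrodes; valence drives a left/right asymmetry
  on one pair), with per-stratum effect strengths so that the
  classifiability of emotion can differ between familiarity strata.

Annotations are emitted at 1 Hz (continuous geometry) or as a single
1–9 rating (video geometry), derived from the same latent trajectories
used for modulation, which are retained on each
:class:`~eegfam.core.Recording` for ground-truth tests.

All random draws for a session flow from a single seeded generator, so
an identical spec + seed yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .core import Recording
from .montage import (
    GEOMETRIES,
    MUSIC12,
    VIDEO32,
    channels_for,
    familiarity_group,
    rate_for,
)
from .preprocess import bands_for, butter_bandpass_sos

__all__ = [
    "BandEffect",
    "CouplingEffect",
    "EmotionCoupling",
    "SessionSpec",
    "simulate_session",
    "make_fixture_suite",
    "mixing_for_psi",
]

#: Baseline oscillator RMS amplitude per band, μV.  Chosen so that band
#: oscillators dominate the in-band share of the 1/f floor (keeping
#: injected power ratios recoverable) while total signal stays in a
#: realistic scalp-EEG range of tens of μV.
BAND_RMS_UV = {"delta": 8.0, "theta": 7.0, "alpha": 12.0, "beta": 6.0, "gamma": 4.0}

# 8 familiar (4-6) and 8 unfamiliar (1-3) scores per subject, interleaved
# so that any truncated prefix still contains both strata.
_MUSIC_FAM_DEFAULT = (6, 1, 5, 2, 4, 3, 6, 1, 5, 2, 4, 3, 6, 1, 5, 2)
_VIDEO_FAM_DEFAULT = tuple(([1, 2, 3, 1, 2, 4, 1, 2, 5, 1, 2, 3] * 4)[:40])


@dataclass(frozen=True)
class BandEffect:
    """High-vs-low familiarity band-power ratio at one electrode."""

    electrode: str
    band: str
    power_ratio: float

    def __post_init__(self) -> None:
        if self.power_ratio <= 0:
            raise ValueError("power_ratio must be > 0")


@dataclass(frozen=True)
class CouplingEffect:
    """Target PSI for an electrode pair in one band, per stratum."""

    pair: tuple[str, str]
    band: str
    psi_high: float
    psi_low: float

    def __post_init__(self) -> None:
        for v in (self.psi_high, self.psi_low):
            if not 0.0 <= v <= 1.0:
                raise ValueError("psi targets must be in [0, 1]")


@dataclass(frozen=True)
class EmotionCoupling:
    """Latent-emotion → feature couplings.

    ``strength`` is the fractional amplitude modulation per unit of
    latent emotion (gain ``1 + strength·latent`` clipped below at
    0.05); ``strength_low``/``strength_high`` override it per
    familiarity stratum, which is how stratum-dependent emotion
    decodability is injected.
    """

    arousal_band: str = "beta"
    arousal_electrodes: tuple[str, ...] = ("F3", "F4", "Fz", "C3", "C4")
    valence_band: str = "alpha"
    valence_pair: tuple[str, str] = ("F3", "F4")
    strength: float = 0.6
    strength_low: float | None = None
    strength_high: float | None = None

    def strength_for(self, group: str) -> float:
        if group == "low":
            return self.strength if self.strength_low is None else self.strength_low
        return self.strength if self.strength_high is None else self.strength_high


@dataclass
class SessionSpec:
    """Full description of a synthetic multi-subject session."""

    geometry: str
    n_subjects: int
    n_stimuli_per_subject: int
    stimulus_duration: float
    sample_rate: float
    familiarity_assignment: tuple[int, ...] | None = None
    band_effect_map: tuple[BandEffect, ...] = ()
    coupling_effect_map: tuple[CouplingEffect, ...] = ()
    emotion_coupling: EmotionCoupling | None = field(default_factory=EmotionCoupling)
    noise_floor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.sample_rate <= 0 or self.stimulus_duration <= 0:
            raise ValueError("sample_rate and stimulus_duration must be positive")
        if self.n_subjects < 1 or self.n_stimuli_per_subject < 1:
            raise ValueError("need at least one subject and one stimulus")
        channels = channels_for(self.geometry)
        band_names = {b.name for b in bands_for(self.geometry)}
        for eff in self.band_effect_map:
            if eff.electrode not in channels:
                raise ValueError(f"band effect on unknown electrode {eff.electrode!r}")
            if eff.band not in band_names:
                raise ValueError(f"band effect on unknown band {eff.band!r}")
        for eff in self.coupling_effect_map:
            for e in eff.pair:
                if e not in channels:
                    raise ValueError(f"coupling on unknown electrode {e!r}")
            if eff.band not in band_names:
                raise ValueError(f"coupling on unknown band {eff.band!r}")
        if self.familiarity_assignment is not None:
            if len(self.familiarity_assignment) != self.n_stimuli_per_subject:
                raise ValueError("familiarity_assignment length != n_stimuli_per_subject")
            for s in self.familiarity_assignment:
                familiarity_group(s, self.geometry)  # range check

    # -- geometry presets ---------------------------------------------------

    @classmethod
    def music12(cls, **overrides) -> "SessionSpec":
        """Music-listening geometry: 12 channels, 250 Hz, 2 min songs,
        16 songs (8 familiar / 8 unfamiliar) per subject, 15 subjects."""
        base = dict(
            geometry=MUSIC12,
            n_subjects=15,
            n_stimuli_per_subject=16,
            stimulus_duration=120.0,
            sample_rate=rate_for(MUSIC12),
        )
        base.update(overrides)
        spec = cls(**base)
        return spec

    @classmethod
    def video32(cls, **overrides) -> "SessionSpec":
        """Music-video geometry: 32 channels, 128 Hz, 1 min trials,
        40 trials per subject (familiarity skewed low), 32 subjects."""
        base = dict(
            geometry=VIDEO32,
            n_subjects=32,
            n_stimuli_per_subject=40,
            stimulus_duration=60.0,
            sample_rate=rate_for(VIDEO32),
        )
        base.update(overrides)
        return cls(**base)

    def familiarity_scores(self) -> tuple[int, ...]:
        if self.familiarity_assignment is not None:
            return self.familiarity_assignment
        default = _MUSIC_FAM_DEFAULT if self.geometry == MUSIC12 else _VIDEO_FAM_DEFAULT
        reps = -(-self.n_stimuli_per_subject // len(default))
        return (default * reps)[: self.n_stimuli_per_subject]


# ---------------------------------------------------------------------------
# noise primitives


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...], rate: float,
               f_knee: float = 1.0) -> np.ndarray:
    """Unit-RMS 1/f-power noise along the last axis.

    The amplitude spectrum is shaped as 1/sqrt(max(f, f_knee)) so power
    falls as 1/f above the knee without a DC blow-up; the DC bin is
    zeroed.
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    scale = 1.0 / np.sqrt(np.maximum(f, f_knee))
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _narrowband(rng: np.random.Generator, shape: tuple[int, ...], rate: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (causal Butterworth)."""
    sos = butter_bandpass_sos(lo, hi, rate, order=5)
    x = signal.sosfilt(sos, rng.standard_normal(shape), axis=-1)
    return x / x.std(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# PSI ↔ mixing-coefficient calibration


def _pink_band_fraction(lo: float, hi: float, rate: float, n: int,
                        f_knee: float = 1.0) -> float:
    """Fraction of 1/f-floor power falling inside [lo, hi)."""
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    p = 1.0 / np.maximum(f, f_knee)
    p[0] = 0.0
    return float(p[(f >= lo) & (f < hi)].sum() / p.sum())


@lru_cache(maxsize=None)
def _psi_curve(
    lo: float, hi: float, rate: float, noise_ratio: float = 0.0
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Monotone lookup of measured PSI versus mixing coefficient λ.

    ``noise_ratio`` is the RMS of uncoupled in-band background relative
    to the oscillator, added to both channels so the lookup already
    accounts for the attenuation by the broadband floor.  Computed once
    per (band, rate, ratio) from a fixed internal seed on 40 s of the
    generator's own narrowband model, then monotonized; the session RNG
    is never consumed, so session output stays a pure function of
    spec + seed.
    """
    from .connectivity import phase_sync_index

    rng = np.random.default_rng(987654321)
    n = int(40 * rate)
    lam_grid = np.linspace(0.0, 1.0, 21)
    psis = []
    for lam in lam_grid:
        s = _narrowband(rng, (n,), rate, lo, hi)
        n1 = _narrowband(rng, (n,), rate, lo, hi)
        n2 = _narrowband(rng, (n,), rate, lo, hi)
        root = np.sqrt(1.0 - lam * lam)
        z1 = lam * s + root * n1
        z2 = lam * s + root * n2
        if noise_ratio > 0.0:
            z1 = z1 + noise_ratio * _narrowband(rng, (n,), rate, lo, hi)
            z2 = z2 + noise_ratio * _narrowband(rng, (n,), rate, lo, hi)
        psis.append(phase_sync_index(z1, z2, rate))
    psis = np.maximum.accumulate(psis)
    return tuple(lam_grid), tuple(psis)


def mixing_for_psi(
    target_psi: float, lo: float, hi: float, rate: float, noise_ratio: float = 0.0
) -> float:
    """Mixing coefficient λ whose expected measured PSI is ``target_psi``.

    Targets above the ceiling reachable under the given noise ratio
    saturate at λ = 1.
    """
    lam_grid, psis = _psi_curve(lo, hi, rate, round(noise_ratio, 2))
    return float(np.interp(target_psi, psis, lam_grid))


# ---------------------------------------------------------------------------
# latent emotion


def _latent_track(rng: np.random.Generator, n_seconds: int) -> np.ndarray:
    """Smooth latent trajectory in (-1, 1) at 1 Hz, roughly zero-centred."""
    pad = 12
    z = rng.standard_normal(n_seconds + 2 * pad)
    t = np.arange(-4 * 3, 4 * 3 + 1)
    kernel = np.exp(-0.5 * (t / 3.0) ** 2)
    kernel /= kernel.sum()
    z = np.convolve(z, kernel, mode="same")[pad : pad + n_seconds]
    sd = z.std()
    if sd == 0.0:
        return np.zeros(n_seconds)
    return np.tanh(z / sd)


# ---------------------------------------------------------------------------
# session synthesis


def simulate_session(spec: SessionSpec) -> list[Recording]:
    """Generate one Recording per subject × stimulus.

    Familiarity-linked band-power ratios and pair couplings, and
    emotion-feature couplings, are realized as configured in the spec;
    latent arousal/valence trajectories are retained on each
    recording's ``latent`` field.
    """
    rng = np.random.default_rng(spec.seed)
    channels = channels_for(spec.geometry)
    bands = bands_for(spec.geometry)
    scores = spec.familiarity_scores()
    rate, dur = spec.sample_rate, spec.stimulus_duration
    n = int(round(rate * dur))
    n_sec = max(1, int(np.floor(dur)))

    band_effects: dict[tuple[str, str], float] = {
        (e.electrode, e.band): e.power_ratio for e in spec.band_effect_map
    }
    couplings: dict[str, list[CouplingEffect]] = {}
    for eff in spec.coupling_effect_map:
        couplings.setdefault(eff.band, []).append(eff)

    recordings = []
    for si in range(spec.n_subjects):
        subject = f"S{si + 1:02d}"
        for ti, score in enumerate(scores):
            stimulus = f"T{ti + 1:02d}"
            group = familiarity_group(score, spec.geometry)

            # latent emotion and its sample-grid modulation profile
            if spec.geometry == MUSIC12:
                lat_a = _latent_track(rng, n_sec)
                lat_v = _latent_track(rng, n_sec)
                t_samples = np.arange(n) / rate
                mod_a = np.interp(t_samples, np.arange(n_sec), lat_a)
                mod_v = np.interp(t_samples, np.arange(n_sec), lat_v)
            else:
                lat_a = float(rng.uniform(-0.9, 0.9))
                lat_v = float(rng.uniform(-0.9, 0.9))
                mod_a = np.full(n, lat_a)
                mod_v = np.full(n, lat_v)

            x = pink_noise(rng, (len(channels), n), rate) * spec.noise_floor

            ec = spec.emotion_coupling
            strength = ec.strength_for(group) if ec is not None else 0.0
            for band in bands:
                osc = _narrowband(rng, (len(channels), n), rate, band.lo, band.hi)
                for eff in couplings.get(band.name, ()):
                    target = eff.psi_high if group == "high" else eff.psi_low
                    floor_rms = spec.noise_floor * np.sqrt(
                        _pink_band_fraction(band.lo, band.hi, rate, n)
                    )
                    lam = mixing_for_psi(
                        target, band.lo, band.hi, rate,
                        noise_ratio=floor_rms / BAND_RMS_UV[band.name],
                    )
                    shared = _narrowband(rng, (n,), rate, band.lo, band.hi)
                    root = np.sqrt(1.0 - lam * lam)
                    for e in eff.pair:
                        ci = channels.index(e)
                        osc[ci] = lam * shared + root * osc[ci]
                for ci, ch in enumerate(channels):
                    amp = BAND_RMS_UV[band.name]
                    if group == "high" and (ch, band.name) in band_effects:
                        amp *= np.sqrt(band_effects[(ch, band.name)])
                    gain = amp
                    if ec is not None and strength != 0.0:
                        profile = np.ones(n)
                        if band.name == ec.arousal_band and ch in ec.arousal_electrodes:
                            profile = profile * np.clip(1.0 + strength * mod_a, 0.05, None)
                        if band.name == ec.valence_band:
                            if ch == ec.valence_pair[0]:
                                profile = profile * np.clip(1.0 + strength * mod_v, 0.05, None)
                            elif ch == ec.valence_pair[1]:
                                profile = profile * np.clip(1.0 - strength * mod_v, 0.05, None)
                        gain = amp * profile
                    x[ci] += gain * osc[ci]

            if spec.geometry == MUSIC12:
                ann = pd.DataFrame(
                    {
                        "t": np.arange(n_sec, dtype=float),
                        "valence": np.clip(lat_v + rng.normal(0.0, 0.03, n_sec), -1, 1),
                        "arousal": np.clip(lat_a + rng.normal(0.0, 0.03, n_sec), -1, 1),
                    }
                )
                latent = {"arousal": lat_a, "valence": lat_v, "annotation_rate": 1.0}
            else:
                v_rating = float(np.clip(5.0 + 4.0 * lat_v + rng.normal(0.0, 0.25), 1, 9))
                a_rating = float(np.clip(5.0 + 4.0 * lat_a + rng.normal(0.0, 0.25), 1, 9))
                ann = (v_rating, a_rating)
                latent = {"arousal": lat_a, "valence": lat_v}

            recordings.append(
                Recording(
                    samples=x,
                    rate=rate,
                    channels=channels,
                    subject_id=subject,
                    stimulus_id=stimulus,
                    familiarity=int(score),
                    annotations=ann,
                    latent=latent,
                )
            )
    return recordings


# ---------------------------------------------------------------------------
# fixture suite


def make_fixture_suite(out_dir: str | Path, seed: int = 7) -> dict:
    """Write a small fixed-seed fixture set in both geometries.

    Each recording becomes a CSV sample matrix plus JSON sidecar (see
    :mod:`eegfam.io`); ``manifest.json`` lists every file together
    with the ground-truth effect parameters of its generating spec.
    Returns the manifest dict.
    """
    from . import io as fio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = {
        "music12": SessionSpec.music12(
            n_subjects=3,
            n_stimuli_per_subject=4,
            stimulus_duration=24.0,
            familiarity_assignment=(6, 5, 1, 2),
            band_effect_map=(BandEffect("T4", "alpha", 2.0),),
            coupling_effect_map=(CouplingEffect(("F3", "F4"), "gamma", 0.8, 0.2),),
            seed=seed,
        ),
        "video32": SessionSpec.video32(
            n_subjects=3,
            n_stimuli_per_subject=4,
            stimulus_duration=20.0,
            familiarity_assignment=(5, 4, 1, 2),
            seed=seed + 1,
        ),
    }
    manifest: dict = {"fixtures": []}
    for name, spec in specs.items():
        sub_dir = out_dir / name
        sub_dir.mkdir(exist_ok=True)
        files = []
        for rec in simulate_session(spec):
            stem = fio.write_recording(rec, sub_dir)
            files.append(
                {
                    "csv": f"{name}/{stem}.csv",
                    "json": f"{name}/{stem}.json",
                    "subject_id": rec.subject_id,
                    "stimulus_id": rec.stimulus_id,
                    "familiarity": rec.familiarity,
                }
            )
        manifest["fixtures"].append(
            {"geometry": name, "spec": _spec_to_jsonable(spec), "files": files}
        )
    fio.write_json(manifest, out_dir / "manifest.json")
    return manifest


def _spec_to_jsonable(spec: SessionSpec) -> dict:
    import json

    # canonical JSON form (tuples -> lists) so the manifest round-trips
    return json.loads(json.dumps(asdict(spec)))
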