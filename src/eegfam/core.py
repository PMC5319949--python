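"""Core data container: a single-stimulus multichannel EEG recording."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

#: Continuous annotations: DataFrame with columns ``t`` (s), ``valence``,
#: ``arousal`` in [-1, 1].  Single-rating annotations: (valence, arousal)
#: on the 1–9 scale.
Annotations = Union[pd.DataFrame, tuple]


@dataclass
class Recording:
    """One subject × stimulus EEG segment.

    Parameters
    ----------
    samples
        ``(n_channels, n_samples)`` array in microvolts.
    rate
        Sampling rate in Hz.
    channels
        Ordered 10–20 labels, one per row of ``samples``.
    subject_id, stimulus_id
        Identifiers of the session.
    familiarity
        Self-reported familiarity score for the stimulus (1–6 music,
        1–5 video).
    annotations
        Either a time-stamped ``(t, valence, arousal)`` DataFrame
        (continuous annotation, music geometry) or a single
        ``(valence, arousal)`` rating pair (video geometry).
    latent
        Optional generator ground truth (latent emotion trajectories,
        injected effect parameters); never used by the analysis path.
    """

    samples: np.ndarray
    rate: float
    channels: tuple[str, ...]
    subject_id: str
    stimulus_id: str
    familiarity: int
    annotations: Annotations
    latent: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.channels = tuple(self.channels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows for {len(self.channels)} channel labels"
            )
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain non-finite values")
        if self.is_continuous:
            t = np.asarray(self.annotations["t"], dtype=float)
            if t.size and (t.min() < 0 or t.max() > self.duration):
                raise ValueError("annotation timestamps outside [0, duration]")
            if t.size and np.any(np.diff(t) <= 0):
                raise ValueError("annotation timestamps must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    @property
    def is_continuous(self) -> bool:
        """True when annotations are a time-stamped stream."""
        return isinstance(self.annotations, pd.DataFrame)

    @property
    def recording_id(self) -> str:
        return f"{self.subject_id}/{self.stimulus_id}"

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in montage {self.channels}") from None

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D series of one electrode."""
        return self.samples[self.channel_index(label)]

    def copy_with(self, **changes) -> "Recording":
        """Return a copy with selected fields replaced."""
        return dataclasses.replace(self, **changes)
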