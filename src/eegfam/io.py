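"""Reading and writing the CSV + JSON fixture format.

A recording is stored as two files sharing a stem:

``<stem>.csv``
    Sample matrix, rows = samples, columns = channel labels, values
    in μV (full float precision so the round trip is exact).
``<stem>.json``
    Sidecar with rate, identifiers, familiarity, annotations (either a
    list of ``[t, valence, arousal]`` points or a single
    ``[valence, arousal]`` rating pair) and optional generator ground
    truth.

EDF reading is available through mne when installed; there is no EDF
writer here, so CSV + JSON is the interchange format.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Recording

__all__ = ["write_recording", "read_recording", "write_json", "read_edf"]


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)
        fh.write("\n")


def write_recording(rec: Recording, directory: str | Path, stem: str | None = None) -> str:
    """Write ``<stem>.csv`` + ``<stem>.json``; returns the stem used."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{rec.subject_id}_{rec.stimulus_id}"
    pd.DataFrame(rec.samples.T, columns=list(rec.channels)).to_csv(
        directory / f"{stem}.csv", index=False
    )
    if rec.is_continuous:
        ann = {
            "kind": "continuous",
            "points": np.asarray(rec.annotations[["t", "valence", "arousal"]]).tolist(),
        }
    else:
        valence, arousal = rec.annotations
        ann = {"kind": "single", "valence": float(valence), "arousal": float(arousal)}
    side = {
        "rate": rec.rate,
        "channels": list(rec.channels),
        "subject_id": rec.subject_id,
        "stimulus_id": rec.stimulus_id,
        "familiarity": rec.familiarity,
        "annotations": ann,
    }
    if rec.latent is not None:
        side["latent"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in rec.latent.items()
        }
    write_json(side, directory / f"{stem}.json")
    return stem


def read_recording(path: str | Path) -> Recording:
    """Load a recording from its CSV (or JSON) fixture path."""
    path = Path(path)
    stem = path.with_suffix("")
    csv_path, json_path = stem.with_suffix(".csv"), stem.with_suffix(".json")
    with open(json_path) as fh:
        side = json.load(fh)
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    channels = tuple(side["channels"])
    if tuple(frame.columns) != channels:
        raise ValueError(f"CSV columns of {csv_path} disagree with sidecar channels")
    ann_raw = side["annotations"]
    if ann_raw["kind"] == "continuous":
        pts = np.asarray(ann_raw["points"], dtype=float).reshape(-1, 3)
        annotations = pd.DataFrame(pts, columns=["t", "valence", "arousal"])
    else:
        annotations = (float(ann_raw["valence"]), float(ann_raw["arousal"]))
    latent = None
    if "latent" in side:
        latent = {
            k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
            for k, v in side["latent"].items()
        }
    return Recording(
        samples=frame.to_numpy().T,
        rate=float(side["rate"]),
        channels=channels,
        subject_id=side["subject_id"],
        stimulus_id=side["stimulus_id"],
        familiarity=int(side["familiarity"]),
        annotations=annotations,
        latent=latent,
    )


def read_directory(directory: str | Path) -> list[Recording]:
    """Load every ``*.csv``/``*.json`` fixture pair in a directory."""
    directory = Path(directory)
    recs = [
        read_recording(p)
        for p in sorted(directory.glob("*.csv"))
        if p.with_suffix(".json").exists()
    ]
    if not recs:
        raise FileNotFoundError(f"no fixture pairs found in {directory}")
    return recs


def read_edf(
    path: str | Path,
    subject_id: str,
    stimulus_id: str,
    familiarity: int,
    annotations,
) -> Recording:
    """Load an EDF file into a Recording (requires mne).

    EDF carries no emotion/familiarity metadata, so identifiers,
    familiarity and annotations must be supplied by the caller.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        samples=raw.get_data() * 1e6,  # volts → μV
        rate=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        subject_id=subject_id,
        stimulus_id=stimulus_id,
        familiarity=familiarity,
        annotations=annotations,
    )
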