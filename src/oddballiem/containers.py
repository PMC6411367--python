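"""Epoch container and on-disk formats.

An :class:`EpochSet` bundles a trials x electrodes x samples array with its
time axis, sampling rate, and the aligned event table. On disk an EpochSet
is a directory holding ``epochs.npy`` (float32, C-order), ``meta.json``
(sampling rate, times, electrode labels, schema version, provenance, array
checksum) and ``events.tsv``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

__all__ = ["EpochSet", "SCHEMA_VERSION"]


@dataclass
class EpochSet:
    """Trials x electrodes x samples epochs with aligned event metadata."""

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    events: pd.DataFrame
    electrode_labels: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x electrodes x samples")
        if self.data.shape[0] != len(self.events):
            raise ValueError("trial count must equal event count")
        if self.data.shape[2] != self.times.size:
            raise ValueError("sample count must match time axis")
        dt = np.diff(self.times)
        if self.times.size > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("times must be strictly increasing and uniform")
        if not self.electrode_labels:
            self.electrode_labels = [f"E{i + 1}" for i in range(self.data.shape[1])]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    def select(self, mask) -> "EpochSet":
        """Subset trials by boolean mask or index array."""
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            times=self.times,
            sampling_rate=self.sampling_rate,
            events=self.events.loc[mask].reset_index(drop=True)
            if mask.dtype == bool
            else self.events.iloc[mask].reset_index(drop=True),
            electrode_labels=self.electrode_labels,
            provenance=dict(self.provenance),
        )

    # -- serialization ------------------------------------------------------

    def save(self, path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arr = np.ascontiguousarray(self.data, dtype=np.float32)
        np.save(path / "epochs.npy", arr)
        meta = {
            "schema_version": SCHEMA_VERSION,
            "sampling_rate": self.sampling_rate,
            "times": self.times.tolist(),
            "electrode_labels": list(self.electrode_labels),
            "shape": list(arr.shape),
            "checksum": hashlib.sha256(arr.tobytes()).hexdigest(),
            "provenance": self.provenance,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=1))
        self.events.to_csv(path / "events.tsv", sep="\t", index=False)
        return path

    @classmethod
    def load(cls, path) -> "EpochSet":
        path = Path(path)
        meta_file = path / "meta.json"
        if not meta_file.exists():
            raise FileNotFoundError(f"missing sidecar {meta_file}: not an epoch container")
        meta = json.loads(meta_file.read_text())
        if meta.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported epoch-container schema {meta.get('schema_version')!r}"
            )
        arr = np.load(path / "epochs.npy")
        if hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest() != meta["checksum"]:
            raise ValueError("epoch array failed its checksum")
        events = pd.read_csv(path / "events.tsv", sep="\t")
        return cls(
            data=arr,
            times=np.asarray(meta["times"]),
            sampling_rate=meta["sampling_rate"],
            events=events,
            electrode_labels=meta["electrode_labels"],
            provenance=meta.get("provenance", {}),
        )
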