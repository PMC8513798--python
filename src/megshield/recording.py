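"""Multichannel recording container with HDF5 / CSV round-tripping.

A :class:`Recording` is the channels-by-samples signal matrix in native
sensor units (T for magnetometers, T/m for planar gradiometers) plus the
sampling rate, the channel names (in array order) and a provenance log
that generators and processing steps append to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["Recording"]


@dataclass
class Recording:
    data: np.ndarray  # (n_channels, n_samples)
    sfreq: float  # Hz
    channel_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_names = list(self.channel_names)
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            sfreq=self.sfreq,
            channel_names=list(self.channel_names),
            provenance=dict(self.provenance),
        )

    def with_data(self, data: np.ndarray, note: dict | None = None) -> "Recording":
        """New recording sharing metadata, with processing note appended."""
        prov = dict(self.provenance)
        if note:
            prov.setdefault("processing", [])
            prov["processing"] = list(prov["processing"]) + [note]
        return Recording(data=data, sfreq=self.sfreq,
                         channel_names=list(self.channel_names), provenance=prov)

    # -- persistence -------------------------------------------------------
    def save_h5(self, path: str | Path) -> None:
        import json

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["sfreq"] = self.sfreq
            f.create_dataset(
                "channel_names", data=np.array(self.channel_names, dtype="S")
            )
            f.attrs["provenance"] = json.dumps(self.provenance, default=str)

    @classmethod
    def load_h5(cls, path: str | Path) -> "Recording":
        import json

        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                sfreq=float(f.attrs["sfreq"]),
                channel_names=[n.decode() for n in f["channel_names"][()]],
                provenance=json.loads(f.attrs.get("provenance", "{}")),
            )

    def to_csv(self, path: str | Path) -> None:
        """Plain-text export (small fixtures only): channels as rows."""
        df = pd.DataFrame(self.data, index=self.channel_names)
        df.index.name = f"sfreq={self.sfreq}"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Recording":
        df = pd.read_csv(path, index_col=0)
        sfreq = float(str(df.index.name).split("=")[1])
        return cls(data=df.to_numpy(), sfreq=sfreq, channel_names=list(df.index))
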