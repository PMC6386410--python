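"""Continuous multichannel recordings and their on-disk formats."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


@dataclass
class Recording:
    """A continuous multichannel surface-potential recording.

    data : (n_samples, n_channels) array, microvolts
    fs : sampling rate in Hz
    channel_ids : one label per column
    reference : optionally the recorded reference trace (microvolts)
    """

    data: np.ndarray
    fs: float
    channel_ids: list[str] = field(default=None)
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_samples, n_channels)")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_ids) != self.data.shape[1]:
            raise ValueError("one channel id per data column required")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.shape != (self.data.shape[0],):
                raise ValueError("reference must be one trace of n_samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    # --- HDF5 -------------------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32))
            f.create_dataset("fs", data=float(self.fs))
            f.create_dataset(
                "channel_ids", data=np.array(self.channel_ids, dtype="S")
            )
            if self.reference is not None:
                f.create_dataset("reference", data=self.reference.astype(np.float32))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "Recording":
        with h5py.File(path, "r") as f:
            data = f["data"][()].astype(float)
            fs = float(f["fs"][()])
            ids = [s.decode() for s in f["channel_ids"][()]]
            ref = f["reference"][()].astype(float) if "reference" in f else None
        return cls(data, fs, ids, ref)

    # --- CSV ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write samples × channels with a leading time column (seconds)."""
        df = pd.DataFrame(self.data, columns=self.channel_ids)
        df.insert(0, "time_s", self.times())
        if self.reference is not None:
            df["__reference__"] = self.reference
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, fs: float | None = None) -> "Recording":
        df = pd.read_csv(path)
        ref = None
        if "__reference__" in df.columns:
            ref = df.pop("__reference__").to_numpy()
        if "time_s" in df.columns:
            t = df.pop("time_s").to_numpy()
            if fs is None:
                if t.size < 2:
                    raise ValueError("cannot infer sampling rate from one sample")
                fs = 1.0 / float(np.median(np.diff(t)))
        elif fs is None:
            raise ValueError("fs required when the CSV has no time column")
        return cls(df.to_numpy(dtype=float), fs, list(df.columns), ref)

    # --- EDF (read-only, via MNE) ------------------------------------------
    @classmethod
    def from_edf(cls, path: str | Path) -> "Recording":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("reading EDF requires mne") from exc
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        data = raw.get_data().T * 1e6  # volts -> microvolts
        return cls(data, float(raw.info["sfreq"]), list(raw.ch_names))
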