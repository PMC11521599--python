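"""Raw-recording container and file input/output.

A recording is a channels x samples voltage matrix (microvolts) with a
sampling rate in Hz.  The native interchange format is HDF5 with a dataset
``"data"`` and attributes ``"sampling_rate_hz"`` and ``"channel_ids"``;
CSV (channels as columns, header row of channel ids) and NPZ are
convenience dialects.

All times are seconds relative to recording onset, sample indices are
0-based, and analysis windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "FormatError",
    "read_recording",
    "write_recording",
    "slice_window",
    "write_results",
]


class FormatError(ValueError):
    """Raised when an input file is malformed or lacks required metadata."""


@dataclass
class RawRecording:
    """Multi-channel extracellular voltage recording.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array, microvolts.
    sampling_rate
        Sampling rate in Hz; must be positive.
    channel_ids
        One label per channel; defaults to ``"ch00", "ch01", ...``.
    t0
        Start time of the matrix in seconds relative to recording onset.
    """

    data: np.ndarray
    sampling_rate: float
    channel_ids: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("recording contains non-finite values")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {self.data.shape[0]} channels"
            )
        self.channel_ids = [str(c) for c in self.channel_ids]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the matrix in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (relative to recording onset)."""
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def with_data(self, data: np.ndarray, sampling_rate: float | None = None,
                  t0: float | None = None) -> "RawRecording":
        """Copy of this recording with replaced matrix (and optionally rate/t0)."""
        return RawRecording(
            data=data,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            channel_ids=list(self.channel_ids),
            t0=self.t0 if t0 is None else t0,
        )


def read_recording(path: str | Path, format: str | None = None,
                   sampling_rate: float | None = None) -> RawRecording:
    """Read a recording from HDF5, CSV or NPZ.

    ``format`` defaults to the file suffix (``.h5``/``.hdf5``, ``.csv``,
    ``.npz``).  CSV files carry no rate, so ``sampling_rate`` is required
    for them; for HDF5/NPZ it overrides the stored value if given.
    """
    path = Path(path)
    if format is None:
        format = {".h5": "hdf5", ".hdf5": "hdf5", ".csv": "csv", ".npz": "npz"}.get(
            path.suffix.lower(), "")
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            if "data" not in f:
                raise FormatError(f"{path}: no 'data' dataset")
            data = f["data"][()]
            attrs = f["data"].attrs
            rate = sampling_rate or attrs.get("sampling_rate_hz") or f.attrs.get(
                "sampling_rate_hz")
            ids = attrs.get("channel_ids", f.attrs.get("channel_ids", None))
            t0 = float(attrs.get("t0_s", f.attrs.get("t0_s", 0.0)))
        if rate is None:
            raise FormatError(f"{path}: missing sampling_rate_hz attribute")
        ids = [c.decode() if isinstance(c, bytes) else str(c) for c in ids] if ids is not None else []
        return RawRecording(data=data, sampling_rate=float(rate), channel_ids=ids, t0=t0)
    if format == "csv":
        if sampling_rate is None:
            raise FormatError(f"{path}: CSV carries no sampling rate; pass sampling_rate")
        df = pd.read_csv(path)
        return RawRecording(data=df.to_numpy().T, sampling_rate=float(sampling_rate),
                            channel_ids=[str(c) for c in df.columns])
    if format == "npz":
        with np.load(path, allow_pickle=False) as z:
            if "data" not in z:
                raise FormatError(f"{path}: no 'data' array")
            data = z["data"]
            rate = sampling_rate
            if rate is None:
                if "sampling_rate_hz" not in z:
                    raise FormatError(f"{path}: missing sampling_rate_hz array")
                rate = float(z["sampling_rate_hz"])
            ids = [str(c) for c in z["channel_ids"]] if "channel_ids" in z else []
            t0 = float(z["t0_s"]) if "t0_s" in z else 0.0
        return RawRecording(data=data, sampling_rate=float(rate), channel_ids=ids, t0=t0)
    raise FormatError(f"unknown format {format!r} for {path}")


def write_recording(rec: RawRecording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording to HDF5 (native), CSV or NPZ."""
    path = Path(path)
    if format is None:
        format = {".h5": "hdf5", ".hdf5": "hdf5", ".csv": "csv", ".npz": "npz"}.get(
            path.suffix.lower(), "hdf5")
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            d = f.create_dataset("data", data=rec.data)
            d.attrs["sampling_rate_hz"] = rec.sampling_rate
            d.attrs["channel_ids"] = [c.encode() for c in rec.channel_ids]
            d.attrs["t0_s"] = rec.t0
    elif format == "csv":
        pd.DataFrame(rec.data.T, columns=rec.channel_ids).to_csv(
            path, index=False, float_format="%.15g")
    elif format == "npz":
        np.savez(path, data=rec.data, sampling_rate_hz=rec.sampling_rate,
                 channel_ids=np.asarray(rec.channel_ids), t0_s=rec.t0)
    else:
        raise FormatError(f"unknown format {format!r}")
    return path


def slice_window(rec: RawRecording, start: float, end: float) -> RawRecording:
    """Extract the half-open time window ``[start, end)`` seconds.

    ``start``/``end`` are relative to recording onset (``t0`` aware).  The
    result has exactly ``round((end - start) * rate)`` samples per channel.
    """
    if not (rec.t0 <= start < end <= rec.t0 + rec.duration + 1e-9):
        raise ValueError(
            f"window ({start}, {end}) outside recording "
            f"[{rec.t0}, {rec.t0 + rec.duration})")
    i0 = int(round((start - rec.t0) * rec.sampling_rate))
    n = int(round((end - start) * rec.sampling_rate))
    if i0 + n > rec.n_samples:
        n = rec.n_samples - i0
    return rec.with_data(rec.data[:, i0:i0 + n], t0=rec.t0 + i0 / rec.sampling_rate)


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  config: dict | None = None, seed: int | None = None,
                  overwrite: bool = False) -> Path:
    """Write one CSV per named table plus a JSON run manifest.

    Returns the manifest path.  Raises ``FileExistsError`` on collision
    unless ``overwrite`` is set.
    """
    import astromea

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True")
        df.to_csv(p, index=False)
        written[name] = p.name
    manifest = {
        "tables": written,
        "seed": seed,
        "config": config or {},
        "versions": {"astromea": astromea.__version__, "numpy": np.__version__},
    }
    mpath = out_dir / "manifest.json"
    if mpath.exists() and not overwrite:
        raise FileExistsError(f"{mpath} exists; pass overwrite=True")
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    return mpath
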