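"""EEG containers, file readers/writers, band-pass filtering and segmentation.

Recordings are plain ``channels x samples`` float arrays (microvolts) with a
sampling rate.  Readers exist for EDF (via :mod:`mne`), CSV (one column per
channel, header row = channel names) and NPZ bundles; synthetic cohorts are
written as one NPZ bundle plus a CSV label manifest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EEGRecord",
    "Segment",
    "read_recording",
    "write_cohort",
    "read_cohort",
    "bandpass",
    "segment_channel",
    "segment_record",
]


@dataclass
class EEGRecord:
    """Multichannel EEG time series with per-subject metadata."""

    data: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float
    channel_names: list[str]
    subject_id: str = "unknown"
    class_label: str = "unknown"  # {"normal", "asd", "unknown"}

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got shape {self.data.shape}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if not np.isfinite(self.data).all():
            raise ValueError(f"non-finite samples in record {self.subject_id!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class Segment:
    """A fixed-length single-channel window cut from a recording.

    ``offset`` is a 0-based sample index; the window covers the half-open
    range [offset, offset + len(samples)).
    """

    samples: np.ndarray
    fs: float
    subject_id: str
    channel: str
    offset: int


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    subject_id: str | None = None,
    class_label: str = "unknown",
) -> EEGRecord:
    """Read one EEG recording from EDF, CSV or NPZ.

    ``format`` is inferred from the suffix when omitted.  CSV files carry no
    sampling rate, so ``fs`` must be supplied for them; EDF and NPZ carry
    their own.  Raises on malformed input, never silently truncates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    sid = subject_id if subject_id is not None else path.stem

    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return EEGRecord(
            data=raw.get_data() * 1e6,  # mne returns volts
            fs=float(raw.info["sfreq"]),
            channel_names=list(raw.ch_names),
            subject_id=sid,
            class_label=class_label,
        )
    if format == "csv":
        if fs is None:
            raise ValueError("CSV carries no sampling rate; pass fs explicitly")
        df = pd.read_csv(path)
        if df.isna().any().any():
            bad = [c for c in df.columns if df[c].isna().any()]
            raise ValueError(
                f"inconsistent channel lengths / missing values in CSV columns: {bad}"
            )
        return EEGRecord(
            data=df.to_numpy(dtype=float).T,
            fs=float(fs),
            channel_names=[str(c) for c in df.columns],
            subject_id=sid,
            class_label=class_label,
        )
    if format == "npz":
        with np.load(path, allow_pickle=False) as z:
            if "data" not in z:
                raise ValueError(f"NPZ bundle {path} lacks a 'data' array")
            data = z["data"]
            file_fs = float(z["fs"]) if "fs" in z else None
            names = [str(n) for n in z["channel_names"]] if "channel_names" in z else None
        rate = fs if fs is not None else file_fs
        if rate is None:
            raise ValueError("NPZ bundle carries no 'fs'; pass fs explicitly")
        if names is None:
            names = [f"ch{i}" for i in range(data.shape[0])]
        return EEGRecord(data=data, fs=rate, channel_names=names,
                         subject_id=sid, class_label=class_label)
    raise ValueError(f"unknown recording format {format!r} (expected edf, csv or npz)")


def write_cohort(records: Sequence[EEGRecord], out_dir: str | Path) -> tuple[Path, Path]:
    """Write a cohort as ``cohort.npz`` (one array per subject) + ``manifest.csv``.

    The manifest has columns subject_id, class, fs, n_channels, n_samples and
    is the label source of truth when reading the cohort back.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    rows = []
    for rec in records:
        arrays[rec.subject_id] = rec.data
        arrays[f"_names_{rec.subject_id}"] = np.array(rec.channel_names)
        rows.append(
            dict(subject_id=rec.subject_id, **{"class": rec.class_label},
                 fs=rec.fs, n_channels=rec.n_channels, n_samples=rec.n_samples)
        )
    npz_path = out_dir / "cohort.npz"
    manifest_path = out_dir / "manifest.csv"
    np.savez_compressed(npz_path, **arrays)
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return npz_path, manifest_path


def read_cohort(npz_path: str | Path, manifest_path: str | Path) -> list[EEGRecord]:
    """Inverse of :func:`write_cohort`."""
    manifest = pd.read_csv(manifest_path)
    records = []
    with np.load(npz_path, allow_pickle=False) as z:
        for row in manifest.to_dict("records"):
            sid = str(row["subject_id"])
            names = [str(n) for n in z[f"_names_{sid}"]]
            records.append(
                EEGRecord(data=z[sid], fs=float(row["fs"]), channel_names=names,
                          subject_id=sid, class_label=str(row["class"]))
            )
    return records


def bandpass(
    record: EEGRecord,
    lo: float = 0.3,
    hi: float = 40.0,
    order: int = 4,
) -> EEGRecord:
    """Zero-phase Butterworth band-pass, applied channel-wise.

    Forward-backward filtering (``sosfiltfilt``) doubles the effective order
    and leaves the phase untouched, which matters because downstream
    bispectral statistics are phase-sensitive.
    """
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= record.fs / 2:
        raise ValueError(f"hi={hi} Hz must be below the Nyquist frequency {record.fs / 2} Hz")
    min_len = 3 * (2 * order + 1)
    if record.n_samples < min_len:
        raise ValueError(
            f"record has {record.n_samples} samples; need >= {min_len} for order-{order} filtering"
        )
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=record.fs, output="sos")
    # default padding is far too short for a 0.3 Hz edge; extend toward ~3
    # periods of the low cutoff so start-up transients stay small
    padlen = min(record.n_samples - 1, int(3 * record.fs / lo))
    filtered = sps.sosfiltfilt(sos, record.data, axis=1, padlen=padlen)
    return replace(record, data=np.ascontiguousarray(filtered))


def segment_channel(
    record: EEGRecord,
    channel: str | int,
    L: int = 5519,
    overlap: int = 0,
) -> list[Segment]:
    """Cut one channel into fixed-length windows of L samples.

    Step is ``L - overlap``; the trailing remainder shorter than L is
    discarded.  A channel shorter than L yields an empty list with a warning.
    """
    if isinstance(channel, str):
        try:
            ch_idx = record.channel_names.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not in record {record.subject_id!r}") from None
    else:
        ch_idx = int(channel)
        if not 0 <= ch_idx < record.n_channels:
            raise KeyError(f"channel index {ch_idx} out of range")
    if L < 1:
        raise ValueError("segment length must be >= 1")
    if not 0 <= overlap < L:
        raise ValueError(f"overlap must satisfy 0 <= overlap < L, got {overlap}")
    x = record.data[ch_idx]
    n = x.size
    if L > n:
        warnings.warn(
            f"channel {record.channel_names[ch_idx]!r} of {record.subject_id!r} has "
            f"{n} < L={L} samples; no segments produced",
            stacklevel=2,
        )
        return []
    step = L - overlap
    name = record.channel_names[ch_idx]
    return [
        Segment(samples=x[off : off + L].copy(), fs=record.fs,
                subject_id=record.subject_id, channel=name, offset=off)
        for off in range(0, n - L + 1, step)
    ]


def segment_record(record: EEGRecord, L: int = 5519, overlap: int = 0) -> list[Segment]:
    """All channels' segments, channel-major order."""
    out: list[Segment] = []
    for name in record.channel_names:
        out.extend(segment_channel(record, name, L=L, overlap=overlap))
    return out
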