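"""Epoch containers and readers for EDF and plain CSV matrices.

An :class:`EEGEpoch` is the unit every downstream stage consumes: a
channels × samples matrix with its sampling rate and a case/control
group label.  EDF reading goes through :mod:`mne`; CSV epochs are plain
rectangular numeric tables (rows = channels).  A minimal int16 EDF
writer is included so round trips can be exercised without external
recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

GROUPS = ("case", "control", "unknown")


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class EEGEpoch:
    """One subject/epoch's multichannel signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal values in arbitrary units.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique labels, one per row of ``samples``.
    subject_id : str
    group : {"case", "control", "unknown"}
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time matrix")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.shape[1] < 16:
            raise ValueError(
                f"epoch too short: {self.samples.shape[1]} samples, need >= 16"
            )
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]


def read_csv_epoch(
    path: str | Path,
    fs: float,
    subject_id: str = "",
    group: str = "unknown",
    channel_labels: list[str] | None = None,
) -> EEGEpoch:
    """Read a rectangular numeric CSV (rows = channels) into an epoch."""
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    mat = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = ~np.isfinite(mat)
    if bad.any():  # ragged rows surface as NaN padding
        row = int(np.argwhere(bad)[0, 0])
        raise FormatError(f"{path}: non-numeric or missing cell in row {row}")
    labels = channel_labels or [f"ch{i}" for i in range(mat.shape[0])]
    return EEGEpoch(mat.astype(float), fs, labels, subject_id, group)


def read_manifest(manifest_path: str | Path) -> list[EEGEpoch]:
    """Read a dataset manifest CSV (subject_id, group, fs, file) into epochs.

    File paths are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path)
    required = {"subject_id", "group", "fs", "file"}
    if not required.issubset(man.columns):
        raise FormatError(
            f"manifest missing columns {sorted(required - set(man.columns))}"
        )
    epochs = []
    for _, row in man.iterrows():
        epochs.append(
            read_csv_epoch(
                manifest_path.parent / row["file"],
                fs=float(row["fs"]),
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
            )
        )
    return epochs


def read_edf(path: str | Path, channels: list[str] | None = None) -> list[EEGEpoch]:
    """Read an EDF file, keeping ``channels`` in the requested order.

    Returns a single-element list (one epoch for the whole record run);
    the list form keeps the signature uniform with epoched sources.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise FormatError(f"{path}: not a readable EDF ({exc})") from exc
    available = list(raw.ch_names)
    if channels is None:
        channels = available
    missing = [c for c in channels if c not in available]
    if missing:
        raise KeyError(
            f"channels {missing} not in file; available: {available}"
        )
    data = raw.get_data(picks=channels)
    # mne rescales channels it recognises as EEG to volts; undo so the
    # caller sees the file's physical units.
    scale = np.array(
        [1e6 if raw.get_channel_types(picks=[c])[0] == "eeg" else 1.0
         for c in channels]
    )
    data = data * scale[:, None]
    return [EEGEpoch(data, float(raw.info["sfreq"]), list(channels),
                     subject_id=path.stem)]


def write_edf(path: str | Path, epoch: EEGEpoch) -> None:
    """Write an epoch as a minimal single-record 16-bit EDF file.

    Quantization: each channel's physical range maps onto the full
    digital range [-32768, 32767].
    """
    path = Path(path)
    data = epoch.samples
    n_ch, n_samp = data.shape
    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = np.where(phys_max > phys_min, phys_max - phys_min, 1.0)
    dig = np.round(
        (data - phys_min[:, None]) / span[:, None] * 65535.0 - 32768.0
    ).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return f"{text:<{width}}".encode("ascii")[:width]

    header = b"".join([
        f("0", 8),
        f(epoch.subject_id or "X", 80),
        f("eegsense", 80),
        f("01.01.00", 8),
        f("00.00.00", 8),
        f(str(256 * (1 + n_ch)), 8),
        f("", 44),
        f("1", 8),                       # one data record
        f(repr(n_samp / epoch.fs), 8),   # record duration in seconds
        f(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(f(lbl, 16) for lbl in epoch.channel_labels),
        b"".join(f("", 80) for _ in range(n_ch)),
        b"".join(f("uV", 8) for _ in range(n_ch)),
        b"".join(f(f"{phys_min[i]:.6g}", 8) for i in range(n_ch)),
        b"".join(f(f"{phys_max[i]:.6g}", 8) for i in range(n_ch)),
        b"".join(f("-32768", 8) for _ in range(n_ch)),
        b"".join(f("32767", 8) for _ in range(n_ch)),
        b"".join(f("", 80) for _ in range(n_ch)),
        b"".join(f(str(n_samp), 8) for _ in range(n_ch)),
        b"".join(f("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        fh.write(dig.tobytes())


def resample_epoch(epoch: EEGEpoch, target_fs: float) -> EEGEpoch:
    """Anti-aliased rate conversion of every channel to ``target_fs``.

    The new length is ``round(n * target_fs / fs)``.  A linear-fit pad
    (``padtype='line'``) keeps constant signals exactly constant.
    """
    if target_fs <= 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if target_fs == epoch.fs:
        return replace(epoch, samples=epoch.samples.copy())
    ratio = Fraction(target_fs / epoch.fs).limit_denominator(10_000)
    out = sps.resample_poly(
        epoch.samples, ratio.numerator, ratio.denominator, axis=1,
        padtype="line",
    )
    n_target = int(round(epoch.n_times * target_fs / epoch.fs))
    out = out[:, :n_target]
    if out.shape[1] < n_target:  # pragma: no cover - resample_poly never shorter
        out = np.pad(out, ((0, 0), (0, n_target - out.shape[1])), mode="edge")
    return EEGEpoch(out, target_fs, list(epoch.channel_labels),
                    epoch.subject_id, epoch.group)
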