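"""Seeded synthetic two-group EEG generator.

Each channel of an epoch is the sum of spectrally shaped 1/f background
noise, band-limited oscillations in the five conventional sub-bands and
white measurement noise.  The "case" group differs from "control" in
two controlled ways modelled on reported group contrasts in the gamma
and alpha bands:

* gamma-band oscillation power is multiplied by
  ``gamma_power_ratio ** effect_size``;
* the alpha oscillation is mixed toward a pure 10 Hz sinusoid with
  mixing weight ``min(1, alpha_regularity * effect_size)``, raising its
  regularity (hence lowering its entropy).

At ``effect_size = 0`` both groups are drawn from the same
distribution, giving an exact null for calibration tests.  Subjects
get multiplicative per-band gain variability (log-normal) so
between-subject variance exists at every effect size; epochs within a
subject share the subject's gains.  Amplitudes are arbitrary units —
downstream features are scale-aware or normalised, so no attempt is
made to match microvolt scales.

Determinism: all draws derive from ``numpy.random.SeedSequence(seed)``
spawned per subject and epoch, so a fixed config reproduces the
dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EEGEpoch

_DEFAULT_CHANNELS = ("P8", "TP8", "T8", "P7", "FT8", "TP7", "F8", "T7",
                     "FT7", "F7")

#: (center frequency Hz, baseline oscillation SD) per band
_BAND_OSC = {
    "delta": (1.5, 0.9),
    "theta": (4.5, 0.6),
    "alpha": (10.0, 1.0),
    "beta": (18.0, 0.4),
    "gamma": (35.0, 0.35),
}
_BAND_WIDTH = {"delta": 1.2, "theta": 1.5, "alpha": 2.0, "beta": 6.0,
               "gamma": 12.0}


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class SynthConfig:
    n_per_group: int = 15
    n_channels: int = 10
    fs: float = 1000.0
    epoch_ms: float = 400.0
    n_epochs_per_subject: int = 80
    effect_size: float = 1.0
    gamma_power_ratio: float = 1.5
    alpha_regularity: float = 0.25
    subject_sd: float = 0.1       # log-normal sigma of per-subject band gains
    noise_sd: float = 0.5         # white measurement noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if self.n_channels < 1:
            raise ConfigError("n_channels must be >= 1")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if self.epoch_ms * self.fs / 1000.0 < 32:
            raise ConfigError(
                "epoch_ms too short: need >= 32 samples (epoch_ms * fs / 1000)"
            )
        if self.n_epochs_per_subject < 1:
            raise ConfigError("n_epochs_per_subject must be >= 1")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.gamma_power_ratio <= 0:
            raise ConfigError("gamma_power_ratio must be positive")
        if not 0.0 <= self.alpha_regularity <= 1.0:
            raise ConfigError("alpha_regularity must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_ms * self.fs / 1000.0))


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-shaped noise, unit SD: white spectrum scaled by f^-1/2."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f / f[1])
    x = np.fft.irfft(spec, n)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _narrowband(rng: np.random.Generator, n: int, fs: float,
                center: float, width: float) -> np.ndarray:
    """Band-limited noise of unit SD around ``center`` (Hz)."""
    lo = max(center - width, 0.1)
    hi = min(center + width, 0.49 * fs)
    if hi <= lo:
        hi = lo * 1.5
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    pad = int(fs)  # settle the filter before taking the epoch
    x = sps.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _epoch_samples(cfg: SynthConfig, rng: np.random.Generator,
                   band_gains: np.ndarray, is_case: bool) -> np.ndarray:
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    alpha_mix = min(1.0, cfg.alpha_regularity * cfg.effect_size) if is_case else 0.0
    gamma_gain = cfg.gamma_power_ratio ** (cfg.effect_size / 2.0) if is_case else 1.0
    out = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        x = _pink_noise(rng, n)
        for b, (band, (f0, sd)) in enumerate(_BAND_OSC.items()):
            f0 = min(f0, 0.45 * cfg.fs)
            osc = _narrowband(rng, n, cfg.fs, f0, _BAND_WIDTH[band])
            if band == "alpha" and alpha_mix > 0:
                sine = np.sqrt(2.0) * np.sin(
                    2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi)
                )
                osc = (1 - alpha_mix) * osc + alpha_mix * sine
            amp = sd * band_gains[b]
            if band == "gamma":
                amp *= gamma_gain
            x = x + amp * osc
        x += cfg.noise_sd * rng.standard_normal(n)
        out[c] = x
    return out


def generate_dataset(cfg: SynthConfig) -> list[EEGEpoch]:
    """Generate ``2 * n_per_group`` subjects' epochs with group labels."""
    if not isinstance(cfg, SynthConfig):
        raise ConfigError("cfg must be a SynthConfig")
    root = np.random.SeedSequence(cfg.seed)
    n_subjects = 2 * cfg.n_per_group
    subject_seeds = root.spawn(n_subjects)
    channels = (
        list(_DEFAULT_CHANNELS[: cfg.n_channels])
        if cfg.n_channels <= len(_DEFAULT_CHANNELS)
        else [f"ch{i}" for i in range(cfg.n_channels)]
    )
    epochs: list[EEGEpoch] = []
    for s in range(n_subjects):
        is_case = s < cfg.n_per_group
        group = "case" if is_case else "control"
        sid = f"{group}{s % cfg.n_per_group:02d}"
        sub_rng = np.random.default_rng(subject_seeds[s])
        band_gains = np.exp(
            sub_rng.normal(0.0, cfg.subject_sd, size=len(_BAND_OSC))
        )
        epoch_seeds = subject_seeds[s].spawn(cfg.n_epochs_per_subject)
        for e in range(cfg.n_epochs_per_subject):
            rng = np.random.default_rng(epoch_seeds[e])
            samples = _epoch_samples(cfg, rng, band_gains, is_case)
            epochs.append(EEGEpoch(samples, cfg.fs, channels, sid, group))
    return epochs


def write_dataset(epochs: list[EEGEpoch], out_dir: str | Path) -> Path:
    """Write one CSV per epoch (rows = channels) plus a manifest CSV.

    Returns the manifest path; :func:`eegsense.io.read_manifest` reads
    it back into identical epochs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    counters: dict[str, int] = {}
    for ep in epochs:
        k = counters.get(ep.subject_id, 0)
        counters[ep.subject_id] = k + 1
        fname = f"{ep.subject_id}_e{k:03d}.csv"
        pd.DataFrame(ep.samples).to_csv(out_dir / fname, header=False,
                                        index=False)
        records.append({"subject_id": ep.subject_id, "group": ep.group,
                        "fs": ep.fs, "file": fname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest
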