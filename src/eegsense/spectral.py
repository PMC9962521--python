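"""Welch power spectral density and sub-band powers.

The PSD is the mean of Hann-windowed, 50%-overlapped, mean-detrended
modified periodograms (scipy's Welch estimator with density scaling),
run at the epoch's original sampling rate over 100 ms windows.
Band powers integrate the PSD over half-open bins [lo, hi) on bin
centers; relative powers divide by the total over the five bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

#: wavelet-aligned band edges (Hz) — the default, so spectral and
#: wavelet features describe the same bands at the 100 Hz analysis rate
BAND_EDGES_WAVELET = {
    "delta": (0.1, 3.0),
    "theta": (3.0, 6.0),
    "alpha": (6.0, 12.0),
    "beta": (12.0, 25.0),
    "gamma": (25.0, 50.0),
}

#: canonical clinical band edges (Hz), available as a preset
BAND_EDGES_CLINICAL = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 100.0),
}

BAND_EDGE_PRESETS = {
    "wavelet": BAND_EDGES_WAVELET,
    "clinical": BAND_EDGES_CLINICAL,
}


@dataclass
class PSDEstimate:
    freqs: np.ndarray          # Hz, 0 .. fs/2
    power: np.ndarray          # units^2 / Hz
    window_ms: float = 100.0
    overlap: float = 0.5
    window_type: str = "hann"


@dataclass
class BandPower:
    """Absolute (integrated PSD) and relative power per band."""

    absolute: dict[str, float]
    relative: dict[str, float]
    total: float
    undefined: bool = False  # True when total power is zero


def welch_psd(
    signal: np.ndarray,
    fs: float,
    window_ms: float = 100.0,
    overlap: float = 0.5,
) -> PSDEstimate:
    """Welch PSD of a 1-D series.

    Raises if the series is shorter than one window
    (``round(window_ms * fs / 1000)`` samples, minimum 8).
    """
    x = np.asarray(signal, dtype=float)
    nperseg = max(int(round(window_ms * fs / 1000.0)), 8)
    if len(x) < nperseg:
        raise ValueError(
            f"signal of length {len(x)} shorter than one Welch window "
            f"({nperseg} samples at {fs} Hz)"
        )
    freqs, power = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="constant",
        scaling="density",
    )
    return PSDEstimate(freqs, power, window_ms, overlap)


def band_powers(
    psd: PSDEstimate, band_edges: dict[str, tuple[float, float]] | None = None
) -> BandPower:
    """Integrate the PSD into absolute and relative band powers.

    Bin inclusion is half-open on bin centers: a bin belongs to
    [lo, hi) of the first band containing its center frequency.
    A zero-total signal yields all-zero powers with ``undefined=True``.
    """
    edges = band_edges or BAND_EDGES_WAVELET
    df = float(np.median(np.diff(psd.freqs)))
    absolute = {}
    for band, (lo, hi) in edges.items():
        mask = (psd.freqs >= lo) & (psd.freqs < hi)
        absolute[band] = float(np.sum(psd.power[mask]) * df)
    total = float(sum(absolute.values()))
    if total <= 0.0:
        return BandPower(absolute, {b: 0.0 for b in edges}, total, undefined=True)
    relative = {b: a / total for b, a in absolute.items()}
    return BandPower(absolute, relative, total)
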