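"""Orthonormal Haar wavelet sub-band decomposition.

A 4-level Haar analysis splits each channel into detail sequences
D1..D4 and a final approximation A4, labelled with the conventional EEG
sub-bands (at a 100 Hz analysis rate: gamma 25-50, beta 12-25,
alpha 6-12, theta 3-6, delta <3 Hz):

======  =====  =========
level   coeff  band
======  =====  =========
1       D1     gamma
2       D2     beta
3       D3     alpha
4       D4     theta
4       A4     delta
======  =====  =========

The orthonormal convention (a = (x[2j]+x[2j+1])/sqrt(2),
d = (x[2j]-x[2j+1])/sqrt(2)) is used throughout.  It yields Parseval
energy conservation and makes the approximation path an exact multiple
of multiscale coarse-graining: A_k = 2^(k/2) * coarse_grain(x, 2^k),
which is what lets the wavelet stage double as the multiscale-entropy
front end.  Odd-length levels replicate their trailing sample before
pairing (a deterministic, length-preserving boundary rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EEGEpoch

SQRT2 = np.sqrt(2.0)

#: band label for each detail level, plus the final approximation
DETAIL_BANDS = {1: "gamma", 2: "beta", 3: "alpha", 4: "theta"}
APPROX_BAND = "delta"
BAND_ORDER = ("gamma", "beta", "alpha", "theta", "delta")


def _haar_step(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One analysis level; odd lengths replicate the trailing sample."""
    if len(x) % 2:
        x = np.concatenate([x, x[-1:]])
    even, odd = x[0::2], x[1::2]
    return (even + odd) / SQRT2, (even - odd) / SQRT2


@dataclass
class HaarBands:
    """Single-channel band-labelled coefficient sequences."""

    bands: dict[str, np.ndarray]
    level_lengths: list[int]  # input length at each analysis level
    levels: int = 4
    wavelet_name: str = "haar"

    def __getitem__(self, band: str) -> np.ndarray:
        return self.bands[band]


@dataclass
class BandDecomposition:
    """Per-channel Haar band decomposition of an epoch."""

    channels: dict[str, HaarBands]
    levels: int = 4
    wavelet_name: str = "haar"


def haar_decompose(signal: np.ndarray, levels: int = 4) -> HaarBands:
    """Decompose a 1-D series into D1..D_levels and the final approximation.

    Bands are labelled per the level table above when ``levels == 4``;
    for other depths the keys are ``"D1"``.. and ``"A{levels}"``.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if len(x) < 2 ** levels:
        raise ValueError(
            f"signal of length {len(x)} too short for {levels} levels; "
            f"need >= {2 ** levels} samples"
        )
    bands: dict[str, np.ndarray] = {}
    lengths: list[int] = []
    approx = x
    for level in range(1, levels + 1):
        lengths.append(len(approx))
        approx, detail = _haar_step(approx)
        key = DETAIL_BANDS[level] if levels == 4 else f"D{level}"
        bands[key] = detail
    bands[APPROX_BAND if levels == 4 else f"A{levels}"] = approx
    return HaarBands(bands, lengths, levels)


def haar_reconstruct(dec: HaarBands) -> np.ndarray:
    """Invert :func:`haar_decompose` (exact when no odd-length padding occurred)."""
    levels = dec.levels
    approx_key = APPROX_BAND if levels == 4 else f"A{levels}"
    approx = dec.bands[approx_key]
    for level in range(levels, 0, -1):
        key = DETAIL_BANDS[level] if levels == 4 else f"D{level}"
        detail = dec.bands[key]
        out = np.empty(2 * len(approx))
        out[0::2] = (approx + detail) / SQRT2
        out[1::2] = (approx - detail) / SQRT2
        approx = out[: dec.level_lengths[level - 1]]
    return approx


def decompose_epoch(epoch: EEGEpoch, levels: int = 4) -> BandDecomposition:
    """Per-channel Haar decomposition keyed by channel label."""
    channels = {
        label: haar_decompose(epoch.samples[i], levels)
        for i, label in enumerate(epoch.channel_labels)
    }
    return BandDecomposition(channels, levels)


def coarse_grain(y: np.ndarray, tau: int) -> np.ndarray:
    """Block-average ``y`` at scale ``tau``; the trailing remainder is dropped."""
    y = np.asarray(y, dtype=float)
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    if tau > len(y):
        raise ValueError(f"tau={tau} exceeds series length {len(y)}")
    n_blocks = len(y) // tau
    return y[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


def haar_approximation(signal: np.ndarray, k: int) -> np.ndarray:
    """The level-``k`` approximation sequence A_k of the Haar analysis."""
    x = np.asarray(signal, dtype=float)
    for _ in range(k):
        x, _d = _haar_step(x)
    return x


def coarse_equivalence_check(
    signal: np.ndarray, k: int, atol: float = 1e-9
) -> bool:
    """Whether A_k equals 2^(k/2) times the scale-2^k coarse-grained series.

    Exact (up to rounding) whenever ``len(signal)`` is a multiple of 2^k,
    which the precondition requires.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) % 2 ** k:
        raise ValueError(f"length {len(signal)} not a multiple of 2^{k}")
    a_k = haar_approximation(signal, k)
    cg = coarse_grain(signal, 2 ** k)
    return bool(np.allclose(a_k, 2 ** (k / 2) * cg, atol=atol, rtol=0))
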