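"""Per-channel, per-band feature extraction and the subject feature table.

Twelve features per channel-band: two spectral (absolute and relative
Welch band power, computed at the epoch's original rate), three
statistical (RMS, variance, coefficient of variation = variance/mean)
and seven information-dynamics features (Shannon entropy plus raw and
min-max-normalised approximate, sample and modified-sample entropies),
the latter computed on the band's Haar coefficient sequence.  Because
the Haar approximation path equals multiscale coarse-graining up to a
2^(k/2) gain — and the entropy tolerance r scales with the series SD —
the band entropies realise multiscale entropy at scales 2^k without a
separate coarse-graining pass.

For C channels the subject vector has C x 5 bands x 12 = 60C entries
(600 at C = 10).  Normalised entropy variants are population-relative:
they are left missing at extraction time and filled by
:meth:`FeatureTable.fill_normalized` with min/max fitted on a chosen
(training) subset.  Undefined values (CV at zero mean, entropies on
too-short sequences, no-match sample entropy) propagate as NaN and are
imputed with the training-fold median before selection/classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EEGEpoch, resample_epoch
from .spectral import BAND_EDGE_PRESETS, band_powers, welch_psd
from .wavelet import BAND_ORDER, coarse_grain, decompose_epoch  # noqa: F401

FEATURE_NAMES = (
    "abs_welch", "rel_welch", "rms", "variance", "cv", "shannon",
    "apen", "apen_norm", "samen", "samen_norm", "msamen", "msamen_norm",
)
_ENTROPY_RAW = ("apen", "samen", "msamen")


@dataclass
class EntropyParams:
    """Template-matching entropy parameters.

    m : embedding length; r_coeff : tolerance as a fraction of the
    series SD; sigmoid_center_coeff : center of the modified-sample
    sigmoid, as a fraction of r; shannon_bins : histogram bins for
    Shannon entropy on continuous coefficients; msamen_exponent :
    'literal' reads the sigmoid argument as d - 0.5 r, 'scaled' as
    (d - 0.5 r)/r.
    """

    m: int = 2
    r_coeff: float = 0.15
    sigmoid_center_coeff: float = 0.5
    shannon_bins: int = 16
    msamen_exponent: str = "literal"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_coeff <= 0:
            raise ValueError("r_coeff must be positive")
        if self.shannon_bins < 2:
            raise ValueError("shannon_bins must be >= 2")
        if self.msamen_exponent not in ("literal", "scaled"):
            raise ValueError("msamen_exponent must be 'literal' or 'scaled'")


def statistical_features(coeffs: np.ndarray) -> tuple[float, float, float]:
    """(RMS, sample variance, CV = variance / mean); CV is NaN at zero mean."""
    x = np.asarray(coeffs, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    rms = float(np.sqrt(np.mean(x ** 2)))
    mu = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    cv = var / mu if mu != 0.0 else float("nan")
    return rms, var, cv


def _templates(x: np.ndarray, m: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, m)


def _cheb_dist(T: np.ndarray) -> np.ndarray:
    return np.max(np.abs(T[:, None, :] - T[None, :, :]), axis=2)


def _tolerance(x: np.ndarray, p: EntropyParams) -> float:
    return p.r_coeff * float(np.std(x))


def apen(x: np.ndarray, p: EntropyParams | None = None,
         printed_form: bool = False) -> float:
    """Approximate entropy with Chebyshev distance and self-matches included.

    Standard form: phi^m - phi^{m+1} with
    phi^m = mean_i ln(n_i^m / (N - m + 1)).  ``printed_form`` instead
    averages the ratio ln(n_i^m)/ln(n_i^{m+1}) over the first N - m
    templates; it is exposed only for comparison and can be undefined
    (division by ln 1 = 0).
    """
    p = p or EntropyParams()
    x = np.asarray(x, dtype=float)
    N = len(x)
    if N < p.m + 2:
        raise ValueError(f"series of length {N} too short; need >= {p.m + 2}")
    r = _tolerance(x, p)

    def counts(m: int) -> np.ndarray:
        d = _cheb_dist(_templates(x, m))
        return np.sum(d <= r, axis=1)  # self-match included

    n_m, n_m1 = counts(p.m), counts(p.m + 1)
    if printed_form:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.log(n_m[: N - p.m]) / np.log(n_m1)
        return float(np.mean(ratio))
    phi_m = float(np.mean(np.log(n_m / (N - p.m + 1))))
    phi_m1 = float(np.mean(np.log(n_m1 / (N - p.m))))
    return phi_m - phi_m1


def _pair_counts(x: np.ndarray, m: int, r: float) -> tuple[float, float]:
    """(B, A): matched template pairs at lengths m and m+1, self excluded.

    Both counts run over the same N - m templates so a constant series
    gives B = A exactly.
    """
    N = len(x)
    n_t = N - m
    d_m = _cheb_dist(_templates(x, m)[:n_t])
    d_m1 = _cheb_dist(_templates(x, m + 1))
    off = ~np.eye(n_t, dtype=bool)
    return float(np.sum((d_m <= r) & off)), float(np.sum((d_m1 <= r) & off))


def samen(x: np.ndarray, p: EntropyParams | None = None) -> float:
    """Sample entropy ln(B/A), self-matches excluded.

    Returns NaN when no template pair matches at length m (nothing to
    compare) and the guarded maximum ln(B) when pairs match at m but
    none survive at m+1.
    """
    p = p or EntropyParams()
    x = np.asarray(x, dtype=float)
    if len(x) < p.m + 2:
        raise ValueError(f"series of length {len(x)} too short; need >= {p.m + 2}")
    B, A = _pair_counts(x, p.m, _tolerance(x, p))
    if B == 0:
        return float("nan")
    if A == 0:
        return float(np.log(B))
    return float(np.log(B / A))


def msamen(x: np.ndarray, p: EntropyParams | None = None) -> float:
    """Modified sample entropy: the 0/1 match is a sigmoid weight.

    Each template pair contributes D = 1 / (1 + exp(d - 0.5 r))
    (or exp((d - 0.5 r)/r) with ``msamen_exponent='scaled'``); the
    entropy is ln(sum D^m / sum D^{m+1}).
    """
    p = p or EntropyParams()
    x = np.asarray(x, dtype=float)
    N = len(x)
    if N < p.m + 2:
        raise ValueError(f"series of length {N} too short; need >= {p.m + 2}")
    r = _tolerance(x, p)
    n_t = N - p.m
    off = ~np.eye(n_t, dtype=bool)

    def weights(d: np.ndarray) -> float:
        arg = d - p.sigmoid_center_coeff * r
        if p.msamen_exponent == "scaled":
            arg = arg / r if r > 0 else np.where(arg > 0, np.inf, -np.inf)
        with np.errstate(over="ignore"):
            w = 1.0 / (1.0 + np.exp(arg))
        return float(np.sum(w[off]))

    B = weights(_cheb_dist(_templates(x, p.m)[:n_t]))
    A = weights(_cheb_dist(_templates(x, p.m + 1)))
    if B == 0:
        return float("nan")
    return float(np.log(B / A)) if A > 0 else float(np.log(B))


def sigmoid_weight(d: float, r: float, p: EntropyParams | None = None) -> float:
    """The modified-sample-entropy similarity weight for one distance."""
    p = p or EntropyParams()
    arg = d - p.sigmoid_center_coeff * r
    if p.msamen_exponent == "scaled" and r > 0:
        arg /= r
    return float(1.0 / (1.0 + np.exp(arg)))


def shannon_entropy(x: np.ndarray, p: EntropyParams | None = None) -> float:
    """Histogram Shannon entropy (natural log, equal-width bins over [min, max])."""
    p = p or EntropyParams()
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty series")
    if np.min(x) == np.max(x):
        return 0.0
    counts, _ = np.histogram(x, bins=p.shannon_bins)
    probs = counts[counts > 0] / len(x)
    return float(-np.sum(probs * np.log(probs)))


def minmax_normalize(values: np.ndarray, fit_values: np.ndarray) -> np.ndarray:
    """(v - min) / (max - min) with min/max from the fit population.

    Applied without clipping, so out-of-population values can leave
    [0, 1].  A degenerate fit population (max == min) yields NaN.
    """
    values = np.asarray(values, dtype=float)
    fit = np.asarray(fit_values, dtype=float)
    if np.all(np.isnan(fit)):
        return np.full_like(values, np.nan)
    lo, hi = np.nanmin(fit), np.nanmax(fit)
    if hi == lo:
        return np.full_like(values, np.nan)
    return (values - lo) / (hi - lo)


@dataclass
class FeatureConfig:
    """Knobs of the extraction stage.

    wavelet_fs is the analysis rate of the Haar stage (100 Hz aligns
    the 4-level bands with the labelled sub-band edges); the Welch
    stage always runs at the epoch's original rate.
    """

    band_edges: str | dict = "wavelet"
    entropy: EntropyParams = field(default_factory=EntropyParams)
    wavelet_fs: float = 100.0
    welch_window_ms: float = 100.0
    welch_overlap: float = 0.5
    levels: int = 4

    def edges(self) -> dict[str, tuple[float, float]]:
        if isinstance(self.band_edges, str):
            return BAND_EDGE_PRESETS[self.band_edges]
        return self.band_edges


def extract_features(
    epoch: EEGEpoch, config: FeatureConfig | None = None
) -> pd.Series:
    """One subject-epoch's feature row, indexed by (channel, band, feature)."""
    cfg = config or FeatureConfig()
    edges = cfg.edges()
    wav_epoch = (
        resample_epoch(epoch, cfg.wavelet_fs)
        if epoch.fs != cfg.wavelet_fs
        else epoch
    )
    dec = decompose_epoch(wav_epoch, cfg.levels)
    values: dict[tuple[str, str, str], float] = {}
    for i, ch in enumerate(epoch.channel_labels):
        bp = band_powers(
            welch_psd(epoch.samples[i], epoch.fs,
                      cfg.welch_window_ms, cfg.welch_overlap),
            edges,
        )
        for band in BAND_ORDER:
            coeffs = dec.channels[ch][band]
            rms, var, cv = statistical_features(coeffs)
            row = {
                "abs_welch": bp.absolute[band],
                "rel_welch": bp.relative[band],
                "rms": rms,
                "variance": var,
                "cv": cv,
                "shannon": shannon_entropy(coeffs, cfg.entropy),
            }
            if len(coeffs) >= cfg.entropy.m + 2:
                row["apen"] = apen(coeffs, cfg.entropy)
                row["samen"] = samen(coeffs, cfg.entropy)
                row["msamen"] = msamen(coeffs, cfg.entropy)
            else:  # too short to embed: flagged missing, filled later
                row["apen"] = row["samen"] = row["msamen"] = float("nan")
            row["apen_norm"] = row["samen_norm"] = row["msamen_norm"] = float("nan")
            for name in FEATURE_NAMES:
                values[(ch, band, name)] = row[name]
    index = pd.MultiIndex.from_tuples(
        [(ch, band, name)
         for ch in epoch.channel_labels
         for band in BAND_ORDER
         for name in FEATURE_NAMES],
        names=["channel", "band", "feature"],
    )
    return pd.Series([values[key] for key in index], index=index)


@dataclass
class FeatureTable:
    """Subjects x features matrix with (channel, band, feature) metadata."""

    data: pd.DataFrame        # index: subject_id; columns: MultiIndex
    groups: pd.Series         # subject_id -> case/control/unknown

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.data.index)
        dup = self.data.columns.duplicated()
        if dup.any():
            raise ValueError("duplicated (channel, band, feature) keys")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def fill_normalized(self, fit_index=None) -> "FeatureTable":
        """Fill *_norm entropy columns using min/max fitted on ``fit_index``.

        Fitting on the training subjects only keeps the test folds
        leakage-free; test values are not clipped to [0, 1].
        """
        fit_index = self.data.index if fit_index is None else fit_index
        data = self.data.copy()
        for ch, band, feat in data.columns:
            if feat not in _ENTROPY_RAW:
                continue
            raw = data[(ch, band, feat)]
            data[(ch, band, feat + "_norm")] = minmax_normalize(
                raw.to_numpy(), raw.loc[fit_index].to_numpy()
            )
        return FeatureTable(data, self.groups)

    def impute_median(self, fit_index=None) -> "FeatureTable":
        """Replace NaN with the per-column median of ``fit_index`` rows.

        Columns that are entirely missing on the fit rows become 0
        (constant, hence inert for selection and classification).
        """
        fit_index = self.data.index if fit_index is None else fit_index
        med = self.data.loc[fit_index].median()
        data = self.data.fillna(med).fillna(0.0)
        return FeatureTable(data, self.groups)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, ("subject", "meta", "group"), self.groups.values)
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        df.columns.names = ["channel", "band", "feature"]
        groups = df.pop(("subject", "meta", "group"))
        return cls(df, pd.Series(groups.values, index=df.index, name="group"))


def build_feature_table(
    epochs: list[EEGEpoch], config: FeatureConfig | None = None
) -> FeatureTable:
    """Extract features for every epoch and average them per subject."""
    cfg = config or FeatureConfig()
    rows: dict[str, list[pd.Series]] = {}
    groups: dict[str, str] = {}
    for ep in epochs:
        rows.setdefault(ep.subject_id, []).append(extract_features(ep, cfg))
        prev = groups.setdefault(ep.subject_id, ep.group)
        if prev != ep.group:
            raise ValueError(f"subject {ep.subject_id} has inconsistent groups")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        data = pd.DataFrame(
            {sid: pd.concat(series, axis=1).mean(axis=1)
             for sid, series in rows.items()}
        ).T
    data.index.name = "subject_id"
    data.columns.names = ["channel", "band", "feature"]
    return FeatureTable(data, pd.Series(groups, name="group").loc[data.index])
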