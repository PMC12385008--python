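"""Multi-domain EEG feature extraction: 527 features per channel.

Per channel the extractor concatenates, in a fixed documented order:

* 13 time-domain statistics — mean, standard deviation, variance, median,
  skewness, zero-crossing rate, Hjorth activity/mobility/complexity, RMS,
  Shannon amplitude entropy, line length, nonlinear (Teager-like) energy;
* 224 wavelet-packet statistics — a 5-level db2 packet tree has 32 terminal
  subbands, each summarised by 7 statistics (mean, median, energy,
  skewness, kurtosis, variance, spectral entropy of the subband);
* 3 spectral scalars — total energy, instantaneous weighted mean frequency
  (IWMF) and instantaneous weighted bandwidth (IWBF) from the normalized
  Welch PSD;
* 257 spectral-kurtosis values — per-bin kurtosis of the one-sided
  512-sample STFT magnitude (257 bins);
* 30 texture values — 10-bin normalized histograms of 1-D local binary
  pattern (LBP), local neighborhood difference pattern (LNDP) and local
  gradient pattern (LGP) codes.

13 + 224 + 3 + 257 + 30 = 527.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pywt
from scipy.signal import ShortTimeFFT, welch
from scipy.signal.windows import hann
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew
from sklearn.base import BaseEstimator, TransformerMixin

from .data import MultiChannelRecording, TrialSet

__all__ = [
    "FEATURES_PER_CHANNEL",
    "time_domain_features",
    "hjorth_parameters",
    "wpt_subband_features",
    "spectral_features",
    "instantaneous_mean_frequency",
    "instantaneous_bandwidth",
    "texture_features",
    "extract_mef",
    "feature_names",
    "MEFExtractor",
]

N_TIME_FEATURES = 13
N_WPT_SUBBANDS = 32
WPT_STATS = ("mean", "median", "energy", "skewness", "kurtosis", "variance", "entropy")
N_WPT_FEATURES = N_WPT_SUBBANDS * len(WPT_STATS)  # 224
N_SK_BINS = 257  # one-sided bins of a 512-sample segment
N_TEXTURE_BINS = 10
SK_SEGMENT = 512
ENTROPY_BINS = 64

TIME_FEATURE_NAMES = (
    "mean",
    "sd",
    "variance",
    "median",
    "skewness",
    "zcr",
    "activity",
    "mobility",
    "complexity",
    "rms",
    "shannon_entropy",
    "line_length",
    "nonlinear_energy",
)

FEATURES_PER_CHANNEL = (
    N_TIME_FEATURES + N_WPT_FEATURES + 3 + N_SK_BINS + 3 * N_TEXTURE_BINS
)
assert FEATURES_PER_CHANNEL == 527


def shannon_amplitude_entropy(x: np.ndarray, bins: int = ENTROPY_BINS) -> float:
    """Shannon entropy (nats) of the equal-width amplitude histogram.

    A constant signal puts all mass in one bin and scores 0; empty bins
    contribute 0.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def hjorth_parameters(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity.

    Activity is the sample variance (N-1 denominator). Mobility is
    sqrt(activity(dx)/activity(x)) with dx the first difference; complexity
    is mobility(dx)/mobility(x). Degenerate (zero-variance) input returns
    (0, 0, 0) by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Hjorth complexity needs at least 3 samples")
    act = float(np.var(x, ddof=1))
    if act == 0.0:
        return 0.0, 0.0, 0.0
    dx = np.diff(x)
    act_d = float(np.var(dx, ddof=1))
    mob = float(np.sqrt(act_d / act))
    if mob == 0.0:
        return act, 0.0, 0.0
    ddx = np.diff(dx)
    act_dd = float(np.var(ddx, ddof=1))
    mob_d = float(np.sqrt(act_dd / act_d)) if act_d > 0 else 0.0
    return act, mob, mob_d / mob


def time_domain_features(x: np.ndarray) -> np.ndarray:
    """The 13 time-domain statistics, in registry order.

    Standard deviation and variance use the 1/N (population) form; Hjorth
    activity uses the 1/(N-1) sample form. Skewness is the bias-uncorrected
    Fisher moment coefficient (0 for a degenerate signal). The zero-crossing
    rate is the fraction of consecutive sample pairs whose signs differ.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("time-domain features need at least 3 samples")
    n = x.size
    mu = float(np.mean(x))
    var = float(np.var(x))  # 1/N
    sd = float(np.sqrt(var))
    med = float(np.median(x))
    skw = float(_skew(x, bias=True)) if var > 0 else 0.0
    signs = np.where(x >= 0, 1, -1)
    zcr = float(np.mean(signs[1:] != signs[:-1]))
    act, mob, cmp_ = hjorth_parameters(x)
    rms = float(np.sqrt(np.mean(x**2)))
    sne = shannon_amplitude_entropy(x)
    ll = float(np.sum(np.abs(np.diff(x))))
    ne = float(np.sum(x[1:-1] ** 2 - x[2:] * x[:-2]))
    return np.array([mu, sd, var, med, skw, zcr, act, mob, cmp_, rms, sne, ll, ne])


def _subband_entropy(coeffs: np.ndarray) -> float:
    energy = float(np.sum(coeffs**2))
    if energy == 0.0:
        return 0.0
    p = coeffs**2 / energy
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def wpt_subband_features(
    x: np.ndarray, wavelet_name: str = "db2", levels: int = 5
) -> np.ndarray:
    """7 statistics for each terminal subband of a full packet tree (224 values).

    Subbands are taken in frequency order. Periodization boundary handling
    keeps the tree orthogonal, so subband energies sum to the signal energy.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2**levels:
        raise ValueError(f"need at least {2 ** levels} samples for {levels} levels")
    wp = pywt.WaveletPacket(
        data=x, wavelet=wavelet_name, mode="periodization", maxlevel=levels
    )
    nodes = wp.get_level(levels, order="freq")
    out = np.empty(len(nodes) * len(WPT_STATS))
    for i, node in enumerate(nodes):
        c = np.asarray(node.data, dtype=float)
        var = float(np.var(c))
        out[i * 7 : (i + 1) * 7] = (
            float(np.mean(c)),
            float(np.median(c)),
            float(np.sum(c**2)),
            float(_skew(c, bias=True)) if var > 0 else 0.0,
            float(_kurtosis(c, fisher=True, bias=True)) if var > 0 else 0.0,
            var,
            _subband_entropy(c),
        )
    return out


def instantaneous_mean_frequency(freqs: np.ndarray, psd: np.ndarray) -> float:
    """PSD-weighted mean frequency; the PSD is normalized to unit sum."""
    psd = np.asarray(psd, dtype=float)
    total = psd.sum()
    if total <= 0:
        return 0.0
    p = psd / total
    return float(np.sum(p * np.asarray(freqs, dtype=float)))


def instantaneous_bandwidth(freqs: np.ndarray, psd: np.ndarray) -> float:
    """PSD-weighted variance of frequency about the weighted mean."""
    psd = np.asarray(psd, dtype=float)
    total = psd.sum()
    if total <= 0:
        return 0.0
    p = psd / total
    freqs = np.asarray(freqs, dtype=float)
    imf = float(np.sum(p * freqs))
    return float(np.sum(p * (freqs - imf) ** 2))


def spectral_kurtosis(x: np.ndarray, fs: float, segment: int = SK_SEGMENT) -> np.ndarray:
    """Kurtosis of the STFT magnitude at each one-sided frequency bin.

    512-sample Hann segments with 50% overlap give 257 bins. Bins with a
    degenerate magnitude distribution score 0.
    """
    x = np.asarray(x, dtype=float)
    win = hann(segment, sym=False)
    sft = ShortTimeFFT(win, hop=segment // 2, fs=fs, mfft=segment)
    mag = np.abs(sft.stft(x))
    with np.errstate(invalid="ignore", divide="ignore"):
        sk = _kurtosis(mag, axis=1, fisher=True, bias=True)
    return np.nan_to_num(np.asarray(sk, dtype=float))


def spectral_features(x: np.ndarray, fs: float) -> np.ndarray:
    """Total energy, IWMF, IWBF and 257 spectral-kurtosis values (260 total)."""
    x = np.asarray(x, dtype=float)
    if x.size < SK_SEGMENT:
        raise ValueError(f"spectral features need at least {SK_SEGMENT} samples")
    en = float(np.sum(x**2))
    if en == 0.0:
        return np.zeros(3 + N_SK_BINS)
    freqs, psd = welch(x, fs=fs, nperseg=min(SK_SEGMENT, x.size))
    imf = instantaneous_mean_frequency(freqs, psd)
    ibw = instantaneous_bandwidth(freqs, psd)
    return np.concatenate([[en, imf, ibw], spectral_kurtosis(x, fs)])


# -- texture descriptors ----------------------------------------------------

_NEIGHBOR_OFFSETS = (-4, -3, -2, -1, 1, 2, 3, 4)  # 4 left, 4 right
_WEIGHTS = 2 ** np.arange(8)  # 2^(i-1), i = 1..8


def _neighbor_diffs(x: np.ndarray) -> np.ndarray:
    """(n_centers, 8) matrix of neighbor-minus-center differences."""
    n = x.size
    centers = np.arange(4, n - 4)
    cols = [x[centers + off] - x[centers] for off in _NEIGHBOR_OFFSETS]
    return np.stack(cols, axis=1)


def _codes_from_diffs(d: np.ndarray) -> np.ndarray:
    bits = (d < 0).astype(int)  # f(x) = 1 for x < 0, else 0
    return bits @ _WEIGHTS


def lbp_codes(x: np.ndarray) -> np.ndarray:
    """1-D local binary pattern codes, 8 neighbors, codes in [0, 255]."""
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError("LBP needs at least 10 samples")
    return _codes_from_diffs(_neighbor_diffs(x))


def lgp_codes(x: np.ndarray) -> np.ndarray:
    """Local gradient pattern codes: LBP coding on the first difference."""
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError("LGP needs at least 10 samples")
    g = np.diff(x)
    return _codes_from_diffs(_neighbor_diffs(g))


def lndp_codes(x: np.ndarray) -> np.ndarray:
    """Local neighborhood difference pattern codes.

    Each bit compares a neighbor's difference from the center against the
    next neighbor's difference (cyclically), so the code captures the local
    ordering of the neighborhood rather than its sign pattern.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError("LNDP needs at least 10 samples")
    d = _neighbor_diffs(x)
    succ = np.roll(d, -1, axis=1)
    return _codes_from_diffs(d - succ)


def _code_histogram(codes: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(codes, bins=N_TEXTURE_BINS, range=(0, 255))
    return counts / codes.size


def texture_features(x: np.ndarray) -> np.ndarray:
    """LBP, LNDP and LGP 10-bin normalized code histograms (30 values)."""
    return np.concatenate(
        [_code_histogram(f(x)) for f in (lbp_codes, lndp_codes, lgp_codes)]
    )


# -- per-channel assembly ---------------------------------------------------


def channel_features(x: np.ndarray, fs: float) -> np.ndarray:
    """All 527 features of one channel, in registry order."""
    return np.concatenate(
        [
            time_domain_features(x),
            wpt_subband_features(x),
            spectral_features(x, fs),
            texture_features(x),
        ]
    )


def feature_names(channel: str) -> list[str]:
    """Registry names ``<channel>.<family>.<feature>`` for one channel."""
    names = [f"{channel}.time.{n}" for n in TIME_FEATURE_NAMES]
    names += [
        f"{channel}.wpt.node{i:02d}.{s}"
        for i in range(N_WPT_SUBBANDS)
        for s in WPT_STATS
    ]
    names += [f"{channel}.spectral.{n}" for n in ("energy", "iwmf", "iwbf")]
    names += [f"{channel}.spectral.sk.bin{i:03d}" for i in range(N_SK_BINS)]
    names += [
        f"{channel}.texture.{fam}.bin{i}"
        for fam in ("lbp", "lndp", "lgp")
        for i in range(N_TEXTURE_BINS)
    ]
    assert len(names) == FEATURES_PER_CHANNEL
    return names


def extract_mef(
    rec: MultiChannelRecording, channels: list[int] | None = None
) -> tuple[np.ndarray, list[str]]:
    """527 features for each selected channel of one recording.

    Returns the concatenated value vector (channel-major, registry order
    within each channel) and its names.
    """
    if channels is None:
        channels = list(range(rec.n_channels))
    for ch in channels:
        if not 0 <= ch < rec.n_channels:
            raise ValueError(f"channel index {ch} out of range")
    values, names = [], []
    for ch in channels:
        try:
            values.append(channel_features(rec.data[ch], rec.fs))
        except ValueError as exc:
            raise ValueError(f"channel {rec.channel_names[ch]}: {exc}") from exc
        names.extend(feature_names(rec.channel_names[ch]))
    return np.concatenate(values), names


class MEFExtractor(BaseEstimator, TransformerMixin):
    """Trial-set to feature-matrix transformer.

    ``transform`` maps a :class:`TrialSet` (or one recording) to a pandas
    DataFrame of shape (n_trials, 527 * n_selected_channels) with registry
    column names.
    """

    def __init__(self, channels: list[int] | None = None):
        self.channels = channels

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        if isinstance(X, MultiChannelRecording):
            X = TrialSet([X])
        rows, names = [], None
        for trial in X.trials:
            vec, names = extract_mef(trial, self.channels)
            rows.append(vec)
        return pd.DataFrame(np.stack(rows), columns=names)
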