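"""EMG and ECG feature extraction.

EMG windows are summarised by five "raw" features — mean, standard deviation,
skewness, kurtosis (population moments, no bias correction, kurtosis without
the excess-3 offset) and dispersion entropy.  ECG windows are summarised by
ten features built on the detected R peaks: max/min/mean R-R interval, the
max/min/mean of the respiratory amplitude modulation (R-peak amplitude
series, a respiration surrogate), and max/min/mean/sd of the instantaneous
breathing frequency obtained by running the SSWT on that modulation and
extracting the maximum-energy ridge in the 0.05-1 Hz breathing band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .rpeak import RPeakSet
from .tfa import SignalSegment, extract_ridge, sswt

__all__ = [
    "DEParams",
    "EMGFeatureVector",
    "ECGFeatureVector",
    "RespModulation",
    "moment_features",
    "dispersion_entropy",
    "emg_feature_vector",
    "rpeak_timing_features",
    "respiratory_modulation",
    "resp_amplitude_features",
    "resp_if_features",
    "ecg_feature_vector",
    "EMG_FEATURE_NAMES",
    "ECG_FEATURE_NAMES",
]

#: Breathing band for respiratory instantaneous frequency, Hz.
BREATH_BAND = (0.05, 1.0)

#: Uniform resampling rate for the respiratory modulation before SSWT, Hz.
RESP_FS = 4.0

EMG_FEATURE_NAMES = ("mean", "sd", "skewness", "kurtosis", "de")
ECG_FEATURE_NAMES = (
    "rr_max", "rr_min", "rr_mean",
    "resp_amp_max", "resp_amp_min", "resp_amp_mean",
    "resp_if_max", "resp_if_min", "resp_if_mean", "resp_if_sd",
)


@dataclass(frozen=True)
class DEParams:
    """Dispersion-entropy parameters: embedding dimension m, classes c, delay d."""

    m: int = 2
    c: int = 5
    d: int = 1

    def __post_init__(self) -> None:
        if self.m < 2 or self.c < 2 or self.d < 1:
            raise ValueError("require m >= 2, c >= 2, d >= 1")

    def n_words(self, n: int) -> int:
        return n - (self.m - 1) * self.d


@dataclass
class EMGFeatureVector:
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    de: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.sd, self.skewness, self.kurtosis, self.de])


@dataclass
class RespModulation:
    """R-peak amplitude series (respiration surrogate) with peak times."""

    amplitudes: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.amplitudes.shape != self.times.shape:
            raise ValueError("amplitudes and times must have equal length")

    def __len__(self) -> int:
        return self.amplitudes.size


@dataclass
class ECGFeatureVector:
    """Ten ECG features in fixed order (see ``ECG_FEATURE_NAMES``)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != 10:
            raise ValueError("ECG feature vector must have exactly 10 values")

    def as_array(self) -> np.ndarray:
        return self.values


# --------------------------------------------------------------------------
# moments
# --------------------------------------------------------------------------

def moment_features(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sd, skewness, kurtosis) as population moments.

    ``skewness = E[(X-E[X])^3] / (E[(X-E[X])^2])^{3/2}`` and
    ``kurtosis = E[(X-E[X])^4] / (E[(X-E[X])^2])^2`` (not excess kurtosis).
    A zero-variance input has undefined shape moments; both are reported as 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(x) == 0:  # exactly constant; fp round-off in the mean would
        return float(x[0]), 0.0, 0.0, 0.0  # otherwise leave a spurious variance
    mean = x.mean()
    dev = x - mean
    var = np.mean(dev ** 2)
    if var == 0:
        return float(mean), 0.0, 0.0, 0.0
    skew = np.mean(dev ** 3) / var ** 1.5
    kurt = np.mean(dev ** 4) / var ** 2
    return float(mean), float(np.sqrt(var)), float(skew), float(kurt)


# --------------------------------------------------------------------------
# dispersion entropy
# --------------------------------------------------------------------------

def _classify(x: np.ndarray, c: int) -> np.ndarray:
    """Map samples to classes 1..c through the Gaussian CDF of the sample itself.

    ``y = Phi((x - mean) / sd)`` then ``z = round_half_up(c y + 0.5)`` clipped
    to [1, c] (clipping guards the y -> 1 boundary).
    """
    mu, sd = x.mean(), x.std()
    if sd == 0 or np.ptp(x) == 0:
        raise ValueError("constant signal: dispersion entropy undefined")
    y = norm.cdf(x, loc=mu, scale=sd)
    z = np.floor(c * y + 1.0).astype(np.int64)  # round-half-up of c*y + 0.5
    return np.clip(z, 1, c)


def dispersion_entropy(x: np.ndarray, p: DEParams = DEParams()) -> float:
    """Dispersion entropy: Shannon entropy of dispersion-pattern frequencies.

    The signal is coarse-grained into ``p.c`` classes via the normal CDF,
    embedded with dimension ``p.m`` and delay ``p.d``, and each embedded word
    is a dispersion pattern; the entropy of the pattern relative frequencies is
    returned (natural log).  Bounded by ``[0, m ln c]``, and invariant under
    strictly increasing affine transforms of ``x``.
    """
    x = np.asarray(x, dtype=float)
    n_words = p.n_words(x.size)
    if n_words < 1:
        raise ValueError("signal too short for the embedding")
    z = _classify(x, p.c)
    # word code in base c, least-significant digit first
    code = np.zeros(n_words, dtype=np.int64)
    for k in range(p.m):
        code += (z[k * p.d:k * p.d + n_words] - 1) * p.c ** k
    counts = np.bincount(code, minlength=p.c ** p.m)
    probs = counts[counts > 0] / n_words
    return float(-np.sum(probs * np.log(probs)))


def emg_feature_vector(window: SignalSegment, p: DEParams = DEParams()
                       ) -> EMGFeatureVector:
    """Five EMG features in fixed order: mean, sd, skewness, kurtosis, DE."""
    mean, sd, skew, kurt = moment_features(window.samples)
    if sd == 0:
        return EMGFeatureVector(mean, sd, skew, kurt, 0.0, degenerate=True)
    de = dispersion_entropy(window.samples, p)
    return EMGFeatureVector(mean, sd, skew, kurt, de)


# --------------------------------------------------------------------------
# ECG features
# --------------------------------------------------------------------------

def rpeak_timing_features(peaks: RPeakSet, fs: float) -> tuple[float, float, float]:
    """(max, min, mean) of successive R-R intervals in seconds."""
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks")
    rr = np.diff(peaks.indices) / fs
    return float(rr.max()), float(rr.min()), float(rr.mean())


def respiratory_modulation(peaks: RPeakSet, signal: SignalSegment) -> RespModulation:
    """R-peak amplitude series: the signal value at each peak, with peak times."""
    idx = peaks.indices
    return RespModulation(amplitudes=signal.samples[idx] if idx.size else np.empty(0),
                          times=peaks.times(signal.fs, signal.t0))


def resp_amplitude_features(r: RespModulation) -> tuple[float, float, float]:
    """(max, min, mean) of the respiratory amplitude modulation."""
    if len(r) == 0:
        raise ValueError("empty modulation")
    a = r.amplitudes
    return float(a.max()), float(a.min()), float(a.mean())


def resp_if_features(r: RespModulation, fs_interp: float = RESP_FS,
                     band: tuple[float, float] = BREATH_BAND,
                     n_voices: int = 32, n_bins: int = 128,
                     edge_frac: float = 0.05
                     ) -> tuple[float, float, float, float]:
    """(max, min, mean, sd) of the instantaneous breathing frequency.

    The modulation is linearly resampled onto a uniform ``fs_interp`` grid,
    the SSWT applied, and the maximum-energy ridge in the breathing band
    extracted.  The first and last ``edge_frac`` of samples are excluded from
    the statistics (wavelet cone of influence).

    Raises ``ValueError`` when the modulation is too short to transform; the
    caller drops such observations.
    """
    if len(r) < 4:
        raise ValueError("too few modulation samples")
    t0, t1 = r.times[0], r.times[-1]
    n = int(np.floor((t1 - t0) * fs_interp)) + 1
    if n < 2 * n_voices:
        raise ValueError("modulation too short for the SSWT")
    grid = t0 + np.arange(n) / fs_interp
    x = np.interp(grid, r.times, r.amplitudes)
    seg = SignalSegment(samples=x - x.mean(), fs=fs_interp, t0=t0, label="resp")
    T = sswt(seg, band, n_voices=n_voices, n_bins=n_bins)
    ridge = extract_ridge(T, band)
    if ridge.is_degenerate:
        raise ValueError("degenerate breathing ridge")
    edge = int(edge_frac * n)
    f = ridge.freq[edge:n - edge] if n > 2 * edge else ridge.freq
    return float(f.max()), float(f.min()), float(f.mean()), float(f.std())


def ecg_feature_vector(peaks: RPeakSet, signal: SignalSegment,
                       p_if: dict | None = None) -> ECGFeatureVector:
    """Ten ECG features: R-R triple, amplitude triple, IF quadruple (fixed order)."""
    rr = rpeak_timing_features(peaks, signal.fs)
    mod = respiratory_modulation(peaks, signal)
    amp = resp_amplitude_features(mod)
    iff = resp_if_features(mod, **(p_if or {}))
    return ECGFeatureVector(values=np.array(rr + amp + iff))
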