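"""The ten-component classification feature vector.

Four components come from the hyperbolic fit (I0, beta, tau, E(T)); the other
six are computed on the preprocessed trace itself:

* instantaneous frequency — power-weighted mean frequency (spectral centroid)
  of one global Kaiser-windowed periodogram,
* spectral entropy — Shannon entropy (base 2) of the normalized one-sided
  power distribution over [0, fs/2],
* approximate entropy — regularity statistic ApEn(m, r, N),
* median, quartile deviation (Q3 - Q1 via the (n+1)-position interpolation
  rule), and mean absolute deviation.

Feature matrices are z-scored with statistics fitted on training data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import kaiser

from .hyperfit import HyperbolicFitResult
from .signal import DLSignal

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "SpectrumEstimate",
    "FeatureVector",
    "NormalizationStats",
    "periodogram",
    "instantaneous_frequency",
    "spectral_entropy",
    "approximate_entropy",
    "median",
    "quartile_deviation",
    "mean_deviation",
    "extract_features",
    "zscore_fit",
    "zscore_apply",
]

#: Fixed component order of the feature vector.
FEATURE_NAMES: tuple[str, ...] = (
    "I0",
    "beta",
    "tau",
    "E_T",
    "inst_freq",
    "spec_entropy",
    "ap_en",
    "median",
    "quartile_dev",
    "mean_dev",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs for the spectrum- and entropy-based features."""

    kaiser_shape: float = 5.0
    apen_m: int = 2
    apen_r_factor: float = 0.2  # tolerance radius = factor * sample sd
    mean_center: bool = True

    def __post_init__(self) -> None:
        if self.kaiser_shape < 0:
            raise ValueError("kaiser_shape must be >= 0")
        if self.apen_m < 1:
            raise ValueError("apen_m must be >= 1")
        if self.apen_r_factor <= 0:
            raise ValueError("apen_r_factor must be positive")


@dataclass
class SpectrumEstimate:
    """One-sided windowed periodogram on bins j*df, j = 0..n_fft/2."""

    frequencies: np.ndarray
    power: np.ndarray
    window_norm: float
    n_fft: int

    @property
    def total_power(self) -> float:
        return float(self.power.sum())


@dataclass
class FeatureVector:
    values: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"feature vector must have {len(FEATURE_NAMES)} components")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector components must be finite")


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def periodogram(signal: DLSignal, kaiser_shape: float = 5.0,
                mean_center: bool = True) -> SpectrumEstimate:
    """Kaiser-windowed one-sided periodogram, zero-padded to a power of two.

    The trace is (optionally) mean-centered, multiplied by a Kaiser window of
    its original length, padded to the next power of two and transformed; bin
    powers are ``|X_j|**2 / (W * n_fft)`` with ``W`` the mean squared window
    weight over the unpadded length.
    """
    if len(signal) < 4:
        raise ValueError("signal too short for a periodogram (need >= 4 points)")
    x = signal.values.astype(float)
    if mean_center:
        x = x - x.mean()
    n = x.size
    w = kaiser(n, kaiser_shape)
    window_norm = float(np.mean(w**2))
    n_fft = _next_pow2(n)
    spectrum = np.fft.rfft(w * x, n_fft)
    power = np.abs(spectrum) ** 2 / (window_norm * n_fft)
    fs = 1.0 / signal.dt
    freqs = np.fft.rfftfreq(n_fft, d=signal.dt)
    assert freqs[-1] == fs / 2
    return SpectrumEstimate(frequencies=freqs, power=power,
                            window_norm=window_norm, n_fft=n_fft)


def instantaneous_frequency(spectrum: SpectrumEstimate) -> float:
    """Power-weighted mean frequency over the one-sided bins, in Hz."""
    total = spectrum.total_power
    if total <= 0:
        raise ValueError("zero total power: instantaneous frequency undefined")
    return float(np.sum(spectrum.frequencies * spectrum.power) / total)


def spectral_entropy(spectrum: SpectrumEstimate) -> float:
    """Shannon entropy (bits) of the normalized one-sided power distribution."""
    total = spectrum.total_power
    if total <= 0:
        raise ValueError("zero total power: spectral entropy undefined")
    p = spectrum.power / total
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def _match_proportions(dist1: np.ndarray, m: int, r: float) -> np.ndarray:
    """Proportions C_i of m-length embeddings within Chebyshev distance r.

    ``dist1`` is the full pairwise |x_i - x_j| matrix; the Chebyshev distance
    between m-embeddings starting at i and j is the running max of its
    diagonal-shifted slices, which avoids materializing the embeddings.
    """
    n = dist1.shape[0]
    n_vec = n - m + 1
    d = dist1[:n_vec, :n_vec].copy()
    for k in range(1, m):
        np.maximum(d, dist1[k:k + n_vec, k:k + n_vec], out=d)
    return np.count_nonzero(d <= r, axis=1) / n_vec


def approximate_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r, N) with self-matches included and distance threshold <= r.

    Natural logarithms; ``r`` defaults to 0.2 x the sample standard deviation.
    Self-match counting keeps every proportion strictly positive, so the
    statistic is defined for all inputs and non-negative in practice.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    n = x.size
    if n <= m + 1:
        raise ValueError("series too short for the requested embedding dimension")
    if r is None:
        r = 0.2 * float(np.std(x, ddof=1))
    if r <= 0:
        raise ValueError("tolerance radius r must be positive")
    dist1 = np.abs(x[:, None] - x[None, :])

    def phi(mm: int) -> float:
        return float(np.mean(np.log(_match_proportions(dist1, mm, r))))

    return phi(m) - phi(m + 1)


def median(series: np.ndarray) -> float:
    """Middle order statistic; the mean of the two middle values for even n."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    return float(np.median(x))


def quartile_deviation(series: np.ndarray) -> float:
    """Q3 - Q1 with quartiles interpolated at positions 0.25(n+1), 0.75(n+1)."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    q1, q3 = np.quantile(x, [0.25, 0.75], method="weibull")
    return float(q3 - q1)


def mean_deviation(series: np.ndarray) -> float:
    """Mean absolute deviation about the arithmetic mean."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    return float(np.mean(np.abs(x - x.mean())))


def extract_features(signal: DLSignal, fit: HyperbolicFitResult,
                     cfg: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Assemble the ordered ten-component feature vector for one sample."""
    if not fit.converged:
        raise ValueError("hyperbolic fit did not converge; features undefined")
    spec = periodogram(signal, cfg.kaiser_shape, cfg.mean_center)
    x = signal.values
    values = np.array([
        fit.params.I0,
        fit.params.beta,
        fit.params.tau,
        fit.e_T,
        instantaneous_frequency(spec),
        spectral_entropy(spec),
        approximate_entropy(x, cfg.apen_m, cfg.apen_r_factor * float(np.std(x, ddof=1))),
        median(x),
        quartile_deviation(x),
        mean_deviation(x),
    ])
    return FeatureVector(values, label=signal.meta.get("label"))


@dataclass(frozen=True)
class NormalizationStats:
    """Per-component mean and sample standard deviation (ddof=1)."""

    mean: np.ndarray
    std: np.ndarray


def zscore_fit(matrix: np.ndarray) -> NormalizationStats:
    """Fit z-score statistics on a (n_samples, n_features) training matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two training vectors")
    mean = m.mean(axis=0)
    std = m.std(axis=0, ddof=1)
    zero = np.nonzero(std == 0)[0]
    if zero.size:
        names = ", ".join(FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else str(i)
                          for i in zero)
        raise ValueError(f"zero-variance component(s): {names}")
    return NormalizationStats(mean=mean, std=std)


def zscore_apply(matrix: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Apply (x - mean) / std componentwise to vectors or a matrix."""
    return (np.asarray(matrix, dtype=float) - stats.mean) / stats.std
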