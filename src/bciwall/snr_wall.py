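"""Sliding-window noise power, noise uncertainty and the SNR-wall.

An energy detector compares the mean-square power of ``N`` samples with
a threshold.  When the noise variance is only known up to a factor
``rho`` (the *noise uncertainty*, the ratio of the largest to the
smallest noise standard deviation seen in a recording), there is an SNR
below which no amount of averaging reaches the target error rates:

.. math::

    \\mathrm{SNR}_{wall} = \\rho - 1/\\rho

(linear scale; reported in dB).  ``rho`` is measured empirically by
scanning the recording with a sliding window (default 2 s, sample by
sample) and taking the extrema of the windowed mean-square power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AnalysisConfig, Recording

__all__ = [
    "SlidingPowerSeries",
    "NoiseProfile",
    "sliding_power",
    "noise_extrema",
    "rho",
    "snr_wall_db",
    "mean_square_power",
    "profile_recording",
]


@dataclass
class SlidingPowerSeries:
    """Windowed mean-square power at successive window start positions."""

    powers: np.ndarray  # V^2, one value per window start
    window_s: float
    stride: int
    fs: float

    def __post_init__(self) -> None:
        self.powers = np.asarray(self.powers, dtype=float)
        if self.powers.size and self.powers.min() < 0:
            raise ValueError("window powers cannot be negative")


@dataclass
class NoiseProfile:
    """Noise-variance extrema, uncertainty and SNR-wall of one recording."""

    sigma2_min: float  # V^2, smallest windowed power
    sigma2_max: float  # V^2, largest windowed power
    rho: float  # dimensionless, >= 1
    sigma2_nominal: float  # V^2, whole-recording mean square
    snr_wall_db: float  # dB, -inf when rho == 1
    window_s: float

    def __post_init__(self) -> None:
        if not 0 < self.sigma2_min <= self.sigma2_max:
            raise ValueError("need 0 < sigma2_min <= sigma2_max")
        if self.rho < 1:
            raise ValueError("rho must be >= 1")


def mean_square_power(x: np.ndarray) -> float:
    """Average power ``T(x) = mean(x**2)`` — no mean subtraction."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute the power of an empty signal")
    return float(np.mean(x * x))


def sliding_power(rec: Recording, window_s: float = 2.0, stride: int = 1) -> SlidingPowerSeries:
    """Mean-square power in a sliding window over the recording.

    ``powers[i]`` is the mean of the squared samples in the window
    starting at sample ``i * stride``.  Any startup transient should be
    discarded from the recording before calling this.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    window = int(round(window_s * rec.fs))
    x = rec.samples
    if x.size < window:
        raise ValueError(
            f"recording has {x.size} samples but one {window_s:g} s window "
            f"needs {window}"
        )
    # O(N) windowed sums via a cumulative sum; float64 is ample for
    # V^2-scale EEG powers (~1e-10) over minutes of data.
    c = np.concatenate(([0.0], np.cumsum(x * x)))
    sums = c[window:] - c[:-window]
    powers = sums[::stride] / window
    # guard against tiny negative values from cancellation
    np.maximum(powers, 0.0, out=powers)
    return SlidingPowerSeries(powers=powers, window_s=window_s, stride=stride, fs=rec.fs)


def noise_extrema(sps: SlidingPowerSeries) -> tuple[float, float]:
    """Smallest and largest windowed power over the recording."""
    if sps.powers.size == 0:
        raise ValueError("empty sliding-power series")
    lo = float(sps.powers.min())
    hi = float(sps.powers.max())
    if lo == 0.0:
        raise ValueError(
            "minimum window power is zero (flatlined channel?); "
            "the noise uncertainty would be infinite"
        )
    return lo, hi


def rho(sigma2_min: float, sigma2_max: float) -> float:
    """Noise uncertainty: ratio of extreme noise standard deviations.

    ``rho = sqrt(sigma2_max / sigma2_min) >= 1``.
    """
    if not sigma2_min > 0:
        raise ValueError("sigma2_min must be positive")
    if sigma2_max < sigma2_min:
        raise ValueError("sigma2_max must be >= sigma2_min")
    return float(np.sqrt(sigma2_max / sigma2_min))


def snr_wall_db(rho_value: float) -> float:
    """SNR-wall ``10*log10(rho - 1/rho)`` in dB.

    ``rho == 1`` (perfectly known noise) gives a wall of minus infinity:
    any positive SNR is then detectable with enough averaging.
    """
    if rho_value < 1:
        raise ValueError(f"rho must be >= 1, got {rho_value}")
    linear = rho_value - 1.0 / rho_value
    if linear == 0.0:
        return float("-inf")
    return float(10.0 * np.log10(linear))


def profile_recording(rec: Recording, cfg: AnalysisConfig | None = None) -> NoiseProfile:
    """Full noise profile of a (filtered) recording.

    Drops the first ``discard_startup_s`` seconds (IIR startup transient
    would masquerade as the maximum variance), scans with the configured
    sliding window, and reports the extrema, ``rho``, the whole-recording
    nominal power and the SNR-wall.
    """
    cfg = cfg or AnalysisConfig()
    skip = int(round(cfg.discard_startup_s * rec.fs))
    x = rec.samples[skip:]
    if x.size < int(round(cfg.window_s * rec.fs)):
        raise ValueError(
            "recording too short after startup discard for one sliding window"
        )
    trimmed = rec.replace(samples=x)
    sps = sliding_power(trimmed, window_s=cfg.window_s, stride=cfg.stride)
    lo, hi = noise_extrema(sps)
    r = rho(lo, hi)
    nominal = mean_square_power(x)
    return NoiseProfile(
        sigma2_min=lo,
        sigma2_max=hi,
        rho=r,
        sigma2_nominal=nominal,
        snr_wall_db=snr_wall_db(r),
        window_s=cfg.window_s,
    )
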