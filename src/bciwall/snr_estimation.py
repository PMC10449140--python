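"""Conscious-signal power from P300 averaging, and the recording SNR.

The consciously generated EEG component cannot be measured in isolation
(that would require paralysing the subject), so its power is estimated
from the P300 oddball response: stimulus-locked epochs are averaged,
uncorrelated noise shrinks as ``1/sqrt(N)``, and the surviving peak
amplitude ``c_max`` gives the conscious signal power ``T_t(c) =
c_max**2``.  For frequency-domain BCIs (desynchronisation) only a
fraction of that band power is under conscious control; with a 40 %
power reduction the usable signal power is ``T_f(c) = 0.6 * T_t(c)``.

The SNR is then ``10*log10(T(c) / sigma2_r)`` with ``sigma2_r`` the
whole-recording mean-square power, which is a good stand-in for the
noise power because the conscious component is tiny compared to the
background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import AnalysisConfig, EventSeries, Recording
from .snr_wall import mean_square_power

__all__ = [
    "EvokedResult",
    "ConsciousPower",
    "SnrResult",
    "evoked_average",
    "conscious_power_time",
    "conscious_power_freq",
    "nominal_noise_power",
    "snr_db",
    "compute_snr",
]

log = logging.getLogger(__name__)


@dataclass
class EvokedResult:
    """Stimulus-locked average and its peak."""

    waveform: np.ndarray  # baseline-corrected average, V
    times_ms: np.ndarray  # time axis relative to stimulus onset
    c_max: float  # V, signed peak of the (smoothed) average
    latency_ms: float  # time of the peak
    n_events: int  # epochs actually averaged
    n_dropped: int = 0  # epochs rejected for running off the recording

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("an evoked average needs at least one epoch")


@dataclass
class ConsciousPower:
    """Conscious signal power in both task conventions."""

    t_time: float  # V^2, P300 peak power
    t_freq: float  # V^2, usable desynchronisation power
    reduction: float
    convention: str

    def __post_init__(self) -> None:
        if not (self.t_time > 0 and self.t_freq > 0):
            raise ValueError("powers must be positive")
        if self.t_freq >= self.t_time:
            raise ValueError("frequency-domain power must be below time-domain power")


@dataclass
class SnrResult:
    snr_db: float
    conscious_power: float  # V^2
    noise_power: float  # V^2
    mode: str  # "time" | "frequency"


def _boxcar_smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average with edge shrinkage (offline, zero phase)."""
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    num = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / norm


def evoked_average(
    rec: Recording,
    events: EventSeries,
    epoch_ms: tuple[float, float] = (200.0, 600.0),
    search_ms: tuple[float, float] = (150.0, 500.0),
    peak_smooth_ms: float = 20.0,
    detrend: str | None = "linear",
) -> EvokedResult:
    """Event-triggered average with per-epoch baseline correction.

    Each epoch spans ``-epoch_ms[0] .. +epoch_ms[1]`` around its event;
    its mean over the pre-stimulus interval is subtracted before
    averaging.  Epochs that run off either end of the recording are
    dropped (with a logged count).

    Slow background drift that survives averaging is removed by fitting
    a straight line to the response-free parts of the average (outside
    ``search_ms`` plus a 30 ms guard) and subtracting it
    (``detrend="linear"``, the default; pass ``None`` to disable).  On
    a drift-free response this step subtracts nothing.

    ``c_max`` is the signed maximum of the average inside ``search_ms``,
    read from a lightly smoothed copy (default 20 ms boxcar) so that
    single-sample noise excursions do not masquerade as the peak; the
    returned waveform stays unsmoothed (but detrended).
    """
    if len(events) == 0:
        raise ValueError("no events to average")
    pre = int(round(epoch_ms[0] / 1000.0 * rec.fs))
    post = int(round(epoch_ms[1] / 1000.0 * rec.fs))
    length = pre + post
    onsets = np.round(events.times * rec.fs).astype(int)
    keep = (onsets - pre >= 0) & (onsets + post <= rec.n_samples)
    n_dropped = int(np.count_nonzero(~keep))
    if n_dropped:
        log.info("evoked_average: dropped %d out-of-bounds epochs", n_dropped)
    onsets = onsets[keep]
    if onsets.size == 0:
        raise ValueError("no usable events: every epoch runs off the recording")
    idx = onsets[:, None] + np.arange(-pre, post)[None, :]
    epochs = rec.samples[idx]
    baselines = epochs[:, :pre].mean(axis=1, keepdims=True) if pre else 0.0
    avg = (epochs - baselines).mean(axis=0)
    times_ms = (np.arange(-pre, post) / rec.fs) * 1000.0

    if detrend == "linear":
        guard = 30.0
        mask = (times_ms < search_ms[0] - guard) | (times_ms > search_ms[1] + guard)
        if np.count_nonzero(mask) >= 2:
            design = np.column_stack([np.ones(mask.sum()), times_ms[mask]])
            coef, *_ = np.linalg.lstsq(design, avg[mask], rcond=None)
            avg = avg - (coef[0] + coef[1] * times_ms)
    elif detrend is not None:
        raise ValueError(f"unknown detrend mode {detrend!r}")

    smooth_n = int(round(peak_smooth_ms / 1000.0 * rec.fs))
    smoothed = _boxcar_smooth(avg, smooth_n)
    in_search = (times_ms >= search_ms[0]) & (times_ms <= search_ms[1])
    if not np.any(in_search):
        raise ValueError("peak search interval lies outside the epoch window")
    seg = smoothed[in_search]
    k = int(np.argmax(seg))
    c_max = float(seg[k])
    latency = float(times_ms[in_search][k])
    return EvokedResult(
        waveform=avg,
        times_ms=times_ms,
        c_max=c_max,
        latency_ms=latency,
        n_events=int(onsets.size),
        n_dropped=n_dropped,
    )


def conscious_power_time(c_max: float) -> float:
    """Time-domain conscious power ``T_t(c) = c_max**2``."""
    if not c_max > 0:
        raise ValueError(f"c_max must be positive, got {c_max}")
    return float(c_max) ** 2


def conscious_power_freq(
    t_time: float, reduction: float = 0.40, convention: str = "power_scaled"
) -> float:
    """Usable conscious power for a desynchronisation task.

    ``power_scaled``
        the reduction acts on the band power:
        ``T_f = T_t - T_t * reduction``.
    ``amplitude_scaled``
        the reduction acts on the amplitude before squaring:
        ``T_f = ((1 - reduction) * c_max)**2 = T_t * (1 - reduction)**2``.

    Both conventions appear in practice; ``power_scaled`` is the
    default and the discrepancy is recorded in result metadata.
    """
    if not 0 < reduction < 1:
        raise ValueError("reduction must be in (0, 1)")
    if not t_time > 0:
        raise ValueError("t_time must be positive")
    if convention == "power_scaled":
        return t_time * (1.0 - reduction)
    if convention == "amplitude_scaled":
        return t_time * (1.0 - reduction) ** 2
    raise ValueError(f"unknown convention {convention!r}")


def nominal_noise_power(rec: Recording) -> float:
    """Whole-recording mean-square power ``sigma2_r ~= T(d)`` in V^2."""
    return mean_square_power(rec.samples)


def snr_db(conscious_power: float, noise_power: float) -> float:
    """``10*log10(T(c) / sigma2_r)`` in dB."""
    if not (conscious_power > 0 and noise_power > 0):
        raise ValueError("powers must be positive")
    return float(10.0 * np.log10(conscious_power / noise_power))


def compute_snr(
    rec: Recording,
    c_max: float,
    cfg: AnalysisConfig | None = None,
    noise_power: float | None = None,
) -> SnrResult:
    """SNR of a recording given the subject's P300 peak amplitude.

    ``noise_power`` defaults to the whole-recording mean square of
    *rec* (which should already be filtered with the setup under test).
    """
    cfg = cfg or AnalysisConfig()
    t_time = conscious_power_time(c_max)
    if cfg.snr_mode == "frequency":
        p_sig = conscious_power_freq(t_time, cfg.reduction_fraction, cfg.freq_power_convention)
    else:
        p_sig = t_time
    p_noise = nominal_noise_power(rec) if noise_power is None else noise_power
    return SnrResult(
        snr_db=snr_db(p_sig, p_noise),
        conscious_power=p_sig,
        noise_power=p_noise,
        mode=cfg.snr_mode,
    )
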