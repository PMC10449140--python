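"""Energy-detector mathematics under stationary and uncertain noise.

The detector averages the squared signal over ``N`` samples,

.. math:: T(x) = \\frac{1}{N} \\sum_{n=1}^{N} x[n]^2,

and compares ``T`` with a threshold ``gamma``.  For real Gaussian
samples the central limit theorem gives ``T ~ Normal(sigma2, 2*sigma2**2/N)``
under noise only, and ``T ~ Normal(t_c + sigma2, 2*(t_c + sigma2)**2/N)``
with an independent Gaussian signal of power ``t_c`` present.  From
these, closed forms follow for the false-alarm and detection
probabilities and for the number of samples needed to meet both —
finite for stationary noise, but infinite once the SNR drops below the
SNR-wall ``rho - 1/rho`` set by the noise uncertainty ``rho``.

``simulate_energy_detector`` is a seeded Monte-Carlo check of those
closed forms, including the worst-case noise schedules (noise at
``rho*sigma2`` when deciding "false alarm", at ``sigma2/rho`` when
deciding "detection") that define the uncertain-noise formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "DetectorDesign",
    "q_function",
    "q_inverse",
    "p_false_alarm",
    "p_detection",
    "samples_required_stationary",
    "samples_required_uncertain",
    "detectable",
    "simulate_energy_detector",
    "design_detector",
    "snr_db_to_linear",
]


def snr_db_to_linear(snr_db: float) -> float:
    """Convert an SNR in dB to the linear power ratio ``T(c)/sigma2``."""
    return float(10.0 ** (snr_db / 10.0))


def q_function(x):
    """Standard normal upper-tail probability ``Q(x) = P(Z > x)``."""
    return special.ndtr(-np.asarray(x, dtype=float))


def q_inverse(p):
    """Inverse of :func:`q_function`: ``Q(q_inverse(p)) == p``."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probability must lie strictly inside (0, 1)")
    return -special.ndtri(p)


def p_false_alarm(gamma: float, sigma2: float, n: int, rho: float = 1.0) -> float:
    """False-alarm probability of the ``N``-sample energy detector.

    With noise uncertainty ``rho`` the worst case for false alarms is
    noise running at its largest power ``rho * sigma2``::

        P_FA = Q( (gamma - rho*sigma2) / (sqrt(2/N) * rho*sigma2) )

    ``rho = 1`` recovers the stationary formula.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if gamma <= 0 or sigma2 <= 0 or rho < 1:
        raise ValueError("need gamma > 0, sigma2 > 0, rho >= 1")
    s = rho * sigma2
    return float(q_function((gamma - s) / (math.sqrt(2.0 / n) * s)))


def p_detection(gamma: float, t_c: float, sigma2: float, n: int, rho: float = 1.0) -> float:
    """Detection probability of the ``N``-sample energy detector.

    The worst case for detection is the signal sitting on the *weakest*
    noise ``sigma2 / rho``::

        P_D = Q( (gamma - (t_c + sigma2/rho)) / (sqrt(2/N) * (t_c + sigma2/rho)) )
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if gamma <= 0 or sigma2 <= 0 or t_c < 0 or rho < 1:
        raise ValueError("need gamma > 0, sigma2 > 0, t_c >= 0, rho >= 1")
    m = t_c + sigma2 / rho
    return float(q_function((gamma - m) / (math.sqrt(2.0 / n) * m)))


def samples_required_stationary(p_fa: float, p_d: float, snr_linear: float, ceil: bool = True):
    """Samples needed under stationary noise for targets ``(p_fa, p_d)``.

    ``N = 2 * [Qinv(p_fa) - Qinv(p_d) * (1 + SNR)]**2 / SNR**2``,
    rounded up to an integer unless ``ceil=False`` (then the raw float
    is returned).  ``p_fa == p_d`` is degenerate and yields 0.
    """
    _check_targets(p_fa, p_d)
    if not snr_linear > 0:
        raise ValueError("snr_linear must be positive")
    raw = 2.0 * (q_inverse(p_fa) - q_inverse(p_d) * (1.0 + snr_linear)) ** 2 / snr_linear**2
    raw = float(raw)
    return math.ceil(raw) if ceil else raw


def samples_required_uncertain(
    p_fa: float, p_d: float, snr_linear: float, rho: float, ceil: bool = True
):
    """Samples needed under noise uncertainty ``rho`` (low-SNR regime).

    ``N = 2 * [Qinv(p_fa) - Qinv(p_d)]**2 / (SNR - (rho - 1/rho))**2``.

    Returns ``math.inf`` when the SNR is at or below the SNR-wall
    ``rho - 1/rho``: no finite averaging length meets the targets.
    """
    _check_targets(p_fa, p_d)
    if not snr_linear > 0:
        raise ValueError("snr_linear must be positive")
    if rho < 1:
        raise ValueError("rho must be >= 1")
    wall = rho - 1.0 / rho
    margin = snr_linear - wall
    if margin <= 0:
        return math.inf
    raw = 2.0 * float(q_inverse(p_fa) - q_inverse(p_d)) ** 2 / margin**2
    return math.ceil(raw) if ceil else raw


def _check_targets(p_fa: float, p_d: float) -> None:
    if not 0 < p_fa < 1 or not 0 < p_d < 1:
        raise ValueError("probabilities must lie in (0, 1)")
    if p_fa >= p_d:
        raise ValueError("need p_fa < p_d for a meaningful detector")


def detectable(snr_db: float, wall_db: float) -> bool:
    """Decision rule: conscious EEG is detectable iff ``SNR > SNR_wall``.

    The inequality is strict: sitting exactly on the wall still needs an
    infinite averaging length, so equality counts as not detectable.
    """
    return bool(snr_db > wall_db)


@dataclass
class DetectorDesign:
    """Bundle of a designed energy detector."""

    p_fa: float
    p_d: float
    snr_linear: float
    rho: float
    gamma: float  # V^2 threshold at the nominal noise power
    n_samples: float  # may be math.inf
    n_samples_raw: float

    def __post_init__(self) -> None:
        _check_targets(self.p_fa, self.p_d)


def design_detector(
    p_fa: float, p_d: float, snr_linear: float, rho: float = 1.0, sigma2: float = 1.0
) -> DetectorDesign:
    """Choose ``N`` and the threshold ``gamma`` for the given targets.

    ``gamma`` is placed to meet ``p_fa`` exactly at the worst-case noise
    power ``rho*sigma2`` and the returned design reports both the raw
    and ceiling-rounded ``N`` (``inf`` below the SNR-wall).
    """
    if rho == 1.0:
        n_raw = samples_required_stationary(p_fa, p_d, snr_linear, ceil=False)
    else:
        n_raw = samples_required_uncertain(p_fa, p_d, snr_linear, rho, ceil=False)
    if math.isinf(n_raw):
        return DetectorDesign(p_fa, p_d, snr_linear, rho, math.nan, math.inf, math.inf)
    n = max(1, math.ceil(n_raw))
    s = rho * sigma2
    gamma = s * (1.0 + math.sqrt(2.0 / n) * float(q_inverse(p_fa)))
    return DetectorDesign(p_fa, p_d, snr_linear, rho, gamma, float(n), n_raw)


def simulate_energy_detector(
    t_c: float,
    sigma2_schedule,
    n: int,
    gamma: float,
    trials: int,
    seed: int | np.random.Generator = 0,
    sigma2_schedule_h1=None,
) -> tuple[float, float]:
    """Monte-Carlo false-alarm and detection rates of the energy detector.

    Per trial, ``n`` real Gaussian noise samples are drawn with the
    trial's scheduled variance; under the signal hypothesis an
    independent Gaussian signal of power ``t_c`` is added.  ``T`` (the
    mean square) is thresholded at ``gamma``.

    ``sigma2_schedule`` is a scalar or a per-trial array of noise
    variances used under the noise-only hypothesis (and, by default,
    under the signal hypothesis too); an adversarial analysis passes a
    different ``sigma2_schedule_h1``.  Deterministic given ``seed``.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s0 = np.broadcast_to(np.asarray(sigma2_schedule, dtype=float), (trials,))
    s1 = s0 if sigma2_schedule_h1 is None else np.broadcast_to(
        np.asarray(sigma2_schedule_h1, dtype=float), (trials,)
    )
    if np.any(s0 <= 0) or np.any(s1 <= 0):
        raise ValueError("scheduled noise variances must be positive")

    # accumulate T per trial in blocks to bound memory at large n*trials
    def rates(sched: np.ndarray, with_signal: bool) -> float:
        hits = 0
        block = max(1, int(5e6 // n))
        for start in range(0, trials, block):
            m = min(block, trials - start)
            x = rng.standard_normal((m, n)) * np.sqrt(sched[start : start + m, None])
            if with_signal and t_c > 0:
                x = x + rng.standard_normal((m, n)) * math.sqrt(t_c)
            t_stat = np.mean(x * x, axis=1)
            hits += int(np.count_nonzero(t_stat > gamma))
        return hits / trials

    p_fa_emp = rates(s0, with_signal=False)
    p_d_emp = rates(s1, with_signal=True)
    return p_fa_emp, p_d_emp
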