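"""Causal pre-processing chains applied to the raw electrode signal.

Five setups are provided, all strictly causal single-pass IIR filters
(realtime BCI cannot look into the future):

``fullband``
    0.1 Hz 4th-order Butterworth highpass + mains bandstop.  Worst case:
    the whole EMG spectrum and low-frequency eye artefacts pass.
``delta``
    0.1-3 Hz 4th-order Butterworth bandpass + mains bandstop.  Isolates
    the low-frequency band where eye blinks and movement artefacts live.
``wide``
    8-18 Hz 4th-order Butterworth bandpass + mains bandstop (motor
    imagery band).  The bandpass itself removes DC.
``alpha``
    8-12 Hz 4th-order Butterworth bandpass + mains bandstop (narrow
    alpha band around 10 Hz).
``derivative``
    First difference ``y[n] = x[n] - x[n-1]`` + mains bandstop, a cheap
    highpass popular in realtime BCI.

The mains bandstop is a 4th-order Butterworth with a 2 Hz half-width
(49-51 Hz at 50 Hz mains), narrow enough to spare the 20-45 Hz band that
is diagnostic for muscle noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import FILTER_SETUPS, Recording

__all__ = ["FilterChain", "design_chain", "apply_chain"]

#: half-width of the mains bandstop in Hz
MAINS_HALF_WIDTH_HZ = 2.0


@dataclass
class FilterChain:
    """An ordered causal filter cascade.

    ``stages`` holds ``(kind, sos)`` pairs where *kind* is a short label
    and *sos* is a second-order-section array, or ``None`` for the
    first-difference stage.
    """

    setup: str
    fs: float
    mains_hz: float
    stages: list = field(default_factory=list)

    def frequency_response(self, freqs_hz) -> np.ndarray:
        """Complex response of the full cascade at the given frequencies."""
        w = 2 * np.pi * np.asarray(freqs_hz, dtype=float) / self.fs
        h = np.ones_like(w, dtype=complex)
        for kind, sos in self.stages:
            if sos is None:  # first difference: H(z) = 1 - z^-1
                h = h * (1.0 - np.exp(-1j * w))
            else:
                _, hs = signal.sosfreqz(sos, worN=w)
                h = h * hs
        return h

    def gain_db(self, freqs_hz) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 20 * np.log10(np.abs(self.frequency_response(freqs_hz)))


def _butter(order: int, corners, btype: str, fs: float) -> np.ndarray:
    arr = np.atleast_1d(corners).astype(float)
    if np.any(arr >= fs / 2):
        raise ValueError(
            f"corner frequency {arr.max():g} Hz is at or above the "
            f"Nyquist frequency {fs / 2:g} Hz"
        )
    wn = float(arr[0]) if arr.size == 1 else arr
    return signal.butter(order, wn, btype=btype, fs=fs, output="sos")


def design_chain(setup: str, fs: float, mains_hz: float = 50.0) -> FilterChain:
    """Build one of the five pre-processing chains for sampling rate *fs*."""
    if setup not in FILTER_SETUPS:
        raise ValueError(f"unknown filter setup {setup!r}; expected one of {FILTER_SETUPS}")
    bandstop = _butter(
        4, [mains_hz - MAINS_HALF_WIDTH_HZ, mains_hz + MAINS_HALF_WIDTH_HZ],
        "bandstop", fs,
    )
    stages: list = []
    if setup == "fullband":
        stages.append(("highpass_0.1Hz", _butter(4, 0.1, "highpass", fs)))
    elif setup == "delta":
        stages.append(("bandpass_0.1-3Hz", _butter(4, [0.1, 3.0], "bandpass", fs)))
    elif setup == "wide":
        # the bandpass already has zero gain at DC, no extra DC stage needed
        stages.append(("bandpass_8-18Hz", _butter(4, [8.0, 18.0], "bandpass", fs)))
    elif setup == "alpha":
        stages.append(("bandpass_8-12Hz", _butter(4, [8.0, 12.0], "bandpass", fs)))
    elif setup == "derivative":
        stages.append(("first_difference", None))
    stages.append((f"bandstop_{mains_hz:g}Hz", bandstop))
    return FilterChain(setup=setup, fs=fs, mains_hz=mains_hz, stages=stages)


def apply_chain(chain: FilterChain, rec: Recording) -> Recording:
    """Run the cascade over a recording (zero initial conditions).

    The output has the same length as the input and is causal: output
    sample *n* depends only on input samples up to *n*.  The returned
    recording carries the setup name in its ``filtered_with`` flag.
    """
    if chain.fs != rec.fs:
        raise ValueError(
            f"chain designed for fs={chain.fs} Hz but recording has fs={rec.fs} Hz"
        )
    y = rec.samples
    for kind, sos in chain.stages:
        if sos is None:
            # y[n] = x[n] - x[n-1], y[0] = x[0]
            y = signal.lfilter([1.0, -1.0], [1.0], y)
        else:
            y = signal.sosfilt(sos, y)
    return rec.replace(samples=y, filtered_with=chain.setup)
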