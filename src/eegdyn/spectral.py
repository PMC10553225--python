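"""Per-channel normalisation, zero-phase FIR band-pass filtering, and
Hilbert-based instantaneous phase and power.

Filters are linear-phase FIRs sized by Kaiser-window order estimation from a
passband-ripple specification and applied forward-backward (``filtfilt``) so
the net phase response is zero.  Phase is the angle of the analytic signal in
(-pi, pi]; power is the squared band-limited signal (the squared real part of
the analytic extension), matching the convention that band power is tracked
sample-by-sample before window averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import BandDefinition
from .recording import Recording

__all__ = [
    "zscore_channels",
    "BandpassFilter",
    "design_bandpass",
    "AnalyticSeries",
    "analytic_signal",
    "mean_window_power",
]


class DegenerateInputError(ValueError):
    """Raised when an input is constant where variation is required."""


def zscore_channels(rec: Recording) -> Recording:
    """Standardise each channel to mean 0, sample SD 1 (denominator N-1).

    A zero-variance channel cannot be standardised and raises
    :class:`DegenerateInputError` naming the channel.
    """
    sd = rec.data.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(rec.channel_names[i] for i in bad)
        raise DegenerateInputError(f"zero-variance channel(s): {names}")
    data = (rec.data - rec.data.mean(axis=1, keepdims=True)) / sd[:, None]
    return Recording(data, rec.rate, rec.channel_names, rec.schedule)


@dataclass(frozen=True)
class BandpassFilter:
    """A designed zero-phase band-pass operator for one band at one rate."""

    band: BandDefinition
    rate: float
    taps: np.ndarray

    @property
    def order(self) -> int:
        return len(self.taps) - 1

    @property
    def edge_samples(self) -> int:
        """Samples at each end contaminated by the filter transient."""
        return math.ceil(self.order / 2)

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Forward-backward filtering along the last axis (zero net phase)."""
        x = np.asarray(x, dtype=float)
        padlen = min(3 * (len(self.taps) - 1), x.shape[-1] - 1)
        return sps.filtfilt(self.taps, [1.0], x, axis=-1, padlen=padlen)


def design_bandpass(
    band: BandDefinition, rate: float, ripple_pct: float = 10.0
) -> BandpassFilter:
    """Design a linear-phase FIR band-pass via Kaiser-window order estimation.

    Passband is [low, high]; the transition regions end at
    ``low - transition_width`` and ``high + transition_width``.  The ripple
    specification (percent deviation, default 10%) sets the Kaiser
    attenuation target.
    """
    nyq = rate / 2.0
    if band.high + band.transition_width >= nyq:
        raise ValueError(
            f"band {band.name!r}: upper transition edge "
            f"{band.high + band.transition_width:g} Hz is at or above Nyquist {nyq:g} Hz"
        )
    if band.low - band.transition_width <= 0:
        raise ValueError(
            f"band {band.name!r}: lower transition edge must be positive"
        )
    if not (0 < ripple_pct < 100):
        raise ValueError("ripple_pct must be in (0, 100)")

    ripple_db = -20.0 * math.log10(ripple_pct / 100.0)
    numtaps, beta = sps.kaiserord(ripple_db, band.transition_width / nyq)
    if numtaps % 2 == 0:  # force odd length -> type-I FIR, integer group delay
        numtaps += 1
    # cutoffs at transition-band midpoints so the skirts span
    # [low - tw, low] and [high, high + tw]
    cutoff = [band.low - band.transition_width / 2.0, band.high + band.transition_width / 2.0]
    taps = sps.firwin(numtaps, cutoff, window=("kaiser", beta), pass_zero=False, fs=rate)
    return BandpassFilter(band, rate, taps)


@dataclass
class AnalyticSeries:
    """Instantaneous phase (radians, (-pi, pi]) and power per channel/sample."""

    phase: np.ndarray
    power: np.ndarray
    rate: float
    edge_samples: int = 0

    def __post_init__(self) -> None:
        if self.phase.shape != self.power.shape:
            raise ValueError("phase and power must have identical shapes")

    @property
    def n_samples(self) -> int:
        return self.phase.shape[-1]


def analytic_signal(filtered: np.ndarray, rate: float, edge_samples: int = 0) -> AnalyticSeries:
    """Hilbert phase and squared-signal power of a band-limited series.

    ``filtered`` is channels x samples (or a single 1-D channel).  Power is
    the squared filtered signal itself — the squared real part of the
    analytic extension — not the envelope.
    """
    x = np.atleast_2d(np.asarray(filtered, dtype=float))
    analytic = sps.hilbert(x, axis=-1)
    phase = np.angle(analytic)
    power = x**2
    return AnalyticSeries(phase, power, rate, edge_samples)


def mean_window_power(series: AnalyticSeries, window: tuple[int, int]) -> float:
    """Mean power over a half-open sample window, averaged across channels."""
    start, stop = window
    if not (0 <= start < stop <= series.n_samples):
        raise ValueError(f"empty or out-of-bounds window [{start}, {stop})")
    return float(series.power[:, start:stop].mean())
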