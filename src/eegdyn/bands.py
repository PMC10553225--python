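"""Canonical EEG frequency bands and the band-edge transition rule.

The four classical bands (delta 1-3 Hz, theta 4-7 Hz, alpha 8-12 Hz,
beta 13-30 Hz) are the default analysis set.  Each band carries a filter
transition width equal to 0.2 times its centre frequency, so that wider,
higher-frequency bands get proportionally wider filter skirts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["BandDefinition", "default_bands", "BAND_NAMES"]

BAND_NAMES = ("delta", "theta", "alpha", "beta")


def _default_transition(low: float, high: float) -> float:
    # transition width = 0.2 x band centre frequency
    return 0.2 * (low + high) / 2.0


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band with pass edges and filter transition width (Hz)."""

    name: str
    low: float
    high: float
    transition_width: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got [{self.low}, {self.high}]"
            )
        if self.transition_width == 0.0:
            object.__setattr__(
                self, "transition_width", _default_transition(self.low, self.high)
            )
        if self.transition_width <= 0:
            raise ValueError(f"band {self.name!r}: transition_width must be > 0")

    @property
    def bandwidth(self) -> float:
        """Pass bandwidth in Hz (high - low)."""
        return self.high - self.low

    @property
    def centre(self) -> float:
        return (self.low + self.high) / 2.0


def default_bands() -> tuple[BandDefinition, ...]:
    """The four canonical analysis bands in fixed (delta, theta, alpha, beta) order."""
    return (
        BandDefinition("delta", 1.0, 3.0),
        BandDefinition("theta", 4.0, 7.0),
        BandDefinition("alpha", 8.0, 12.0),
        BandDefinition("beta", 13.0, 30.0),
    )
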