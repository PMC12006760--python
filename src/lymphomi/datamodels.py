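"""Core in-memory containers for time-domain FLIM data.

A TCSPC (time-correlated single photon counting) acquisition produces, for
each pixel, a histogram of photon arrival times over one laser period. A
whole field of view is therefore a 3-D array of counts indexed by
(row, col, time-bin), plus the time base shared by every pixel. The
instrument response function (IRF) is a 1-D histogram on the same base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TCSPCImage", "InstrumentResponse"]

_TIMEBASE_RTOL = 1e-9


@dataclass
class TCSPCImage:
    """Photon-count histogram image for one fluorophore channel.

    Parameters
    ----------
    counts
        Array of shape ``(rows, cols, n_bins)`` of non-negative photon
        counts. Integer counts in acquired/simulated data; floats are
        accepted for noiseless expected-value stacks.
    bin_width_ns
        Width of one time bin in nanoseconds.
    period_ns
        Laser repetition period in nanoseconds (12.5 ns at 80 MHz).
    channel
        Free-form channel label, e.g. ``"nadh"`` or ``"fad"``.
    """

    counts: np.ndarray
    bin_width_ns: float
    period_ns: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (rows, cols, n_bins)")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")
        if not np.isclose(
            self.n_bins * self.bin_width_ns, self.period_ns, rtol=_TIMEBASE_RTOL
        ):
            raise ValueError(
                f"time base mismatch: {self.n_bins} bins x {self.bin_width_ns} ns "
                f"!= period {self.period_ns} ns"
            )

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    def bin_centers(self) -> np.ndarray:
        """Time at the center of each bin, ``(k + 1/2) * bin_width``."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ns

    def intensity(self) -> np.ndarray:
        """Per-pixel photon sum (the intensity image)."""
        return self.counts.sum(axis=2)


@dataclass
class InstrumentResponse:
    """The instrument response function as a 1-D histogram.

    The IRF is the system's temporal blur: every measured decay is the true
    fluorescence impulse response convolved with it. Experimentally it is
    recorded from a second-harmonic-generation signal; the simulator uses an
    analytic Gaussian by default.
    """

    counts: np.ndarray
    bin_width_ns: float
    period_ns: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("IRF counts must be 1-D")
        if np.any(self.counts < 0) or not np.any(self.counts > 0):
            raise ValueError("IRF must be non-negative with at least one positive bin")
        if self.period_ns == 0.0:
            self.period_ns = self.counts.size * self.bin_width_ns

    @property
    def n_bins(self) -> int:
        return self.counts.size

    def normalized(self) -> np.ndarray:
        """IRF scaled to unit sum (a probability mass over bins)."""
        return self.counts / self.counts.sum()
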