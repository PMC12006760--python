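"""Numerical kernels shared by the simulator and the fitter.

The physical model: under pulsed excitation at 80 MHz the fluorophore never
fully decays between pulses, so the detected histogram is the *periodic*
steady state of the impulse response, circularly convolved with the IRF over
one laser period. For a single exponential component with lifetime tau the
periodic steady state over t in [0, P) is

    d(t) = exp(-t/tau) / (1 - exp(-P/tau))

(the geometric sum of all preceding pulses), and a bi-exponential decay is
the amplitude-weighted sum of two such components.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "bin_centers",
    "periodic_exponential",
    "circular_convolve",
    "decay_curve",
]


def bin_centers(n_bins: int, period_ns: float) -> np.ndarray:
    """Bin-center times ``(k + 1/2) * dt`` for ``k = 0..n_bins-1``."""
    dt = period_ns / n_bins
    return (np.arange(n_bins) + 0.5) * dt


def periodic_exponential(tau: np.ndarray, t: np.ndarray, period_ns: float) -> np.ndarray:
    """Period-wrapped exponential decay, broadcast over lifetimes.

    Parameters
    ----------
    tau
        Lifetimes (ns), any shape; must be positive.
    t
        Sample times within one period, shape ``(n_bins,)``.

    Returns
    -------
    Array of shape ``tau.shape + (n_bins,)`` with value
    ``exp(-t/tau) / (1 - exp(-P/tau))``, i.e. unit amplitude at t=0 summed
    over all preceding excitation pulses.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("lifetimes must be positive")
    tt = tau[..., np.newaxis]
    return np.exp(-t / tt) / (-np.expm1(-period_ns / tt))


def circular_convolve(signal: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Circular (period-wrapped) convolution along the last axis."""
    n = signal.shape[-1]
    if kernel.shape[-1] != n:
        raise ValueError("signal and kernel must share the time base")
    out = np.fft.irfft(np.fft.rfft(signal, axis=-1) * np.fft.rfft(kernel, axis=-1), n=n, axis=-1)
    return out


def decay_curve(
    tau1: float,
    tau2: float,
    a1: float,
    irf_norm: np.ndarray,
    period_ns: float,
    n_bins: int,
) -> np.ndarray:
    """Expected decay *shape* (unit sum) for a bi-exponential model.

    ``a1`` is the fractional amplitude of the short component at t=0
    (amplitude convention, not photon-fraction convention); the result is
    the IRF-convolved periodic bi-exponential normalized to sum 1.
    """
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("lifetimes must be positive")
    if not 0.0 <= a1 <= 1.0:
        raise ValueError("a1 must lie in [0, 1]")
    t = bin_centers(n_bins, period_ns)
    comps = periodic_exponential(np.array([tau1, tau2]), t, period_ns)
    raw = a1 * comps[0] + (1.0 - a1) * comps[1]
    conv = circular_convolve(raw, irf_norm)
    return conv / conv.sum()
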