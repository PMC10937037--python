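"""Spectral and temporal oscillation metrics shared by the rate and spiking layers.

Frequency content is estimated with Welch's averaged-periodogram method
(Hann window, 50% overlap, mean detrend).  Spiking activity is analysed from
the pooled population PSTH, downsampled to 1 kHz before the PSD so the
frequency resolution suits the beta band (13-30 Hz), the band of interest
for Parkinsonian basal-ganglia oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import ArgumentError

#: beta band limits in Hz
BETA_BAND = (13.0, 30.0)


@dataclass
class SpectrumResult:
    freqs: np.ndarray          # Hz
    power: np.ndarray          # power spectral density, >= 0
    dominant_frequency: float  # Hz, on the grid (0 when no peak stands out)
    peak_prominence: float     # dominant peak power over the median power

    def band_slice(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        return (self.freqs >= lo) & (self.freqs <= hi)


def welch_psd(
    x: np.ndarray,
    fs: float,
    nperseg: int | None = None,
    overlap: float = 0.5,
) -> SpectrumResult:
    """Welch PSD of a uniformly sampled series.

    Defaults: Hann window, 50% overlap, segment length min(len/4, 4096).
    The DC bin is excluded from dominant-frequency extraction.
    """
    x = np.asarray(x, dtype=float)
    if nperseg is None:
        nperseg = int(min(len(x) // 4, 4096))
    if len(x) < 2 * nperseg or nperseg < 8:
        raise ArgumentError(
            f"signal too short for Welch PSD: {len(x)} samples, nperseg={nperseg}"
        )
    freqs, power = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="constant",
    )
    # dominant frequency among non-DC bins
    if len(freqs) > 1:
        k = 1 + int(np.argmax(power[1:]))
        med = float(np.median(power[1:]))
        prominence = float(power[k] / med) if med > 0 else np.inf
        dom = float(freqs[k]) if power[k] > 0 else 0.0
    else:
        dom, prominence = 0.0, 0.0
    return SpectrumResult(
        freqs=freqs, power=power, dominant_frequency=dom, peak_prominence=prominence
    )


def band_power(spec: SpectrumResult, band: tuple[float, float] = BETA_BAND) -> float:
    """Integral of the power density over [f_lo, f_hi] (trapezoid rule).

    Additive over disjoint bands that share the splitting grid point.
    """
    lo, hi = band
    if hi < lo:
        raise ArgumentError(f"inverted band ({lo}, {hi})")
    if lo < spec.freqs[0] or hi > spec.freqs[-1]:
        raise ArgumentError("band outside the frequency grid")
    # integrate on the grid restricted to the band, with interpolated endpoints
    grid = spec.freqs
    inside = (grid > lo) & (grid < hi)
    f = np.concatenate(([lo], grid[inside], [hi]))
    p = np.interp(f, grid, spec.power)
    return float(np.trapezoid(p, f))


def _quarter_amplitudes(x: np.ndarray) -> tuple[float, float, float]:
    """Peak-to-trough amplitude of the early half, third and last quarter."""
    m = len(x)
    q = m // 4
    early = x[: 2 * q]
    prev = x[-2 * q : -q]
    last = x[-q:]
    pt = lambda s: float(np.max(s) - np.min(s))
    return pt(early), pt(prev), pt(last)


def oscillation_class(
    x: np.ndarray,
    fs: float,
    amplitude_floor: float = 1e-3,
    sustain_ratio: float = 0.9,
) -> tuple[str, float]:
    """Classify a signal as none / transient / sustained, with dominant Hz.

    A sustained oscillation keeps >= ``sustain_ratio`` of the previous
    quarter's peak-to-trough amplitude in the final quarter and stays above
    the absolute floor; a transient one is above the floor early but decays
    below it.  The dominant frequency is reported only for oscillatory
    classes.  Classification is invariant to amplitude rescaling above the
    floor.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 32:
        raise ArgumentError("signal too short to classify (need >= 32 samples)")
    amp_early, amp_prev, amp_last = _quarter_amplitudes(x)
    if amp_last > amplitude_floor and amp_last >= sustain_ratio * amp_prev:
        label = "sustained"
    elif amp_early > amplitude_floor and amp_last < amplitude_floor:
        label = "transient"
    else:
        label = "none"
    if label == "none":
        return label, 0.0
    try:
        spec = welch_psd(x - np.mean(x), fs)
        freq = spec.dominant_frequency
    except ArgumentError:
        freq = 0.0
    return label, freq


def downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Block-average downsampling by an integer factor (anti-aliasing by
    averaging); used to bring 0.1 ms PSTH bins or 0.01 ms rate samples to
    1 kHz before spectral analysis."""
    factor = int(round(fs_in / fs_out))
    if factor < 1:
        raise ArgumentError("fs_out must not exceed fs_in")
    if factor == 1:
        return np.asarray(x, dtype=float)
    m = (len(x) // factor) * factor
    return np.asarray(x[:m], dtype=float).reshape(-1, factor).mean(axis=1)
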