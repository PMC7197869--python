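"""Spike-count power spectra via a complex Morlet wavelet transform.

Spikes are binned into non-overlapping 4-ms count windows; the count series
is convolved with complex Morlet wavelets on a geometric frequency ladder
(1/64 Hz times powers of 2^(1/8), up to the 125 Hz Nyquist of the count
series).  The power S(f) is the time average of |TFR|^2, divided by the
train's mean rate so that a homogeneous Poisson train gives S(f) ~ 1 at all
frequencies.  Low frequencies in bursty trains rise as S(f) ~ f^-beta.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .segments import SpikeTrainSegment

__all__ = ["frequency_ladder", "morlet_power_spectrum", "spectral_exponent"]

BIN_S = 0.004          # 4 ms count windows
F0 = 1.0 / 64.0        # lowest ladder frequency, Hz
OMEGA0 = 6.0           # Morlet centre-frequency/bandwidth ratio: sigma_t = 6/(2 pi f)


def frequency_ladder(f_max: float | None = None) -> np.ndarray:
    """Frequencies 1/64 * 2^(k/8) Hz up to f_max (default: Nyquist 125 Hz)."""
    nyquist = 0.5 / BIN_S
    f_max = nyquist if f_max is None else min(f_max, nyquist)
    kmax = int(np.floor(8 * np.log2(f_max / F0)))
    return F0 * 2.0 ** (np.arange(kmax + 1) / 8.0)


def _wavelet(f: float, dt: float) -> np.ndarray:
    sigma_t = OMEGA0 / (2.0 * np.pi * f)
    j = np.arange(-int(np.ceil(3 * sigma_t / dt)), int(np.ceil(3 * sigma_t / dt)) + 1)
    t = j * dt
    w = np.exp(-t**2 / (2 * sigma_t**2)) * np.exp(2j * np.pi * f * t)
    # L2 normalization sum |w|^2 = 1/dt makes E<|TFR|^2> = rate for white
    # (Poisson) spike noise, i.e. S(f) -> 1 after rate division.
    return w / np.sqrt(dt * np.sum(np.abs(w) ** 2))


def morlet_power_spectrum(
    segment: SpikeTrainSegment, f_max: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rate-normalized Morlet power spectrum of one segment.

    Returns (frequencies, S).  The convolution zero-pads the count series;
    edge samples within 3 sigma_t of either end of the window are discarded
    before time-averaging (capped so at least half of the window is kept,
    which matters only for ladder frequencies whose wavelet is comparable in
    extent to the window itself).
    """
    if segment.n_spikes < 11:
        raise ValueError("need at least 11 spikes for a spectrum")
    nbins = int(round(segment.t_seg / BIN_S))
    counts = np.bincount(
        np.minimum((segment.spike_times / BIN_S).astype(int), nbins - 1),
        minlength=nbins,
    ).astype(float)
    rate = segment.n_spikes / segment.t_seg
    freqs = frequency_ladder(f_max)
    power = np.empty(freqs.size)
    for i, f in enumerate(freqs):
        w = _wavelet(f, BIN_S)
        tfr = fftconvolve(counts, w, mode="same")
        edge = min((w.size - 1) // 2, nbins // 4)
        power[i] = np.mean(np.abs(tfr[edge : nbins - edge]) ** 2) / rate
    return freqs, power


def spectral_exponent(
    freqs: np.ndarray, power: np.ndarray, f_min: float = 0.05, f_max: float = 10.0
) -> float:
    """Power-law exponent beta of S(f) ~ f^-beta fitted on [f_min, f_max]."""
    sel = (freqs >= f_min) & (freqs <= f_max) & (power > 0)
    if sel.sum() < 3:
        raise ValueError("too few frequencies in the fit band")
    slope = np.polyfit(np.log(freqs[sel]), np.log(power[sel]), 1)[0]
    return float(-slope)
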