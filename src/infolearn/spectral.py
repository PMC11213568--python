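"""Single-trial gamma-band power from raw trial-locked voltage traces.

Processing chain (all steps strictly per-trial):

1. bipolar referencing between adjacent contacts of a depth electrode,
   rejecting common-mode (volume-conducted) signal;
2. sliding-window multitaper band power in the 50-100 Hz gamma band: 200 ms
   windows (15 cycles of the 75 Hz center frequency) multiplied by 9 Slepian
   tapers, demodulated at 75 Hz; power is the mean over tapers of the squared
   demodulated amplitude, giving an effective +-25 Hz smoothing around the
   center;
3. anti-aliased downsampling of the power envelope to 256 Hz;
4. Savitzky-Golay smoothing (11-point window, polynomial order 3; the
   classical odd-window formulation of a nominal 10-point filter).

Supported raw sampling rates are 512 and 1024 Hz (integer multiples of the
256 Hz analysis rate); other rates are resampled with a warning.  Samples
within half a taper window of the epoch edges are invalid and returned NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import xarray as xr
from scipy import signal

__all__ = [
    "ContactInfo",
    "ROIS",
    "bipolar_reference",
    "multitaper_gamma_power",
    "downsample_power",
    "smooth_power",
    "raw_to_power",
]

ROIS = ("aINS", "dlPFC", "lOFC", "vmPFC")

GAMMA_CENTER = 75.0  # Hz
WINDOW_S = 0.2  # 15 cycles at 75 Hz
N_TAPERS = 9
TARGET_SFREQ = 256.0


@dataclass(frozen=True)
class ContactInfo:
    """Identity of one (bipolar) recording site."""

    subject: int
    roi: str
    electrode: str
    index: int

    def __post_init__(self) -> None:
        if self.roi not in ROIS and self.roi != "sim":
            raise ValueError(f"unknown ROI {self.roi!r}; expected one of {ROIS}")


def bipolar_reference(traces: np.ndarray) -> np.ndarray:
    """Adjacent-contact differences along the first axis.

    ``traces`` is (n_contacts, ..., time) for one electrode, contacts ordered
    by index; output k is ``contact[k+1] - contact[k]`` (n-1 derivations).
    A single-contact electrode yields an empty output with a warning.
    """
    traces = np.asarray(traces)
    if traces.shape[0] < 2:
        warnings.warn("electrode has a single contact: no bipolar derivation")
        return traces[:0]
    return np.diff(traces, axis=0)


def multitaper_gamma_power(
    traces: np.ndarray,
    sfreq: float,
    center: float = GAMMA_CENTER,
    window_s: float = WINDOW_S,
    n_tapers: int = N_TAPERS,
) -> np.ndarray:
    """Sliding multitaper band power around ``center`` Hz.

    For each Slepian taper h_k the trace is demodulated at the center
    frequency and convolved, y_k(t) = sum_tau x(t+tau) h_k(tau) e^{-i 2 pi f
    tau}; power is the mean over tapers of |y_k|^2.  With a 200 ms window and
    9 tapers the half-bandwidth is 25 Hz, covering 50-100 Hz.  Output has the
    input shape; the half-window edges are NaN.
    """
    traces = np.asarray(traces, dtype=float)
    if sfreq < TARGET_SFREQ:
        raise ValueError(f"sampling rate must be >= {TARGET_SFREQ} Hz")
    m = int(round(window_s * sfreq))
    if traces.shape[-1] < m:
        raise ValueError("trace shorter than one taper window")
    nw = (n_tapers + 1) / 2.0  # 2*NW - 1 usable tapers
    tapers = signal.windows.dpss(m, nw, Kmax=n_tapers)
    tau = (np.arange(m) - m // 2) / sfreq
    carrier = np.exp(-2j * np.pi * center * tau)
    power = np.zeros(traces.shape)
    for h in tapers:
        kern = (h * carrier)[::-1]
        flat = traces.reshape(-1, traces.shape[-1])
        y = signal.fftconvolve(flat, kern[None, :], mode="same", axes=-1)
        power += (y.real**2 + y.imag**2).reshape(traces.shape)
    power /= n_tapers
    half = m // 2
    power[..., :half] = np.nan
    power[..., -half:] = np.nan
    return power


def downsample_power(
    power: np.ndarray, sfreq: float, target: float = TARGET_SFREQ
) -> tuple[np.ndarray, float]:
    """Anti-aliased decimation of a power envelope to ``target`` Hz.

    Integer source/target ratios use polyphase decimation; non-integer ratios
    are resampled rationally with a warning.  NaN edge samples are excluded
    from filtering and restored as NaN.  Returns ``(power, target)``.
    """
    power = np.asarray(power, dtype=float)
    if sfreq == target:
        return power, target
    if sfreq < target:
        raise ValueError("source rate below target rate")
    frac = Fraction(target / sfreq).limit_denominator(1000)
    if sfreq % target != 0:
        warnings.warn(
            f"non-integer decimation ratio {sfreq}/{target}; rational resampling"
        )
    valid = ~np.isnan(power)
    filled = np.where(valid, power, np.nanmean(power) if np.any(valid) else 0.0)
    out = signal.resample_poly(filled, frac.numerator, frac.denominator, axis=-1)
    # propagate NaN edges onto the decimated grid
    n_out = out.shape[-1]
    idx = np.minimum(
        (np.arange(n_out) * sfreq / target).astype(int), power.shape[-1] - 1
    )
    out[~valid[..., idx]] = np.nan
    return out, target


def smooth_power(power: np.ndarray, window: int = 11, order: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing along time (odd window, default 11 points)."""
    power = np.asarray(power, dtype=float)
    if power.shape[-1] < window:
        raise ValueError("series shorter than the smoothing window")
    valid = ~np.isnan(power)
    filled = np.where(valid, power, 0.0)
    out = signal.savgol_filter(filled, window, order, axis=-1)
    out[~valid] = np.nan
    return out


def raw_to_power(
    traces: np.ndarray,
    sfreq: float,
    times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None, float]:
    """Full spectral chain: multitaper power -> 256 Hz -> Savitzky-Golay.

    ``traces`` is (..., time) raw voltage at ``sfreq``; returns the smoothed
    power, the decimated time axis (if ``times`` was given; alignment at
    t = 0 is preserved by index-subsampling the axis), and the output rate.
    """
    power = multitaper_gamma_power(traces, sfreq)
    power, out_rate = downsample_power(power, sfreq, TARGET_SFREQ)
    power = smooth_power(power)
    out_times = None
    if times is not None:
        step = sfreq / out_rate
        idx = np.minimum(
            (np.arange(power.shape[-1]) * step).astype(int), len(times) - 1
        )
        out_times = np.asarray(times)[idx]
    return power, out_times, out_rate
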