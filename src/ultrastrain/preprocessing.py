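"""RF preprocessing: analytic signal, baseband demodulation, multirate pyramid.

The estimation stages never touch raw RF directly.  Each frame is converted
to its analytic signal (Hilbert transform per scan line), demodulated by the
carrier ``exp(j w0 t)`` to complex baseband, and decimated into a pyramid of
downsample rates.  Envelope (``|baseband|``) planes feed the coarse block
matching; the rate-1 baseband phase feeds the fine phase zero-crossing stage.
"""

from __future__ import annotations

import logging
import time
import warnings

import numpy as np
from scipy import signal as sps

from .rf_frames import (AnalyticFrame, BasebandPyramid, PyramidLevel, RFFrame,
                        ValidationError)

logger = logging.getLogger("ultrastrain")

__all__ = ["analytic_signal", "demodulate", "baseband_bandwidth", "build_pyramid"]

# taps of the anti-alias FIR (odd length => exactly linear phase, and a
# centered 'same' convolution applies it with zero net delay)
_AA_TAPS = 65


def analytic_signal(frame: RFFrame) -> AnalyticFrame:
    """Analytic signal of every scan line via the Hilbert transform.

    The real part equals the input RF; the imaginary part is its Hilbert
    transform, so the modulus is the echo envelope and the angle the
    instantaneous carrier phase.
    """
    t0 = time.perf_counter()
    values = sps.hilbert(frame.samples, axis=0)
    logger.info("analytic_signal: shape=%s elapsed=%.3fs",
                frame.samples.shape, time.perf_counter() - t0)
    return AnalyticFrame.like(frame, values)


def demodulate(frame: AnalyticFrame, w0: float) -> np.ndarray:
    """Demodulate an analytic frame to complex baseband.

    Multiplies each line by ``exp(-j w0 t)`` with ``t = i / fs``; this
    shifts the spectrum down by ``w0`` and leaves the modulus untouched.

    Parameters
    ----------
    w0 : float
        Demodulation angular frequency, rad/s.  A value more than 25% away
        from ``2*pi*f0`` triggers a warning (the phase-zero update assumes
        the residual carrier is small).
    """
    if w0 <= 0:
        raise ValidationError("w0 must be positive")
    nominal = 2.0 * np.pi * frame.f0
    if abs(w0 - nominal) > 0.25 * nominal:
        warnings.warn(
            f"w0={w0:g} is more than 25% away from the carrier {nominal:g}",
            stacklevel=2,
        )
    t = np.arange(frame.n_samples) / frame.fs
    return frame.values * np.exp(-1j * w0 * t)[:, None]


def baseband_bandwidth(baseband: np.ndarray, fs: float, floor_db: float = 20.0) -> float:
    """One-sided bandwidth of a complex baseband frame, Hz.

    Returns the largest ``|f|`` at which the line-averaged power spectrum is
    within ``floor_db`` dB of its peak — a cheap, conservative estimate used
    for the decimation Nyquist check.
    """
    n = baseband.shape[0]
    spec = np.fft.fft(baseband, axis=0)
    power = np.mean(np.abs(spec) ** 2, axis=1)
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    keep = power >= power.max() * 10.0 ** (-floor_db / 10.0)
    return float(np.max(np.abs(freqs[keep])))


def _anti_alias(baseband: np.ndarray, fs: float, rate: int) -> np.ndarray:
    """Zero-phase low-pass before factor-``rate`` decimation."""
    cutoff = 0.8 * (fs / rate) / 2.0
    taps = sps.firwin(_AA_TAPS, cutoff, fs=fs)
    return sps.fftconvolve(baseband, taps[:, None], mode="same", axes=0)


def build_pyramid(baseband: np.ndarray, rates, w0: float, fs: float) -> BasebandPyramid:
    """Decimate a baseband frame into a multirate envelope/baseband pyramid.

    Each requested rate ``r`` must satisfy ``fs / r > 2 B`` where ``B`` is
    the measured one-sided baseband bandwidth (20 dB floor); violating rates
    raise with the offending rate and the measurement.  Rate-1 levels are
    passed through unfiltered.
    """
    t0 = time.perf_counter()
    rates = [int(r) for r in rates]
    bw = baseband_bandwidth(baseband, fs)
    levels = []
    for r in rates:
        if r < 1:
            raise ValidationError(f"downsample rate must be >= 1, got {r}")
        if r > 1 and fs / r <= 2.0 * bw:
            raise ValidationError(
                f"rate {r} violates the Nyquist contract: fs/rate = {fs / r:g} Hz "
                f"<= 2 x measured bandwidth {bw:g} Hz"
            )
        dec = baseband if r == 1 else _anti_alias(baseband, fs, r)[::r]
        levels.append(PyramidLevel(rate=r, baseband=dec, envelope=np.abs(dec)))
    logger.info("build_pyramid: rates=%s bandwidth=%.3gHz elapsed=%.3fs",
                rates, bw, time.perf_counter() - t0)
    return BasebandPyramid(levels=levels, w0=w0)
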