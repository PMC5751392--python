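"""Shared fixtures and synthetic-signal helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from ultrastrain.rf_frames import RFFrame, RunConfig

FS = 120e6
F0 = 7.5e6
W0_SAMP = 2.0 * np.pi * F0 / FS


def make_rf_speckle(n_samples: int, n_lines: int, seed: int,
                    fs: float = FS, f0: float = F0) -> RFFrame:
    """Band-limited RF speckle: white noise convolved with a Gaussian pulse."""
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_samples, n_lines))
    t = np.arange(-40, 41)
    # 60% fractional -6 dB bandwidth pulse
    sigma_f = 0.6 * f0 / (2 * np.sqrt(2 * np.log(2)))
    sigma = fs / (2 * np.pi * sigma_f)
    pulse = np.exp(-t**2 / (2 * sigma**2)) * np.cos(2 * np.pi * f0 / fs * t)
    rf = np.apply_along_axis(lambda x: np.convolve(x, pulse, mode="same"), 0, noise)
    return RFFrame(rf, fs=fs, f0=f0, c=1540.0, line_spacing=0.15e-3)


def delay_frame(frame: RFFrame, delay_samples: float) -> RFFrame:
    """Delay every line by a (fractional) number of samples via FFT phase."""
    n = frame.n_samples
    freqs = np.fft.rfftfreq(n)
    shift = np.exp(-2j * np.pi * freqs * delay_samples)[:, None]
    out = np.fft.irfft(np.fft.rfft(frame.samples, axis=0) * shift, n=n, axis=0)
    return RFFrame(out, **frame.meta())


def make_analytic_speckle(n_samples: int, n_lines: int, seed: int,
                          w0: float = W0_SAMP, corr_len: float = 8.0):
    """Complex analytic speckle: smooth complex envelope times the carrier."""
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_samples, n_lines)) \
        + 1j * rng.standard_normal((n_samples, n_lines))
    g = gaussian_filter1d(g.real, corr_len, axis=0) \
        + 1j * gaussian_filter1d(g.imag, corr_len, axis=0)
    t = np.arange(n_samples)
    return g, g * np.exp(1j * w0 * t)[:, None]


def warp_analytic(envelope: np.ndarray, u: np.ndarray,
                  w0: float = W0_SAMP) -> np.ndarray:
    """Analytic signal observed after axial displacement ``u`` (samples).

    The post signal at sample ``t`` is the pre signal evaluated at ``t - u(t)``:
    the smooth envelope is linearly interpolated and the carrier phase applied
    analytically, so delays are exact for slowly varying ``u``.
    """
    n = envelope.shape[0]
    t = np.arange(n, dtype=float)
    out = np.empty_like(envelope)
    u = np.broadcast_to(u, envelope.shape)
    for j in range(envelope.shape[1]):
        pos = np.clip(t - u[:, j], 0, n - 1)
        re = np.interp(pos, t, envelope[:, j].real)
        im = np.interp(pos, t, envelope[:, j].imag)
        out[:, j] = (re + 1j * im) * np.exp(1j * w0 * pos)
    return out


def gaussian_tone(n: int, center: float, sigma: float = 20.0,
                  w0: float = W0_SAMP, delay: float = 0.0) -> np.ndarray:
    """Analytic Gaussian-enveloped tone centered at ``center`` samples.

    ``delay`` shifts the whole waveform — envelope *and* carrier phase — by
    that many samples, producing a true time-delayed copy.
    """
    t = np.arange(n, dtype=float) - delay
    return np.exp(-(t - center) ** 2 / (2 * sigma ** 2)) * np.exp(1j * w0 * t)


def envelope_field(n_rows: int, n_cols: int, seed: int,
                   smooth: float = 4.0) -> np.ndarray:
    """Positive smooth random field standing in for an envelope plane."""
    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.standard_normal((n_rows, n_cols)), smooth)
    return f - f.min() + 0.1


@pytest.fixture(scope="session")
def small_cfg() -> RunConfig:
    """Desk-scale run config: shallow 10x10 mm phantom, 32 lines."""
    return RunConfig(n_lines=32, width=0.010, height=0.010,
                     inclusion_depth=0.005, inclusion_lateral=0.005,
                     inclusion_radius=0.002, mesh_n=24,
                     roi_radius=0.8e-3, roi_bg_offset=3.5e-3,
                     lsqse_kernel=21, scatterer_density=20.0,
                     level1_win_lines=8, lateral_search=3,
                     level2_cols=9, sg_window=7)


@pytest.fixture(scope="session")
def small_pair(small_cfg):
    """One simulated pre/post pair of the small phantom at 2% strain."""
    from ultrastrain import phantom_sim as ps
    from ultrastrain import pipeline as pl
    spec = pl.phantom_spec(small_cfg, compression=0.02 * small_cfg.height,
                           e_background=2.5e4)
    tspec = pl.transducer_spec(small_cfg)
    truth = ps.solve_fem(spec)
    pre, post, _ = ps.make_pair(spec, tspec, 42, truth=truth)
    return pre, post, truth, spec
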