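"""End-to-end estimation pipelines built from the stage modules.

Three algorithms share the same preprocessing and strain/metric stages and
differ only in displacement estimation:

* ``proposed``  — 2D multiresolution hybrid: 3-level coarse NCC search on
  envelope pyramids, Savitzky-Golay finalized lateral displacement, then
  coarse-initialized laterally compensated phase zero-crossing.
* ``oned``      — original 1D elastography: chained phase zero-crossing on
  the full-rate data, no lateral handling.
* ``oned_ds``   — the chained estimator run on decimated baseband.
"""

from __future__ import annotations

import logging
import time

import numpy as np

from . import coarse_estimation as ce
from . import fine_estimation as fe
from . import phantom_sim as ps
from . import preprocessing as pp
from . import strain_metrics as sm
from .rf_frames import (DisplacementField, DisplacementGrid, RFFrame, RunConfig,
                        StrainMap, ValidationError)

logger = logging.getLogger("ultrastrain")

ALGORITHMS = ("proposed", "oned", "oned_ds")

__all__ = ["ALGORITHMS", "phantom_spec", "transducer_spec", "phase_cfg",
           "calibrated_phantom", "run_proposed", "run_chained",
           "run_downsampled", "run_algorithm", "default_rois", "metrics",
           "truth_map_like"]


def phantom_spec(cfg: RunConfig, compression: float | None = None,
                 e_background: float | None = None,
                 homogeneous: bool = False) -> ps.PhantomSpec:
    """PhantomSpec from a run config; compression in metres."""
    e_bg = e_background if e_background is not None else (
        cfg.e_background if cfg.e_background > 0 else cfg.e_inclusion)
    return ps.PhantomSpec(
        width=cfg.width, height=cfg.height,
        inclusion_center=(cfg.inclusion_depth, cfg.inclusion_lateral),
        inclusion_radius=0.0 if homogeneous else cfg.inclusion_radius,
        e_inclusion=e_bg if homogeneous else cfg.e_inclusion,
        e_background=e_bg, poisson=cfg.poisson, density=cfg.density,
        compression=compression if compression is not None else 0.6e-3,
        mesh_n=cfg.mesh_n)


def transducer_spec(cfg: RunConfig) -> ps.TransducerSpec:
    return ps.TransducerSpec(
        f0=cfg.f0, fs=cfg.fs, n_lines=cfg.n_lines,
        line_spacing=cfg.line_spacing, c=cfg.c, pulse_bw=cfg.pulse_bw,
        beam_sigma=cfg.beam_sigma, scatterer_density=cfg.scatterer_density,
        noise_snr=cfg.noise_snr)


def calibrated_phantom(cfg: RunConfig, compression: float) -> ps.PhantomSpec:
    """Phantom spec with the background modulus set by contrast calibration
    (skipped when the config pins ``e_background`` explicitly)."""
    spec = phantom_spec(cfg, compression=compression)
    if cfg.e_background > 0:
        return spec
    import dataclasses
    e_bg = ps.calibrate_contrast(spec, cfg.contrast)
    return dataclasses.replace(spec, e_background=e_bg)


def phase_cfg(cfg: RunConfig, init_mode: str) -> fe.PhaseZeroConfig:
    return fe.PhaseZeroConfig(
        window_T=max(4, int(round(cfg.fine_window_wavelengths
                                  * cfg.wavelength_samples))),
        overlap=cfg.fine_overlap,
        w0=2.0 * np.pi * cfg.f0 / cfg.fs,
        max_iter=cfg.newton_max_iter, tol=cfg.newton_tol,
        init_mode=init_mode)


def _level_specs(cfg: RunConfig, n_rows_finest: int):
    """Window/search sizing of the three coarse levels from the config."""
    lam = cfg.wavelength_samples
    r1, r2, r3 = cfg.rates
    h1 = max(8, int(round(cfg.level1_win_wavelengths * lam / r1)))
    w1 = cfg.level1_win_lines
    sh1 = max(4, int(np.ceil(0.75 * cfg.expected_max_strain * n_rows_finest / r1)))
    spec1 = ce.SearchSpec(h1, w1, sh1, cfg.lateral_search, cfg.depth_growth)
    h2 = max(6, int(round(h1 * r1 / r2 / 3.0)))
    w2 = max(3, int(round(w1 / 3.0)))
    spec2 = ce.SearchSpec(h2, w2, cfg.level2_search_axial, cfg.level2_search_lateral)
    h3 = max(4, int(round(h2 * r2 / r3 / 2.0)))
    w3 = max(3, int(round(w2 / 2.0)))
    spec3 = ce.SearchSpec(h3, w3, cfg.level3_search_axial, cfg.level3_search_lateral)
    return spec1, spec2, spec3


def coarse_pipeline(pre: RFFrame, post: RFFrame, cfg: RunConfig):
    """Preprocessing + 3-level coarse search.

    Returns ``(level3_grid, final_lateral, analytic_pre, analytic_post)``;
    the grid is in level-3 samples, ``final_lateral`` in lines on the same
    grid.
    """
    w0 = 2.0 * np.pi * cfg.f0
    pyramids = []
    analytic = []
    for frame in (pre, post):
        ana = pp.analytic_signal(frame)
        bb = pp.demodulate(ana, w0)
        pyramids.append(pp.build_pyramid(bb, list(cfg.rates) + [1], w0, cfg.fs))
        analytic.append(ana)
    r1, r2, r3 = cfg.rates
    spec1, spec2, spec3 = _level_specs(cfg, pre.n_samples)
    env = lambda p, r: p.level(r).envelope
    g1 = ce.level1_search(env(pyramids[0], r1), env(pyramids[1], r1), spec1,
                          valid_floor=cfg.valid_floor, rate=r1)
    # continuity limits: half the fine-stage capture range, in level units
    half_capture = cfg.wavelength_samples / 4.0
    g2 = ce.level2_search(env(pyramids[0], r2), env(pyramids[1], r2), g1, spec2,
                          rate=r2, rows=cfg.level2_rows, cols=cfg.level2_cols,
                          valid_floor=cfg.valid_floor,
                          max_steps=cfg.track_max_steps,
                          continuity_limit=(max(1.0, half_capture / r2), 1.0))
    g3 = ce.level3_search(env(pyramids[0], r3), env(pyramids[1], r3), g2, spec3,
                          rate=r3, overlap=cfg.level3_overlap,
                          valid_floor=cfg.valid_floor,
                          max_steps=cfg.track_max_steps,
                          continuity_limit=(max(1.0, 2 * half_capture / r3), 1.0))
    n_cols = g3.lateral.shape[1]
    sg_win = cfg.sg_window
    if n_cols < sg_win:                      # small frames: shrink the filter
        sg_win = n_cols if n_cols % 2 == 1 else n_cols - 1
        sg_win = max(sg_win, cfg.sg_order + 1 + (cfg.sg_order + 1) % 2)
        logger.info("finalize_lateral: shrinking sg_window to %d for %d columns",
                    sg_win, n_cols)
    final_lateral = ce.finalize_lateral(g3, sg_win, cfg.sg_order,
                                        cfg.lateral_sig_threshold)
    return g3, final_lateral, analytic[0], analytic[1]


def _fine_grid_init(grid3: DisplacementGrid, final_lateral: np.ndarray,
                    n_samples: int, n_lines: int, pcfg: fe.PhaseZeroConfig):
    """Interpolate the coarse results onto the fine window grid (finest units)."""
    starts = fe._fine_centers(n_samples, pcfg)
    centers = starts + pcfg.window_T // 2
    src = DisplacementGrid(grid3.axial, final_lateral, grid3.centers_axial,
                           grid3.centers_lateral,
                           np.ones_like(grid3.valid), rate=grid3.rate)
    return ce.interp_grid(src, centers, np.arange(n_lines),
                          scale_axial=float(grid3.rate))


def run_proposed(pre: RFFrame, post: RFFrame, cfg: RunConfig):
    """Full 2D multiresolution hybrid pipeline; returns (StrainMap, field, diag)."""
    t0 = time.perf_counter()
    grid3, final_lateral, ana_pre, ana_post = coarse_pipeline(pre, post, cfg)
    pcfg = phase_cfg(cfg, "coarse")
    init = _fine_grid_init(grid3, final_lateral, pre.n_samples, pre.n_lines, pcfg)
    field = fe.fine_field_modified(ana_pre, ana_post, init.axial, init.lateral,
                                   pcfg)
    smap = _to_strain(field, cfg, pre)
    diag = {"elapsed": time.perf_counter() - t0,
            "coarse_valid_frac": float(grid3.valid.mean()),
            "fine_converged_frac": float(field.valid.mean())}
    return smap, field, diag


def run_chained(pre: RFFrame, post: RFFrame, cfg: RunConfig):
    """Original chained 1D phase-zero baseline."""
    t0 = time.perf_counter()
    pcfg = phase_cfg(cfg, "chained")
    field = fe.fine_field_chained_1d(pp.analytic_signal(pre),
                                     pp.analytic_signal(post), pcfg)
    smap = _to_strain(field, cfg, pre)
    return smap, field, {"elapsed": time.perf_counter() - t0,
                         "fine_converged_frac": float(field.valid.mean())}


def run_downsampled(pre: RFFrame, post: RFFrame, cfg: RunConfig):
    """Chained 1D baseline on decimated baseband."""
    t0 = time.perf_counter()
    pcfg = phase_cfg(cfg, "chained")
    field = fe.fine_field_downsampled_1d(pre, post, cfg.ds_rate, pcfg)
    smap = _to_strain(field, cfg, pre)
    return smap, field, {"elapsed": time.perf_counter() - t0,
                         "fine_converged_frac": float(field.valid.mean())}


_RUNNERS = {"proposed": run_proposed, "oned": run_chained,
            "oned_ds": run_downsampled}


def run_algorithm(name: str, pre: RFFrame, post: RFFrame, cfg: RunConfig):
    if name not in _RUNNERS:
        raise ValidationError(
            f"unknown algorithm {name!r}; choose from {', '.join(ALGORITHMS)}")
    return _RUNNERS[name](pre, post, cfg)


def _to_strain(field: DisplacementField, cfg: RunConfig, frame: RFFrame) -> StrainMap:
    kernel = cfg.lsqse_kernel
    if kernel >= field.shape[0]:
        kernel = max(3, (field.shape[0] - 1) // 2 * 2 - 1)
        logger.info("strain_map: shrinking kernel to %d for %d windows",
                    kernel, field.shape[0])
    return sm.strain_map(field, kernel, fs=frame.fs, c=frame.c,
                         line_spacing=frame.line_spacing,
                         depth_offset=frame.depth_offset)


def default_rois(cfg: RunConfig) -> tuple[sm.ROISpec, sm.ROISpec]:
    """Inclusion and background ROIs: equal circles at the inclusion depth,
    the background one laterally offset past the inclusion edge."""
    inc = sm.ROISpec("circle", (cfg.inclusion_depth, cfg.inclusion_lateral),
                     radius=cfg.roi_radius, role="inclusion")
    bg = sm.ROISpec("circle", (cfg.inclusion_depth,
                               cfg.inclusion_lateral + cfg.roi_bg_offset),
                    radius=cfg.roi_radius, role="background")
    return inc, bg


def metrics(smap: StrainMap, cfg: RunConfig) -> dict:
    """CNRe, background/inclusion strain ratio and inclusion area ratio."""
    inc, bg = default_rois(cfg)
    binary = sm.binarize(smap)
    return {"cnre": sm.cnre(smap, inc, bg),
            "strain_ratio": sm.strain_ratio(smap, inc, bg),
            "area_ratio": sm.inclusion_area_ratio(binary)}


def truth_map_like(truth: ps.GroundTruth, smap: StrainMap) -> StrainMap:
    """Ground-truth strain sampled on the same grid as an estimated map."""
    zz, xx = np.meshgrid(smap.depths, smap.laterals, indexing="ij")
    return StrainMap(truth.strain_at(zz, xx), smap.centers_axial,
                     smap.centers_lateral, fs=smap.fs, c=smap.c,
                     line_spacing=smap.line_spacing,
                     depth_offset=smap.depth_offset)
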