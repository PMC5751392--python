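"""Three-level coarse displacement estimation on envelope data.

Level 1 runs an exhaustive zero-normalized cross-correlation (NCC) search in
nine evenly distributed windows at the coarsest pyramid scale.  Levels 2 and
3 refine on progressively finer scales with the greedy "following tracking"
strategy — the reference point repeatedly moves to the best-correlated point
among its 5x5 neighbourhood — plus a "delivering" strategy that seeds each
window with the result of the window above it in the same column.  The final
lateral displacement is Savitzky-Golay smoothed and thresholded to its
significant part before being handed to the fine stage.

All displacements inside this module are expressed in samples at the scale
of the envelope plane being searched, and in whole scan lines laterally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .rf_frames import DisplacementGrid, ValidationError

logger = logging.getLogger("ultrastrain")

__all__ = [
    "SearchSpec",
    "CorrelationSurface",
    "TrackResult",
    "ncc",
    "following_track",
    "reject_outliers",
    "level1_search",
    "level2_search",
    "level3_search",
    "finalize_lateral",
    "interp_grid",
    "default_neighborhood",
]


@dataclass
class SearchSpec:
    """Window and search-region sizing for one coarse level.

    ``calc_h``/``calc_w``: calculation-window height (samples at the level's
    scale) and width (lines).  ``search_h``/``search_w``: half-ranges of the
    search region.  ``depth_growth``: additive fractional growth of
    ``search_h`` per window row (deeper windows accumulate displacement).
    """

    calc_h: int
    calc_w: int
    search_h: int
    search_w: int
    depth_growth: float = 0.0

    def __post_init__(self) -> None:
        if self.calc_h < 4 or self.calc_w < 2:
            raise ValidationError("calculation window must be at least 4 x 2")
        if self.search_h < 1 or self.search_w < 1:
            raise ValidationError("search half-ranges must be >= 1")


@dataclass
class CorrelationSurface:
    """NCC values over a grid of (axial, lateral) offsets."""

    values: np.ndarray
    offsets_axial: np.ndarray
    offsets_lateral: np.ndarray

    def argmax(self) -> tuple[int, int, float]:
        """Best offset under the deterministic tie-break; returns (dy, dx, peak)."""
        vals = self.values
        if np.all(np.isnan(vals)):
            return 0, 0, float("nan")
        dy_g, dx_g = np.meshgrid(self.offsets_axial, self.offsets_lateral, indexing="ij")
        flat = np.column_stack([dy_g.ravel(), dx_g.ravel()])
        i = _best_index(flat, vals.ravel())
        return int(flat[i, 0]), int(flat[i, 1]), float(vals.ravel()[i])


@dataclass
class TrackResult:
    """Outcome of one following-tracking run."""

    point: tuple[int, int]
    status: str  # converged | hit_boundary | max_steps
    steps: int
    value: float = float("nan")


def _best_index(points: np.ndarray, values: np.ndarray) -> int:
    """Argmax with deterministic tie-break: smallest offset magnitude,
    then smallest dy, then smallest dx.  NaNs never win."""
    vals = np.where(np.isnan(values), -np.inf, values)
    best = vals.max()
    tied = np.flatnonzero(vals >= best - 1e-15)
    if len(tied) == 1:
        return int(tied[0])
    pts = points[tied]
    order = np.lexsort((pts[:, 1], pts[:, 0], np.hypot(pts[:, 0], pts[:, 1])))
    return int(tied[order[0]])


def ncc(A_window: np.ndarray, B_region: np.ndarray,
        offsets_axial, offsets_lateral, anchor=(0, 0)) -> CorrelationSurface:
    """Zero-normalized cross-correlation of a window against patches of a region.

    ``values[i, j]`` correlates ``A_window`` with the equally sized patch of
    ``B_region`` whose top-left corner sits at
    ``(anchor[0] + offsets_axial[i], anchor[1] + offsets_lateral[j])``.
    Offsets must keep every patch inside ``B_region``.  A zero-variance
    ``A_window`` yields an all-NaN surface and a warning; zero-variance
    patches yield NaN at their offset.
    """
    A = np.asarray(A_window, dtype=float)
    B = np.asarray(B_region, dtype=float)
    offs_y = np.asarray(offsets_axial, dtype=int)
    offs_x = np.asarray(offsets_lateral, dtype=int)
    h, w = A.shape
    py = anchor[0] + offs_y
    px = anchor[1] + offs_x
    if py.min() < 0 or px.min() < 0 or py.max() > B.shape[0] - h or px.max() > B.shape[1] - w:
        raise ValidationError("requested offsets extend past B_region")
    Am = A - A.mean()
    As = np.sqrt(np.sum(Am * Am))
    if As == 0.0:
        warnings.warn("zero-variance calculation window: all-NaN correlation surface",
                      stacklevel=2)
        values = np.full((len(offs_y), len(offs_x)), np.nan)
        return CorrelationSurface(values, offs_y, offs_x)
    sliding = sliding_window_view(B, (h, w))
    P = sliding[py[:, None], px[None, :]]            # (n_dy, n_dx, h, w)
    Pm = P - P.mean(axis=(2, 3), keepdims=True)
    Ps = np.sqrt(np.sum(Pm * Pm, axis=(2, 3)))
    num = np.einsum("ijkl,kl->ij", Pm, Am)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = num / (As * Ps)
    values[Ps == 0.0] = np.nan
    return CorrelationSurface(values, offs_y, offs_x)


def default_neighborhood(radius: int = 2) -> np.ndarray:
    """Full (2r+1)^2 stencil minus the center — the enlarged neighbour set."""
    offs = [(dy, dx)
            for dy in range(-radius, radius + 1)
            for dx in range(-radius, radius + 1)
            if (dy, dx) != (0, 0)]
    return np.array(offs, dtype=int)


def following_track(surface_eval, init, bounds, neighborhood=None,
                    max_steps: int = 50) -> TrackResult:
    """Greedy hill climbing on a correlation surface.

    Parameters
    ----------
    surface_eval : callable
        Maps an ``(N, 2)`` int array of (dy, dx) offsets to ``(N,)``
        correlation values.  Called in batches; results are cached here.
    init : (dy, dx)
        Initial reference point; must lie inside ``bounds``.
    bounds : (dy_min, dy_max, dx_min, dx_max)
        Inclusive search-region bounds.
    neighborhood : (M, 2) int array, optional
        Offset stencil around the reference point (default full 5x5).

    The reference point moves to the best-correlated point among itself and
    its in-bounds neighbours until it stays put ("fixed position", status
    ``converged``; ``hit_boundary`` if it stalled on the region edge) or
    ``max_steps`` is exhausted.
    """
    if neighborhood is None:
        neighborhood = default_neighborhood(2)
    dy_min, dy_max, dx_min, dx_max = bounds
    current = (int(init[0]), int(init[1]))
    if not (dy_min <= current[0] <= dy_max and dx_min <= current[1] <= dx_max):
        raise ValidationError(f"init {current} outside bounds {bounds}")
    cache: dict[tuple[int, int], float] = {}

    def evaluate(points: list[tuple[int, int]]) -> np.ndarray:
        new = [p for p in points if p not in cache]
        if new:
            vals = surface_eval(np.array(new, dtype=int))
            for p, v in zip(new, vals):
                cache[p] = float(v)
        return np.array([cache[p] for p in points])

    steps = 0
    for _ in range(max_steps):
        cands = [current]
        for dy, dx in neighborhood:
            p = (current[0] + int(dy), current[1] + int(dx))
            if dy_min <= p[0] <= dy_max and dx_min <= p[1] <= dx_max:
                cands.append(p)
        vals = evaluate(cands)
        best = cands[_best_index(np.array(cands), vals)]
        if best == current:
            on_edge = (current[0] in (dy_min, dy_max) or current[1] in (dx_min, dx_max))
            status = "hit_boundary" if on_edge else "converged"
            return TrackResult(current, status, steps, cache[current])
        current = best
        steps += 1
    return TrackResult(current, "max_steps", steps, cache[current])


# ---------------------------------------------------------------------------
# Level searches
# ---------------------------------------------------------------------------

def _window_origin(center: int, size: int) -> int:
    return int(center) - size // 2


def _feasible_offsets(top: int, left: int, h: int, w: int, shape,
                      dy_range, dx_range):
    """Clip symmetric search ranges so every patch stays inside the frame."""
    dy_lo = max(dy_range[0], -top)
    dy_hi = min(dy_range[1], shape[0] - h - top)
    dx_lo = max(dx_range[0], -left)
    dx_hi = min(dx_range[1], shape[1] - w - left)
    return (dy_lo, dy_hi), (dx_lo, dx_hi)


def level1_search(pre_env: np.ndarray, post_env: np.ndarray, spec: SearchSpec,
                  valid_floor: float = 0.3, rate: int = 1) -> DisplacementGrid:
    """Exhaustive NCC search in nine evenly distributed windows (3x3 grid).

    Window centers sit at fractions {1/6, 1/2, 5/6} of the frame depth and
    width.  The axial search half-range of row ``r`` is enlarged by
    ``1 + depth_growth * r`` — displacement accumulates with depth.  Windows
    whose peak correlation falls below ``valid_floor`` are flagged invalid.
    """
    H, W = pre_env.shape
    h, w = spec.calc_h, spec.calc_w
    fracs = (1 / 6, 1 / 2, 5 / 6)
    rows = np.array([int(round(f * (H - 1))) for f in fracs])
    cols = np.array([int(round(f * (W - 1))) for f in fracs])
    max_sh = int(round(spec.search_h * (1 + spec.depth_growth * 2)))
    if rows[0] - h // 2 < 0 or rows[-1] + (h - h // 2) > H or \
       cols[0] - w // 2 < 0 or cols[-1] + (w - w // 2) > W or 2 * max_sh + h > H:
        raise ValidationError(
            f"frame {pre_env.shape} too small for the 3x3 level-1 layout: needs at "
            f"least {(3 * h, 3 * w)} plus search margin {max_sh}"
        )
    axial = np.zeros((3, 3))
    lateral = np.zeros((3, 3))
    peak = np.zeros((3, 3))
    for i, rc in enumerate(rows):
        sh = int(round(spec.search_h * (1 + spec.depth_growth * i)))
        for j, cc in enumerate(cols):
            top, left = _window_origin(rc, h), _window_origin(cc, w)
            A = pre_env[top:top + h, left:left + w]
            (dy_lo, dy_hi), (dx_lo, dx_hi) = _feasible_offsets(
                top, left, h, w, post_env.shape, (-sh, sh),
                (-spec.search_w, spec.search_w))
            surf = ncc(A, post_env, np.arange(dy_lo, dy_hi + 1),
                       np.arange(dx_lo, dx_hi + 1), anchor=(top, left))
            dy, dx, pk = surf.argmax()
            axial[i, j], lateral[i, j], peak[i, j] = dy, dx, pk
    valid = np.isfinite(peak) & (peak >= valid_floor)
    logger.info("level1_search: %d/9 valid, peak range [%.2f, %.2f]",
                valid.sum(), np.nanmin(peak), np.nanmax(peak))
    return DisplacementGrid(axial, lateral, rows, cols, valid, rate=rate,
                            peak_corr=peak)


class _PatchMatcher:
    """Batched NCC evaluation of one calculation window against a frame."""

    def __init__(self, pre_env: np.ndarray, post_env: np.ndarray, h: int, w: int):
        self.pre = pre_env
        self.post = post_env
        self.h, self.w = h, w
        self.sliding = sliding_window_view(post_env, (h, w))

    def evaluator(self, top: int, left: int):
        A = self.pre[top:top + self.h, left:left + self.w]
        Am = A - A.mean()
        As = np.sqrt(np.sum(Am * Am))

        def evaluate(offsets: np.ndarray) -> np.ndarray:
            if As == 0.0:
                return np.full(len(offsets), np.nan)
            py = top + offsets[:, 0]
            px = left + offsets[:, 1]
            P = self.sliding[py, px]
            Pm = P - P.mean(axis=(1, 2), keepdims=True)
            Ps = np.sqrt(np.sum(Pm * Pm, axis=(1, 2)))
            num = np.einsum("nkl,kl->n", Pm, Am)
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = num / (As * Ps)
            vals[Ps == 0.0] = np.nan
            return vals

        return evaluate


def _fill_invalid(axial, lateral, valid):
    """Replace invalid entries by the median of their valid 3x3 neighbours."""
    axial, lateral = axial.copy(), lateral.copy()
    if valid.all():
        return axial, lateral
    if not valid.any():
        return np.zeros_like(axial), np.zeros_like(lateral)
    todo = ~valid
    for _ in range(max(axial.shape)):
        filled = valid.copy()
        progressed = False
        for i, j in zip(*np.nonzero(todo)):
            sl = (slice(max(0, i - 1), i + 2), slice(max(0, j - 1), j + 2))
            m = valid[sl]
            if m.any():
                axial[i, j] = np.median(axial[sl][m])
                lateral[i, j] = np.median(lateral[sl][m])
                filled[i, j] = True
                progressed = True
        valid = filled
        todo = ~valid
        if not todo.any() or not progressed:
            break
    if todo.any():
        axial[todo] = np.median(axial[~todo])
        lateral[todo] = np.median(lateral[~todo])
    return axial, lateral


def reject_outliers(grid: DisplacementGrid, limit_axial: float,
                    limit_lateral: float) -> DisplacementGrid:
    """Displacement-continuity error correction on a coarse grid.

    Windows whose axial (lateral) estimate deviates from the 3x3 median of
    the grid by more than ``limit_axial`` (``limit_lateral``) are marked
    invalid and refilled from their valid neighbours — isolated false NCC
    peaks violate the spatial continuity of a quasi-static deformation.
    Limits are in the grid's own sample/line units.
    """
    med_a = median_filter(grid.axial, size=3, mode="nearest")
    med_l = median_filter(grid.lateral, size=3, mode="nearest")
    ok = grid.valid & (np.abs(grid.axial - med_a) <= limit_axial) \
        & (np.abs(grid.lateral - med_l) <= limit_lateral)
    axial, lateral = _fill_invalid(grid.axial, grid.lateral, ok)
    return DisplacementGrid(axial, lateral, grid.centers_axial,
                            grid.centers_lateral, ok, rate=grid.rate,
                            peak_corr=grid.peak_corr)


def _tracked_search(pre_env, post_env, centers_r, centers_c, init_axial,
                    init_lateral, spec: SearchSpec, valid_floor: float,
                    max_steps: int, neighborhood, rate: int) -> DisplacementGrid:
    """Shared level-2/3 engine: following tracking with per-column delivering."""
    h, w = spec.calc_h, spec.calc_w
    matcher = _PatchMatcher(pre_env, post_env, h, w)
    nr, nc = len(centers_r), len(centers_c)
    axial = np.zeros((nr, nc))
    lateral = np.zeros((nr, nc))
    peak = np.full((nr, nc), np.nan)
    ok = np.zeros((nr, nc), dtype=bool)
    for j in range(nc):
        delivered: tuple[int, int] | None = None
        for i in range(nr):
            top = _window_origin(centers_r[i], h)
            left = _window_origin(centers_c[j], w)
            c_dy = int(round(init_axial[i, j]))
            c_dx = int(round(init_lateral[i, j]))
            (dy_lo, dy_hi), (dx_lo, dx_hi) = _feasible_offsets(
                top, left, h, w, post_env.shape,
                (c_dy - spec.search_h, c_dy + spec.search_h),
                (c_dx - spec.search_w, c_dx + spec.search_w))
            if dy_lo > dy_hi or dx_lo > dx_hi:
                delivered = None
                continue
            start = delivered if delivered is not None else (c_dy, c_dx)
            start = (int(np.clip(start[0], dy_lo, dy_hi)),
                     int(np.clip(start[1], dx_lo, dx_hi)))
            res = following_track(matcher.evaluator(top, left), start,
                                  (dy_lo, dy_hi, dx_lo, dx_hi),
                                  neighborhood, max_steps)
            axial[i, j], lateral[i, j] = res.point
            peak[i, j] = res.value
            ok[i, j] = np.isfinite(res.value) and res.value >= valid_floor
            delivered = res.point if ok[i, j] else None
    axial, lateral = _fill_invalid(axial, lateral, ok)
    return DisplacementGrid(axial, lateral, np.asarray(centers_r),
                            np.asarray(centers_c), ok, rate=rate, peak_corr=peak)


def _even_centers(extent: int, n: int, margin: int) -> np.ndarray:
    lo, hi = margin, extent - 1 - margin
    if hi <= lo or n < 2:
        raise ValidationError(f"frame extent {extent} too small for {n} windows "
                              f"with margin {margin}")
    return np.unique(np.round(np.linspace(lo, hi, n)).astype(int))


def level2_search(pre_env, post_env, init_grid: DisplacementGrid,
                  spec: SearchSpec, rate: int, rows: int = 7, cols: int = 11,
                  valid_floor: float = 0.5, max_steps: int = 50,
                  neighborhood=None,
                  continuity_limit: tuple | None = None) -> DisplacementGrid:
    """Mid-scale search on a ``rows x cols`` grid (default 7 x 11).

    The level-1 grid is rescaled to this level's sample units, bilinearly
    interpolated onto the new window centers, and refined by following
    tracking; within each column the previous window's converged point seeds
    the next window's initial reference point (delivering strategy).
    """
    if init_grid.valid.sum() < 5:
        raise ValidationError(
            f"level-1 grid has only {int(init_grid.valid.sum())} valid windows (need >= 5)")
    scale = init_grid.rate / rate
    margin_ax = spec.calc_h // 2 + 1
    margin_lat = spec.calc_w // 2 + 1
    centers_r = _even_centers(pre_env.shape[0], rows, margin_ax)
    centers_c = _even_centers(pre_env.shape[1], cols, margin_lat)
    src_axial, src_lateral = _fill_invalid(init_grid.axial, init_grid.lateral,
                                           init_grid.valid)
    src = DisplacementGrid(src_axial, src_lateral, init_grid.centers_axial,
                           init_grid.centers_lateral,
                           np.ones_like(init_grid.valid), rate=init_grid.rate)
    init = interp_grid(src, centers_r, centers_c, scale_axial=scale)
    grid = _tracked_search(pre_env, post_env, centers_r, centers_c,
                           init.axial, init.lateral, spec, valid_floor,
                           max_steps, neighborhood, rate)
    if continuity_limit is not None:
        grid = reject_outliers(grid, *continuity_limit)
    return grid


def level3_search(pre_env, post_env, init_grid: DisplacementGrid,
                  spec: SearchSpec, rate: int, overlap: float = 0.5,
                  valid_floor: float = 0.5, max_steps: int = 50,
                  neighborhood=None,
                  continuity_limit: tuple | None = None) -> DisplacementGrid:
    """Finest coarse-scale search whose windows tile the whole frame.

    Window centers step by ``calc_size * (1 - overlap)`` in both directions;
    tracking and delivering work exactly as at level 2.  When
    ``continuity_limit`` (axial samples, lateral lines) is given, the grid is
    post-filtered by :func:`reject_outliers`.
    """
    scale = init_grid.rate / rate
    step_r = max(1, int(round(spec.calc_h * (1.0 - overlap))))
    step_c = max(1, int(round(spec.calc_w * (1.0 - overlap))))
    margin_ax = spec.calc_h // 2 + 1
    margin_lat = spec.calc_w // 2 + 1
    centers_r = np.arange(margin_ax, pre_env.shape[0] - margin_ax, step_r)
    centers_c = np.arange(margin_lat, pre_env.shape[1] - margin_lat, step_c)
    if len(centers_r) < 2 or len(centers_c) < 2:
        raise ValidationError("frame too small for level-3 tiling")
    src_axial, src_lateral = _fill_invalid(init_grid.axial, init_grid.lateral,
                                           init_grid.valid)
    src = DisplacementGrid(src_axial, src_lateral, init_grid.centers_axial,
                           init_grid.centers_lateral,
                           np.ones_like(init_grid.valid), rate=init_grid.rate)
    init = interp_grid(src, centers_r, centers_c, scale_axial=scale)
    grid = _tracked_search(pre_env, post_env, centers_r, centers_c,
                           init.axial, init.lateral, spec, valid_floor,
                           max_steps, neighborhood, rate)
    if continuity_limit is not None:
        grid = reject_outliers(grid, *continuity_limit)
    logger.info("level3_search: grid %s, %.1f%% valid", grid.shape,
                100.0 * grid.valid.mean())
    return grid


def finalize_lateral(grid: DisplacementGrid, sg_window: int = 9,
                     sg_order: int = 2,
                     significance_threshold: float = 0.25) -> np.ndarray:
    """Smooth and threshold the lateral displacement of the level-3 grid.

    Each row is Savitzky-Golay filtered along the lateral direction; entries
    whose smoothed magnitude stays below ``significance_threshold`` (lines)
    are zeroed, so only the significant region is shifted laterally during
    fine estimation.
    """
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ValidationError("sg_window must be odd and greater than sg_order")
    if grid.lateral.shape[1] < sg_window:
        raise ValidationError(
            f"grid has {grid.lateral.shape[1]} columns, fewer than sg_window={sg_window}")
    smooth = savgol_filter(grid.lateral, sg_window, sg_order, axis=1, mode="interp")
    smooth[np.abs(smooth) < significance_threshold] = 0.0
    return smooth


def interp_grid(grid: DisplacementGrid, target_centers_axial,
                target_centers_lateral, scale_axial: float = 1.0,
                scale_lateral: float = 1.0) -> DisplacementGrid:
    """Rescale a displacement grid between pyramid units and bilinearly
    interpolate it onto new window centers.

    ``scale_axial`` converts axial sample units (source rate / target rate)
    and is applied to both the axial displacements and the axial center
    coordinates; likewise ``scale_lateral`` for the lateral component.
    Targets outside the source hull are linearly extrapolated from the edge
    cells (displacement keeps growing toward the frame edges, so clamping
    would bias the margins).
    """
    if grid.axial.size == 0:
        raise ValidationError("cannot interpolate an empty grid")
    rows = grid.centers_axial * scale_axial
    cols = grid.centers_lateral * scale_lateral
    tr = np.asarray(target_centers_axial, dtype=float)
    tc = np.asarray(target_centers_lateral, dtype=float)
    mesh = np.meshgrid(tr, tc, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    out = {}
    for name, values, scale in (("axial", grid.axial, scale_axial),
                                ("lateral", grid.lateral, scale_lateral)):
        if len(rows) == 1 or len(cols) == 1:  # degenerate axis: nearest
            out[name] = np.full((len(tr), len(tc)), float(values.flat[0]) * scale)
            continue
        f = RegularGridInterpolator((rows, cols), values * scale, method="linear",
                                    bounds_error=False, fill_value=None)
        out[name] = f(pts).reshape(len(tr), len(tc))
    shape = out["axial"].shape
    return DisplacementGrid(out["axial"], out["lateral"],
                            np.asarray(target_centers_axial, dtype=float),
                            np.asarray(target_centers_lateral, dtype=float),
                            np.ones(shape, dtype=bool), rate=1)
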