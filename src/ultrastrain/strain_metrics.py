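"""Strain reconstruction and elastographic image-quality metrics.

Strain is the local gradient of the axial displacement field.  The
least-squares strain estimator (LSQSE) fits ``u_i = a z_i + b`` over a
centered kernel of displacement samples and reports the slope ``a`` at each
position — a piecewise linear fit that trades axial resolution for noise
suppression.  The package reports compression as *positive* strain.

Image quality is quantified by the elastographic contrast-to-noise ratio

    CNRe = 2 (s1 - s2)^2 / (sigma1^2 + sigma2^2)

over an inclusion ROI (s1) and a background ROI (s2), by the
background/inclusion mean strain ratio, and by the inclusion area ratio of
the mean-thresholded binary strain image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .rf_frames import DisplacementField, StrainMap, ValidationError

__all__ = ["ROISpec", "lsqse_line", "strain_map", "roi_mask", "cnre",
           "strain_ratio", "binarize", "inclusion_area_ratio", "write_pgm"]


@dataclass
class ROISpec:
    """A circular or rectangular region of interest in physical units.

    ``center`` is (depth, lateral) in metres.  For circles give ``radius``;
    for rectangles give ``half_extents`` (depth, lateral), both in metres.
    """

    shape: str                      # "circle" | "rectangle"
    center: tuple[float, float]
    radius: float = 0.0
    half_extents: tuple[float, float] = (0.0, 0.0)
    role: str = "inclusion"         # "inclusion" | "background"

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "rectangle"):
            raise ValidationError("ROI shape must be 'circle' or 'rectangle'")
        if self.shape == "circle" and self.radius <= 0:
            raise ValidationError("circular ROI needs a positive radius")


def lsqse_line(u: np.ndarray, z: np.ndarray, kernel: int) -> np.ndarray:
    """Least-squares slope of displacement against depth over a moving kernel.

    At each interior position the strain is the slope ``a`` of the
    least-squares line ``u = a z + b`` fitted over the centered window of
    ``kernel`` points.  The returned vector is shorter than ``u`` by
    ``kernel - 1`` (the fit-kernel margin).  Exact for linear ``u(z)``.
    """
    u = np.asarray(u, dtype=float)
    z = np.asarray(z, dtype=float)
    if kernel % 2 == 0:
        raise ValidationError("kernel must be odd")
    if kernel < 3:
        raise ValidationError("kernel must be >= 3")
    if kernel > len(u):
        raise ValidationError(f"kernel {kernel} exceeds line length {len(u)}")
    if u.shape != z.shape:
        raise ValidationError("u and z must have the same length")
    uw = sliding_window_view(u, kernel)
    zw = sliding_window_view(z, kernel)
    zm = zw - zw.mean(axis=-1, keepdims=True)
    um = uw - uw.mean(axis=-1, keepdims=True)
    denom = np.sum(zm * zm, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sum(zm * um, axis=-1) / denom


def strain_map(field: DisplacementField, kernel: int, fs: float, c: float,
               line_spacing: float, depth_offset: float = 0.0) -> StrainMap:
    """Axial strain map from a displacement field via per-line LSQSE.

    Displacement and depth are both in finest-scale samples, so the slope is
    dimensionless.  The sign is flipped once here so that compression
    (displacement decreasing with depth) reads positive.
    """
    half = kernel // 2
    z = field.centers_axial
    slopes = np.empty((field.shape[0] - 2 * half, field.shape[1]))
    for j in range(field.shape[1]):
        slopes[:, j] = lsqse_line(field.axial[:, j], z, kernel)
    return StrainMap(-slopes, z[half:len(z) - half], field.centers_lateral,
                     fs=fs, c=c, line_spacing=line_spacing,
                     depth_offset=depth_offset)


def roi_mask(smap: StrainMap, roi: ROISpec) -> np.ndarray:
    """Boolean pixel mask of an ROI on a strain map's center grid."""
    zz, xx = np.meshgrid(smap.depths, smap.laterals, indexing="ij")
    cz, cx = roi.center
    if roi.shape == "circle":
        lo_z, hi_z = cz - roi.radius, cz + roi.radius
        lo_x, hi_x = cx - roi.radius, cx + roi.radius
        mask = (zz - cz) ** 2 + (xx - cx) ** 2 <= roi.radius ** 2
    else:
        hz, hx = roi.half_extents
        lo_z, hi_z, lo_x, hi_x = cz - hz, cz + hz, cx - hx, cx + hx
        mask = (np.abs(zz - cz) <= hz) & (np.abs(xx - cx) <= hx)
    if (lo_z < smap.depths.min() or hi_z > smap.depths.max()
            or lo_x < smap.laterals.min() or hi_x > smap.laterals.max()):
        raise ValidationError("ROI extends outside the strain map extent")
    return mask


def _roi_stats(smap: StrainMap, roi: ROISpec, min_pixels: int = 25):
    vals = smap.strain[roi_mask(smap, roi)]
    if vals.size < min_pixels:
        raise ValidationError(
            f"ROI contains only {vals.size} strain pixels (need >= {min_pixels})")
    return float(vals.mean()), float(vals.var())


def cnre(smap: StrainMap, roi_inc: ROISpec, roi_bg: ROISpec) -> float:
    """Elastographic contrast-to-noise ratio between two ROIs.

    ``2 (s1 - s2)^2 / (sigma1^2 + sigma2^2)`` with means and variances taken
    over the ROI pixels; larger is better.  Invariant under any affine
    rescaling of the strain map.  Zero total variance returns ``inf`` with a
    warning.
    """
    s1, v1 = _roi_stats(smap, roi_inc)
    s2, v2 = _roi_stats(smap, roi_bg)
    if v1 + v2 == 0.0:
        warnings.warn("zero strain variance in both ROIs: CNRe is infinite",
                      stacklevel=2)
        return float("inf") if s1 != s2 else 0.0
    return 2.0 * (s1 - s2) ** 2 / (v1 + v2)


def strain_ratio(smap: StrainMap, roi_inc: ROISpec, roi_bg: ROISpec) -> float:
    """Mean background strain divided by mean inclusion strain.

    Oriented so a phantom built with strain contrast 5 reads as ~5 (the
    stiff inclusion strains less than the background).  A near-zero
    inclusion mean returns ``inf``.
    """
    s1, _ = _roi_stats(smap, roi_inc)
    s2, _ = _roi_stats(smap, roi_bg)
    if abs(s1) < 1e-12 * max(abs(s2), 1e-30):
        return float("inf")
    return s2 / s1


def binarize(smap: StrainMap) -> np.ndarray:
    """Binary strain image thresholded at the whole-map mean strain.

    True ("black") marks pixels strictly below the mean — the low-strain
    stiff inclusion shows up black on a white background.
    """
    if not np.all(np.isfinite(smap.strain)):
        raise ValidationError("strain map contains non-finite values")
    return smap.strain < smap.strain.mean()


def inclusion_area_ratio(binary: np.ndarray) -> float:
    """Fraction of black pixels in a binary strain image."""
    binary = np.asarray(binary, dtype=bool)
    if binary.size == 0:
        raise ValidationError("empty binary image")
    return float(binary.sum()) / binary.size


def write_pgm(path, image: np.ndarray) -> None:
    """Export an image as a plain-text PGM (P2), scaled to 0..255."""
    img = np.asarray(image, dtype=float)
    lo, hi = np.nanmin(img), np.nanmax(img)
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    pix = np.round(scaled * 255).astype(int)
    lines = [f"P2\n{img.shape[1]} {img.shape[0]}\n255"]
    lines += [" ".join(map(str, row)) for row in pix]
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")
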