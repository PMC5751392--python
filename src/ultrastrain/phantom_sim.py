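"""Simulated inclusion phantom: plane-strain FEM truth and convolution RF model.

The study phantom is a 20 x 20 mm tissue block containing a 3 mm-radius
stiff circular inclusion (Young's modulus 100 kPa, Poisson ratio 0.495,
density 1000 kg/m^3), compressed uniaxially from the top by 0.3-0.8 mm with
the bottom edge fixed.  Ground-truth displacement and strain fields come
from a 2-D plane-strain linear-elasticity FEM on a regular bilinear
quadrilateral mesh; the near-incompressible material is handled by selective
reduced integration of the volumetric (lambda) term, which would otherwise
lock the mesh at nu = 0.495.

RF frames are synthesised with a separable convolution model: each randomly
placed scatterer contributes a Gaussian-enveloped carrier pulse along the
axial direction weighted by a Gaussian lateral beam profile, plus additive
white noise.  Post-compression frames reuse the same scatterer realization
at FEM-displaced positions, so the speckle pattern moves exactly as the
elastic solution dictates.

Axes: depth ``z`` grows downward from the transducer face (z = 0 at the
top, compressed edge); positive axial displacement is motion toward greater
depth.  Displacements are reported in the transducer frame — the transducer
rides on the compressed top surface, so axial displacement is zero at z = 0
and approaches ``-compression`` (motion toward the transducer) at the fixed
bottom.  Strain is reported compression-positive.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import spsolve

from .rf_frames import RFFrame, ValidationError

logger = logging.getLogger("ultrastrain")

__all__ = ["PhantomSpec", "TransducerSpec", "GroundTruth", "Scatterers",
           "solve_fem", "calibrate_contrast", "make_scatterers",
           "displace_scatterers", "simulate_rf", "make_pair"]


@dataclass
class PhantomSpec:
    """Geometry, materials and loading of the simulated phantom (SI units)."""

    width: float = 0.020
    height: float = 0.020
    inclusion_center: tuple[float, float] = (0.010, 0.010)   # (depth, lateral)
    inclusion_radius: float = 0.003
    e_inclusion: float = 1.0e5
    e_background: float = 2.0e4
    poisson: float = 0.495
    density: float = 1000.0
    compression: float = 0.6e-3        # applied top displacement, m
    mesh_n: int = 80                   # elements per side

    def __post_init__(self) -> None:
        cz, cx = self.inclusion_center
        r = self.inclusion_radius
        if r > 0 and not (r <= cz <= self.height - r and r <= cx <= self.width - r):
            raise ValidationError("inclusion must lie fully inside the block")
        if not (0.0 < self.poisson < 0.5):
            raise ValidationError("poisson must lie in (0, 0.5)")
        if not (0.0 <= self.compression < 0.1 * self.height):
            raise ValidationError("compression must be below 10% of the height")
        if self.e_inclusion <= 0 or self.e_background <= 0:
            raise ValidationError("Young's moduli must be positive")
        if self.mesh_n < 8:
            raise ValidationError("mesh_n must be >= 8")


@dataclass
class TransducerSpec:
    """Linear-array acquisition parameters for the convolution RF model."""

    f0: float = 7.5e6
    fs: float = 120e6
    n_lines: int = 128
    line_spacing: float = 0.020 / 128
    c: float = 1540.0
    pulse_bw: float = 0.6              # fractional -6 dB bandwidth
    beam_sigma: float = 0.4e-3         # lateral Gaussian beam sigma, m
    scatterer_density: float = 20.0    # per mm^2
    noise_snr: float = 30.0            # dB

    def __post_init__(self) -> None:
        if not (self.fs > 2.0 * self.f0):
            raise ValidationError("fs must exceed 2*f0")
        for name in ("n_lines", "line_spacing", "c", "pulse_bw", "beam_sigma",
                     "scatterer_density"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def line_positions(self) -> np.ndarray:
        """Lateral position (m) of each scan line, centered in its pitch."""
        return (np.arange(self.n_lines) + 0.5) * self.line_spacing


@dataclass
class Scatterers:
    """Random point scatterers: positions (m) and scattering amplitudes."""

    z: np.ndarray
    x: np.ndarray
    amp: np.ndarray


@dataclass
class GroundTruth:
    """FEM displacement and strain fields with point evaluators.

    Nodal displacements (m, transducer frame: zero at the imaged top
    surface) live on the ``(z_nodes, x_nodes)`` grid, the element-center
    axial strain (compression-positive, dimensionless) on ``(z_el, x_el)``.
    Evaluators clip query points to the grid hull.
    """

    z_nodes: np.ndarray
    x_nodes: np.ndarray
    axial_disp: np.ndarray       # positive toward greater depth
    lateral_disp: np.ndarray
    z_el: np.ndarray
    x_el: np.ndarray
    strain_axial: np.ndarray     # compression-positive
    _interp: dict = field(default_factory=dict, repr=False)

    def _f(self, name: str) -> RegularGridInterpolator:
        if name not in self._interp:
            grids = {"axial": (self.z_nodes, self.x_nodes, self.axial_disp),
                     "lateral": (self.z_nodes, self.x_nodes, self.lateral_disp),
                     "strain": (self.z_el, self.x_el, self.strain_axial)}
            zg, xg, vals = grids[name]
            self._interp[name] = RegularGridInterpolator((zg, xg), vals,
                                                         method="linear")
        return self._interp[name]

    def _eval(self, name: str, z, x) -> np.ndarray:
        zc = np.clip(np.asarray(z, dtype=float),
                     self._f(name).grid[0][0], self._f(name).grid[0][-1])
        xc = np.clip(np.asarray(x, dtype=float),
                     self._f(name).grid[1][0], self._f(name).grid[1][-1])
        zc, xc = np.broadcast_arrays(zc, xc)
        pts = np.stack([zc, xc], axis=-1)
        out = self._f(name)(pts.reshape(-1, 2)).reshape(zc.shape)
        return float(out) if out.ndim == 0 else out

    def axial_at(self, z, x) -> np.ndarray:
        return self._eval("axial", z, x)

    def lateral_at(self, z, x) -> np.ndarray:
        return self._eval("lateral", z, x)

    def strain_at(self, z, x) -> np.ndarray:
        return self._eval("strain", z, x)

    def to_arrays(self) -> dict:
        return {"z_nodes": self.z_nodes, "x_nodes": self.x_nodes,
                "axial": self.axial_disp, "lateral": self.lateral_disp,
                "z_el": self.z_el, "x_el": self.x_el,
                "strain": self.strain_axial}

    @classmethod
    def from_arrays(cls, arrays: dict) -> "GroundTruth":
        return cls(arrays["z_nodes"], arrays["x_nodes"], arrays["axial"],
                   arrays["lateral"], arrays["z_el"], arrays["x_el"],
                   arrays["strain"])


# ---------------------------------------------------------------------------
# Plane-strain FEM
# ---------------------------------------------------------------------------

_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)


def _b_matrix(xi: float, eta: float, hx: float, hy: float) -> np.ndarray:
    """Strain-displacement matrix of the bilinear quad at (xi, eta)."""
    dN_dxi = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
    dN_deta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
    dN_dx = dN_dxi * 2.0 / hx
    dN_dy = dN_deta * 2.0 / hy
    B = np.zeros((3, 8))
    B[0, 0::2] = dN_dx          # eps_xx
    B[1, 1::2] = dN_dy          # eps_yy (axial)
    B[2, 0::2] = dN_dy          # gamma_xy
    B[2, 1::2] = dN_dx
    return B


def _element_stiffness(hx: float, hy: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit-coefficient element stiffness split into shear (mu) and
    volumetric (lambda) parts; the lambda part is integrated at the element
    center only (selective reduced integration)."""
    detJ = hx * hy / 4.0
    D_mu = np.diag([2.0, 2.0, 1.0])                       # x mu
    D_lam = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
    K_mu = np.zeros((8, 8))
    for xi in _GP:
        for eta in _GP:
            B = _b_matrix(xi, eta, hx, hy)
            K_mu += B.T @ D_mu @ B * detJ
    B0 = _b_matrix(0.0, 0.0, hx, hy)
    K_lam = B0.T @ D_lam @ B0 * detJ * 4.0
    return K_mu, K_lam


def solve_fem(spec: PhantomSpec) -> GroundTruth:
    """Solve plane-strain elasticity for the compressed inclusion phantom.

    Boundary conditions: bottom edge axially fixed on frictionless rollers
    (one node pinned laterally); top edge driven downward by
    ``spec.compression`` with free lateral slip; side edges traction free.
    For a homogeneous block this reproduces the uniform uniaxial plane-strain
    field exactly.  Returns nodal displacements and element-center axial
    strain.
    """
    t0 = time.perf_counter()
    n = spec.mesh_n
    hx, hy = spec.width / n, spec.height / n
    nn = n + 1
    node_id = np.arange(nn * nn).reshape(nn, nn)       # [iy, ix]

    ex, ey = np.meshgrid(np.arange(n), np.arange(n), indexing="xy")
    ey, ex = ey.ravel(), ex.ravel()
    conn = np.stack([node_id[ey, ex], node_id[ey, ex + 1],
                     node_id[ey + 1, ex + 1], node_id[ey + 1, ex]], axis=1)
    dofs = np.empty((len(conn), 8), dtype=int)
    dofs[:, 0::2] = 2 * conn
    dofs[:, 1::2] = 2 * conn + 1

    xc = (ex + 0.5) * hx
    zc = (ey + 0.5) * hy
    cz, cx = spec.inclusion_center
    inside = (zc - cz) ** 2 + (xc - cx) ** 2 <= spec.inclusion_radius ** 2

    def lame(E):
        lam = E * spec.poisson / ((1 + spec.poisson) * (1 - 2 * spec.poisson))
        mu = E / (2 * (1 + spec.poisson))
        return lam, mu

    K_mu, K_lam = _element_stiffness(hx, hy)
    lam_i, mu_i = lame(spec.e_inclusion)
    lam_b, mu_b = lame(spec.e_background)
    Ke_inc = mu_i * K_mu + lam_i * K_lam
    Ke_bg = mu_b * K_mu + lam_b * K_lam
    data = np.where(inside[:, None, None], Ke_inc[None], Ke_bg[None])

    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    ndof = 2 * nn * nn
    K = sparse.coo_matrix((data.ravel(), (rows, cols)),
                          shape=(ndof, ndof)).tocsr()

    # Dirichlet constraints: bottom axially fixed with free lateral slip
    # (a frictionless support; full lateral fixity would destroy the uniform
    # closed-form field near incompressibility), one bottom-center node
    # pinned laterally against rigid-body translation; top edge driven
    # downward with free slip; sides traction-free.
    u = np.zeros(ndof)
    known = np.zeros(ndof, dtype=bool)
    bottom = node_id[n, :]
    known[2 * bottom + 1] = True
    known[2 * node_id[n, n // 2]] = True
    top = node_id[0, :]
    known[2 * top + 1] = True
    u[2 * top + 1] = spec.compression          # downward = positive axial
    if spec.compression > 0 and not known.any():
        raise ValidationError("system has no constrained dofs")

    free = ~known
    if spec.compression == 0.0:
        u[:] = 0.0
    else:
        rhs = -K[free][:, known] @ u[known]
        u[free] = spsolve(K[free][:, free].tocsc(), rhs)

    ux = u[0::2].reshape(nn, nn)
    # report axial displacement in the transducer frame: the transducer sits
    # on the moving top surface, so echoes from the top face keep zero delay
    # and |displacement| accumulates with depth (deepest scatterers move the
    # full compression toward the transducer)
    uy = u[1::2].reshape(nn, nn) - spec.compression

    # element-center axial strain from the reduced-integration B matrix
    B0 = _b_matrix(0.0, 0.0, hx, hy)
    ue = u[dofs]                                # (n_el, 8)
    eps = ue @ B0.T                             # (n_el, 3)
    strain_axial = (-eps[:, 1]).reshape(n, n)   # compression-positive

    z_nodes = np.arange(nn) * hy
    x_nodes = np.arange(nn) * hx
    z_el = (np.arange(n) + 0.5) * hy
    x_el = (np.arange(n) + 0.5) * hx
    logger.info("solve_fem: mesh %dx%d, compression %.3g mm, %.3fs",
                n, n, spec.compression * 1e3, time.perf_counter() - t0)
    return GroundTruth(z_nodes, x_nodes, uy, ux, z_el, x_el, strain_axial)


def _region_ratio(truth: GroundTruth, spec: PhantomSpec,
                  roi_radius: float = 1.5e-3, bg_offset: float = 6.5e-3) -> float:
    """Background/inclusion mean strain ratio over the default metric ROIs."""
    cz, cx = spec.inclusion_center
    zz, xx = np.meshgrid(truth.z_el, truth.x_el, indexing="ij")
    inc = (zz - cz) ** 2 + (xx - cx) ** 2 <= roi_radius ** 2
    bg = (zz - cz) ** 2 + (xx - (cx + bg_offset)) ** 2 <= roi_radius ** 2
    return float(truth.strain_axial[bg].mean() / truth.strain_axial[inc].mean())


def calibrate_contrast(spec: PhantomSpec, target_ratio: float,
                       tol: float = 0.02) -> float:
    """Background Young's modulus achieving a given strain contrast.

    Runs a bracketed 1-D search over ``e_background`` (inclusion modulus
    fixed) until the FEM background/inclusion mean strain ratio — measured
    over the same circular ROIs the metrics use — is within ``tol`` of
    ``target_ratio``.  Softer backgrounds strain more, so the ratio grows as
    ``e_background`` shrinks.
    """
    import dataclasses as _dc
    from scipy.optimize import brentq

    if target_ratio < 1.0:
        raise ValidationError("target_ratio must be >= 1")
    if abs(target_ratio - 1.0) < 1e-12:
        return spec.e_inclusion
    compression = spec.compression if spec.compression > 0 else 0.5e-3

    def ratio_of(e_bg: float) -> float:
        s = _dc.replace(spec, e_background=e_bg, compression=compression)
        return _region_ratio(solve_fem(s), s)

    lo = spec.e_inclusion / (8.0 * target_ratio)
    hi = spec.e_inclusion
    f_lo = ratio_of(lo) - target_ratio
    f_hi = ratio_of(hi) - target_ratio
    if f_lo * f_hi > 0:
        raise ValidationError(
            f"search range [{lo:g}, {hi:g}] Pa does not bracket ratio {target_ratio}")
    e_bg = brentq(lambda e: ratio_of(e) - target_ratio, lo, hi, rtol=1e-4)
    achieved = ratio_of(e_bg)
    if abs(achieved - target_ratio) > tol * target_ratio:
        raise ValidationError(
            f"calibration stalled at ratio {achieved:.3f} (target {target_ratio})")
    logger.info("calibrate_contrast: E_background=%.4g Pa gives ratio %.3f",
                e_bg, achieved)
    return float(e_bg)


# ---------------------------------------------------------------------------
# Scatterers and RF synthesis
# ---------------------------------------------------------------------------

def make_scatterers(spec: PhantomSpec, tspec: TransducerSpec,
                    seed: int) -> Scatterers:
    """Uniform random scatterers with standard-normal amplitudes.

    The count is Poisson with mean ``density x area``; everything is
    reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    area_mm2 = spec.width * spec.height * 1e6
    n = int(rng.poisson(tspec.scatterer_density * area_mm2))
    z = rng.uniform(0.0, spec.height, n)
    x = rng.uniform(0.0, spec.width, n)
    amp = rng.standard_normal(n)
    return Scatterers(z=z, x=x, amp=amp)


def displace_scatterers(scatterers: Scatterers, truth: GroundTruth,
                        spec: PhantomSpec | None = None) -> Scatterers:
    """Move each scatterer by the interpolated FEM displacement.

    Amplitudes are unchanged.  Scatterers outside the FEM domain are clipped
    to the boundary with a warning before evaluation.
    """
    z, x = scatterers.z, scatterers.x
    z_lo, z_hi = truth.z_nodes[0], truth.z_nodes[-1]
    x_lo, x_hi = truth.x_nodes[0], truth.x_nodes[-1]
    outside = (z < z_lo) | (z > z_hi) | (x < x_lo) | (x > x_hi)
    if outside.any():
        warnings.warn(f"{int(outside.sum())} scatterer(s) outside the FEM domain "
                      "were clipped to the boundary", stacklevel=2)
        z = np.clip(z, z_lo, z_hi)
        x = np.clip(x, x_lo, x_hi)
    return Scatterers(z=z + truth.axial_at(z, x),
                      x=x + truth.lateral_at(z, x),
                      amp=scatterers.amp.copy())


def _pulse_sigma_t(tspec: TransducerSpec) -> float:
    sigma_f = tspec.pulse_bw * tspec.f0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return 1.0 / (2.0 * np.pi * sigma_f)


def simulate_rf(scatterers: Scatterers, tspec: TransducerSpec, seed: int,
                depth: float = 0.020) -> RFFrame:
    """Synthesise one RF frame from a scatterer field.

    Per line at lateral position ``x_l`` every scatterer contributes
    ``amp * exp(-(x - x_l)^2 / (2 beam_sigma^2))`` times a Gaussian-enveloped
    pulse ``cos(2 pi f0 (t - 2 z / c))`` sampled at ``fs``, plus white
    Gaussian noise at ``noise_snr`` dB relative to the clean signal RMS.
    """
    t0 = time.perf_counter()
    n_samples = int(np.ceil(2.0 * depth / tspec.c * tspec.fs)) + 1
    sigma_t = _pulse_sigma_t(tspec)
    half = int(np.ceil(4.0 * sigma_t * tspec.fs))
    offsets = np.arange(-half, half + 1)
    rf = np.zeros((n_samples, tspec.n_lines))
    cut = 3.5 * tspec.beam_sigma
    for l, xl in enumerate(tspec.line_positions()):
        sel = np.abs(scatterers.x - xl) < cut
        if not sel.any():
            continue
        zs = scatterers.z[sel]
        w = scatterers.amp[sel] * np.exp(
            -((scatterers.x[sel] - xl) ** 2) / (2.0 * tspec.beam_sigma ** 2))
        ts = 2.0 * zs / tspec.c
        center = np.rint(ts * tspec.fs).astype(int)
        idx = center[:, None] + offsets[None, :]
        t_rel = idx / tspec.fs - ts[:, None]
        contrib = w[:, None] * np.exp(-t_rel ** 2 / (2.0 * sigma_t ** 2)) \
            * np.cos(2.0 * np.pi * tspec.f0 * t_rel)
        ok = (idx >= 0) & (idx < n_samples)
        np.add.at(rf[:, l], idx[ok], contrib[ok])
    rms = np.sqrt(np.mean(rf ** 2))
    if tspec.noise_snr < 200 and rms > 0:
        rng = np.random.default_rng(seed)
        rf += rng.normal(0.0, rms * 10.0 ** (-tspec.noise_snr / 20.0), rf.shape)
    logger.info("simulate_rf: %d scatterers -> frame %s, %.3fs",
                len(scatterers.z), rf.shape, time.perf_counter() - t0)
    return RFFrame(samples=rf, fs=tspec.fs, f0=tspec.f0, c=tspec.c,
                   line_spacing=tspec.line_spacing, depth_offset=0.0)


def make_pair(spec: PhantomSpec, tspec: TransducerSpec, seed: int,
              truth: GroundTruth | None = None):
    """Matched pre/post-compression frames from one scatterer realization.

    The FEM solution may be passed in to avoid re-solving when sweeping
    seeds at a fixed compression.  Returns ``(pre, post, truth)``.
    """
    if tspec.n_lines * tspec.line_spacing > spec.width * (1 + 1e-9):
        raise ValidationError("scan lines extend beyond the phantom width")
    if truth is None:
        truth = solve_fem(spec)
    s_seed, n1, n2 = (int(s) for s in
                      np.random.SeedSequence(seed).generate_state(3) % (2 ** 31))
    scat = make_scatterers(spec, tspec, s_seed)
    pre = simulate_rf(scat, tspec, n1, depth=spec.height)
    moved = displace_scatterers(scat, truth, spec)
    post = simulate_rf(moved, tspec, n2, depth=spec.height)
    return pre, post, truth
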