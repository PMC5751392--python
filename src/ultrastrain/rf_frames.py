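"""Containers, file I/O and run configuration for RF elastography data.

Conventions used throughout the package:

* The axial (depth) axis is the first array axis; row index increases with
  depth.  The lateral axis is the second axis; line index increases left to
  right.
* Axial displacements are stored in *samples at the grid's own scale*
  (finest-scale samples unless a downsample rate is attached), lateral
  displacements in *scan lines*.  Positive axial displacement means motion
  toward greater depth.  Conversion to millimetres happens only at reporting
  time, using ``c / (2 fs)`` axially and ``line_spacing`` laterally.
* Sample index ``i`` maps to depth ``z = depth_offset + i * c / (2 fs)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

logger = logging.getLogger("ultrastrain")

__all__ = [
    "FormatError",
    "ValidationError",
    "ConfigError",
    "RFFrame",
    "AnalyticFrame",
    "PyramidLevel",
    "BasebandPyramid",
    "DisplacementGrid",
    "DisplacementField",
    "StrainMap",
    "RunConfig",
    "read_frame",
    "write_frame",
    "write_pair",
    "read_pair",
    "load_config",
]


class ValidationError(ValueError):
    """An in-memory object violates one of its invariants."""


class FormatError(ValueError):
    """A file does not conform to the on-disk container format."""


class ConfigError(ValueError):
    """A run-configuration key is unknown or out of range."""


_FRAME_ATTRS = ("fs", "f0", "c", "line_spacing", "depth_offset")


@dataclass
class RFFrame:
    """One frame of raw RF echo data plus acquisition metadata.

    Parameters
    ----------
    samples : (n_samples, n_lines) float array
        Real-valued RF data, axial sample index by scan-line index, in
        arbitrary linear amplitude units.
    fs : float
        Sampling frequency of the RF data, Hz.
    f0 : float
        Nominal transducer center frequency, Hz.
    c : float
        Assumed speed of sound, m/s.
    line_spacing : float
        Lateral distance between adjacent scan lines, m.
    depth_offset : float
        Depth of the first axial sample, m.
    """

    samples: np.ndarray
    fs: float
    f0: float
    c: float
    line_spacing: float
    depth_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D array (axial x lateral)")
        if self.samples.shape[1] < 2:
            raise ValidationError("frame needs at least 2 scan lines")
        if self.samples.shape[0] < 64:
            raise ValidationError("frame needs at least 64 axial samples")
        if not (self.fs > 2.0 * self.f0):
            raise ValidationError(
                f"fs={self.fs:g} must exceed twice the center frequency f0={self.f0:g}"
            )
        for name in ("fs", "f0", "c", "line_spacing"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.depth_offset < 0:
            raise ValidationError("depth_offset must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    @property
    def sample_pitch(self) -> float:
        """Axial depth increment per sample, m."""
        return self.c / (2.0 * self.fs)

    @property
    def period_samples(self) -> float:
        """Carrier period expressed in axial samples (fs / f0)."""
        return self.fs / self.f0

    def depth_of(self, index) -> np.ndarray:
        """Depth (m) of axial sample ``index``; strictly increasing."""
        return self.depth_offset + np.asarray(index, dtype=float) * self.sample_pitch

    def meta(self) -> dict:
        return {k: float(getattr(self, k)) for k in _FRAME_ATTRS}

    def __eq__(self, other) -> bool:  # payload + metadata equality
        if not isinstance(other, RFFrame):
            return NotImplemented
        return self.meta() == other.meta() and np.array_equal(self.samples, other.samples)


@dataclass
class AnalyticFrame:
    """Complex analytic signal of an RF frame (real part = RF samples)."""

    values: np.ndarray
    fs: float
    f0: float
    c: float
    line_spacing: float
    depth_offset: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_lines(self) -> int:
        return self.values.shape[1]

    @classmethod
    def like(cls, frame: RFFrame, values: np.ndarray) -> "AnalyticFrame":
        return cls(values=values, **frame.meta())


@dataclass
class PyramidLevel:
    rate: int
    baseband: np.ndarray
    envelope: np.ndarray


@dataclass
class BasebandPyramid:
    """Complex baseband frames at decreasing downsample rates.

    ``levels`` is ordered coarsest (largest rate) first; the finest level has
    rate 1.  ``w0`` is the demodulation angular frequency in rad/s.
    """

    levels: list[PyramidLevel]
    w0: float

    def __post_init__(self) -> None:
        rates = [lv.rate for lv in self.levels]
        if any(r2 >= r1 for r1, r2 in zip(rates, rates[1:])):
            raise ValidationError(f"rates must strictly decrease, got {rates}")
        if rates and rates[-1] != 1:
            raise ValidationError("finest pyramid level must have rate 1")
        for lv in self.levels:
            if not np.allclose(lv.envelope, np.abs(lv.baseband)):
                raise ValidationError("envelope must equal |baseband| at every level")

    def level(self, rate: int) -> PyramidLevel:
        for lv in self.levels:
            if lv.rate == rate:
                return lv
        raise KeyError(f"no pyramid level with rate {rate}")


def _check_grid(axial, lateral, valid, centers_axial, centers_lateral) -> None:
    shape = (len(centers_axial), len(centers_lateral))
    for name, arr in (("axial", axial), ("lateral", lateral), ("valid", valid)):
        if arr.shape != shape:
            raise ValidationError(
                f"{name} shape {arr.shape} does not match centers {shape}"
            )
    for name, cs in (("centers_axial", centers_axial), ("centers_lateral", centers_lateral)):
        if len(cs) > 1 and not np.all(np.diff(cs) > 0):
            raise ValidationError(f"{name} must be strictly increasing")


@dataclass
class DisplacementGrid:
    """Sparse axial+lateral displacement estimates on a window-center grid.

    Units: axial displacement and ``centers_axial`` in samples at downsample
    factor ``rate`` (1 = finest); lateral displacement and
    ``centers_lateral`` in scan lines.
    """

    axial: np.ndarray
    lateral: np.ndarray
    centers_axial: np.ndarray
    centers_lateral: np.ndarray
    valid: np.ndarray
    rate: int = 1
    peak_corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.axial = np.asarray(self.axial, dtype=float)
        self.lateral = np.asarray(self.lateral, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.centers_axial = np.asarray(self.centers_axial, dtype=float)
        self.centers_lateral = np.asarray(self.centers_lateral, dtype=float)
        _check_grid(self.axial, self.lateral, self.valid,
                    self.centers_axial, self.centers_lateral)

    @property
    def shape(self) -> tuple[int, int]:
        return self.axial.shape


@dataclass
class DisplacementField:
    """Dense per-window displacement estimates from the fine stage.

    Same conventions as :class:`DisplacementGrid` at rate 1 (finest scale),
    plus the Newton iteration count per window.
    """

    axial: np.ndarray
    lateral: np.ndarray
    centers_axial: np.ndarray
    centers_lateral: np.ndarray
    valid: np.ndarray
    iterations: np.ndarray = None

    def __post_init__(self) -> None:
        self.axial = np.asarray(self.axial, dtype=float)
        self.lateral = np.asarray(self.lateral, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.centers_axial = np.asarray(self.centers_axial, dtype=float)
        self.centers_lateral = np.asarray(self.centers_lateral, dtype=float)
        if self.iterations is None:
            self.iterations = np.zeros(self.axial.shape, dtype=int)
        self.iterations = np.asarray(self.iterations, dtype=int)
        _check_grid(self.axial, self.lateral, self.valid,
                    self.centers_axial, self.centers_lateral)
        if np.any(self.iterations < 0):
            raise ValidationError("iterations must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.axial.shape


@dataclass
class StrainMap:
    """Axial strain on the fine window grid (positive = compression).

    Carries the acquisition geometry needed to place ROIs in metres:
    row centers are finest-scale samples, column centers scan lines.
    """

    strain: np.ndarray
    centers_axial: np.ndarray
    centers_lateral: np.ndarray
    fs: float
    c: float
    line_spacing: float
    depth_offset: float = 0.0

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.centers_axial = np.asarray(self.centers_axial, dtype=float)
        self.centers_lateral = np.asarray(self.centers_lateral, dtype=float)
        if self.strain.shape != (len(self.centers_axial), len(self.centers_lateral)):
            raise ValidationError("strain shape must match its center grids")

    @property
    def depths(self) -> np.ndarray:
        """Depth (m) of each strain row."""
        return self.depth_offset + self.centers_axial * self.c / (2.0 * self.fs)

    @property
    def laterals(self) -> np.ndarray:
        """Lateral position (m) of each strain column."""
        return self.centers_lateral * self.line_spacing


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

# (low, high) inclusive validation ranges; None = unbounded on that side.
_RANGES: dict[str, tuple[float | None, float | None]] = {
    "fs": (1e5, None), "f0": (1e4, None), "c": (100.0, 5000.0),
    "n_lines": (2, None), "width": (1e-3, 1.0), "height": (1e-3, 1.0),
    "inclusion_radius": (0.0, 0.5), "inclusion_depth": (0.0, 1.0),
    "inclusion_lateral": (0.0, 1.0),
    "e_inclusion": (1.0, None), "e_background": (0.0, None),
    "poisson": (0.0, 0.4999), "density": (1.0, None),
    "contrast": (1.0, 100.0), "mesh_n": (8, 512),
    "pulse_bw": (0.05, 1.5), "beam_sigma": (1e-5, 1e-2),
    "scatterer_density": (1.0, 1000.0), "noise_snr": (0.0, 200.0),
    "level1_win_wavelengths": (2.0, 100.0), "level1_win_lines": (3, 64),
    "expected_max_strain": (1e-4, 0.2), "depth_growth": (0.0, 5.0),
    "lateral_search": (1, 32),
    "level2_rows": (2, 64), "level2_cols": (2, 64),
    "level2_search_axial": (1, 256), "level2_search_lateral": (1, 32),
    "level3_overlap": (0.0, 0.95), "level3_search_axial": (1, 256),
    "level3_search_lateral": (1, 32),
    "track_max_steps": (1, 10000), "valid_floor": (-1.0, 1.0),
    "sg_window": (3, 255), "sg_order": (0, 10),
    "lateral_sig_threshold": (0.0, 32.0),
    "fine_window_wavelengths": (0.25, 50.0), "fine_overlap": (0.0, 0.99),
    "newton_max_iter": (1, 1000), "newton_tol": (1e-9, 1.0),
    "ds_rate": (1, 64), "lsqse_kernel": (3, 1001),
    "roi_radius": (1e-5, 0.5), "roi_bg_offset": (0.0, 0.5),
    "replicates": (1, 1000), "seed": (0, 2**31 - 1),
    "cnre_distinguish_threshold": (0.0, None),
}


@dataclass
class RunConfig:
    """All tunables of the simulation and estimation pipeline.

    Units are SI unless stated.  Displacement search ranges are in samples
    at the level's own scale / in scan lines; window sizes are given in
    carrier wavelengths (axial) and lines (lateral) so they adapt to fs/f0.
    """

    # --- acquisition / transducer (defaults: 7.5 MHz array, 120 MHz sampling)
    fs: float = 120e6              # RF sampling frequency, Hz
    f0: float = 7.5e6              # transducer center frequency, Hz
    c: float = 1540.0              # sound speed, m/s
    n_lines: int = 128             # scan lines per frame
    pulse_bw: float = 0.6          # fractional -6 dB pulse bandwidth
    beam_sigma: float = 0.4e-3     # lateral Gaussian beam sigma, m
    scatterer_density: float = 20.0  # scatterers per mm^2
    noise_snr: float = 30.0        # additive white noise SNR, dB

    # --- phantom (20 x 20 mm block, 3 mm stiff inclusion, contrast 5)
    width: float = 0.020           # lateral extent, m
    height: float = 0.020          # depth extent, m
    inclusion_radius: float = 0.003
    inclusion_depth: float = 0.010     # inclusion center depth, m
    inclusion_lateral: float = 0.010   # inclusion center lateral position, m
    e_inclusion: float = 1.0e5     # inclusion Young's modulus, Pa
    e_background: float = 0.0      # 0 = calibrate from `contrast`
    poisson: float = 0.495
    density: float = 1000.0        # kg/m^3 (inertia unused in statics)
    contrast: float = 5.0          # target background/inclusion strain ratio
    mesh_n: int = 80               # FEM elements per side

    # --- pyramid
    rates: tuple = (8, 4, 2)       # coarse levels 1..3; rate 1 kept for fine

    # --- coarse estimation
    level1_win_wavelengths: float = 15.0   # level-1 calc window height, wavelengths
    level1_win_lines: int = 18             # level-1 calc window width, lines
    expected_max_strain: float = 0.04      # sizes the level-1 search range
    depth_growth: float = 0.5              # +50% search range per level-1 row
    lateral_search: int = 4                # level-1 lateral half-range, lines
    level2_rows: int = 7
    level2_cols: int = 11
    level2_search_axial: int = 8           # half-range, level-2 samples
    level2_search_lateral: int = 2         # half-range, lines
    level3_overlap: float = 0.5            # level-3 window overlap fraction
    level3_search_axial: int = 6           # half-range, level-3 samples
    level3_search_lateral: int = 2
    track_max_steps: int = 50
    valid_floor: float = 0.5               # min peak correlation for validity
    sg_window: int = 9                     # Savitzky-Golay window, grid columns
    sg_order: int = 2
    lateral_sig_threshold: float = 0.25    # lines; smaller shifts zeroed

    # --- fine estimation
    fine_window_wavelengths: float = 1.5   # phase-zero window, wavelengths
    fine_overlap: float = 0.75
    newton_max_iter: int = 20
    newton_tol: float = 1e-3               # samples
    ds_rate: int = 4                       # downsampled-1D baseline rate

    # --- strain + metrics
    lsqse_kernel: int = 41                 # least-squares fit kernel, windows
    roi_radius: float = 1.5e-3             # inclusion/background ROI radius, m
    roi_bg_offset: float = 6.5e-3          # background ROI lateral offset, m

    # --- study
    strain_levels: tuple = (0.002, 0.005, 0.008, 0.010, 0.015,
                            0.020, 0.025, 0.030, 0.035, 0.040)
    replicates: int = 5
    seed: int = 0
    cnre_distinguish_threshold: float = 1.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if lo is not None and v < lo:
                raise ConfigError(f"{name}={v} below allowed minimum {lo}")
            if hi is not None and v > hi:
                raise ConfigError(f"{name}={v} above allowed maximum {hi}")
        if self.fs <= 2 * self.f0:
            raise ConfigError("fs must exceed 2*f0")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ConfigError("sg_window must be odd and greater than sg_order")
        if self.lsqse_kernel % 2 == 0:
            raise ConfigError("lsqse_kernel must be odd")
        rates = tuple(int(r) for r in self.rates)
        if any(r2 >= r1 for r1, r2 in zip(rates, rates[1:])) or any(r < 1 for r in rates):
            raise ConfigError(f"rates must be strictly decreasing positive ints, got {rates}")
        self.rates = rates
        self.strain_levels = tuple(float(s) for s in self.strain_levels)
        if any(not (0 <= s <= 0.1) for s in self.strain_levels):
            raise ConfigError("strain levels must lie in [0, 0.1]")

    @property
    def line_spacing(self) -> float:
        """Lateral pitch consistent with the image zone: width / n_lines."""
        return self.width / self.n_lines

    @property
    def wavelength_samples(self) -> float:
        """Carrier period in axial samples."""
        return self.fs / self.f0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


_LIST_FIELDS = {"rates", "strain_levels"}


def load_config(path) -> RunConfig:
    """Load a ``key = value`` text config; unspecified keys take defaults.

    Lines starting with ``#`` and blank lines are ignored.  List-valued
    keys (``rates``, ``strain_levels``) take comma-separated values.
    """
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    overrides: dict = {}
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in fields:
            raise ConfigError(
                f"unknown config key {key!r}; valid keys: {', '.join(sorted(fields))}"
            )
        if key in _LIST_FIELDS:
            overrides[key] = tuple(float(v) for v in value.split(","))
        else:
            ftype = fields[key].type
            caster = int if ftype == "int" else float
            try:
                overrides[key] = caster(value)
            except ValueError as exc:
                raise ConfigError(f"line {lineno}: cannot parse {value!r} for {key}") from exc
    cfg = RunConfig(**overrides)
    logger.info("loaded config %s (hash %s), %d overrides",
                path, cfg.config_hash(), len(overrides))
    return cfg


# ---------------------------------------------------------------------------
# On-disk container
# ---------------------------------------------------------------------------

def _atomic_target(path: Path):
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), suffix=path.suffix + ".tmp")
    os.close(fd)
    return Path(tmp)


def write_frame(frame: RFFrame, path) -> None:
    """Write a single RF frame; HDF5 for ``.h5/.hdf5``, raw+JSON for ``.bin``.

    The write is atomic: data goes to a temporary file in the same directory
    which is renamed over the target.
    """
    if not isinstance(frame, RFFrame):
        raise ValidationError("write_frame expects an RFFrame")
    path = Path(path)
    if path.suffix in (".h5", ".hdf5", ".hdf"):
        tmp = _atomic_target(path)
        try:
            with h5py.File(tmp, "w") as f:
                ds = f.create_dataset("rf", data=frame.samples.astype(np.float32))
                for k, v in frame.meta().items():
                    ds.attrs[k] = v
            os.replace(tmp, path)
        finally:
            tmp.unlink(missing_ok=True)
    elif path.suffix == ".bin":
        tmp = _atomic_target(path)
        sidecar = path.with_suffix(".json")
        tmp_sc = _atomic_target(sidecar)
        try:
            frame.samples.astype(np.float32).tofile(tmp)
            meta = dict(frame.meta(), shape=list(frame.samples.shape), dtype="float32")
            tmp_sc.write_text(json.dumps(meta, indent=1))
            os.replace(tmp_sc, sidecar)
            os.replace(tmp, path)
        finally:
            tmp.unlink(missing_ok=True)
            tmp_sc.unlink(missing_ok=True)
    else:
        raise FormatError(f"unsupported container suffix {path.suffix!r} (use .h5 or .bin)")


def _frame_from_meta(samples: np.ndarray, meta: dict, path) -> RFFrame:
    missing = [k for k in _FRAME_ATTRS if k not in meta]
    if missing:
        raise FormatError(f"{path}: missing metadata key(s): {', '.join(missing)}")
    return RFFrame(samples=samples, **{k: float(meta[k]) for k in _FRAME_ATTRS})


def read_frame(path) -> RFFrame:
    """Read an RF frame written by :func:`write_frame` (either container)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.suffix in (".h5", ".hdf5", ".hdf"):
        with h5py.File(path, "r") as f:
            if "rf" not in f:
                raise FormatError(f"{path}: missing dataset 'rf'")
            ds = f["rf"]
            samples = np.asarray(ds, dtype=np.float64)
            meta = {k: ds.attrs[k] for k in ds.attrs}
        return _frame_from_meta(samples, meta, path)
    if path.suffix == ".bin":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FormatError(f"{path}: missing JSON sidecar {sidecar.name}")
        meta = json.loads(sidecar.read_text())
        if "shape" not in meta:
            raise FormatError(f"{path}: missing metadata key(s): shape")
        shape = tuple(int(s) for s in meta["shape"])
        raw = np.fromfile(path, dtype=np.float32)
        if raw.size != shape[0] * shape[1]:
            raise FormatError(
                f"{path}: payload has {raw.size} values but metadata declares shape {shape}"
            )
        return _frame_from_meta(raw.reshape(shape).astype(np.float64), meta, path)
    raise FormatError(f"unsupported container suffix {path.suffix!r}")


def write_pair(path, pre: RFFrame, post: RFFrame, truth: dict | None = None,
               attrs: dict | None = None) -> None:
    """Write a matched pre/post-compression pair (HDF5 only).

    ``truth`` maps dataset names (e.g. ``axial``, ``lateral``, ``strain``,
    ``z_nodes`` ...) to arrays stored under ``/truth``.  ``attrs`` are scalar
    root attributes such as the applied strain.
    """
    path = Path(path)
    tmp = _atomic_target(path)
    try:
        with h5py.File(tmp, "w") as f:
            for name, frame in (("pre", pre), ("post", post)):
                g = f.create_group(name)
                g.create_dataset("rf", data=frame.samples.astype(np.float32))
                for k, v in frame.meta().items():
                    g.attrs[k] = v
            if truth:
                g = f.create_group("truth")
                for k, v in truth.items():
                    g.create_dataset(k, data=np.asarray(v))
            for k, v in (attrs or {}).items():
                f.attrs[k] = v
        os.replace(tmp, path)
    finally:
        tmp.unlink(missing_ok=True)


def read_pair(path) -> tuple[RFFrame, RFFrame, dict, dict]:
    """Read a pair container; returns (pre, post, truth_arrays, attrs)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    with h5py.File(path, "r") as f:
        frames = []
        for name in ("pre", "post"):
            if name not in f:
                raise FormatError(f"{path}: missing group '{name}'")
            g = f[name]
            samples = np.asarray(g["rf"], dtype=np.float64)
            frames.append(_frame_from_meta(samples, dict(g.attrs), path))
        truth = {}
        if "truth" in f:
            truth = {k: np.asarray(v) for k, v in f["truth"].items()}
        attrs = {k: f.attrs[k] for k in f.attrs}
    return frames[0], frames[1], truth, attrs
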