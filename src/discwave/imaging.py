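"""Synthetic GCaMP movies: rendering, fluorescence transform, TIFF I/O.

A :class:`Movie` is the common currency between the simulator and the
quantification pipeline: a T×Y×X intensity stack with physical pixel size
(μm) and frame interval (s).  Rendering rasterizes a trajectory onto a
pixel grid — each pixel takes the fluorescence of the cell containing its
center — through a Hill-type GCaMP transform (Kd 0.46 μM for GCaMP5G)
plus optional seeded Gaussian noise.

Stacks are written as multi-page TIFF with a JSON sidecar carrying the
physical metadata; 8-bit content round-trips bit-exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import tifffile

from .lattice import TissueLattice
from .model import Trajectory

__all__ = [
    "Movie",
    "GCaMPTransform",
    "fluorescence",
    "render",
    "rasterize_cells",
    "region_mask",
    "write_tiff",
    "read_tiff",
    "mmss",
]

_DEFAULT_PIXEL_SIZE = 1.0   # μm/px
_DEFAULT_FRAME_INTERVAL = 5.0  # s


@dataclass
class Movie:
    """T×Y×X intensity stack with physical metadata."""

    frames: np.ndarray       # (T, Y, X), uint8 or float32
    pixel_size: float        # μm per pixel
    frame_interval: float    # s
    t0: float = 0.0          # time of the first frame, s

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.ndim != 3 or min(f.shape) < 1:
            raise ValueError("frames must be a T×Y×X array with T,Y,X ≥ 1")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        if f.dtype == np.uint8:
            pass
        elif np.issubdtype(f.dtype, np.floating):
            self.frames = f.astype(np.float32, copy=False)
        else:
            raise ValueError("frames must be 8-bit or floating point")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds."""
        return self.t0 + self.frame_interval * np.arange(self.n_frames)

    def to_uint8(self) -> "Movie":
        """Clip to [0, 255] and round to 8-bit (≤ 0.5 quantization error)."""
        if self.frames.dtype == np.uint8:
            return self
        f = np.clip(np.round(self.frames), 0, 255).astype(np.uint8)
        return Movie(f, self.pixel_size, self.frame_interval, self.t0)


@dataclass(frozen=True)
class GCaMPTransform:
    """Hill-type calcium-to-fluorescence transform.

    Defaults: Kd 0.46 μM (GCaMP5G), Hill coefficient 2.7 (literature value
    for GCaMP5G, configurable), intensities spanning the 8-bit display
    range used in the recordings.
    """

    f0: float = 8.0
    fmax: float = 248.0
    kd: float = 0.46
    n_hill: float = 2.7

    def __post_init__(self):
        if not (self.fmax > self.f0 >= 0):
            raise ValueError("need fmax > f0 ≥ 0")
        if self.kd <= 0 or self.n_hill <= 0:
            raise ValueError("kd and n_hill must be > 0")


def fluorescence(c, transform: GCaMPTransform = GCaMPTransform()):
    """F = f0 + (fmax − f0)·cⁿ/(cⁿ + kdⁿ); monotone increasing in c."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("calcium concentration must be ≥ 0")
    cn = c**transform.n_hill
    return transform.f0 + (transform.fmax - transform.f0) * cn / (
        cn + transform.kd**transform.n_hill
    )


# ---------------------------------------------------------------------- #
# Rasterization
# ---------------------------------------------------------------------- #


def rasterize_cells(lattice: TissueLattice, pixel_size: float) -> np.ndarray:
    """Label image (Y, X) mapping each pixel to the cell containing its
    center, or -1 outside the tissue."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if pixel_size**2 > lattice.areas.min():
        raise ValueError(
            f"pixel_size {pixel_size} μm: smallest cell "
            f"({lattice.areas.min():.2f} μm²) spans less than one pixel"
        )
    minx, miny, maxx, maxy = lattice.bounding_box
    nx = int(np.ceil((maxx - minx) / pixel_size))
    ny = int(np.ceil((maxy - miny) / pixel_size))
    xs = minx + (np.arange(nx) + 0.5) * pixel_size
    ys = miny + (np.arange(ny) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    pts = shapely.points(gx.ravel(), gy.ravel())
    polys = np.array(
        [shapely.Polygon(p) for p in lattice.polygons], dtype=object
    )
    tree = shapely.STRtree(polys)
    labels = np.full(nx * ny, -1, dtype=np.int32)
    pt_idx, cell_idx = tree.query(pts, predicate="intersects")
    # first match wins (boundary pixels are claimed by one of the cells)
    labels[pt_idx[::-1]] = cell_idx[::-1]
    return labels.reshape(ny, nx)


def region_mask(
    lattice: TissueLattice, region: str, pixel_size: float
) -> np.ndarray:
    """Boolean (Y, X) mask of pixels whose centers lie in a region."""
    poly = lattice.region_polygon(region)
    minx, miny, maxx, maxy = lattice.bounding_box
    nx = int(np.ceil((maxx - minx) / pixel_size))
    ny = int(np.ceil((maxy - miny) / pixel_size))
    xs = minx + (np.arange(nx) + 0.5) * pixel_size
    ys = miny + (np.arange(ny) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    return shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(ny, nx)


def render(
    trajectory: Trajectory,
    lattice: TissueLattice,
    transform: GCaMPTransform = GCaMPTransform(),
    pixel_size: float = _DEFAULT_PIXEL_SIZE,
    noise_sd: float = 0.0,
    seed: int = 0,
    dtype: str = "uint8",
) -> Movie:
    """Rasterize a trajectory into a synthetic GCaMP movie.

    Each pixel takes the fluorescence of the cell containing its center;
    background pixels are 0.  Seeded Gaussian noise of standard deviation
    ``noise_sd`` (intensity units) is added per pixel and frame.
    """
    if trajectory.c.shape[0] == 0:
        raise ValueError("empty trajectory")
    if trajectory.c.shape[1] != lattice.n_cells:
        raise ValueError("trajectory and lattice cell counts differ")
    labels = rasterize_cells(lattice, pixel_size)
    flat = labels.ravel()
    inside = flat >= 0
    T = trajectory.c.shape[0]
    ny, nx = labels.shape
    fcells = fluorescence(
        np.asarray(trajectory.c, dtype=np.float64), transform
    ).astype(np.float32)
    frames = np.zeros((T, ny * nx), dtype=np.float32)
    frames[:, inside] = fcells[:, flat[inside]]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames += rng.normal(0.0, noise_sd, frames.shape).astype(np.float32)
    frames = frames.reshape(T, ny, nx)
    dtimes = np.diff(trajectory.times)
    interval = float(dtimes[0]) if len(dtimes) else _DEFAULT_FRAME_INTERVAL
    movie = Movie(frames, pixel_size, interval, t0=float(trajectory.times[0]))
    if dtype == "uint8":
        movie = movie.to_uint8()
    return movie


# ---------------------------------------------------------------------- #
# TIFF I/O
# ---------------------------------------------------------------------- #


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_tiff(movie: Movie, path, dtype: str | None = None) -> None:
    """Multi-page TIFF (one page per frame, row-major, top-left origin)
    plus a JSON metadata sidecar."""
    frames = movie.frames
    if dtype == "uint8" and frames.dtype != np.uint8:
        frames = movie.to_uint8().frames
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "pixel_size_um": movie.pixel_size,
        "frame_interval_s": movie.frame_interval,
        "t0_s": movie.t0,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh)


def read_tiff(path) -> Movie:
    """Read a multi-page TIFF and its JSON sidecar into a Movie.

    A missing sidecar falls back to defaults (1 μm/px, 5 s) with a warning;
    non-uniform page shapes are an error.
    """
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) != 1:
            raise ValueError(f"non-uniform page shapes in {path}: {shapes}")
        frames = tif.asarray()
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        px = float(meta.get("pixel_size_um", _DEFAULT_PIXEL_SIZE))
        dtf = float(meta.get("frame_interval_s", _DEFAULT_FRAME_INTERVAL))
        t0 = float(meta.get("t0_s", 0.0))
    else:
        warnings.warn(
            f"no metadata sidecar for {path}; assuming "
            f"{_DEFAULT_PIXEL_SIZE} μm/px and {_DEFAULT_FRAME_INTERVAL} s",
            stacklevel=2,
        )
        px, dtf, t0 = _DEFAULT_PIXEL_SIZE, _DEFAULT_FRAME_INTERVAL, 0.0
    return Movie(frames, px, dtf, t0)


def mmss(seconds: float) -> str:
    """Format a time in the mm:ss convention used for all time series."""
    m, s = divmod(int(round(seconds)), 60)
    return f"{m:02d}:{s:02d}"
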