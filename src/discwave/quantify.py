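"""Quantification of GCaMP time-lapse movies.

Implements the measurement pipeline used on the recordings: single-pixel
intensity traces, line-profile kymographs, FIJI-style difference masks,
wave-event detection with origin mapping, oscillation frequency, wave-front
speed from half-max front tracking, inter-spike-interval (ISI) statistics
with the SD-vs-mean regression diagnostic of cell-cell coupling, and
domain counts on difference masks.

Wave events are segmented from the smoothed ΔF/F0 signal: pixels activate
above a ΔF/F0 threshold, events are contiguous episodes in which the
activated fraction of the analysis region exceeds a floor, and an event
qualifies as a *wave* only if its activated area covers at least a minimum
fraction of the region (excluding locally confined spikes) and its
activation grows contiguously from a compact origin.  Episodes that light
up synchronously everywhere (the uniform response to a ligand dose step)
are classified as flashes, and spatially incoherent episodes (independent
cell-autonomous firing) as scattered — neither counts as a propagating
wave.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .imaging import Movie

__all__ = [
    "PointROI",
    "LineSegment",
    "RegionMask",
    "WaveThresholds",
    "WaveEvent",
    "FrontFit",
    "OriginMap",
    "ISIStats",
    "trace",
    "kymograph",
    "difference_mask",
    "detect_waves",
    "detect_events",
    "oscillation_frequency",
    "front_speed",
    "radial_line",
    "map_origins",
    "isi_analysis",
    "isi_from_spike_times",
    "domain_count",
    "rois_from_json",
    "polygon_mask",
]


# ---------------------------------------------------------------------- #
# ROI types
# ---------------------------------------------------------------------- #


@dataclass(frozen=True)
class PointROI:
    """A single-pixel ROI at physical coordinates (μm)."""

    x: float
    y: float

    def to_pixel(self, movie: Movie):
        j = int(self.x / movie.pixel_size)
        i = int(self.y / movie.pixel_size)
        _, ny, nx = movie.shape
        if not (0 <= i < ny and 0 <= j < nx):
            raise ValueError(
                f"point ({self.x}, {self.y}) μm is outside the "
                f"{nx * movie.pixel_size}×{ny * movie.pixel_size} μm movie"
            )
        return i, j


@dataclass(frozen=True)
class LineSegment:
    """A line ROI from (x0, y0) to (x1, y1), μm."""

    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def length(self) -> float:
        return float(np.hypot(self.x1 - self.x0, self.y1 - self.y0))


@dataclass
class RegionMask:
    """Binary Y×X analysis mask."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("region mask is empty")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def rois_from_json(source) -> dict:
    """Load ROIs from JSON.

    Accepts a path, a file object or a JSON string of the form
    ``{"points": [[x, y], ...], "lines": [[x0, y0, x1, y1], ...],
    "polygons": [[[x, y], ...], ...]}`` (all in μm) and returns
    ``{"points": [PointROI], "lines": [LineSegment], "polygons": [ndarray]}``.
    """
    import json
    from pathlib import Path

    if hasattr(source, "read"):
        obj = json.load(source)
    elif isinstance(source, (str, Path)) and str(source).lstrip().startswith("{"):
        obj = json.loads(str(source))
    else:
        with open(source) as fh:
            obj = json.load(fh)
    return {
        "points": [PointROI(float(x), float(y)) for x, y in obj.get("points", [])],
        "lines": [
            LineSegment(*(float(v) for v in quad)) for quad in obj.get("lines", [])
        ],
        "polygons": [
            np.asarray(poly, dtype=float) for poly in obj.get("polygons", [])
        ],
    }


def polygon_mask(vertices, shape, pixel_size: float) -> RegionMask:
    """Rasterize a polygon ROI (μm vertices) to a movie-shaped mask."""
    import shapely

    poly = shapely.Polygon(np.asarray(vertices, dtype=float))
    ny, nx = shape
    xs = (np.arange(nx) + 0.5) * pixel_size
    ys = (np.arange(ny) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    return RegionMask(shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(ny, nx))


def _as_mask(region, movie: Movie) -> np.ndarray:
    m = region.mask if isinstance(region, RegionMask) else np.asarray(region, bool)
    if m.shape != movie.shape[1:]:
        raise ValueError(
            f"region mask shape {m.shape} does not match movie {movie.shape[1:]}"
        )
    if not m.any():
        raise ValueError("region mask is empty")
    return m


# ---------------------------------------------------------------------- #
# Traces and kymographs
# ---------------------------------------------------------------------- #


def trace(movie: Movie, roi: PointROI) -> pd.Series:
    """Single-pixel intensity over time (the Z-axis profile of a 1-px ROI)."""
    i, j = roi.to_pixel(movie)
    return pd.Series(
        movie.frames[:, i, j].astype(float), index=movie.times, name="intensity"
    )


def kymograph(
    movie: Movie, line: LineSegment, orientation: str = "YT"
) -> np.ndarray:
    """Space-time intensity profile along a line ROI.

    Positions are sampled at 1-pixel spacing with bilinear interpolation.
    ``orientation='YT'`` puts positions on rows and time on columns;
    ``'TX'`` is the transpose.
    """
    if line.length == 0:
        raise ValueError("zero-length line")
    if orientation not in ("YT", "TX"):
        raise ValueError("orientation must be 'YT' or 'TX'")
    n = max(2, int(round(line.length / movie.pixel_size)) + 1)
    ts = np.linspace(0.0, 1.0, n)
    xs = (line.x0 + ts * (line.x1 - line.x0)) / movie.pixel_size - 0.5
    ys = (line.y0 + ts * (line.y1 - line.y0)) / movie.pixel_size - 0.5
    _, ny, nx = movie.shape
    if (
        xs.min() < -0.5 or ys.min() < -0.5
        or xs.max() > nx - 0.5 or ys.max() > ny - 0.5
    ):
        raise ValueError("line extends outside the movie")
    coords = np.vstack([ys, xs])
    out = np.empty((n, movie.n_frames), dtype=float)
    frames = movie.frames
    for k in range(movie.n_frames):
        out[:, k] = ndimage.map_coordinates(
            frames[k].astype(np.float32), coords, order=1, mode="nearest"
        )
    return out if orientation == "YT" else out.T


def difference_mask(movie: Movie, lag: float) -> Movie:
    """FIJI-style inverted difference stack.

    ``out(t) = 255 − max(I(t) − I(t−lag), 0)`` in exact integer arithmetic
    (negative differences clamp to 0; the result is inverted so 0 = white,
    255 = black).  Defined for frames with ``t ≥ lag``.
    """
    if movie.frames.dtype != np.uint8:
        raise ValueError("difference_mask requires an 8-bit movie")
    k = lag / movie.frame_interval
    ki = int(round(k))
    if ki < 1 or abs(k - ki) > 1e-6:
        raise ValueError(
            f"lag {lag} s is not a positive multiple of the frame interval "
            f"{movie.frame_interval} s"
        )
    a = movie.frames[ki:].astype(np.int16)
    b = movie.frames[:-ki].astype(np.int16)
    out = 255 - np.clip(a - b, 0, 255)
    return Movie(
        out.astype(np.uint8),
        movie.pixel_size,
        movie.frame_interval,
        t0=movie.t0 + ki * movie.frame_interval,
    )


# ---------------------------------------------------------------------- #
# Wave detection
# ---------------------------------------------------------------------- #


@dataclass(frozen=True)
class WaveThresholds:
    """Thresholds of the wave-event segmentation.

    activate : ΔF/F0 level above which a pixel counts as activated.
    quiet : activated-area fraction below which the region is quiescent;
        episodes are separated when coverage stays below this for
        ``quiet_seconds`` of recording time.
    area_min_frac : minimum activated-area fraction of the region for an
        event to count as a wave rather than a locally confined spike.
    smooth_px / smooth_seconds : Gaussian smoothing (σ, pixels / seconds)
        applied to the stack in space and time before thresholding.
    baseline_percentile : per-pixel percentile over time used as F0.
    f0_floor : lower bound on F0 in the ΔF/F0 denominator.
    flash_clusters : an event whose first active frame already contains at
        least this many separate activated clusters (or more than half the
        region at once, ``flash_coverage``) is a synchronized flash.
    coherent_frac : minimum fraction of the event footprint that the
        largest space-time connected component must cover for the event to
        count as one propagating wave (smaller → 'scattered').
    min_cluster_px : speckles smaller than this are ignored when counting
        onset clusters.
    spike_min_voxels : minimum space-time extent (pixels × frames) of a
        locally confined activation to count as a spike rather than noise.
    """

    activate: float = 0.3
    quiet: float = 0.10
    quiet_seconds: float = 4.0
    area_min_frac: float = 0.10
    smooth_px: float = 1.0
    smooth_seconds: float = 0.5
    baseline_percentile: float = 10.0
    f0_floor: float = 4.0
    flash_clusters: int = 8
    flash_coverage: float = 0.5
    coherent_frac: float = 0.5
    min_cluster_px: int = 3
    spike_min_voxels: int = 10


@dataclass
class WaveEvent:
    """One detected activation episode."""

    onset_time: float                 # s
    origin: tuple                     # (x, y) μm
    n_pixels: int                     # participating pixels (footprint)
    max_radius: float                 # μm from origin to farthest pixel
    front_track: list                 # [(time s, front radius μm), ...]
    footprint: np.ndarray             # bool (Y, X)
    t_start: float                    # s, episode span
    t_end: float
    kind: str                         # 'wave' | 'flash' | 'scattered' | 'spike'
    area_fraction: float              # footprint / region

    def overlap_fraction(self, region_mask: np.ndarray) -> float:
        m = np.asarray(region_mask, bool)
        return float((self.footprint & m).sum() / max(m.sum(), 1))


def _df_f0(movie: Movie, thresholds: WaveThresholds) -> np.ndarray:
    # smooth the raw stack first so the percentile baseline is not biased
    # low by shot noise, then form ΔF/F0
    f = movie.frames.astype(np.float32)
    sigma_t = thresholds.smooth_seconds / movie.frame_interval
    if thresholds.smooth_px > 0 or sigma_t > 0:
        f = ndimage.gaussian_filter(
            f,
            sigma=(sigma_t, thresholds.smooth_px, thresholds.smooth_px),
            mode="nearest",
        )
    f0 = np.percentile(f, thresholds.baseline_percentile, axis=0)
    f0 = np.maximum(f0, thresholds.f0_floor).astype(np.float32)
    return (f - f0) / f0


def _episodes(coverage: np.ndarray, thresholds: WaveThresholds, frame_interval: float):
    """Frame spans where coverage exceeds `quiet`, merging short dips."""
    on = coverage >= thresholds.quiet
    quiet_frames = max(1, int(round(thresholds.quiet_seconds / frame_interval)))
    spans = []
    start = None
    below = 0
    for k, v in enumerate(on):
        if v:
            if start is None:
                start = k
            below = 0
        elif start is not None:
            below += 1
            if below >= quiet_frames:
                spans.append((start, k - below + 1))
                start = None
    if start is not None:
        spans.append((start, len(on)))
    return spans


def detect_events(
    movie: Movie,
    region,
    thresholds: WaveThresholds = WaveThresholds(),
) -> list:
    """All activation episodes (waves, flashes, scattered, spikes).

    Spike-scale episodes (activated area below ``area_min_frac`` of the
    region) are returned with ``kind='spike'``; use :func:`detect_waves`
    for propagating waves only.
    """
    mask = _as_mask(region, movie)
    a = _df_f0(movie, thresholds)
    act = (a > thresholds.activate) & mask[None, :, :]
    region_px = mask.sum()
    coverage = act[:, mask].mean(axis=1)
    times = movie.times
    dt = movie.frame_interval
    events: list = []

    spans = _episodes(coverage, thresholds, movie.frame_interval)
    for k0, k1 in spans:
        sub = act[k0:k1]
        footprint = sub.any(axis=0)
        area_frac = footprint.sum() / region_px
        # dominant space-time component
        lab3, n3 = ndimage.label(sub)
        if n3 == 0:
            continue
        sizes = ndimage.sum_labels(
            np.ones_like(lab3, dtype=np.int32), lab3, np.arange(1, n3 + 1)
        )
        dom = int(np.argmax(sizes)) + 1
        dom3 = lab3 == dom
        dom_fp = dom3.any(axis=0)
        coherent = dom_fp.sum() / max(footprint.sum(), 1)

        # onset-frame structure (first frame of the dominant component)
        kd = int(np.argmax(dom3.any(axis=(1, 2))))
        lab2, n2 = ndimage.label(
            sub[kd], structure=np.ones((3, 3), dtype=int)
        )
        if n2:
            sz2 = ndimage.sum_labels(
                np.ones_like(lab2, dtype=np.int32), lab2, np.arange(1, n2 + 1)
            )
            big = sz2[sz2 >= thresholds.min_cluster_px]
            n_onset_clusters = len(big)
            onset_dominance = big.max() / big.sum() if len(big) else 1.0
        else:
            n_onset_clusters = 0
            onset_dominance = 1.0
        onset_cov = sub[kd][mask].mean()

        if area_frac < thresholds.area_min_frac:
            kind = "spike"
        elif (
            n_onset_clusters >= thresholds.flash_clusters
            and onset_dominance < 0.5
        ) or onset_cov >= thresholds.flash_coverage:
            # many comparable clusters igniting at once, or most of the
            # region in a single frame: a synchronized flash, not a wave
            kind = "flash"
        elif coherent < thresholds.coherent_frac:
            kind = "scattered"
        else:
            kind = "wave"

        # origin: centroid of the largest onset cluster of the dominant
        # component, in physical coordinates
        onset_dom = dom3[kd]
        labo, no = ndimage.label(onset_dom, structure=np.ones((3, 3), int))
        if no:
            szo = ndimage.sum_labels(
                np.ones_like(labo, dtype=np.int32), labo, np.arange(1, no + 1)
            )
            iy, ix = np.nonzero(labo == int(np.argmax(szo)) + 1)
        else:  # pragma: no cover - dominant component is non-empty
            iy, ix = np.nonzero(onset_dom)
        px = movie.pixel_size
        origin = (float((ix.mean() + 0.5) * px), float((iy.mean() + 0.5) * px))

        # front track: per-frame farthest activated pixel of the dominant
        # component from the origin
        fy, fx = np.nonzero(footprint)
        rad = np.hypot(
            (fx + 0.5) * px - origin[0], (fy + 0.5) * px - origin[1]
        )
        max_radius = float(rad.max()) if len(rad) else 0.0
        front = []
        for kk in range(kd, dom3.shape[0]):
            yy, xx = np.nonzero(dom3[kk])
            if len(yy) == 0:
                break
            r = np.hypot(
                (xx + 0.5) * px - origin[0], (yy + 0.5) * px - origin[1]
            ).max()
            front.append((float(times[k0 + kk]), float(r)))

        events.append(
            WaveEvent(
                onset_time=float(times[k0]),
                origin=origin,
                n_pixels=int(footprint.sum()),
                max_radius=max_radius,
                front_track=front,
                footprint=footprint,
                t_start=float(times[k0]),
                t_end=float(times[min(k1, len(times) - 1)]),
                kind=kind,
                area_fraction=float(area_frac),
            )
        )

    # locally confined spikes that never push coverage above `quiet`
    quiet_act = act.copy()
    for k0, k1 in spans:
        quiet_act[k0:k1] = False
    lab3, n3 = ndimage.label(quiet_act)
    if n3:
        objs = ndimage.find_objects(lab3)
        px = movie.pixel_size
        for li, sl in enumerate(objs, start=1):
            blob = lab3[sl] == li
            if int(blob.sum()) < thresholds.spike_min_voxels:
                continue
            npx = int(blob.any(axis=0).sum())
            fp = np.zeros_like(mask)
            fp[sl[1], sl[2]] = blob.any(axis=0)
            k0 = sl[0].start
            yy, xx = np.nonzero(fp)
            events.append(
                WaveEvent(
                    onset_time=float(times[k0]),
                    origin=(
                        float((xx.mean() + 0.5) * px),
                        float((yy.mean() + 0.5) * px),
                    ),
                    n_pixels=npx,
                    max_radius=0.0,
                    front_track=[],
                    footprint=fp,
                    t_start=float(times[k0]),
                    t_end=float(times[min(sl[0].stop, len(times) - 1)]),
                    kind="spike",
                    area_fraction=float(npx / region_px),
                )
            )
    events.sort(key=lambda e: e.onset_time)
    return events


def detect_waves(
    movie: Movie,
    region,
    thresholds: WaveThresholds = WaveThresholds(),
) -> list:
    """Propagating wave events only (see module docstring for the rules)."""
    return [e for e in detect_events(movie, region, thresholds)
            if e.kind == "wave"]


def oscillation_frequency(events, region, duration: float) -> float:
    """Events per hour whose front enters ``region``.

    An event enters the region when its activated footprint covers at
    least 10% of the region's pixels.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    mask = region.mask if isinstance(region, RegionMask) else np.asarray(region, bool)
    count = sum(
        1 for e in events
        if e.kind in ("wave",) and e.overlap_fraction(mask) >= 0.10
    )
    return count * 3600.0 / duration


# ---------------------------------------------------------------------- #
# Front speed
# ---------------------------------------------------------------------- #


@dataclass
class FrontFit:
    """Half-max front positions along a line and the fitted speed."""

    speed: float                 # μm/s
    times: np.ndarray            # s
    positions: np.ndarray        # μm along the line
    amplitudes: np.ndarray       # intensity at the front per frame
    intercept: float

    def amplitude_decrement(self) -> float:
        """Relative drop of the front amplitude from first to last frame."""
        a = self.amplitudes
        return float((a[0] - a[-1]) / a[0]) if len(a) > 1 and a[0] else 0.0


def radial_line(event: WaveEvent, movie: Movie) -> LineSegment:
    """Line from the event origin through its farthest footprint pixel."""
    yy, xx = np.nonzero(event.footprint)
    px = movie.pixel_size
    x = (xx + 0.5) * px
    y = (yy + 0.5) * px
    d = np.hypot(x - event.origin[0], y - event.origin[1])
    i = int(np.argmax(d))
    return LineSegment(event.origin[0], event.origin[1], float(x[i]), float(y[i]))


def front_speed(
    movie: Movie,
    event: WaveEvent,
    line: LineSegment,
    rel_threshold: float = 0.5,
    min_frames: int = 3,
) -> FrontFit:
    """Wave-front speed from half-max front tracking along a line.

    The front position in each frame of the expansion phase is the
    farthest position along the line whose intensity reaches ``baseline +
    rel_threshold × (event peak − baseline)``; the speed is the
    least-squares slope of position against time.  The intensity at the
    front is recorded per frame for the amplitude-decrement check.
    """
    d0 = np.hypot(line.x0 - event.origin[0], line.y0 - event.origin[1])
    if d0 > 5 * movie.pixel_size:
        raise ValueError("line must start at the event origin")
    kym = kymograph(movie, line, "YT")  # positions × time
    times = movie.times
    in_span = (times >= event.t_start) & (times <= event.t_end)
    pre = times < event.t_start
    baseline = (
        np.percentile(kym[:, pre], 10) if pre.any() else np.percentile(kym, 10)
    )
    peak = kym[:, in_span].max()
    level = baseline + rel_threshold * (peak - baseline)
    pos_um = np.arange(kym.shape[0]) * movie.pixel_size

    ks = np.flatnonzero(in_span)
    fr_t, fr_x, fr_a = [], [], []
    for k in ks:
        above = kym[:, k] >= level
        if not above.any():
            if fr_t:
                break
            continue
        idx = int(np.flatnonzero(above).max())
        fr_t.append(times[k])
        fr_x.append(pos_um[idx])
        # front amplitude: peak intensity within 10 μm behind the front
        back = max(0, idx - int(round(10.0 / movie.pixel_size)))
        fr_a.append(kym[back : idx + 1, k].max())
    if not fr_t:
        raise ValueError("no frames with the front above half-max")
    # expansion phase: up to the first time the front reaches its maximum;
    # the final frame is dropped when possible since the front may have
    # been clipped there by the region boundary or the wave's full extent
    imax = int(np.argmax(fr_x))
    if imax >= min_frames:
        imax -= 1
    fr_t, fr_x, fr_a = fr_t[: imax + 1], fr_x[: imax + 1], fr_a[: imax + 1]
    if len(fr_t) < min_frames:
        raise ValueError(
            f"only {len(fr_t)} trackable frames during expansion; "
            f"need ≥ {min_frames}"
        )
    t = np.asarray(fr_t)
    x = np.asarray(fr_x)
    slope, intercept = np.polyfit(t, x, 1)
    return FrontFit(
        speed=float(slope),
        times=t,
        positions=x,
        amplitudes=np.asarray(fr_a),
        intercept=float(intercept),
    )


# ---------------------------------------------------------------------- #
# Origin mapping
# ---------------------------------------------------------------------- #


@dataclass
class OriginMap:
    """Wave initiation sites and their recurrence clusters."""

    origins: np.ndarray          # (K, 2) μm
    cluster_labels: np.ndarray   # (K,) int
    cluster_sizes: dict
    dispersion: float            # rms distance to the cluster centroid, μm


def map_origins(events, r_cluster: float = 25.0) -> OriginMap:
    """Group event origins lying within ``r_cluster`` μm of each other."""
    waves = [e for e in events if e.kind == "wave"]
    if not waves:
        raise ValueError("no wave events to map")
    pts = np.array([e.origin for e in waves])
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    pairs = tree.query_pairs(r_cluster, output_type="ndarray")
    n = len(pts)
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    sizes = {int(k): int(v) for k, v in zip(*np.unique(labels, return_counts=True))}
    disp = []
    for k in sizes:
        sub = pts[labels == k]
        disp.extend(np.hypot(*(sub - sub.mean(axis=0)).T))
    return OriginMap(
        origins=pts,
        cluster_labels=labels,
        cluster_sizes=sizes,
        dispersion=float(np.sqrt(np.mean(np.square(disp)))) if disp else 0.0,
    )


# ---------------------------------------------------------------------- #
# ISI statistics
# ---------------------------------------------------------------------- #


@dataclass
class ISIStats:
    """Per-point inter-spike intervals and the SD-vs-Tav regression.

    In uncoupled cells stochastic spiking makes SD grow linearly with the
    mean interval (slope ≈ 1); strong cell-cell coupling abolishes the
    relation (regression F-test not significant).
    """

    table: pd.DataFrame          # per point: n_spikes, tav, sd
    slope: float
    intercept: float
    r_squared: float
    p_value: float               # F-test of the regression

    @property
    def tav(self) -> np.ndarray:
        return self.table["tav"].to_numpy()

    @property
    def sd(self) -> np.ndarray:
        return self.table["sd"].to_numpy()


def isi_from_spike_times(spike_times: dict, min_spikes: int = 3) -> ISIStats:
    """ISI statistics from per-point spike-time lists."""
    rows = []
    for name, tt in spike_times.items():
        tt = np.sort(np.asarray(tt, dtype=float))
        if len(tt) < min_spikes:
            warnings.warn(
                f"point {name!r}: only {len(tt)} spikes; excluded", stacklevel=2
            )
            continue
        isi = np.diff(tt)
        rows.append(
            {"point": name, "n_spikes": len(tt),
             "tav": float(isi.mean()), "sd": float(isi.std(ddof=1))}
        )
    if len(rows) < 3:
        raise ValueError(f"only {len(rows)} usable points; need ≥ 3")
    table = pd.DataFrame(rows).set_index("point")
    tav = table["tav"].to_numpy()
    if np.ptp(tav) < 0.02 * tav.mean():
        # all points share one rhythm: the mean-interval axis has no
        # meaningful spread, so no SD-Tav relation is identifiable (this
        # is the strongly coupled regime)
        return ISIStats(
            table=table, slope=0.0,
            intercept=float(table["sd"].mean()), r_squared=0.0, p_value=1.0,
        )
    res = stats.linregress(table["tav"], table["sd"])
    return ISIStats(
        table=table,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )


def spike_times_from_trace(
    series: pd.Series,
    threshold: float | None = None,
    lockout: float = 30.0,
    baseline_percentile: float = 10.0,
) -> np.ndarray:
    """Upward threshold crossings of an intensity trace with a refractory
    lockout.  Default threshold: baseline + 0.5 × (max − baseline)."""
    v = series.to_numpy(dtype=float)
    t = series.index.to_numpy(dtype=float)
    base = np.percentile(v, baseline_percentile)
    thr = threshold if threshold is not None else base + 0.5 * (v.max() - base)
    up = np.flatnonzero((v[1:] >= thr) & (v[:-1] < thr)) + 1
    out = []
    last = -np.inf
    for i in up:
        if t[i] - last >= lockout:
            out.append(t[i])
            last = t[i]
    return np.asarray(out)


def isi_analysis(
    movie: Movie,
    grid_points,
    spike_threshold: float | None = None,
    lockout: float = 30.0,
    min_spikes: int = 3,
) -> ISIStats:
    """ISI statistics over a grid of single-pixel ROIs.

    Spikes are upward crossings of ``baseline + 0.5 (max − baseline)``
    per point (or an absolute ``spike_threshold``) with a refractory
    lockout; points with fewer than ``min_spikes`` spikes are excluded
    with a warning, and at least 3 usable points are required.
    """
    spike_times = {}
    for i, p in enumerate(grid_points):
        s = trace(movie, p)
        spike_times[i] = spike_times_from_trace(
            s, threshold=spike_threshold, lockout=lockout
        )
    return isi_from_spike_times(spike_times, min_spikes=min_spikes)


# ---------------------------------------------------------------------- #
# Domain counts
# ---------------------------------------------------------------------- #


def domain_count(
    diff: Movie, frame: int, threshold: float = 20.0, min_size: int = 4
) -> int:
    """Number of coherent moving-signal domains in a difference-mask frame.

    Counts 8-connected components of pixels darker than ``255 − threshold``
    after removing components below ``min_size`` pixels.
    """
    if not (0 <= frame < diff.n_frames):
        raise ValueError(f"frame {frame} out of range (0..{diff.n_frames - 1})")
    mask = diff.frames[frame] < (255 - threshold)
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(np.ones_like(lab, np.int32), lab, np.arange(1, n + 1))
    return int((sizes >= min_size).sum())
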