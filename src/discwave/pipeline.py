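"""End-to-end experiment orchestration.

``run_preset`` executes a named experiment configuration — build the
lattice, simulate the calcium model under its pharmacology schedule,
render the GCaMP movie, and quantify waves, frequencies, speeds, origins
and ISI statistics — per seed and pooled, writing TIFF movies, CSV tables
and JSON summaries.  ``run_recovery_suite`` re-measures the study's
headline quantities from calibrated presets and reports them against
their reference values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging, quantify
from .lattice import TissueLattice, mean_cell_area
from .model import ModelParams, PharmacologySchedule, simulate
from .presets import experiment_preset, lattice_preset
from .quantify import WaveThresholds

__all__ = [
    "ExperimentConfig",
    "SeedResult",
    "run_preset",
    "run_seed",
    "run_recovery_suite",
    "RECOVERY_TARGETS",
]

log = logging.getLogger("discwave")


@dataclass
class ExperimentConfig:
    """Resolved configuration of one experiment preset."""

    name: str
    lattice: str
    duration: float
    schedule: list = field(default_factory=lambda: [(0.0, {})])
    params: dict = field(default_factory=dict)
    dt: float = 0.02
    record_interval: float = 1.0
    render: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    seeds: list = field(default_factory=lambda: [1, 2, 3])
    measure_speed: bool = True
    measure_isi: bool = False
    speed_region: str | None = None

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "ExperimentConfig":
        obj = experiment_preset(name)
        obj = {**obj, **overrides}
        obj.pop("description", None)
        return cls(**obj)

    def model_params(self) -> ModelParams:
        return ModelParams(**self.params)

    def thresholds(self) -> WaveThresholds:
        return WaveThresholds(**self.analysis)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SeedResult:
    """Quantification of one seeded end-to-end run."""

    seed: int
    lattice: TissueLattice
    movie: imaging.Movie
    events: list
    frequencies: dict            # region -> waves/hour
    speeds: list                 # per-event FrontFit speeds, μm/s
    mean_speed: float
    n_by_kind: dict
    origins: list
    isi: dict | None
    mean_calcium: float

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "frequencies_per_hour": self.frequencies,
            "speeds_um_s": list(self.speeds),
            "mean_speed_um_s": self.mean_speed,
            "events_by_kind": self.n_by_kind,
            "origins_um": [list(o) for o in self.origins],
            "isi": self.isi,
            "mean_calcium_um": self.mean_calcium,
        }


def _tissue_mask(lattice: TissueLattice, pixel_size: float) -> np.ndarray:
    return imaging.rasterize_cells(lattice, pixel_size) >= 0


def _grid_points(lattice: TissueLattice, region: str, n: int = 20):
    """A rectangular grid of single-pixel ROIs inside a region."""
    import shapely

    poly = lattice.region_polygon(region)
    minx, miny, maxx, maxy = poly.bounds
    pts = []
    # oversampled grid, filtered to the region, thinned to n
    for frac in (0.75, 0.6, 0.5):
        nx = max(2, int(np.ceil(np.sqrt(n / frac))))
        xs = np.linspace(minx + 2, maxx - 2, nx)
        ys = np.linspace(miny + 2, maxy - 2, nx)
        gx, gy = np.meshgrid(xs, ys)
        ok = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
        pts = list(zip(gx.ravel()[ok], gy.ravel()[ok]))
        if len(pts) >= n:
            break
    step = max(1, len(pts) // n)
    return [quantify.PointROI(float(x), float(y)) for x, y in pts[::step][:n]]


def run_seed(
    config: ExperimentConfig, seed: int, outdir: Path | None = None
) -> SeedResult:
    """One seeded end-to-end run of a preset."""
    lat = lattice_preset(config.lattice, seed=seed)
    params = config.model_params()
    schedule = PharmacologySchedule(config.schedule)
    log.info(
        "preset %s seed %d: %d cells, %.0f s model time (hash %s)",
        config.name, seed, lat.n_cells, config.duration, config.config_hash(),
    )
    traj = simulate(
        lat, params, schedule, duration=config.duration, dt=config.dt,
        record_interval=config.record_interval, seed=seed,
    )
    render_kw = dict(pixel_size=1.0, noise_sd=2.0)
    render_kw.update(config.render)
    movie = imaging.render(traj, lat, seed=seed, **render_kw)

    thresholds = config.thresholds()
    px = movie.pixel_size
    tissue = _tissue_mask(lat, px)
    events = quantify.detect_events(movie, tissue, thresholds)
    freqs = {
        "tissue": quantify.oscillation_frequency(events, tissue, config.duration)
    }
    masks = {}
    for region in lat.regions:
        masks[region] = imaging.region_mask(lat, region, px)
        freqs[region] = quantify.oscillation_frequency(
            events, masks[region], config.duration
        )
    # hinge frequency is read at the dorsal/ventral hinge domains (the
    # sectors behind the folds, which the YT kymograph crosses); the narrow
    # anterior/posterior corridor sectors are excluded from the mask
    dv = [r for r in ("hinge_dorsal", "hinge_ventral") if r in masks]
    if dv:
        hm = np.zeros_like(tissue)
        for r in dv:
            hm |= masks[r]
        freqs["hinge"] = quantify.oscillation_frequency(events, hm, config.duration)

    speeds = []
    speed_region = config.speed_region
    if config.measure_speed:
        rmask = masks.get(speed_region) if speed_region else None
        for ev in events:
            if ev.kind != "wave":
                continue
            if rmask is not None:
                ox = int(ev.origin[0] / px)
                oy = int(ev.origin[1] / px)
                if not (
                    0 <= oy < rmask.shape[0] and 0 <= ox < rmask.shape[1]
                    and rmask[oy, ox]
                ):
                    continue  # the wave started outside the measured region
            try:
                line = _speed_line(ev, movie, rmask)
                # ≥4 tracked frames: 3-point fits are dominated by the
                # launch transient and front-merging artifacts
                fit = quantify.front_speed(movie, ev, line, min_frames=4)
            except ValueError:
                continue
            if _clean_front_fit(fit):
                speeds.append(fit.speed)
    # median over events: single-event fits on merged or re-nucleating
    # fronts occasionally overshoot, and the median is robust to them
    mean_speed = float(np.median(speeds)) if speeds else float("nan")

    n_by_kind: dict = {}
    for ev in events:
        n_by_kind[ev.kind] = n_by_kind.get(ev.kind, 0) + 1

    isi = None
    if config.measure_isi:
        region = speed_region or next(iter(lat.regions))
        try:
            st = quantify.isi_analysis(movie, _grid_points(lat, region))
            isi = {
                "slope": st.slope, "intercept": st.intercept,
                "r_squared": st.r_squared, "p_value": st.p_value,
                "n_points": int(len(st.table)),
            }
        except ValueError as err:
            isi = {"error": str(err)}

    origins = [e.origin for e in events if e.kind == "wave"]
    result = SeedResult(
        seed=seed, lattice=lat, movie=movie, events=events,
        frequencies=freqs, speeds=speeds, mean_speed=mean_speed,
        n_by_kind=n_by_kind, origins=origins, isi=isi,
        mean_calcium=float(np.asarray(traj.c, dtype=np.float64).mean()),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        base = outdir / f"{config.name}_seed{seed}"
        imaging.write_tiff(movie, f"{base}.tif")
        _events_table(events).to_csv(f"{base}_events.csv", index=False)
        with open(f"{base}_summary.json", "w") as fh:
            json.dump(result.summary(), fh, indent=1)
    return result


def _clean_front_fit(fit) -> bool:
    """Keep only well-behaved expansion fits: a positive, steadily
    advancing front with a tightly linear trajectory."""
    if fit.speed <= 0 or np.any(np.diff(fit.positions) <= 0):
        return False
    pred = fit.speed * fit.times + fit.intercept
    ss_res = float(np.sum((fit.positions - pred) ** 2))
    ss_tot = float(np.sum((fit.positions - fit.positions.mean()) ** 2))
    return ss_tot > 0 and 1 - ss_res / ss_tot >= 0.95


def _speed_line(event, movie, region_mask=None):
    """Radial line from the origin to the farthest footprint pixel,
    optionally restricted to a region."""
    fp = event.footprint
    if region_mask is not None:
        fp = fp & region_mask
        if not fp.any():
            raise ValueError("event footprint does not reach the region")
    yy, xx = np.nonzero(fp)
    px = movie.pixel_size
    x = (xx + 0.5) * px
    y = (yy + 0.5) * px
    d = np.hypot(x - event.origin[0], y - event.origin[1])
    i = int(np.argmax(d))
    return quantify.LineSegment(
        event.origin[0], event.origin[1], float(x[i]), float(y[i])
    )


def _events_table(events) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "onset_time_s": e.onset_time,
                "kind": e.kind,
                "origin_x_um": e.origin[0],
                "origin_y_um": e.origin[1],
                "n_pixels": e.n_pixels,
                "max_radius_um": e.max_radius,
                "area_fraction": e.area_fraction,
                "t_start_s": e.t_start,
                "t_end_s": e.t_end,
            }
            for e in events
        ]
    )


def run_preset(
    config: ExperimentConfig | str, outdir: Path | None = None, seeds=None
) -> dict:
    """Run a preset for all its seeds and pool the summaries.

    Returns the pooled report; per-seed movies/CSV/JSON are written when
    ``outdir`` is given.  Re-running the same configuration reproduces the
    summaries exactly.
    """
    if isinstance(config, str):
        config = ExperimentConfig.from_preset(config)
    seeds = list(seeds if seeds is not None else config.seeds)
    results = [run_seed(config, s, outdir) for s in seeds]
    pooled_freq: dict = {}
    for r in results:
        for k, v in r.frequencies.items():
            pooled_freq.setdefault(k, []).append(v)
    all_speeds = [s for r in results for s in r.speeds]
    report = {
        "preset": config.name,
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "per_seed": [r.summary() for r in results],
        "pooled": {
            "frequencies_per_hour": {
                k: float(np.mean(v)) for k, v in pooled_freq.items()
            },
            "mean_speed_um_s": (
                float(np.median(all_speeds)) if all_speeds else float("nan")
            ),
            "n_speed_measurements": len(all_speeds),
            "mean_calcium_um": float(np.mean([r.mean_calcium for r in results])),
        },
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / f"{config.name}_pooled.json", "w") as fh:
            json.dump(report, fh, indent=1)
    return report


# ---------------------------------------------------------------------- #
# Recovery suite
# ---------------------------------------------------------------------- #

#: Reference values recovered by the calibrated presets; cmp 'eq' targets
#: carry the pooled stochastic tolerance, 'ge' is a lower bound.
RECOVERY_TARGETS = {
    "t1": {"quantity": "pouch frequency, 18 °C preset", "units": "waves/h",
           "reference": 5.1, "cmp": "eq", "rtol": 0.15},
    "t2": {"quantity": "hinge frequency, 18 °C preset", "units": "waves/h",
           "reference": 3.3, "cmp": "eq", "rtol": 0.15},
    "t3": {"quantity": "pouch frequency, 25 °C preset", "units": "waves/h",
           "reference": 8.2, "cmp": "eq", "rtol": 0.15},
    "t4": {"quantity": "hinge frequency, 25 °C preset", "units": "waves/h",
           "reference": 5.6, "cmp": "eq", "rtol": 0.15},
    "t5": {"quantity": "pouch front speed, 18 °C preset", "units": "μm/s",
           "reference": 15.4, "cmp": "eq", "rtol": 0.15},
    "t6": {"quantity": "pouch front speed, 25 °C preset", "units": "μm/s",
           "reference": 18.0, "cmp": "eq", "rtol": 0.15},
    "t7": {"quantity": "peripodium front speed", "units": "μm/s",
           "reference": 36.4, "cmp": "ge", "rtol": 0.0},
    "t8": {"quantity": "pouch mean cell area", "units": "μm²",
           "reference": 4.4, "cmp": "eq", "rtol": 0.05},
    "t9": {"quantity": "peripodium mean cell area", "units": "μm²",
           "reference": 113.5, "cmp": "eq", "rtol": 0.05},
}


def run_recovery_suite(seeds=(1, 2, 3), outdir: Path | None = None) -> pd.DataFrame:
    """Recompute every recovery quantity end-to-end and tabulate verdicts.

    The measured values are produced by the full simulate → render →
    quantify pipeline (or the lattice generator for the cell-area rows);
    nothing is read from stored results.
    """
    seeds = list(seeds)
    values = {}

    rep18 = run_preset(
        ExperimentConfig.from_preset("pouch-18C"), outdir=outdir, seeds=seeds
    )
    values["t1"] = rep18["pooled"]["frequencies_per_hour"]["pouch"]
    values["t2"] = rep18["pooled"]["frequencies_per_hour"]["hinge"]
    values["t5"] = rep18["pooled"]["mean_speed_um_s"]

    rep25 = run_preset(
        ExperimentConfig.from_preset("pouch-25C"), outdir=outdir, seeds=seeds
    )
    values["t3"] = rep25["pooled"]["frequencies_per_hour"]["pouch"]
    values["t4"] = rep25["pooled"]["frequencies_per_hour"]["hinge"]
    values["t6"] = rep25["pooled"]["mean_speed_um_s"]

    repp = run_preset(
        ExperimentConfig.from_preset("peripodium"), outdir=outdir, seeds=seeds
    )
    values["t7"] = repp["pooled"]["mean_speed_um_s"]

    values["t8"] = mean_cell_area(lattice_preset("pouch", seed=seeds[0]), "pouch")
    values["t9"] = mean_cell_area(
        lattice_preset("peripodium", seed=seeds[0]), "peripodium"
    )

    rows = []
    for tid, spec in RECOVERY_TARGETS.items():
        v = float(values[tid])
        ref = spec["reference"]
        if spec["cmp"] == "ge":
            ok = v >= ref
            tol = f"≥ {ref}"
        else:
            ok = abs(v - ref) <= spec["rtol"] * ref
            tol = f"±{spec['rtol'] * 100:.0f}%"
        rows.append(
            {"target": tid, "quantity": spec["quantity"], "units": spec["units"],
             "measured": v, "reference": ref, "tolerance": tol,
             "verdict": "pass" if ok else "FAIL"}
        )
    table = pd.DataFrame(rows).set_index("target")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "recovery_suite.csv")
    return table
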