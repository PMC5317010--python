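"""Shipped presets: lattice templates and end-to-end experiment configs.

Region geometry is stored in JSON as parametric shapes (ellipses, annulus
sectors, rectangles) so that adjacent regions are built from byte-identical
boundary coordinates; the loader turns them into shapely polygons.

The wing-disc template places an elliptical pouch inside an annular hinge
split into large dorsal/ventral sectors and narrow anterior/posterior
corridor sectors on the long axis.  Fold boundaries block the dorsal and
ventral pouch borders entirely; the corridors carry a small residual
junctional conductance.  The peripodium is a separate single-region
lattice of large squamous cells (no inter-layer coupling).

Hinge cell areas are not reported for this tissue; the template uses an
assumed 18 μm², between the measured pouch (4.4 μm²) and peripodium
(113.5 μm²) values.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
from shapely.geometry import Polygon

from .lattice import RegionSpec, TissueLattice, build_lattice
from .model import ModelParams, PharmacologySchedule

__all__ = [
    "available_lattice_presets",
    "available_experiment_presets",
    "lattice_regions",
    "lattice_preset",
    "experiment_preset",
    "params_from_preset",
    "schedule_from_preset",
]

# angular sectors in degrees; image convention (y grows downward), so
# 'dorsal' spans the y<0 half.  Anterior/posterior are the narrow
# corridors on the long axis.
_WEDGE_ANGLES = {
    "anterior": (162.0, 198.0),
    "posterior": (-18.0, 18.0),
    "dorsal": (198.0, 342.0),
    "ventral": (18.0, 162.0),
}
_WEDGE_SPAN = 1000.0


def _wedge_polygon(center, spec) -> Polygon:
    """Pie-slice wedge; adjacent wedges share boundary-ray coordinates."""
    start, end = _WEDGE_ANGLES[spec] if isinstance(spec, str) else spec
    n_arc = max(2, int(np.ceil((end - start) / 30.0)) + 1)
    # reduce mod 360 before deg2rad so that the boundary rays of adjacent
    # wedges are built from bit-identical coordinates across the 0° seam
    th = np.deg2rad(np.linspace(start, end, n_arc) % 360.0)
    pts = [(center[0], center[1])] + [
        (center[0] + _WEDGE_SPAN * np.cos(a), center[1] + _WEDGE_SPAN * np.sin(a))
        for a in th
    ]
    return Polygon(pts)


def _ellipse(center, semi_axes, n_vertices=96) -> Polygon:
    cx, cy = center
    a, b = semi_axes
    th = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return Polygon(np.column_stack([cx + a * np.cos(th), cy + b * np.sin(th)]))


def _shape_to_polygon(shape: dict) -> Polygon:
    kind = shape["type"]
    if kind == "ellipse":
        return _ellipse(
            shape["center"], shape["semi_axes"], shape.get("n_vertices", 96)
        )
    if kind == "rectangle":
        (x0, y0), (x1, y1) = shape["corners"]
        return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
    if kind == "polygon":
        return Polygon(shape["vertices"])
    if kind == "annulus_sector":
        outer = _ellipse(
            shape["center"], shape["outer"], shape.get("n_vertices", 96)
        )
        inner = _ellipse(
            shape["center"], shape["inner"], shape.get("n_vertices", 96)
        )
        annulus = outer.difference(inner)
        wedge = _wedge_polygon(shape["center"], shape["wedge"])
        sector = annulus.intersection(wedge)
        if sector.geom_type == "MultiPolygon":
            sector = max(sector.geoms, key=lambda g: g.area)
        return sector
    raise ValueError(f"unknown shape type {kind!r}")


def _preset_text(filename: str) -> dict:
    ref = resources.files("discwave").joinpath("data").joinpath(filename)
    return json.loads(ref.read_text())


def _data_dir():
    return resources.files("discwave").joinpath("data")


def available_lattice_presets() -> list:
    return sorted(
        p.name[len("lattice_"):-len(".json")].replace("_", "-")
        for p in _data_dir().iterdir()
        if p.name.startswith("lattice_") and p.name.endswith(".json")
    )


def available_experiment_presets() -> list:
    return sorted(
        p.name[len("experiment_"):-len(".json")].replace("_", "-")
        for p in _data_dir().iterdir()
        if p.name.startswith("experiment_") and p.name.endswith(".json")
    )


def lattice_regions(name: str):
    """Region specs and fold edges of a shipped lattice preset."""
    try:
        obj = _preset_text(f"lattice_{name.replace('-', '_').lower()}.json")
    except FileNotFoundError:
        raise ValueError(
            f"unknown lattice preset {name!r}; available: "
            f"{available_lattice_presets()}"
        ) from None
    specs = [
        RegionSpec(
            name=r["name"],
            geometry=_shape_to_polygon(r["shape"]),
            mean_cell_area=r["mean_cell_area"],
            area_cv=r.get("area_cv", 0.2),
        )
        for r in obj["regions"]
    ]
    folds = [tuple(p) for p in obj.get("fold_edges", [])]
    bc = [tuple(p) for p in obj.get("boundary_coupling", [])]
    return specs, folds, bc


def lattice_preset(name: str, seed: int = 0) -> TissueLattice:
    """Build a shipped lattice preset with a given seed."""
    specs, folds, bc = lattice_regions(name)
    return build_lattice(specs, fold_edges=folds, seed=seed, boundary_coupling=bc)


def experiment_preset(name: str) -> dict:
    """Full experiment configuration (lattice, params, schedule, analysis)."""
    try:
        obj = _preset_text(f"experiment_{name.replace('-', '_').lower()}.json")
    except FileNotFoundError:
        raise ValueError(
            f"unknown experiment preset {name!r}; available: "
            f"{available_experiment_presets()}"
        ) from None
    obj.setdefault("name", name)
    return obj


def params_from_preset(config: dict) -> ModelParams:
    return ModelParams(**config.get("params", {}))


def schedule_from_preset(config: dict) -> PharmacologySchedule:
    return PharmacologySchedule(config.get("schedule", [(0.0, {})]))
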