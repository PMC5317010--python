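"""Seeded polygonal cell lattices for a patterned epithelium.

The wing imaginal disc is modeled as a set of named regions (pouch, hinge
sectors, notum, peripodium), each tiled by polygonal cells obtained from a
seeded Voronoi tessellation with centroidal (Lloyd) relaxation.  Cells are
coupled through gap junctions along shared edges; edges that cross a fold
boundary between regions carry zero coupling, which is what confines waves
to the pouch except for the anterior/posterior corridors.

Coordinates are in micrometres, image convention: origin at the top-left of
the bounding box, x rightward, y downward.  All indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
import scipy.sparse as sp
from scipy.spatial import Voronoi
from shapely.geometry import MultiPolygon, Point, Polygon

__all__ = [
    "REGION_NAMES",
    "RegionSpec",
    "TissueLattice",
    "build_lattice",
    "coupling_graph",
    "mean_cell_area",
]

#: Admissible region labels for a wing-disc lattice.
REGION_NAMES = frozenset(
    {
        "pouch",
        "hinge_dorsal",
        "hinge_ventral",
        "hinge_anterior",
        "hinge_posterior",
        "notum",
        "peripodium",
    }
)

# Minimum shared-boundary length (μm) for two cells to count as adjacent;
# rules out corner-touching pairs and negligible slivers.
_MIN_EDGE_LEN = 0.05


@dataclass(frozen=True)
class RegionSpec:
    """One named tissue region to be tiled with cells.

    Parameters
    ----------
    name : str
        Region label, one of :data:`REGION_NAMES`.
    geometry : shapely.Polygon
        Simple (non-self-intersecting) closed polygon, in μm.
    mean_cell_area : float
        Requested mean apical cell area, μm².
    area_cv : float
        Coefficient of variation of cell areas (a property of the random
        tessellation; the realized CV approaches this only loosely).
    """

    name: str
    geometry: Polygon
    mean_cell_area: float
    area_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise ValueError(
                f"unknown region name {self.name!r}; expected one of "
                f"{sorted(REGION_NAMES)}"
            )
        if not isinstance(self.geometry, Polygon):
            raise TypeError("geometry must be a shapely Polygon")
        if not self.geometry.is_valid or self.geometry.area <= 0:
            raise ValueError(
                f"region {self.name!r}: geometry must be a simple polygon "
                "with positive area"
            )
        if not self.mean_cell_area > 0:
            raise ValueError(f"region {self.name!r}: mean_cell_area must be > 0")
        if self.mean_cell_area > self.geometry.area * (1 + 1e-9):
            raise ValueError(
                f"region {self.name!r}: mean_cell_area ({self.mean_cell_area} μm²) "
                f"exceeds region area ({self.geometry.area:.3f} μm²)"
            )
        if self.area_cv < 0:
            raise ValueError(f"region {self.name!r}: area_cv must be ≥ 0")


@dataclass
class TissueLattice:
    """A tessellated tissue with a gap-junction adjacency structure.

    Attributes
    ----------
    centroids : (N, 2) float array
        Cell centroids, μm.
    polygons : list of (k, 2) float arrays
        Cell boundary vertices, μm.
    areas : (N,) float array
        Cell areas, μm².
    region_labels : (N,) str array
        Region name per cell.
    edge_a, edge_b : (E,) int arrays
        Indices of the two cells joined by each undirected edge (a < b).
    edge_length : (E,) float array
        Shared boundary length, μm.
    coupling_factor : (E,) float array
        In [0, 1]; exactly 0 for edges crossing a fold boundary.
    regions : dict
        name -> RegionSpec used to build the lattice.
    bounding_box : (minx, miny, maxx, maxy)
    seed : int
    """

    centroids: np.ndarray
    polygons: list
    areas: np.ndarray
    region_labels: np.ndarray
    edge_a: np.ndarray
    edge_b: np.ndarray
    edge_length: np.ndarray
    coupling_factor: np.ndarray
    regions: dict
    bounding_box: tuple
    seed: int
    fold_edges: list = field(default_factory=list)

    # ------------------------------------------------------------------ #
    @property
    def n_cells(self) -> int:
        return len(self.areas)

    @property
    def n_edges(self) -> int:
        return len(self.edge_a)

    def cells_in_region(self, region: str) -> np.ndarray:
        """Indices of cells belonging to ``region``."""
        return np.flatnonzero(self.region_labels == region)

    def region_polygon(self, region: str) -> Polygon:
        return self.regions[region].geometry

    def to_networkx(self):
        """Adjacency as a networkx graph; zero-coupling edges are omitted."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_cells))
        for a, b, w, f in zip(
            self.edge_a, self.edge_b, self.edge_length, self.coupling_factor
        ):
            if f > 0:
                g.add_edge(int(a), int(b), length=float(w), coupling=float(f))
        return g

    # ------------------------------------------------------------------ #
    def to_json(self, path=None) -> str:
        """Serialize the lattice (cells, polygons, edges, regions) to JSON."""
        obj = {
            "seed": self.seed,
            "bounding_box": list(self.bounding_box),
            "fold_edges": [list(p) for p in self.fold_edges],
            "regions": {
                name: {
                    "mean_cell_area": spec.mean_cell_area,
                    "area_cv": spec.area_cv,
                    "polygon": np.asarray(spec.geometry.exterior.coords).tolist(),
                }
                for name, spec in self.regions.items()
            },
            "cells": [
                {
                    "id": i,
                    "centroid": self.centroids[i].tolist(),
                    "polygon": np.asarray(self.polygons[i]).tolist(),
                    "area": float(self.areas[i]),
                    "region": str(self.region_labels[i]),
                }
                for i in range(self.n_cells)
            ],
            "edges": [
                {
                    "a": int(a),
                    "b": int(b),
                    "shared_edge_length": float(l),
                    "coupling_factor": float(f),
                }
                for a, b, l, f in zip(
                    self.edge_a, self.edge_b, self.edge_length, self.coupling_factor
                )
            ],
        }
        text = json.dumps(obj)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TissueLattice":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        cells = obj["cells"]
        edges = obj["edges"]
        regions = {
            name: RegionSpec(
                name=name,
                geometry=Polygon(r["polygon"]),
                mean_cell_area=r["mean_cell_area"],
                area_cv=r["area_cv"],
            )
            for name, r in obj["regions"].items()
        }
        return cls(
            centroids=np.array([c["centroid"] for c in cells], dtype=float),
            polygons=[np.array(c["polygon"], dtype=float) for c in cells],
            areas=np.array([c["area"] for c in cells], dtype=float),
            region_labels=np.array([c["region"] for c in cells], dtype="U16"),
            edge_a=np.array([e["a"] for e in edges], dtype=np.int64),
            edge_b=np.array([e["b"] for e in edges], dtype=np.int64),
            edge_length=np.array(
                [e["shared_edge_length"] for e in edges], dtype=float
            ),
            coupling_factor=np.array(
                [e["coupling_factor"] for e in edges], dtype=float
            ),
            regions=regions,
            bounding_box=tuple(obj["bounding_box"]),
            seed=int(obj["seed"]),
            fold_edges=[tuple(p) for p in obj.get("fold_edges", [])],
        )

    def to_dataframe(self):
        """Per-cell table (id, x, y, area, region) as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "x_um": self.centroids[:, 0],
                "y_um": self.centroids[:, 1],
                "area_um2": self.areas,
                "region": self.region_labels,
            }
        )


# ---------------------------------------------------------------------- #
# Tessellation internals
# ---------------------------------------------------------------------- #


def _sample_points_in_polygon(poly: Polygon, n: int, rng: np.random.Generator):
    """Uniform rejection sampling of n points inside poly."""
    minx, miny, maxx, maxy = poly.bounds
    pts = np.empty((0, 2))
    # batched rejection; polygon fills a decent fraction of its bbox
    while len(pts) < n:
        m = max(4 * (n - len(pts)), 64)
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(m, 2))
        inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        pts = np.vstack([pts, cand[inside]])
    return pts[:n]


def _clipped_voronoi(points: np.ndarray, boundary: Polygon):
    """Voronoi cells of `points` clipped to `boundary`.

    Distant ghost points close every real cell so clipping is well defined.
    Returns a list of shapely Polygons, one per input point, in order.
    """
    minx, miny, maxx, maxy = boundary.bounds
    cx, cy = (minx + maxx) / 2, (miny + maxy) / 2
    span = 10.0 * max(maxx - minx, maxy - miny, 1.0)
    ghosts = np.array(
        [
            (cx - span, cy),
            (cx + span, cy),
            (cx, cy - span),
            (cx, cy + span),
            (cx - span, cy - span),
            (cx + span, cy - span),
            (cx - span, cy + span),
            (cx + span, cy + span),
        ]
    )
    vor = Voronoi(np.vstack([points, ghosts]))
    cells = []
    for i in range(len(points)):
        verts = vor.vertices[vor.regions[vor.point_region[i]]]
        cell = Polygon(verts)
        if not cell.is_valid:
            cell = cell.buffer(0)
        clipped = cell.intersection(boundary)
        if isinstance(clipped, MultiPolygon):
            # non-convex region boundary can split a cell; keep the piece
            # containing the generating point (fall back to largest)
            pt = Point(points[i])
            containing = [g for g in clipped.geoms if g.contains(pt)]
            clipped = (
                containing[0]
                if containing
                else max(clipped.geoms, key=lambda g: g.area)
            )
        cells.append(clipped)
    return cells


def _tessellate_region(
    spec: RegionSpec, rng: np.random.Generator, relax_rounds: int = 3
):
    """Seeded Voronoi tessellation of one region with Lloyd relaxation."""
    n = max(1, int(round(spec.geometry.area / spec.mean_cell_area)))
    pts = _sample_points_in_polygon(spec.geometry, n, rng)
    cells = _clipped_voronoi(pts, spec.geometry)
    for _ in range(relax_rounds):
        pts = np.array([[c.centroid.x, c.centroid.y] for c in cells])
        # keep relaxed points strictly inside the region
        outside = ~shapely.contains_xy(spec.geometry, pts[:, 0], pts[:, 1])
        if outside.any():
            for i in np.flatnonzero(outside):
                pts[i] = _sample_points_in_polygon(spec.geometry, 1, rng)[0]
        cells = _clipped_voronoi(pts, spec.geometry)
    return cells


def _shared_edges(all_polys, labels):
    """Adjacency (a, b, shared boundary length) between tessellation cells.

    Within a region, cells come from one Voronoi diagram and share exact
    edges.  Across region boundaries the two tessellations were clipped
    independently, so coincident edges can disagree by rounding; there the
    shared length is estimated from the overlap area of thin buffers.
    """
    geoms = np.array(all_polys, dtype=object)
    tree = shapely.STRtree(geoms)
    ia, ib = tree.query(geoms, predicate="dwithin", distance=1e-4)
    mask = ia < ib
    ia, ib = ia[mask], ib[mask]
    same = labels[ia] == labels[ib]
    lengths = np.zeros(len(ia))
    if same.any():
        inter = shapely.intersection(geoms[ia[same]], geoms[ib[same]])
        lengths[same] = shapely.length(inter)
    cross = ~same
    if cross.any():
        eps = 1e-3
        ba = shapely.buffer(geoms[ia[cross]], eps)
        bb = shapely.buffer(geoms[ib[cross]], eps)
        overlap = shapely.area(shapely.intersection(ba, bb))
        lengths[cross] = np.maximum(overlap / (2 * eps) - np.pi * eps / 2, 0.0)
    keep = lengths > _MIN_EDGE_LEN
    return ia[keep], ib[keep], lengths[keep]


def build_lattice(
    regions,
    fold_edges=(),
    seed: int = 0,
    relax_rounds: int = 3,
    boundary_coupling=(),
) -> TissueLattice:
    """Generate a seeded, patterned polygonal cell lattice.

    Parameters
    ----------
    regions : list of RegionSpec
        Non-overlapping regions; adjacent regions should share boundary
        geometry exactly so that cross-region cell adjacency is detected.
    fold_edges : iterable of (region_a, region_b)
        Unordered region pairs whose mutual boundary is a fold: every
        cell-cell edge crossing it gets ``coupling_factor = 0``.
    seed : int
        Seed for the point process; identical inputs give identical output.
    relax_rounds : int
        Lloyd (centroidal) relaxation rounds.
    boundary_coupling : iterable of (region_a, region_b, factor)
        Partial junctional conductance (in [0, 1]) for edges crossing a
        region boundary, e.g. a narrow corridor with sparse gap junctions.

    Notes
    -----
    The number of cells per region is ``round(region_area / mean_cell_area)``,
    so the realized mean area matches the request up to rounding.
    """
    specs = list(regions)
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate region names")
    for i, a in enumerate(specs):
        for b in specs[i + 1 :]:
            ov = a.geometry.intersection(b.geometry).area
            if ov > 1e-6 * min(a.geometry.area, b.geometry.area):
                raise ValueError(f"regions {a.name!r} and {b.name!r} overlap")

    fold_set = {frozenset(p) for p in fold_edges}
    pair_factor = {frozenset((a, b)): float(f) for a, b, f in boundary_coupling}
    if any(not (0 <= f <= 1) for f in pair_factor.values()):
        raise ValueError("boundary_coupling factors must be in [0, 1]")
    rng = np.random.default_rng(seed)

    polys, labels = [], []
    for spec in specs:
        cells = _tessellate_region(spec, rng, relax_rounds)
        polys.extend(cells)
        labels.extend([spec.name] * len(cells))
    labels = np.array(labels, dtype="U16")

    areas = np.array([p.area for p in polys])
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in polys])

    ia, ib, lengths = _shared_edges(polys, labels)
    coupling = np.ones(len(ia))
    cross = labels[ia] != labels[ib]
    for k in np.flatnonzero(cross):
        pair = frozenset((str(labels[ia[k]]), str(labels[ib[k]])))
        if pair in fold_set:
            coupling[k] = 0.0
        elif pair in pair_factor:
            coupling[k] = pair_factor[pair]

    # shift to image convention: bounding-box top-left at the origin
    minx = min(p.bounds[0] for p in polys)
    miny = min(p.bounds[1] for p in polys)
    maxx = max(p.bounds[2] for p in polys)
    maxy = max(p.bounds[3] for p in polys)
    shift = np.array([minx, miny])
    centroids = centroids - shift
    poly_arrays = [np.asarray(p.exterior.coords)[:-1] - shift for p in polys]
    shifted_regions = {
        s.name: RegionSpec(
            name=s.name,
            geometry=shapely.transform(
                s.geometry, lambda xy: xy - shift
            ),
            mean_cell_area=s.mean_cell_area,
            area_cv=s.area_cv,
        )
        for s in specs
    }

    return TissueLattice(
        centroids=centroids,
        polygons=poly_arrays,
        areas=areas,
        region_labels=labels,
        edge_a=ia.astype(np.int64),
        edge_b=ib.astype(np.int64),
        edge_length=lengths,
        coupling_factor=coupling,
        regions=shifted_regions,
        bounding_box=(0.0, 0.0, maxx - minx, maxy - miny),
        seed=seed,
        fold_edges=[tuple(sorted(p)) for p in fold_set],
    )


# ---------------------------------------------------------------------- #
# Derived quantities
# ---------------------------------------------------------------------- #


def coupling_graph(
    lattice: TissueLattice, base_permeability: float, fold_block: bool = True
) -> sp.csr_matrix:
    """Symmetric gap-junction weight matrix.

    ``weight(a, b) = base_permeability × shared_edge_length × coupling_factor``
    with the coupling factor forced to 1 when ``fold_block`` is off.
    """
    if base_permeability < 0:
        raise ValueError("base_permeability must be ≥ 0")
    factor = lattice.coupling_factor if fold_block else np.ones(lattice.n_edges)
    w = base_permeability * lattice.edge_length * factor
    n = lattice.n_cells
    mat = sp.coo_matrix(
        (
            np.concatenate([w, w]),
            (
                np.concatenate([lattice.edge_a, lattice.edge_b]),
                np.concatenate([lattice.edge_b, lattice.edge_a]),
            ),
        ),
        shape=(n, n),
    )
    return mat.tocsr()


def mean_cell_area(lattice: TissueLattice, region: str) -> float:
    """Arithmetic mean of cell polygon areas in a region, μm²."""
    idx = lattice.cells_in_region(region)
    if len(idx) == 0:
        raise ValueError(f"region {region!r} contains no cells")
    return float(lattice.areas[idx].mean())
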