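import numpy as np
import pytest
from shapely.geometry import Polygon

from discwave.lattice import RegionSpec, build_lattice


def square_region(side=10.0, name="pouch", mean_cell_area=None, area_cv=0.2):
    poly = Polygon([(0, 0), (side, 0), (side, side), (0, side)])
    return RegionSpec(
        name=name,
        geometry=poly,
        mean_cell_area=mean_cell_area or side * side,
        area_cv=area_cv,
    )


@pytest.fixture(scope="session")
def one_cell_lattice():
    """A lattice consisting of exactly one 100 μm² cell."""
    return build_lattice([square_region(10.0)], seed=0)


@pytest.fixture(scope="session")
def ten_cell_lattice():
    """Small coupled lattice for integrator and conservation checks."""
    return build_lattice([square_region(10.0, mean_cell_area=10.0)], seed=3)


@pytest.fixture(scope="session")
def small_lattice():
    """~100-cell lattice used by tissue-level property tests."""
    return build_lattice([square_region(21.0, mean_cell_area=4.4)], seed=2)


@pytest.fixture(scope="session")
def mini_pouch():
    from discwave.presets import lattice_preset

    return lattice_preset("pouch-mini", seed=1)
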