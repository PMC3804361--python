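"""Shared test fixtures: small meshes, bases and canonical surfaces."""

import numpy as np
import pytest

from fealign import (DGBasis, GridGeometry, ShapeSpec, Surface, Tessellation,
                     make_shape)


@pytest.fixture
def unit_grid_2d():
    return GridGeometry.unit(2, 65)


@pytest.fixture
def coarse_basis_2d():
    """8x8 uniform quadtree mesh with bilinear elements."""
    return DGBasis(Tessellation.unit(2, 3), 1)


@pytest.fixture
def coarse_basis_3d():
    """4x4x4 uniform octree mesh with trilinear elements."""
    return DGBasis(Tessellation.unit(3, 2), 1)


@pytest.fixture
def circle():
    return make_shape(ShapeSpec(family="circle", radius=0.3, resolution=256))


@pytest.fixture
def random_polygon():
    """Random star-shaped 12-gon around (0.5, 0.5), fixed seed."""
    rng = np.random.default_rng(42)
    theta = np.sort(rng.uniform(0.0, 2.0 * np.pi, 12))
    r = rng.uniform(0.15, 0.35, 12)
    verts = 0.5 + np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    return Surface.closed_polyline(verts)


def crossing_mask(values: np.ndarray) -> np.ndarray:
    """Nodes adjacent to a sign change of ``values`` along any axis."""
    cross = np.zeros_like(values, dtype=bool)
    sign = np.sign(values)
    for ax in range(values.ndim):
        lo = np.take(sign, range(0, values.shape[ax] - 1), axis=ax)
        hi = np.take(sign, range(1, values.shape[ax]), axis=ax)
        change = (lo * hi) <= 0
        idx = [slice(None)] * values.ndim
        idx[ax] = slice(0, values.shape[ax] - 1)
        cross[tuple(idx)] |= change
        idx[ax] = slice(1, values.shape[ax])
        cross[tuple(idx)] |= change
    return cross
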