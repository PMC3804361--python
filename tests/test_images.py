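"""Feature-image unit tests: distance transforms, curvature, robust weights."""

import numpy as np
import pytest
from conftest import crossing_mask

import fealign as fa
from fealign.images import OrientationUndefinedError, band_mask


# --------------------------------------------------------------------------
# grid and raster basics
# --------------------------------------------------------------------------

def test_grid_geometry_validation():
    with pytest.raises(ValueError):
        fa.GridGeometry((0.0,), (0.1, 0.1), (5, 5))
    with pytest.raises(ValueError):
        fa.GridGeometry((0.0, 0.0), (0.1, -0.1), (5, 5))
    with pytest.raises(ValueError):
        fa.GridGeometry((0.0, 0.0), (0.1, 0.1), (5, 1))


def test_unit_grid_covers_unit_square():
    g = fa.GridGeometry.unit(2, 65)
    assert g.upper == (1.0, 1.0)
    nodes = g.nodes()
    assert nodes.shape == (65 * 65, 2)
    assert nodes.min() == 0.0 and nodes.max() == 1.0


def test_bilinear_sampling_reproduces_affine_fields(unit_grid_2d):
    nodes = unit_grid_2d.nodes()
    vals = (1.5 * nodes[:, 0] - 0.7 * nodes[:, 1] + 0.2).reshape(
        unit_grid_2d.shape)
    img = fa.RasterImage(unit_grid_2d, vals)
    rng = np.random.default_rng(0)
    pts = rng.uniform(0.0, 1.0, size=(200, 2))
    expected = 1.5 * pts[:, 0] - 0.7 * pts[:, 1] + 0.2
    assert np.abs(img.sample(pts) - expected).max() < 1e-12


def test_sampling_clamps_outside_domain(unit_grid_2d):
    nodes = unit_grid_2d.nodes()
    img = fa.RasterImage(unit_grid_2d, nodes[:, 0].reshape(unit_grid_2d.shape))
    assert img.sample(np.array([[2.0, 0.5]]))[0] == pytest.approx(1.0)
    assert img.sample(np.array([[-1.0, 0.5]]))[0] == pytest.approx(0.0)


def test_raster_image_rejects_bad_values(unit_grid_2d):
    with pytest.raises(ValueError):
        fa.RasterImage(unit_grid_2d, np.zeros((3, 3)))
    bad = np.zeros(unit_grid_2d.shape)
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        fa.RasterImage(unit_grid_2d, bad)


def test_warp_image_identity_matches_plain_sampling(unit_grid_2d, circle):
    img = fa.signed_distance(circle, unit_grid_2d)
    rng = np.random.default_rng(1)
    pts = rng.uniform(0.1, 0.9, size=(50, 2))
    zero = np.zeros_like(pts)
    assert np.array_equal(fa.warp_image(img, pts, zero), img.sample(pts))


# --------------------------------------------------------------------------
# signed distance
# --------------------------------------------------------------------------

def test_circle_distance_matches_analytic(unit_grid_2d, circle):
    img = fa.signed_distance(circle, unit_grid_2d)
    nodes = unit_grid_2d.nodes()
    exact = np.linalg.norm(nodes - 0.5, axis=1) - 0.3
    # dominant error: polygonization sag of the 256-gon, (2pi/256)^2 r / 8
    assert np.abs(img.values.ravel() - exact).max() < 5e-5


def test_distance_is_negative_inside_positive_outside(circle):
    inner = fa.distance_to_surface(circle, np.array([[0.5, 0.5]]))
    outer = fa.distance_to_surface(circle, np.array([[0.95, 0.95]]))
    assert inner[0] < 0 < outer[0]


def test_distance_gradient_has_unit_magnitude(circle):
    grid = fa.GridGeometry.unit(2, 129)
    img = fa.signed_distance(circle, grid)
    gx, gy = img.gradient()
    norm = np.hypot(gx.values, gy.values)
    nodes_r = np.linalg.norm(grid.nodes() - 0.5, axis=1).reshape(grid.shape)
    # away from the center (gradient singularity) and the domain boundary
    sel = (nodes_r > 0.1) & (nodes_r < 0.45)
    assert np.abs(norm[sel] - 1.0).max() < 5e-3


def test_open_surface_signed_distance_raises():
    verts = np.array([[0.2, 0.2], [0.8, 0.2], [0.5, 0.8]])
    cells = np.array([[0, 1], [1, 2]])          # missing closing segment
    open_surf = fa.Surface(verts, cells)
    assert not open_surf.is_closed()
    with pytest.raises(OrientationUndefinedError):
        fa.distance_to_surface(open_surf, np.array([[0.5, 0.5]]))
    unsigned = fa.distance_to_surface(open_surf, np.array([[0.5, 0.2]]),
                                      signed=False)
    assert unsigned[0] == pytest.approx(0.0, abs=1e-15)


def test_sphere_distance_matches_analytic_within_faceting():
    spec = fa.ShapeSpec(family="sphere", center=(0.5, 0.5, 0.5), radius=0.3,
                        resolution=256)
    sphere = fa.make_shape(spec)
    rng = np.random.default_rng(3)
    pts = rng.uniform(0.1, 0.9, size=(40, 3))
    d = fa.distance_to_surface(sphere, pts)
    exact = np.linalg.norm(pts - 0.5, axis=1) - 0.3
    sag = 0.3 * (np.pi / 32) ** 2               # inscribed-chord sag bound
    assert np.abs(d - exact).max() < 2 * sag
    assert np.all(np.sign(d) == np.sign(exact))


def test_signed_distance_dimension_mismatch(circle):
    with pytest.raises(ValueError):
        fa.signed_distance(circle, fa.GridGeometry.unit(3, 9))


# --------------------------------------------------------------------------
# bounding and curvature
# --------------------------------------------------------------------------

def test_bound_distance_clips_upper_tail_only(unit_grid_2d, circle):
    img = fa.signed_distance(circle, unit_grid_2d)
    bounded = fa.bound_distance(img, 0.1)
    assert bounded.values.max() == pytest.approx(0.1)
    inside = img.values < 0
    assert np.array_equal(bounded.values[inside], img.values[inside])
    twice = fa.bound_distance(bounded, 0.1)
    assert np.array_equal(twice.values, bounded.values)


def test_bound_distance_rejects_nonpositive_bound(unit_grid_2d, circle):
    img = fa.signed_distance(circle, unit_grid_2d)
    with pytest.raises(ValueError):
        fa.bound_distance(img, 0.0)


def test_curvature_second_order_convergence(circle):
    """Laplacian error on the smooth part of the circle distance ~ O(h^2)."""
    errs = []
    for n in (65, 129):
        grid = fa.GridGeometry.unit(2, n)
        nodes = grid.nodes()
        r = np.linalg.norm(nodes - 0.5, axis=1)
        img = fa.RasterImage(grid, (r - 0.3).reshape(grid.shape))
        curv = fa.mean_curvature_image(img)
        sel = ((r > 0.25) & (r < 0.35)).reshape(grid.shape)
        errs.append(np.abs(curv.values[sel] - 1.0 / r.reshape(grid.shape)[sel]
                           ).max())
    assert errs[0] / errs[1] > 3.0


def test_band_mask_width(unit_grid_2d, circle):
    img = fa.signed_distance(circle, unit_grid_2d)
    mask = band_mask(img, 0.05)
    nodes_r = np.linalg.norm(unit_grid_2d.nodes() - 0.5, axis=1)
    assert np.array_equal(mask.ravel(), np.abs(nodes_r - 0.3) < 0.05 + 1e-12)


# --------------------------------------------------------------------------
# robust weights and channels
# --------------------------------------------------------------------------

def test_robust_weight_modes():
    resid = np.array([0.0, 0.1, -0.2])
    assert np.array_equal(
        fa.robust_weight(fa.RobustWeightSpec("none"), resid), np.ones(3))
    gm = fa.robust_weight(fa.RobustWeightSpec("geman_mcclure", C=0.05), resid)
    assert np.allclose(gm, 0.05 ** 2 + resid ** 2)
    grad = np.array([[1.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
    dm = fa.robust_weight(fa.RobustWeightSpec("demons"), resid, grad)
    assert np.allclose(dm, np.array([1.0, 4.0, 2.0]) + resid ** 2)
    with pytest.raises(ValueError):
        fa.robust_weight(fa.RobustWeightSpec("demons"), resid)
    with pytest.raises(ValueError):
        fa.RobustWeightSpec("huber")
    with pytest.raises(ValueError):
        fa.RobustWeightSpec("geman_mcclure", C=0.0)


def test_surface_feature_channels_band_masking(circle):
    grid = fa.GridGeometry.unit(2, 129)
    tgt = fa.make_shape(fa.ShapeSpec(family="ellipse", radii=(0.32, 0.27),
                                     resolution=256))
    channels, dist0 = fa.surface_feature_channels(circle, tgt, grid, b=0.1,
                                                  alpha=1.0, beta=0.5)
    assert [ch.name for ch in channels] == ["distance", "curvature"]
    assert channels[0].reference.values.max() <= 0.1
    # curvature is zeroed outside the band |I| < b - 2h
    h = grid.spacing[0]
    outside = ~band_mask(dist0, 0.1 - 2 * h)
    assert np.all(channels[1].reference.values[outside] == 0.0)
    assert np.any(channels[1].reference.values != 0.0)
    # the unbounded reference distance is returned for mesh refinement
    assert dist0.values.max() > 0.1


def test_feature_channel_grid_mismatch(circle):
    g1 = fa.GridGeometry.unit(2, 65)
    g2 = fa.GridGeometry.unit(2, 33)
    a = fa.signed_distance(circle, g1)
    b = fa.signed_distance(circle, g2)
    with pytest.raises(ValueError):
        fa.FeatureChannel(a, b)


def test_check_surface_margin(circle):
    grid = fa.GridGeometry.unit(2, 65)
    fa.check_surface_margin(circle, grid, 0.1)       # margin 0.2 >= 0.1
    with pytest.raises(ValueError):
        fa.check_surface_margin(circle, grid, 0.25)


def test_analytic_image_sampling_and_gradient():
    grid = fa.GridGeometry.unit(2, 17)
    img = fa.AnalyticImage(grid, lambda p: p[:, 0] ** 2,
                           (lambda p: 2 * p[:, 0], lambda p: 0 * p[:, 0]))
    pts = np.array([[0.3, 0.9], [0.7, 0.1]])
    assert np.allclose(img.sample(pts), [0.09, 0.49])
    gx, gy = img.gradient()
    assert np.allclose(gx.sample(pts), [0.6, 1.4])
    assert np.allclose(gy.sample(pts), 0.0)


def test_raster_gradient_channel_consistency_scale():
    """The precomputed grid gradient agrees with the interpolant derivative
    at the expected O(h^2) integrated scale on raster channels."""
    from fealign.energy import distance_gradient, distance_value

    basis = fa.DGBasis(fa.Tessellation.unit(2, 4), 1)
    grid = fa.GridGeometry.unit(2, 129)
    ref = fa.make_shape(fa.ShapeSpec(family="circle", radius=0.25,
                                     resolution=512))
    tgt = fa.make_shape(fa.ShapeSpec(family="ellipse", radii=(0.3, 0.22),
                                     resolution=512))
    channels, _ = fa.surface_feature_channels(ref, tgt, grid, b=0.1)
    u = fa.make_warp(fa.WarpSpec(type="gaussian_bumps", amplitude=0.03,
                                 scale=0.2, n_bumps=2, seed=3), basis)
    v = fa.make_warp(fa.WarpSpec(type="fourier_smooth", amplitude=0.05,
                                 frequency=2, seed=4), basis)
    eps = 1e-6
    up = fa.DGVectorField.from_flat(basis, u.flat + eps * v.flat)
    um = fa.DGVectorField.from_flat(basis, u.flat - eps * v.flat)
    fd = (distance_value(channels, up) - distance_value(channels, um)) / \
        (2 * eps)
    dd = float(distance_gradient(channels, u) @ v.flat)
    assert abs(dd - fd) / abs(fd) < 5e-3
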