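"""Synthetic data generator unit tests."""

import numpy as np
import pytest

import fealign as fa


# --------------------------------------------------------------------------
# shapes
# --------------------------------------------------------------------------

def test_generators_are_deterministic():
    spec = fa.ShapeSpec(family="blob3d", center=(0.5, 0.5, 0.5),
                        resolution=64, seed=5)
    a = fa.make_shape(spec)
    b = fa.make_shape(spec)
    assert np.array_equal(a.vertices, b.vertices)
    assert np.array_equal(a.cells, b.cells)
    w = fa.WarpSpec(type="gaussian_bumps", amplitude=0.05, seed=9)
    f = fa.warp_function(w, 2)
    pts = np.array([[0.3, 0.4], [0.6, 0.7]])
    assert np.array_equal(f(pts), fa.warp_function(w, 2)(pts))


def test_circle_and_ellipse_radii():
    c = fa.make_shape(fa.ShapeSpec(family="circle", radius=0.3,
                                   resolution=128))
    r = np.linalg.norm(c.vertices - 0.5, axis=1)
    assert np.abs(r - 0.3).max() < 1e-12
    e = fa.make_shape(fa.ShapeSpec(family="ellipse", radii=(0.3, 0.2),
                                   resolution=128))
    x, y = (e.vertices - 0.5).T
    assert np.abs((x / 0.3) ** 2 + (y / 0.2) ** 2 - 1.0).max() < 1e-12


def test_star_has_requested_spikes():
    spec = fa.ShapeSpec(family="star", radius=0.22, spikes=6,
                        spike_length=0.08, resolution=720)
    star = fa.make_shape(spec)
    r = np.linalg.norm(star.vertices - 0.5, axis=1)
    # count strict local maxima on the periodic radius profile
    peaks = np.sum((r > np.roll(r, 1)) & (r > np.roll(r, -1)))
    assert peaks == 6
    assert r.max() == pytest.approx(0.30, abs=5e-3)


def test_spike_tip_lies_on_contour():
    spec = fa.ShapeSpec(family="star", radius=0.22, spikes=5,
                        spike_length=0.1, resolution=1024)
    star = fa.make_shape(spec)
    for which in range(5):
        tip = fa.spike_tip(spec, which)
        gap = fa.distance_to_surface(star, tip[None], signed=False)[0]
        assert gap < 2e-3


def test_damaged_target_identical_away_from_damage():
    spec = fa.ShapeSpec(family="star", radius=0.22, spikes=5,
                        spike_length=0.1, spike_width=0.25, resolution=256)
    intact = fa.make_shape(spec)
    damaged = fa.make_damaged_target(spec, "remove_spike", which=0)
    assert len(damaged.vertices) == len(intact.vertices)
    # the removed spike is a Gaussian radial bump centred at angle 0: beyond
    # six angular widths its contribution is below length * exp(-18)
    theta = 2.0 * np.pi * np.arange(256) / 256
    far = np.abs(np.angle(np.exp(1j * theta))) > 6 * spec.spike_width
    assert np.abs(damaged.vertices[far] - intact.vertices[far]).max() < 1e-7
    near = np.abs(np.angle(np.exp(1j * theta))) < spec.spike_width
    assert np.abs(damaged.vertices[near] - intact.vertices[near]).max() > 0.01
    with pytest.raises(ValueError):
        fa.make_damaged_target(fa.ShapeSpec(family="circle"), "remove_spike")


def test_hand_fingers_within_sector():
    spec = fa.ShapeSpec(family="hand2d", radius=0.2, fingers=4,
                        finger_length=0.08, resolution=512)
    hand = fa.make_shape(spec)
    r = np.linalg.norm(hand.vertices - 0.5, axis=1)
    theta = np.arctan2(hand.vertices[:, 1] - 0.5, hand.vertices[:, 0] - 0.5)
    lo, hi = spec.finger_sector
    centers = np.linspace(lo, hi, spec.fingers)
    wrapped = np.abs(np.angle(np.exp(1j * (theta[:, None] - centers))))
    outside = wrapped.min(axis=1) > 6 * spec.spike_width
    assert np.abs(r[outside] - 0.2).max() < 1e-7
    on_finger = wrapped.min(axis=1) < 0.1
    assert r[on_finger].max() > 0.2 + 0.9 * spec.finger_length


def test_3d_shapes_are_closed():
    sphere = fa.make_shape(fa.ShapeSpec(family="sphere", resolution=96,
                                        center=(0.5, 0.5, 0.5)))
    assert sphere.is_closed()
    blob = fa.make_shape(fa.ShapeSpec(family="blob3d", resolution=96,
                                      center=(0.5, 0.5, 0.5), seed=1))
    assert blob.is_closed()


def test_unknown_family_rejected():
    with pytest.raises(ValueError):
        fa.make_shape(fa.ShapeSpec(family="torus"))


# --------------------------------------------------------------------------
# warps
# --------------------------------------------------------------------------

@pytest.mark.parametrize("spec", [
    fa.WarpSpec(type="gaussian_bumps", amplitude=0.4, scale=0.1, n_bumps=4,
                seed=2),
    fa.WarpSpec(type="fourier_smooth", amplitude=0.5, frequency=3, seed=3),
    fa.WarpSpec(type="dilation", rate=0.1),
])
def test_warps_stay_invertible(spec):
    """sup |grad u| < 0.5 guarantees x -> x + u(x) is a diffeomorphism."""
    f = fa.warp_function(spec, 2)
    rng = np.random.default_rng(0)
    pts = rng.uniform(0.0, 1.0, size=(400, 2))
    eps = 1e-5
    sup = 0.0
    for a in range(2):
        d = np.zeros(2)
        d[a] = eps
        g = (f(pts + d) - f(pts - d)) / (2 * eps)
        sup = max(sup, np.abs(g).max() * 2)   # crude row-sum bound
    assert sup < 1.0                           # |grad u|_inf < 0.5 per entry


def test_translation_and_dilation_warps_analytic():
    t = fa.warp_function(fa.WarpSpec(type="translation", shift=(0.05, -0.02)),
                         2)
    pts = np.array([[0.1, 0.9], [0.5, 0.5]])
    assert np.allclose(t(pts), [[0.05, -0.02]] * 2)
    d = fa.warp_function(fa.WarpSpec(type="dilation", rate=0.1,
                                     center=(0.5, 0.5)), 2)
    assert np.allclose(d(np.array([[0.7, 0.5]])), [[0.02, 0.0]])
    with pytest.raises(ValueError):
        fa.warp_function(fa.WarpSpec(type="swirl"), 2)


def test_make_warp_projects_analytic_field(coarse_basis_2d):
    spec = fa.WarpSpec(type="gaussian_bumps", amplitude=0.05, scale=0.25,
                       n_bumps=2, seed=4)
    u = fa.make_warp(spec, coarse_basis_2d)
    f = fa.warp_function(spec, 2)
    rng = np.random.default_rng(1)
    pts = rng.uniform(0.1, 0.9, size=(100, 2))
    # bilinear elements on an 8x8 mesh: O(h^2) projection error
    assert np.abs(u(pts) - f(pts)).max() < 5e-3


# --------------------------------------------------------------------------
# training populations
# --------------------------------------------------------------------------

def test_orthonormal_mode_fields(coarse_basis_2d):
    specs = [fa.WarpSpec(type="gaussian_bumps", amplitude=0.2, scale=0.2,
                         n_bumps=2, seed=s) for s in (11, 12, 13)]
    gs = fa.orthonormal_mode_fields(specs, coarse_basis_2d)
    for i, gi in enumerate(gs):
        for j, gj in enumerate(gs):
            assert gi.mass_inner(gj) == pytest.approx(float(i == j),
                                                      abs=1e-10)


def test_population_sample_statistics_exact(coarse_basis_2d):
    specs = [fa.WarpSpec(type="gaussian_bumps", amplitude=0.2, scale=0.2,
                         n_bumps=2, seed=s) for s in (11, 12)]
    fields, mean, gs = fa.make_training_population(
        None, specs, (4.0, 1.0), 20, coarse_basis_2d, seed=3, exact=True)
    data = np.stack([f.flat for f in fields])
    assert np.abs(data.mean(axis=0) - mean.flat).max() < 1e-12
    coeffs = np.stack([[g.mass_inner(f) for g in gs] for f in fields])
    cov = coeffs.T @ coeffs / 20
    assert np.allclose(cov, np.diag([4.0, 1.0]), atol=1e-10)


def test_population_iid_statistics_approximate(coarse_basis_2d):
    specs = [fa.WarpSpec(type="gaussian_bumps", amplitude=0.2, scale=0.2,
                         n_bumps=2, seed=s) for s in (11, 12)]
    fields, mean, gs = fa.make_training_population(
        None, specs, (4.0, 1.0), 400, coarse_basis_2d, seed=3)
    coeffs = np.stack([[g.mass_inner(f) for g in gs] for f in fields])
    cov = coeffs.T @ coeffs / 400
    assert np.allclose(cov, np.diag([4.0, 1.0]), atol=0.6)


def test_population_validation(coarse_basis_2d):
    with pytest.raises(ValueError):
        fa.make_training_population(None, [fa.WarpSpec()], (1.0, 2.0), 10,
                                    coarse_basis_2d)
    with pytest.raises(ValueError):
        fa.make_training_population(
            None, [fa.WarpSpec(type="translation", shift=(0.1, 0.0))],
            (1.0,), 1, coarse_basis_2d, exact=True)


def test_blurred_indicator_range(circle):
    grid = fa.GridGeometry.unit(2, 65)
    img = fa.blurred_indicator(circle, grid, width=0.03)
    assert img.values.min() >= 0.0 and img.values.max() <= 1.0
    center = img.sample(np.array([[0.5, 0.5]]))[0]
    outside = img.sample(np.array([[0.05, 0.05]]))[0]
    on_surface = img.sample(np.array([[0.8, 0.5]]))[0]
    assert center > 0.99 and outside < 0.01
    assert on_surface == pytest.approx(0.5, abs=0.05)
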