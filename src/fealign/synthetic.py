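"""Synthetic shapes, ground-truth warps and training populations.

Desk-scale stand-ins for anatomical data: closed 2D contours (circle,
ellipse, bump-star, schematic hand) and 3D meshes (sphere, smooth blob),
analytic smooth warps with a known invertibility margin, and training
populations with planted orthonormal deformation modes of known variances
so that model-recovery has an exact answer.  Every generator is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .basis import DGBasis, DGVectorField, interpolate_function
from .images import GridGeometry, RasterImage, Surface


# --------------------------------------------------------------------------
# shapes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeSpec:
    """Parametric closed shape.

    families: circle, ellipse (radii=(a, b)), star (radial Gaussian bumps
    equally spaced around the circle), hand2d (bumps confined to an angular
    sector, one per finger), sphere, blob3d (randomly perturbed sphere).
    """

    family: str = "circle"
    center: tuple[float, ...] = (0.5, 0.5)
    radius: float = 0.3
    radii: tuple[float, float] = (0.3, 0.2)
    spikes: int = 5
    spike_length: float = 0.08
    spike_width: float = 0.25          # angular width (radians)
    fingers: int = 5
    finger_length: float = 0.1
    finger_sector: tuple[float, float] = (0.35, 2.8)  # angular range (radians)
    resolution: int = 256
    seed: int = 0


def _radial_contour(spec: ShapeSpec,
                    radial: Callable[[np.ndarray], np.ndarray]) -> Surface:
    theta = 2.0 * np.pi * np.arange(spec.resolution) / spec.resolution
    r = radial(theta)
    c = np.asarray(spec.center)
    verts = c + np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    return Surface.closed_polyline(verts)


def _bump_profile(theta: np.ndarray, centers: Sequence[float],
                  length: float, width: float) -> np.ndarray:
    out = np.zeros_like(theta)
    for t0 in centers:
        d = np.angle(np.exp(1j * (theta - t0)))    # wrapped difference
        out += length * np.exp(-0.5 * (d / width) ** 2)
    return out


def _star_centers(spikes: int) -> list[float]:
    return [2.0 * np.pi * j / spikes for j in range(spikes)]


def _hand_centers(spec: ShapeSpec) -> list[float]:
    lo, hi = spec.finger_sector
    if spec.fingers == 1:
        return [0.5 * (lo + hi)]
    return list(np.linspace(lo, hi, spec.fingers))


def _uv_sphere(center: np.ndarray, radial: Callable[[np.ndarray, np.ndarray],
                                                    np.ndarray],
               n_theta: int, n_phi: int) -> Surface:
    """Closed lat-long triangulation with radius radial(polar, azimuth)."""
    verts = []
    # poles
    verts.append((0.0, 0.0))           # (polar, azimuth) placeholders
    ring_start = {}
    polar = np.linspace(0.0, np.pi, n_theta + 1)
    for i in range(1, n_theta):
        ring_start[i] = len(verts)
        for j in range(n_phi):
            verts.append((polar[i], 2.0 * np.pi * j / n_phi))
    south = len(verts)
    verts.append((np.pi, 0.0))
    ang = np.array(verts)
    r = radial(ang[:, 0], ang[:, 1])
    xyz = center + np.stack([
        r * np.sin(ang[:, 0]) * np.cos(ang[:, 1]),
        r * np.sin(ang[:, 0]) * np.sin(ang[:, 1]),
        r * np.cos(ang[:, 0])], axis=1)
    tris = []
    first = ring_start[1]
    for j in range(n_phi):
        tris.append((0, first + j, first + (j + 1) % n_phi))
    for i in range(1, n_theta - 1):
        a0, b0 = ring_start[i], ring_start[i + 1]
        for j in range(n_phi):
            j1 = (j + 1) % n_phi
            tris.append((a0 + j, b0 + j, b0 + j1))
            tris.append((a0 + j, b0 + j1, a0 + j1))
    last = ring_start[n_theta - 1]
    for j in range(n_phi):
        tris.append((south, last + (j + 1) % n_phi, last + j))
    return Surface(xyz, np.array(tris))


def make_shape(spec: ShapeSpec) -> Surface:
    """Generate a closed surface; deterministic given the spec (incl. seed)."""
    needed = 3 if spec.family in ("sphere", "blob3d") else 2
    if len(spec.center) != needed:
        raise ValueError(f"{spec.family} needs a {needed}-component center, "
                         f"got {spec.center}")
    if spec.family == "circle":
        return _radial_contour(spec, lambda t: np.full_like(t, spec.radius))
    if spec.family == "ellipse":
        a, b = spec.radii

        def radial(t):
            return a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
        return _radial_contour(spec, radial)
    if spec.family == "star":
        centers = _star_centers(spec.spikes)
        return _radial_contour(
            spec, lambda t: spec.radius + _bump_profile(
                t, centers, spec.spike_length, spec.spike_width))
    if spec.family == "hand2d":
        centers = _hand_centers(spec)
        return _radial_contour(
            spec, lambda t: spec.radius + _bump_profile(
                t, centers, spec.finger_length, spec.spike_width))
    if spec.family == "sphere":
        n = max(8, spec.resolution // 8)
        return _uv_sphere(np.asarray(spec.center),
                          lambda p, a: np.full_like(p, spec.radius), n, 2 * n)
    if spec.family == "blob3d":
        rng = np.random.default_rng(spec.seed)
        coef = rng.normal(0.0, 1.0, size=(3, 3, 2))

        def radial(p, a):
            out = np.full_like(p, spec.radius)
            for l in range(1, 3):
                for m in range(3):
                    out += 0.03 * spec.radius * (
                        coef[l, m, 0] * np.cos(m * a) +
                        coef[l, m, 1] * np.sin(m * a)) * np.cos(l * p)
            return out
        n = max(8, spec.resolution // 8)
        return _uv_sphere(np.asarray(spec.center), radial, n, 2 * n)
    raise ValueError(f"unknown shape family {spec.family!r}")


def spike_tip(spec: ShapeSpec, which: int = 0) -> np.ndarray:
    """Analytic position of a star spike / hand finger tip."""
    if spec.family == "star":
        t0 = _star_centers(spec.spikes)[which]
        r = spec.radius + spec.spike_length
    elif spec.family == "hand2d":
        t0 = _hand_centers(spec)[which]
        r = spec.radius + spec.finger_length
    else:
        raise ValueError("spike_tip only applies to star / hand2d shapes")
    return np.asarray(spec.center) + r * np.array([np.cos(t0), np.sin(t0)])


def make_damaged_target(spec: ShapeSpec, damage: str = "remove_spike",
                        which: int = 0) -> Surface:
    """Damaged variant of a star/hand: one spike/finger removed or flattened.

    The contour keeps the same angular sampling, so vertices outside the
    damage zone are identical to the intact shape's.
    """
    if spec.family not in ("star", "hand2d"):
        raise ValueError("damage model applies to star / hand2d shapes")
    if spec.family == "star":
        centers = _star_centers(spec.spikes)
        length = spec.spike_length
    else:
        centers = _hand_centers(spec)
        length = spec.finger_length
    if damage in ("remove_spike", "remove_finger"):
        kept = [c for i, c in enumerate(centers) if i != which]
    elif damage == "flatten_region":
        kept = [c for i, c in enumerate(centers) if i != which]
    else:
        raise ValueError(f"unknown damage mode {damage!r}")
    return _radial_contour(
        spec, lambda t: spec.radius + _bump_profile(
            t, kept, length, spec.spike_width))


# --------------------------------------------------------------------------
# warps
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WarpSpec:
    """Smooth analytic deformation field with invertibility margin.

    Generated amplitudes keep sup |grad u| < 0.5 so x -> x + u(x) is a
    diffeomorphism.
    """

    type: str = "translation"
    amplitude: float = 0.05
    shift: tuple[float, ...] = (0.05, 0.0)
    center: tuple[float, ...] = (0.5, 0.5)
    rate: float = 0.05                 # dilation: u = rate (x - center)
    scale: float = 0.15                # smoothness length scale
    n_bumps: int = 3
    frequency: int = 1
    seed: int = 0


def warp_function(spec: WarpSpec, dim: int) -> Callable[[np.ndarray], np.ndarray]:
    """Analytic callable u(points) -> (n, dim) for a warp spec."""
    if spec.type == "translation":
        shift = np.asarray(spec.shift, dtype=float)[:dim]

        def func(pts):
            return np.broadcast_to(shift, (len(pts), dim)).copy()
        return func
    if spec.type == "dilation":
        center = np.asarray(spec.center, dtype=float)[:dim]

        def func(pts):
            return spec.rate * (np.asarray(pts) - center)
        return func
    if spec.type == "gaussian_bumps":
        rng = np.random.default_rng(spec.seed)
        centers = rng.uniform(0.25, 0.75, size=(spec.n_bumps, dim))
        dirs = rng.normal(size=(spec.n_bumps, dim))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        amp = spec.amplitude / max(spec.n_bumps, 1)
        s = spec.scale
        # per-bump sup|grad| = amp/(s*sqrt(e)); keep the total under 0.5
        cap = 0.45 * s * np.sqrt(np.e) / max(spec.n_bumps, 1)
        amp = min(amp, cap)

        def func(pts):
            pts = np.asarray(pts)
            out = np.zeros((len(pts), dim))
            for c, d in zip(centers, dirs):
                r2 = np.sum((pts - c) ** 2, axis=1)
                out += amp * np.exp(-0.5 * r2 / s ** 2)[:, None] * d
            return out
        return func
    if spec.type == "fourier_smooth":
        rng = np.random.default_rng(spec.seed)
        k = spec.frequency
        coef = rng.normal(size=(dim,))
        coef /= np.abs(coef).sum()
        amp = min(spec.amplitude, 0.45 / (np.pi * k * dim))

        def func(pts):
            pts = np.asarray(pts)
            out = np.empty((len(pts), dim))
            for c in range(dim):
                f = np.ones(len(pts))
                for a in range(dim):
                    f *= np.sin(np.pi * k * pts[:, a]) if (a + c) % 2 == 0 \
                        else np.cos(np.pi * k * pts[:, a])
                out[:, c] = amp * coef[c] * f
            return out
        return func
    raise ValueError(f"unknown warp type {spec.type!r}")


def make_warp(spec: WarpSpec, basis: DGBasis) -> DGVectorField:
    """Sample an analytic warp into the DG space by L2 projection."""
    return interpolate_function(basis, warp_function(spec, basis.dim))


# --------------------------------------------------------------------------
# training populations with planted eigenstructure
# --------------------------------------------------------------------------

def orthonormal_mode_fields(mode_specs: Sequence[WarpSpec],
                            basis: DGBasis) -> list[DGVectorField]:
    """Project mode warps into V_h and Gram-Schmidt-orthonormalize them in
    the L2 (mass) inner product."""
    fields = [make_warp(s, basis) for s in mode_specs]
    out: list[DGVectorField] = []
    for f in fields:
        v = f.flat.copy()
        for g in out:
            v -= g.mass_inner(DGVectorField.from_flat(basis, v)) * g.flat
        cand = DGVectorField.from_flat(basis, v)
        norm = np.sqrt(cand.l2_norm_sq())
        if norm < 1e-12:
            raise ValueError("mode fields are linearly dependent in V_h")
        out.append(DGVectorField.from_flat(basis, v / norm))
    return out


def make_training_population(mean_spec: WarpSpec | None,
                             modes: Sequence[WarpSpec],
                             variances: Sequence[float], n: int,
                             basis: DGBasis, seed: int = 0,
                             exact: bool = False,
                             ) -> tuple[list[DGVectorField],
                                        DGVectorField,
                                        list[DGVectorField]]:
    """Fields u_i = mean + sum_j c_ij g_j with c_ij ~ N(0, variance_j).

    The g_j are L2-orthonormalized smooth fields, so the population has a
    known mean and known covariance eigenstructure.  With ``exact=True`` the
    drawn coefficients are centered and whitened so that their *sample* mean
    is exactly zero and their sample covariance (1/n normalization) is
    exactly diag(variances) -- the planted spectrum is then a property of
    the finite sample itself rather than of the infinite population, which
    removes the O(1/sqrt(n)) sampling error from recovery studies.  Returns
    (fields, mean field, orthonormal mode fields).
    """
    if len(modes) != len(variances):
        raise ValueError("need one variance per mode")
    rng = np.random.default_rng(seed)
    mean = make_warp(mean_spec, basis) if mean_spec is not None \
        else DGVectorField.zeros(basis)
    gs = orthonormal_mode_fields(modes, basis)
    sd = np.sqrt(np.asarray(variances, dtype=float))
    if exact:
        if n <= len(gs):
            raise ValueError("exact sample statistics need n > number of modes")
        raw = rng.normal(size=(n, len(gs)))
        raw -= raw.mean(axis=0)
        cov = raw.T @ raw / n
        chol = np.linalg.cholesky(cov)
        coeffs = np.linalg.solve(chol, raw.T).T * sd
    else:
        coeffs = rng.normal(size=(n, len(gs))) * sd
    fields = []
    for i in range(n):
        dofs = mean.flat.copy()
        for j, g in enumerate(gs):
            dofs = dofs + coeffs[i, j] * g.flat
        fields.append(DGVectorField.from_flat(basis, dofs))
    return fields, mean, gs


# --------------------------------------------------------------------------
# smooth intensity channel ("CT"-like)
# --------------------------------------------------------------------------

def blurred_indicator(surface: Surface, grid: GridGeometry,
                      width: float = 0.03) -> RasterImage:
    """Smooth inside-indicator image: 1 inside, 0 outside, smoothed over
    ``width`` -- a stand-in intensity channel for multi-feature tests."""
    from .images import signed_distance

    d = signed_distance(surface, grid)
    vals = 0.5 * (1.0 - np.tanh(d.values / max(width, 1e-9)))
    return RasterImage(grid, vals)
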