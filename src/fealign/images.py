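"""Feature images: signed distance, bounded distance, curvature, robust weights.

A closed surface is represented on a regular grid by its signed Euclidean
distance image (negative inside, zero on the surface).  Because the distance
image is zero on the whole surface it carries no tangential information, so a
curvature image -- the Laplacian of the distance image, which on the zero
level set equals the sum of the principal curvatures of the surface -- is
matched alongside it.  Additional scalar channels (e.g. CT-like intensities)
can be registered simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage


# --------------------------------------------------------------------------
# grid geometry and raster images
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridGeometry:
    """Node-centred regular grid in physical coordinates.

    Node ``i`` sits at ``origin + i * spacing`` (per axis); the grid covers
    the rectangular domain exactly, i.e. the domain is
    ``[origin, origin + (shape - 1) * spacing]``.
    """

    origin: tuple[float, ...]
    spacing: tuple[float, ...]
    shape: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.origin) == len(self.spacing) == len(self.shape)):
            raise ValueError("origin, spacing and shape must have equal length")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")
        if any(n < 2 for n in self.shape):
            raise ValueError("grid needs at least 2 nodes per axis")

    @property
    def dim(self) -> int:
        return len(self.shape)

    @property
    def upper(self) -> tuple[float, ...]:
        return tuple(o + (n - 1) * s
                     for o, s, n in zip(self.origin, self.spacing, self.shape))

    @property
    def extent(self) -> tuple[float, ...]:
        return tuple((n - 1) * s for s, n in zip(self.spacing, self.shape))

    def nodes(self) -> np.ndarray:
        """All grid nodes as an (n_nodes, dim) array (C order, axis 0 slowest)."""
        axes = [o + s * np.arange(n)
                for o, s, n in zip(self.origin, self.spacing, self.shape)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    @classmethod
    def unit(cls, dim: int, nodes_per_axis: int) -> "GridGeometry":
        """Uniform grid over the unit square/cube."""
        h = 1.0 / (nodes_per_axis - 1)
        return cls((0.0,) * dim, (h,) * dim, (nodes_per_axis,) * dim)


@dataclass
class RasterImage:
    """Scalar field sampled on a :class:`GridGeometry` (values indexed x-first)."""

    grid: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    @property
    def dim(self) -> int:
        return self.grid.dim

    def same_grid(self, other: "RasterImage") -> bool:
        return self.grid == other.grid

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Multilinear interpolation at physical ``points`` ((n, dim) array).

        Points outside the domain are clamped to the nearest boundary value,
        consistent with bounded distance images being constant near the
        domain boundary.
        """
        return sample_image(self, points)

    def gradient(self) -> list["RasterImage"]:
        """Central-difference gradient, one image per axis."""
        grads = np.gradient(self.values, *self.grid.spacing, edge_order=2)
        if self.dim == 1:
            grads = [grads]
        return [RasterImage(self.grid, g) for g in grads]


@dataclass
class AnalyticImage:
    """Scalar field given in closed form (with closed-form gradient).

    A drop-in alternative to :class:`RasterImage` for feature channels in
    ground-truth experiments: sampling and gradients are exact, so e.g.
    derivative checks of the registration functional see no
    image-representation error.  ``gradient_functions`` holds one callable
    per axis, each mapping (n, dim) points to values.
    """

    grid: GridGeometry
    function: "callable"
    gradient_functions: tuple = ()

    @property
    def dim(self) -> int:
        return self.grid.dim

    def same_grid(self, other) -> bool:
        return self.grid == other.grid

    def sample(self, points: np.ndarray) -> np.ndarray:
        return sample_image(self, points)

    def gradient(self) -> list["AnalyticImage"]:
        if len(self.gradient_functions) != self.dim:
            raise ValueError("analytic image needs one gradient callable "
                             "per axis")
        return [AnalyticImage(self.grid, g) for g in self.gradient_functions]


def sample_image(image, points: np.ndarray) -> np.ndarray:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if isinstance(image, AnalyticImage):
        return np.asarray(image.function(points), dtype=float)
    origin = np.asarray(image.grid.origin)
    spacing = np.asarray(image.grid.spacing)
    idx = (points - origin) / spacing          # index coordinates
    coords = [idx[:, a] for a in range(image.dim)]
    return ndimage.map_coordinates(image.values, coords, order=1, mode="nearest")


def warp_image(image: RasterImage, points: np.ndarray,
               displacements: np.ndarray) -> np.ndarray:
    """Sample ``image`` at the warped positions ``x + u(x)``."""
    return sample_image(image, np.asarray(points) + np.asarray(displacements))


# --------------------------------------------------------------------------
# surfaces
# --------------------------------------------------------------------------

@dataclass
class Surface:
    """Closed oriented polygonal surface.

    2D: ``vertices`` (n, 2) with ``cells`` (n, 2) consecutive segment indices
    of a closed polyline, counterclockwise = inside on the left.
    3D: ``vertices`` (n, 3) with ``cells`` (m, 3) triangle indices, outward
    orientation.
    """

    vertices: np.ndarray
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.cells = np.asarray(self.cells, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] not in (2, 3):
            raise ValueError("vertices must be an (n, 2) or (n, 3) array")

    @property
    def dim(self) -> int:
        return self.vertices.shape[1]

    def is_closed(self) -> bool:
        """Every edge (3D) / vertex (2D) must be shared by exactly two cells."""
        if self.dim == 2:
            counts = np.bincount(self.cells.ravel(), minlength=len(self.vertices))
            return bool(np.all(counts == 2))
        edges: dict[tuple[int, int], int] = {}
        for tri in self.cells:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (min(a, b), max(a, b))
                edges[key] = edges.get(key, 0) + 1
        return all(c == 2 for c in edges.values())

    @classmethod
    def closed_polyline(cls, vertices: np.ndarray) -> "Surface":
        """Build a 2D surface from an ordered list of polygon vertices."""
        vertices = np.asarray(vertices, dtype=float)
        n = len(vertices)
        cells = np.stack([np.arange(n), (np.arange(n) + 1) % n], axis=1)
        return cls(vertices, cells)


class OrientationUndefinedError(ValueError):
    """Raised when a signed distance is requested for an open surface."""


# --------------------------------------------------------------------------
# exact distance transforms
# --------------------------------------------------------------------------

def _point_segment_distance_sq(points: np.ndarray, a: np.ndarray,
                               b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        diff = points - a
        return np.einsum("ij,ij->i", diff, diff)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    diff = points - (a + t[:, None] * ab)
    return np.einsum("ij,ij->i", diff, diff)


def _inside_polygon(points: np.ndarray, vertices: np.ndarray,
                    cells: np.ndarray) -> np.ndarray:
    """Even-odd crossing test along the +x ray, vectorized over points."""
    inside = np.zeros(len(points), dtype=bool)
    px, py = points[:, 0], points[:, 1]
    for i, j in cells:
        x0, y0 = vertices[i]
        x1, y1 = vertices[j]
        crosses = (y0 > py) != (y1 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (px < xint)
    return inside


def _point_triangle_distance_sq(points: np.ndarray, a: np.ndarray,
                                b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Squared distance from each point to triangle abc (Ericson's region test)."""
    ab, ac = b - a, c - a
    ap = points - a
    d1 = ap @ ab
    d2 = ap @ ac
    bp = points - b
    d3 = bp @ ab
    d4 = bp @ ac
    cp = points - c
    d5 = cp @ ab
    d6 = cp @ ac
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    closest = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    def assign(mask: np.ndarray, value: np.ndarray) -> None:
        m = mask & ~done
        closest[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), np.broadcast_to(a, points.shape))
    assign((d3 >= 0) & (d4 <= d3), np.broadcast_to(b, points.shape))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t_ab[:, None] * ab)
    assign((d6 >= 0) & (d5 <= d6), np.broadcast_to(c, points.shape))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + t_ac[:, None] * ac)
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           b + t_bc[:, None] * (c - b))
    # interior projection
    s = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(s != 0, vb / s, 0.0)
        w = np.where(s != 0, vc / s, 0.0)
    assign(np.ones(len(points), dtype=bool),
           a + v[:, None] * ab + w[:, None] * ac)
    diff = points - closest
    return np.einsum("ij,ij->i", diff, diff)


# fixed, slightly skew ray direction: avoids hitting edges/vertices of
# axis-symmetric meshes from axis-aligned grid nodes
_RAY3D = np.array([0.8442669, 0.42346129, 0.32840366])
_RAY3D /= np.linalg.norm(_RAY3D)


def _inside_mesh(points: np.ndarray, vertices: np.ndarray,
                 cells: np.ndarray) -> np.ndarray:
    """Parity of ray crossings along a fixed skew direction (Moller-Trumbore)."""
    crossings = np.zeros(len(points), dtype=np.int64)
    d = _RAY3D
    eps = 1e-14
    for tri in cells:
        a, b, c = vertices[tri[0]], vertices[tri[1]], vertices[tri[2]]
        e1, e2 = b - a, c - a
        pvec = np.cross(d, e2)
        det = e1 @ pvec
        if abs(det) < eps:
            continue
        inv = 1.0 / det
        tvec = points - a
        u = (tvec @ pvec) * inv
        qvec = np.cross(tvec, e1)
        v = (qvec @ d) * inv
        t = (qvec @ e2) * inv
        crossings += ((u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)).astype(np.int64)
    return crossings % 2 == 1


def distance_to_surface(surface: Surface, points: np.ndarray,
                        signed: bool = True) -> np.ndarray:
    """Exact (un)signed Euclidean distance from ``points`` to the surface.

    The unsigned distance is the minimum over all point-to-segment (2D) or
    point-to-triangle (3D) distances; the sign comes from an even-odd ray
    parity test.  Raises :class:`OrientationUndefinedError` for an open
    surface when a signed distance is requested.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if signed and not surface.is_closed():
        raise OrientationUndefinedError(
            "orientation undefined: surface is not closed; "
            "request an unsigned distance instead")
    best = np.full(len(points), np.inf)
    if surface.dim == 2:
        for i, j in surface.cells:
            d2 = _point_segment_distance_sq(points, surface.vertices[i],
                                            surface.vertices[j])
            np.minimum(best, d2, out=best)
    else:
        for tri in surface.cells:
            d2 = _point_triangle_distance_sq(
                points, surface.vertices[tri[0]], surface.vertices[tri[1]],
                surface.vertices[tri[2]])
            np.minimum(best, d2, out=best)
    dist = np.sqrt(best)
    if not signed:
        return dist
    if surface.dim == 2:
        inside = _inside_polygon(points, surface.vertices, surface.cells)
    else:
        inside = _inside_mesh(points, surface.vertices, surface.cells)
    dist[inside] *= -1.0
    return dist


def signed_distance(surface: Surface, grid: GridGeometry,
                    signed: bool = True) -> RasterImage:
    """Signed distance image of a closed surface on ``grid`` (Euclidean,
    negative inside, zero on the surface)."""
    if surface.dim != grid.dim:
        raise ValueError("surface and grid dimension mismatch")
    values = distance_to_surface(surface, grid.nodes(), signed=signed)
    return RasterImage(grid, values.reshape(grid.shape))


def bound_distance(image: RasterImage, b: float) -> RasterImage:
    """Clip a distance image from above at ``b`` (idempotent).

    Only the upper tail is bounded; negative (inside) values pass through.
    """
    if b <= 0:
        raise ValueError("invalid bound: b must be positive")
    return RasterImage(image.grid, np.minimum(image.values, b))


def mean_curvature_image(image: RasterImage) -> RasterImage:
    """Discrete Laplacian of a distance image.

    Because |grad I| = 1 almost everywhere for a distance image, the
    Laplacian equals div(grad I / |grad I|): on the zero level set it is the
    sum of the principal curvatures of the surface ((d-1)/r for a sphere of
    radius r).  Boundary nodes use neighbour-replicated stencils.
    """
    v = image.values
    lap = np.zeros_like(v)
    for axis, h in enumerate(image.grid.spacing):
        padded = np.pad(v, [(1, 1) if a == axis else (0, 0)
                            for a in range(v.ndim)], mode="edge")
        lo = np.take(padded, range(0, v.shape[axis]), axis=axis)
        hi = np.take(padded, range(2, v.shape[axis] + 2), axis=axis)
        lap += (lo + hi - 2 * v) / h ** 2
    return RasterImage(image.grid, lap)


def band_mask(distance: RasterImage, width: float) -> np.ndarray:
    """Boolean mask of nodes with |I| < width."""
    return np.abs(distance.values) < width


# --------------------------------------------------------------------------
# robust weights and feature channels
# --------------------------------------------------------------------------

RobustMode = Literal["none", "geman_mcclure", "demons"]


@dataclass(frozen=True)
class RobustWeightSpec:
    """Robust weighting of a channel's squared residual.

    geman_mcclure: Q = C^2 + residual^2 (C in the channel's units controls
    robustness); demons: Q = |grad X1(x+u)|^2 + residual^2; none: Q = 1.
    """

    mode: RobustMode = "none"
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "geman_mcclure", "demons"):
            raise ValueError(f"unknown robust mode {self.mode!r}")
        if self.mode != "none" and self.C <= 0:
            raise ValueError("robustness parameter C must be positive")


def robust_weight(spec: RobustWeightSpec, residual: np.ndarray,
                  grad_warped: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the robust weight field Q for given residuals.

    ``grad_warped`` holds the warped target gradient vectors (n, d); it is
    required only in demons mode.
    """
    residual = np.asarray(residual, dtype=float)
    if spec.mode == "none":
        return np.ones_like(residual)
    if spec.mode == "geman_mcclure":
        return spec.C ** 2 + residual ** 2
    if grad_warped is None:
        raise ValueError("demons mode requires the warped image gradient")
    gnorm2 = np.einsum("ij,ij->i", grad_warped, grad_warped)
    q = gnorm2 + residual ** 2
    # where gradient and residual both vanish (flat far field) the weighted
    # residual term is 0/0; the limit is 0, realized by an infinite weight
    q[q == 0.0] = np.inf
    return q


@dataclass
class FeatureChannel:
    """A matched pair of feature images with weight and robustness spec."""

    reference: RasterImage
    target: RasterImage
    weight: float = 1.0
    robust: RobustWeightSpec = field(default_factory=RobustWeightSpec)
    name: str = "feature"

    # central-difference gradient of the target, cached on first use;
    # the gradient images themselves are warped (sampled at x + u)
    _target_gradient: list[RasterImage] | None = None

    def __post_init__(self) -> None:
        if not self.reference.same_grid(self.target):
            raise ValueError(f"channel {self.name!r}: reference and target "
                             "must share the grid geometry")
        if self.weight < 0:
            raise ValueError("channel weight must be nonnegative")

    @property
    def target_gradient(self) -> list[RasterImage]:
        if self._target_gradient is None:
            self._target_gradient = self.target.gradient()
        return self._target_gradient


def surface_feature_channels(reference: Surface, target: Surface,
                             grid: GridGeometry, b: float,
                             alpha: float = 1.0, beta: float = 0.0,
                             robust: RobustWeightSpec | None = None,
                             curvature_robust: RobustWeightSpec | None = None,
                             ) -> tuple[list[FeatureChannel], RasterImage]:
    """Build distance (+ optional curvature) channels for a surface pair.

    Returns the channels and the reference's unbounded distance image (used
    for mesh refinement).  Curvature is computed from the *unbounded*
    distance image, then masked to the band |I| < b - 2h and set to zero
    outside -- bounding first would create an artificial kink at |I| = b.
    """
    if b <= 0:
        raise ValueError("invalid bound: b must be positive")
    d0 = signed_distance(reference, grid)
    d1 = signed_distance(target, grid)
    channels = [FeatureChannel(bound_distance(d0, b), bound_distance(d1, b),
                               weight=alpha,
                               robust=robust or RobustWeightSpec(),
                               name="distance")]
    if beta > 0:
        hmax = max(grid.spacing)
        width = max(b - 2 * hmax, hmax)
        h0 = mean_curvature_image(d0)
        h1 = mean_curvature_image(d1)
        m0 = np.where(band_mask(d0, width), h0.values, 0.0)
        m1 = np.where(band_mask(d1, width), h1.values, 0.0)
        channels.append(FeatureChannel(
            RasterImage(grid, m0), RasterImage(grid, m1), weight=beta,
            robust=curvature_robust or RobustWeightSpec(),
            name="curvature"))
    return channels, d0


def check_surface_margin(surface: Surface, grid: GridGeometry,
                         b: float) -> None:
    """Verify the surface lies inside the domain with margin >= b."""
    lo = np.asarray(grid.origin)
    hi = np.asarray(grid.upper)
    vmin = surface.vertices.min(axis=0)
    vmax = surface.vertices.max(axis=0)
    if np.any(vmin - lo < b) or np.any(hi - vmax < b):
        raise ValueError(
            f"surface must lie inside the domain with margin >= b={b}")
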