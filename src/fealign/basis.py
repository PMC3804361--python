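"""Per-element orthonormal polynomial bases and DG vector fields.

Each element T carries a tensor-product Legendre basis scaled so that
``int_T phi_a . phi_b = |T| delta_ab``; the global mass matrix is therefore
exactly diagonal with entries |T|, which makes the functional-PCA weighting
of the statistical prior cheap.  Fields are globally discontinuous.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
import hashlib

import numpy as np
from numpy.polynomial import legendre as npleg

from .mesh import Tessellation


# --------------------------------------------------------------------------
# reference-element tables (unit cube [0,1]^d)
# --------------------------------------------------------------------------

def _legendre_1d(q: int, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Values and derivatives of shifted Legendre polynomials on [0,1].

    ``L_k(x) = sqrt(2k+1) P_k(2x-1)`` so that int_0^1 L_j L_k = delta_jk.
    Returns arrays of shape (n_pts, q+1).
    """
    x = np.asarray(pts)
    vals = np.empty((len(x), q + 1))
    ders = np.empty((len(x), q + 1))
    for k in range(q + 1):
        c = np.zeros(k + 1)
        c[k] = np.sqrt(2 * k + 1)
        vals[:, k] = npleg.legval(2 * x - 1, c)
        ders[:, k] = 2 * npleg.legval(2 * x - 1, npleg.legder(c))
    return vals, ders


def gauss_points(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on [0,1]."""
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


@lru_cache(maxsize=None)
def tensor_quadrature(dim: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor Gauss rule on the unit cube: points (n^dim, dim), weights (n^dim,)."""
    x1, w1 = gauss_points(n)
    grids = np.meshgrid(*([x1] * dim), indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=-1)
    wgrids = np.meshgrid(*([w1] * dim), indexing="ij")
    w = np.ones(len(pts))
    for g in wgrids:
        w *= g.ravel()
    return pts, w


def _mode_indices(dim: int, q: int) -> np.ndarray:
    """Tensor-product multi-indices, shape ((q+1)^dim, dim)."""
    return np.array(list(np.ndindex(*([q + 1] * dim))), dtype=int)


def eval_modes(dim: int, q: int, ref_points: np.ndarray,
               derivatives: bool = False):
    """Evaluate the orthonormal reference basis at points in [0,1]^dim.

    Returns ``vals`` of shape (n_pts, n_modes) and, if requested, ``grads``
    of shape (dim, n_pts, n_modes) (reference-coordinate derivatives).
    """
    ref_points = np.atleast_2d(ref_points)
    modes = _mode_indices(dim, q)
    per_axis = []
    for a in range(dim):
        v, d = _legendre_1d(q, ref_points[:, a])
        per_axis.append((v, d))
    vals = np.ones((len(ref_points), len(modes)))
    for a in range(dim):
        vals *= per_axis[a][0][:, modes[:, a]]
    if not derivatives:
        return vals
    grads = np.empty((dim, len(ref_points), len(modes)))
    for da in range(dim):
        g = np.ones((len(ref_points), len(modes)))
        for a in range(dim):
            table = per_axis[a][1] if a == da else per_axis[a][0]
            g *= table[:, modes[:, a]]
        grads[da] = g
    return vals, grads


# --------------------------------------------------------------------------
# DG basis over a tessellation
# --------------------------------------------------------------------------

class DGBasis:
    """Vector-valued discontinuous space [Q_q(T)]^d over a tessellation.

    DOF layout: ``dofs[e, c, m]`` with element e, component c and scalar
    mode m; flattened C-order for linear algebra, N = s * d * (q+1)^d.
    """

    def __init__(self, mesh: Tessellation, order: int = 1):
        if order < 0:
            raise ValueError("polynomial order must be nonnegative")
        self.mesh = mesh
        self.order = order
        self.dim = mesh.dim
        self.n_modes = (order + 1) ** self.dim
        self.r = self.dim * self.n_modes          # vector DOFs per element
        self.n_dofs = mesh.n_elements * self.r

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.mesh.n_elements, self.dim, self.n_modes)

    def fingerprint(self) -> str:
        """Hash of mesh + order; identifies the basis for model files."""
        h = hashlib.sha256()
        h.update(np.asarray(self.mesh.origin).tobytes())
        h.update(np.asarray(self.mesh.size).tobytes())
        h.update(repr(self.mesh.leaves).encode())
        h.update(str(self.order).encode())
        return h.hexdigest()

    # -- mass matrix -------------------------------------------------------

    def mass_diagonal(self) -> np.ndarray:
        """Diagonal of the (exactly diagonal) mass matrix, length N."""
        return np.repeat(self.mesh.measures, self.r)

    # -- quadrature --------------------------------------------------------

    def volume_quadrature(self, n_points: int | None = None):
        """Per-element tensor Gauss rule in physical coordinates.

        Returns (points, weights, basis_vals) with points of shape
        (s, n_q, dim), weights (s, n_q) including |T|, and reference basis
        values (n_q, n_modes) shared by all elements.
        """
        n = n_points if n_points is not None else self.order + 1
        ref_pts, ref_w = tensor_quadrature(self.dim, n)
        corners = self.mesh.corners[:, None, :]
        widths = self.mesh.widths[:, None, :]
        points = corners + widths * ref_pts[None, :, :]
        weights = self.mesh.measures[:, None] * ref_w[None, :]
        vals = eval_modes(self.dim, self.order, ref_pts)
        return points, weights, vals

    def reference_gradients(self, n_points: int | None = None) -> np.ndarray:
        n = n_points if n_points is not None else self.order + 1
        ref_pts, _ = tensor_quadrature(self.dim, n)
        _, grads = eval_modes(self.dim, self.order, ref_pts, derivatives=True)
        return grads   # (dim, n_q, n_modes); physical grad = ref / width[axis]

    # -- point evaluation --------------------------------------------------

    def local_coords(self, points: np.ndarray, elements: np.ndarray) -> np.ndarray:
        corners = self.mesh.corners[elements]
        widths = self.mesh.widths[elements]
        return (points - corners) / widths


@dataclass
class DGVectorField:
    """A deformation (or test) field as DOFs over a :class:`DGBasis`."""

    basis: DGBasis
    dofs: np.ndarray

    def __post_init__(self) -> None:
        self.dofs = np.asarray(self.dofs, dtype=float).reshape(self.basis.shape)

    @classmethod
    def zeros(cls, basis: DGBasis) -> "DGVectorField":
        return cls(basis, np.zeros(basis.shape))

    @classmethod
    def from_flat(cls, basis: DGBasis, flat: np.ndarray) -> "DGVectorField":
        return cls(basis, np.asarray(flat, dtype=float))

    @property
    def flat(self) -> np.ndarray:
        return self.dofs.reshape(-1)

    def copy(self) -> "DGVectorField":
        return DGVectorField(self.basis, self.dofs.copy())

    # -- evaluation --------------------------------------------------------

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Evaluate at arbitrary physical points, shape (n, d)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        elems = self.basis.mesh.locate(points)
        xi = self.basis.local_coords(points, elems)
        vals = eval_modes(self.basis.dim, self.basis.order, xi)  # (n, modes)
        return np.einsum("ncm,nm->nc", self.dofs[elems], vals)

    def at_quadrature(self, basis_vals: np.ndarray) -> np.ndarray:
        """Values at the shared per-element quadrature points, (s, n_q, d)."""
        return np.einsum("ecm,qm->eqc", self.dofs, basis_vals)

    def gradient_at_quadrature(self, ref_grads: np.ndarray) -> np.ndarray:
        """Physical gradients d u_c / d x_a at quadrature points, (s, n_q, d, d).

        Index order: [element, point, component c, derivative axis a].
        """
        g = np.einsum("ecm,aqm->eqca", self.dofs, ref_grads)
        return g / self.basis.mesh.widths[:, None, None, :]

    # -- norms -------------------------------------------------------------

    def l2_norm_sq(self) -> float:
        """Exact squared L2 norm via the diagonal mass matrix."""
        m = self.basis.mass_diagonal()
        return float(self.flat @ (m * self.flat))

    def mass_inner(self, other: "DGVectorField") -> float:
        m = self.basis.mass_diagonal()
        return float(self.flat @ (m * other.flat))


def interpolate_function(basis: DGBasis, func) -> DGVectorField:
    """L2-project an analytic vector field ``func(points) -> (n, d)`` into V_h.

    Uses an order+2 point Gauss rule per element; exact for polynomials of
    degree <= order+1 per axis, a good projection for smooth fields.
    """
    n = basis.order + 2
    pts, w, vals = basis.volume_quadrature(n)
    s, n_q, _ = pts.shape
    f = np.asarray(func(pts.reshape(-1, basis.dim))).reshape(s, n_q, basis.dim)
    # coeff_m = (1/|T|) int_T f_c phi_m
    coef = np.einsum("eq,eqc,qm->ecm", w, f, vals) / \
        basis.mesh.measures[:, None, None]
    return DGVectorField(basis, coef)


def prolong(field: DGVectorField, new_basis: DGBasis) -> DGVectorField:
    """L2-project a field onto a (nested) refinement of its mesh.

    Exact for the piecewise polynomials of the coarse space whenever each
    new element is contained in an old element (pure refinement).
    """
    old = field.basis
    if new_basis.dim != old.dim:
        raise ValueError("dimension mismatch")
    q = max(old.order, new_basis.order)
    n = q + 1
    pts, w, vals = new_basis.volume_quadrature(n)
    s, n_q, _ = pts.shape
    flat_pts = pts.reshape(-1, old.dim)
    elems = old.mesh.locate(flat_pts)
    xi = old.local_coords(flat_pts, elems)
    old_vals = eval_modes(old.dim, old.order, xi)
    f = np.einsum("ncm,nm->nc", field.dofs[elems], old_vals)
    f = f.reshape(s, n_q, old.dim)
    coef = np.einsum("eq,eqc,qm->ecm", w, f, vals) / \
        new_basis.mesh.measures[:, None, None]
    return DGVectorField(new_basis, coef)
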