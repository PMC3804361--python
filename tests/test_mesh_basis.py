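"""Tessellation, DG basis and field unit tests."""

import numpy as np
import pytest

import fealign as fa
from fealign.basis import eval_modes, interpolate_function, prolong, \
    tensor_quadrature
from fealign.mesh import Tessellation


# --------------------------------------------------------------------------
# tessellation
# --------------------------------------------------------------------------

def test_uniform_mesh_counts_and_measures():
    mesh = Tessellation.unit(2, 3)
    assert mesh.n_elements == 64
    assert mesh.measures.sum() == pytest.approx(1.0)
    mesh3 = Tessellation.unit(3, 2)
    assert mesh3.n_elements == 64
    assert mesh3.measures.sum() == pytest.approx(1.0)


def test_refine_single_element_adds_children():
    mesh = Tessellation.unit(2, 2)
    flags = np.zeros(mesh.n_elements, dtype=bool)
    flags[5] = True
    fine = mesh.refine(flags)
    assert fine.n_elements == mesh.n_elements - 1 + 4
    assert fine.measures.sum() == pytest.approx(1.0)


def _is_two_one_balanced(mesh):
    """Brute-force 2:1 check: any two face-adjacent leaves differ by <= 1 level."""
    for i in range(mesh.n_elements):
        for j in range(i + 1, mesh.n_elements):
            if abs(int(mesh.levels[i]) - int(mesh.levels[j])) <= 1:
                continue
            lo_i = mesh.corners[i]
            hi_i = lo_i + mesh.widths[i]
            lo_j = mesh.corners[j]
            hi_j = lo_j + mesh.widths[j]
            touch = np.isclose(hi_i, lo_j) | np.isclose(hi_j, lo_i)
            overlap = (np.minimum(hi_i, hi_j) - np.maximum(lo_i, lo_j)) > 1e-12
            # face-adjacent: touching on one axis, overlapping on the others
            for ax in range(mesh.dim):
                if touch[ax] and all(overlap[a] for a in range(mesh.dim)
                                     if a != ax):
                    return False
    return True


def test_refinement_closure_restores_balance():
    mesh = Tessellation.unit(2, 2)
    # refine one corner element twice: the neighbours must follow
    for _ in range(3):
        flags = np.zeros(mesh.n_elements, dtype=bool)
        flags[int(np.argmin(mesh.measures))] = True
        mesh = mesh.refine(flags)
    assert _is_two_one_balanced(mesh)
    assert mesh.measures.sum() == pytest.approx(1.0)


def test_locate_returns_containing_element():
    mesh = Tessellation.unit(2, 2)
    flags = np.zeros(mesh.n_elements, dtype=bool)
    flags[:4] = True
    mesh = mesh.refine(flags)
    rng = np.random.default_rng(0)
    pts = rng.uniform(0.0, 1.0, size=(100, 2))
    elems = mesh.locate(pts)
    lo = mesh.corners[elems]
    hi = lo + mesh.widths[elems]
    assert np.all((pts >= lo - 1e-12) & (pts <= hi + 1e-12))


def test_interior_faces_of_uniform_mesh():
    mesh = Tessellation.unit(2, 2)      # 4x4
    interior = [f for f in mesh.faces if not f.is_boundary]
    boundary = [f for f in mesh.faces if f.is_boundary]
    assert len(interior) == 2 * 4 * 3
    assert len(boundary) == 4 * 4
    for f in interior:
        # minus element sits on the lower side along the face axis
        assert mesh.centers[f.minus][f.axis] < f.center[f.axis]
        assert mesh.centers[f.plus][f.axis] > f.center[f.axis]


def test_nonconforming_faces_use_fine_partition():
    mesh = Tessellation.unit(2, 1)      # 2x2
    flags = np.array([True, False, False, False])
    mesh = mesh.refine(flags)
    interior = [f for f in mesh.faces if not f.is_boundary]
    # hanging faces: the coarse neighbour appears in two half-faces
    halves = [f for f in interior
              if mesh.levels[f.minus] != mesh.levels[f.plus]]
    assert len(halves) == 4
    for f in halves:
        fine = f.minus if mesh.levels[f.minus] > mesh.levels[f.plus] \
            else f.plus
        assert np.allclose(2.0 * np.asarray(f.halfwidth).max(),
                           mesh.widths[fine].max())


# --------------------------------------------------------------------------
# basis
# --------------------------------------------------------------------------

def test_reference_basis_orthonormal():
    pts, w = tensor_quadrature(2, 4)
    vals = eval_modes(2, 2, pts)
    gram = np.einsum("q,qm,qn->mn", w, vals, vals)
    assert np.abs(gram - np.eye(vals.shape[1])).max() < 1e-12


def test_mass_diagonal_matches_quadrature_gram(coarse_basis_2d):
    basis = coarse_basis_2d
    _, w, vals = basis.volume_quadrature(3)
    gram = np.einsum("eq,qm,qn->emn", w, vals, vals)
    expected = basis.mesh.measures[:, None, None] * np.eye(basis.n_modes)
    assert np.abs(gram - expected).max() < 1e-14
    m = basis.mass_diagonal()
    assert m.shape == (basis.n_dofs,)
    assert np.allclose(m.reshape(basis.shape)[:, 0, 0], basis.mesh.measures)


def test_interpolation_reproduces_affine_fields(coarse_basis_2d):
    def f(pts):
        return np.stack([1.0 + 2.0 * pts[:, 0] - pts[:, 1],
                         0.5 * pts[:, 0] + 3.0 * pts[:, 1]], axis=1)

    u = interpolate_function(coarse_basis_2d, f)
    rng = np.random.default_rng(1)
    pts = rng.uniform(0.0, 1.0, size=(100, 2))
    assert np.abs(u(pts) - f(pts)).max() < 1e-12


def test_field_evaluation_matches_quadrature_path(coarse_basis_2d):
    u = fa.make_warp(fa.WarpSpec(type="gaussian_bumps", amplitude=0.1,
                                 scale=0.2, n_bumps=2, seed=2),
                     coarse_basis_2d)
    pts, _, vals = coarse_basis_2d.volume_quadrature()
    uq = u.at_quadrature(vals)
    direct = u(pts.reshape(-1, 2)).reshape(uq.shape)
    assert np.abs(uq - direct).max() < 1e-12


def test_gradient_at_quadrature_exact_for_affine(coarse_basis_2d):
    def f(pts):
        return np.stack([2.0 * pts[:, 0] + 3.0 * pts[:, 1],
                         -pts[:, 0] + 0.5 * pts[:, 1]], axis=1)

    u = interpolate_function(coarse_basis_2d, f)
    g = u.gradient_at_quadrature(coarse_basis_2d.reference_gradients())
    expected = np.array([[2.0, 3.0], [-1.0, 0.5]])
    assert np.abs(g - expected).max() < 1e-12


def test_prolong_exact_on_nested_refinement(coarse_basis_2d):
    u = interpolate_function(
        coarse_basis_2d,
        lambda p: np.stack([p[:, 0] * p[:, 1], p[:, 0] - p[:, 1]], axis=1))
    mesh = coarse_basis_2d.mesh
    flags = np.zeros(mesh.n_elements, dtype=bool)
    flags[::3] = True
    fine = fa.DGBasis(mesh.refine(flags), 1)
    v = prolong(u, fine)
    rng = np.random.default_rng(4)
    pts = rng.uniform(0.0, 1.0, size=(200, 2))
    assert np.abs(v(pts) - u(pts)).max() < 1e-12
    assert v.l2_norm_sq() == pytest.approx(u.l2_norm_sq(), rel=1e-12)


def test_fingerprint_distinguishes_meshes_and_orders():
    b1 = fa.DGBasis(Tessellation.unit(2, 2), 1)
    b2 = fa.DGBasis(Tessellation.unit(2, 3), 1)
    b3 = fa.DGBasis(Tessellation.unit(2, 2), 2)
    assert b1.fingerprint() != b2.fingerprint()
    assert b1.fingerprint() != b3.fingerprint()
    assert b1.fingerprint() == fa.DGBasis(Tessellation.unit(2, 2), 1).fingerprint()


def test_dof_counts_3d(coarse_basis_3d):
    assert coarse_basis_3d.n_modes == 8
    assert coarse_basis_3d.r == 24
    assert coarse_basis_3d.n_dofs == 64 * 24
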