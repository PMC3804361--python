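"""Discontinuous Galerkin assembly of the elastic operator -mu*Lap - nu*grad div.

The second-order operator is treated in first-order (flux) form: the flux
tensor is sigma(u) = mu*grad(u) + nu*div(u)*I, coupled across elements by
central averages on faces, with an interior-penalty stabilization eta/h_F on
the jumps and one-sided fluxes encoding homogeneous Dirichlet data at the
domain boundary.  The resulting matrix is symmetric, positive definite (with
the boundary terms), consistent, and has an element + face-neighbour stencil;
nonconforming (hanging-node) faces are integrated on the finer face partition.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .basis import DGBasis, eval_modes, tensor_quadrature, gauss_points
from .mesh import Face


def default_penalty(order: int, mu: float, nu: float) -> float:
    """Stabilization coefficient eta = 4 q^2 (mu + nu), applied as eta/h_F."""
    return 4.0 * max(order, 1) ** 2 * (mu + nu)


def _face_quadrature(dim: int, n: int):
    """Gauss rule on the unit (d-1)-cube: points ((n^(d-1)), d-1), weights."""
    if dim == 1:
        return np.zeros((1, 0)), np.ones(1)
    return tensor_quadrature(dim - 1, n)


def assemble_elliptic(basis: DGBasis, mu: float, nu: float,
                      penalty: float | None = None) -> sparse.csr_matrix:
    """Assemble the DG matrix of the operator -mu*Lap(u) - nu*grad(div u).

    ``penalty`` is the jump-stabilization coefficient eta (default
    ``4 q^2 (mu + nu)``); pass 0.0 for the pure central-flux scheme.
    Returns an N x N sparse symmetric matrix acting on flattened DOFs.
    """
    if mu <= 0:
        raise ValueError("mu must be positive (problem is ill-posed otherwise)")
    if nu < 0:
        raise ValueError("nu must be nonnegative")
    eta = default_penalty(basis.order, mu, nu) if penalty is None else penalty

    mesh = basis.mesh
    d = basis.dim
    q = basis.order
    n_modes = basis.n_modes
    r = basis.r

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    # ---- volume terms: int_T mu grad(u):grad(v) + nu div(u) div(v) -------
    nq = q + 1
    ref_pts, ref_w = tensor_quadrature(d, nq)
    _, ref_grads = eval_modes(d, q, ref_pts, derivatives=True)  # (d, nq, m)
    # per element, physical gradient scale 1/width[axis]; measure |T|
    for e in range(mesh.n_elements):
        w = mesh.widths[e]
        meas = mesh.measures[e]
        G = ref_grads / w[:, None, None]           # (d, nq, m) physical
        # scalar stiffness: S[a,b][mi,mj] = int gradients; grad(u):grad(v)
        # couples equal components only
        S = np.einsum("q,aqm,aqn->mn", ref_w, G, G) * meas
        K = np.zeros((r, r))
        for c in range(d):
            sl = slice(c * n_modes, (c + 1) * n_modes)
            K[sl, sl] += mu * S
        # divergence term couples components: int (d_cu u_cu)(d_cv v_cv)
        D = np.einsum("q,aqm,bqn->abmn", ref_w, G, G) * meas
        for cu in range(d):
            for cv in range(d):
                K[cv * n_modes:(cv + 1) * n_modes,
                  cu * n_modes:(cu + 1) * n_modes] += nu * D[cv, cu]
        idx = e * r + np.arange(r)
        rr, cc = np.meshgrid(idx, idx, indexing="ij")
        rows.append(rr.ravel()); cols.append(cc.ravel()); vals.append(K.ravel())

    # ---- face terms ------------------------------------------------------
    fq_ref, fq_w = _face_quadrature(d, q + 1)
    for face in mesh.faces:
        _assemble_face(basis, face, mu, nu, eta, fq_ref, fq_w,
                       rows, cols, vals)

    n = basis.n_dofs
    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n)).tocsr()
    return mat


def _face_basis(basis: DGBasis, e: int, points: np.ndarray):
    """Trace values and physical gradients of element e's basis at points."""
    mesh = basis.mesh
    xi = (points - mesh.corners[e]) / mesh.widths[e]
    xi = np.clip(xi, 0.0, 1.0)
    vals, grads = eval_modes(basis.dim, basis.order, xi, derivatives=True)
    grads = grads / mesh.widths[e][:, None, None]
    return vals, grads


def _assemble_face(basis: DGBasis, face: Face, mu: float, nu: float,
                   eta: float, fq_ref: np.ndarray, fq_w: np.ndarray,
                   rows, cols, vals) -> None:
    mesh = basis.mesh
    d = basis.dim
    n_modes = basis.n_modes
    r = basis.r
    a = face.axis

    # physical quadrature points on the face rectangle
    tang = [ax for ax in range(d) if ax != a]
    center = np.asarray(face.center)
    half = np.asarray(face.halfwidth)
    pts = np.tile(center, (len(fq_ref), 1))
    for t_i, ax in enumerate(tang):
        pts[:, ax] = center[ax] + (2.0 * fq_ref[:, t_i] - 1.0) * half[ax]
    area = float(np.prod([2.0 * half[ax] for ax in tang])) if tang else 1.0
    w = fq_w * area

    if face.is_boundary:
        e = face.minus
        s = float(face.normal_sign)
        h_f = mesh.widths[e][a]
        T, G = _face_basis(basis, e, pts)
        K = _face_block(T, G, T, G, a, d, n_modes, mu, nu, w,
                        sign_u=1.0, sign_v=1.0, wt_u=s, wt_v=s,
                        eta_over_h=eta / h_f)
        idx = e * r + np.arange(r)
        rr, cc = np.meshgrid(idx, idx, indexing="ij")
        rows.append(rr.ravel()); cols.append(cc.ravel()); vals.append(K.ravel())
        return

    em, ep = face.minus, face.plus
    h_f = min(mesh.widths[em][a], mesh.widths[ep][a])
    Tm, Gm = _face_basis(basis, em, pts)
    Tp, Gp = _face_basis(basis, ep, pts)
    sides = {em: (Tm, Gm, +1.0), ep: (Tp, Gp, -1.0)}
    for eu, (Tu, Gu, su) in sides.items():
        for ev, (Tv, Gv, sv) in sides.items():
            K = _face_block(Tv, Gv, Tu, Gu, a, d, n_modes, mu, nu, w,
                            sign_u=su, sign_v=sv, wt_u=0.5, wt_v=0.5,
                            eta_over_h=eta / h_f)
            iv = ev * r + np.arange(r)
            iu = eu * r + np.arange(r)
            rr, cc = np.meshgrid(iv, iu, indexing="ij")
            rows.append(rr.ravel()); cols.append(cc.ravel())
            vals.append(K.ravel())


def _face_block(Tv, Gv, Tu, Gu, axis, d, n_modes, mu, nu, w,
                sign_u, sign_v, wt_u, wt_v, eta_over_h) -> np.ndarray:
    """Local face matrix K[(cv,mv),(cu,mu)] for one (side_v, side_u) pair.

    Terms: -{sigma(u) n}.[v] - {sigma(v) n}.[u] + (eta/h)[u].[v], with
    jump signs ``sign_*`` and average/one-sided weights ``wt_*``.
    """
    r = d * n_modes
    K = np.zeros((r, r))

    # -mu {d_a u_c} [v_c]   (equal components)
    A = -mu * wt_u * sign_v * np.einsum("q,qm,qn->mn", w, Tv, Gu[axis])
    # symmetric counterpart: -mu {d_a v_c} [u_c]
    B = -mu * wt_v * sign_u * np.einsum("q,qm,qn->mn", w, Gv[axis], Tu)
    # penalty (equal components)
    P = eta_over_h * sign_u * sign_v * np.einsum("q,qm,qn->mn", w, Tv, Tu)
    for c in range(d):
        sl = slice(c * n_modes, (c + 1) * n_modes)
        K[sl, sl] += A + B + P

    if nu != 0.0:
        # -nu {div u} [v_a] : couples trial component cu with test comp axis
        for cu in range(d):
            K[axis * n_modes:(axis + 1) * n_modes,
              cu * n_modes:(cu + 1) * n_modes] += \
                -nu * wt_u * sign_v * np.einsum("q,qm,qn->mn", w, Tv, Gu[cu])
        # -nu {div v} [u_a]
        for cv in range(d):
            K[cv * n_modes:(cv + 1) * n_modes,
              axis * n_modes:(axis + 1) * n_modes] += \
                -nu * wt_v * sign_u * np.einsum("q,qm,qn->mn", w, Gv[cv], Tu)
    return K


def assemble_load(basis: DGBasis, func) -> np.ndarray:
    """Load vector b_k = int f . phi_k for an analytic f(points) -> (n, d)."""
    pts, w, vals = basis.volume_quadrature(basis.order + 2)
    s, n_q, _ = pts.shape
    f = np.asarray(func(pts.reshape(-1, basis.dim))).reshape(s, n_q, basis.dim)
    b = np.einsum("eq,eqc,qm->ecm", w, f, vals)
    return b.reshape(-1)
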