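"""Continuous statistical deformation model (functional PCA) and prior energy.

Given training deformation fields u_1..u_n on a common DG basis, the model
holds the mean field and the eigenpairs (variances sigma_i^2, L2-orthonormal
eigenfunctions rho_i) of the sample covariance operator
C[w] = (1/n) sum_i (u_i - mean) int (u_i - mean) . w.  In DOF space the
operator is A = Sigma M with mass matrix M; its eigenpairs come from the
symmetric matrix M^(1/2) Sigma M^(1/2), computed through the reduced n x n
Gram problem of the M^(1/2)-weighted centered data -- the N x N matrix is
never formed.  The prior energy penalizes the Mahalanobis distance on the
model span plus an isotropic shrinkage term sigma^2 acting on the whole
space, so registrations may leave (but stay near) the model span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import LinearOperator

from .basis import DGBasis, DGVectorField

_RANK_CUTOFF = 1e-10   # relative eigenvalue threshold for "positive"


@dataclass
class DeformationModel:
    """Mean field, orthonormal modes with variances, and shrinkage variance."""

    mean: DGVectorField
    modes: np.ndarray        # (m, N) DOF rows, L2-orthonormal
    variances: np.ndarray    # (m,) positive, descending
    shrinkage: float         # sigma^2 > 0
    fingerprint: str

    def __post_init__(self) -> None:
        self.modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
        if self.modes.size == 0:
            self.modes = self.modes.reshape(0, self.mean.basis.n_dofs)
        self.variances = np.asarray(self.variances, dtype=float)
        if self.shrinkage <= 0:
            raise ValueError("shrinkage variance must be positive")
        if np.any(self.variances <= 0):
            raise ValueError("model variances must be positive")
        if np.any(np.diff(self.variances) > 0):
            raise ValueError("variances must be sorted descending")

    @property
    def n_modes(self) -> int:
        return len(self.variances)

    @property
    def basis(self) -> DGBasis:
        return self.mean.basis

    def mode_field(self, i: int) -> DGVectorField:
        return DGVectorField.from_flat(self.basis, self.modes[i])

    def check_basis(self, u: DGVectorField) -> None:
        if u.basis.shape != self.basis.shape or \
                u.basis.fingerprint() != self.fingerprint:
            raise ValueError("field does not live on the model's DG basis")


def build_model(training: list[DGVectorField], shrinkage: float,
                ddof: int = 0) -> DeformationModel:
    """Estimate the deformation model from >= 2 training fields.

    The covariance uses the 1/n normalization (``ddof=0``); pass ``ddof=1``
    for the unbiased 1/(n-1) variant.  Eigenpairs with eigenvalues below
    1e-10 of the largest are discarded; each mode's sign is fixed by making
    its first nonzero DOF positive.
    """
    if len(training) < 2:
        raise ValueError("need at least 2 training fields")
    basis = training[0].basis
    fp = basis.fingerprint()
    for u in training[1:]:
        if u.basis.shape != basis.shape or u.basis.fingerprint() != fp:
            raise ValueError("training fields must share one DG basis")
    n = len(training)
    data = np.stack([u.flat for u in training])          # (n, N)
    mean = data.mean(axis=0)
    centered = data - mean
    m_diag = basis.mass_diagonal()
    sqrt_m = np.sqrt(m_diag)
    denom = n - ddof
    B = (centered * sqrt_m) / np.sqrt(denom)             # rows = b_i^T
    gram = B @ B.T                                       # (n, n)
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > _RANK_CUTOFF * max(evals.max(), 0.0) if evals.size else []
    keep = np.asarray(keep, dtype=bool)
    keep &= evals > 0
    evals = evals[keep]
    evecs = evecs[:, keep]
    if evals.size == 0:
        modes = np.zeros((0, basis.n_dofs))
        variances = np.zeros(0)
    else:
        # unit eigenvectors r_i of M^(1/2) Sigma M^(1/2): r_i = B^T y_i / sqrt(l_i)
        r_vecs = (B.T @ evecs) / np.sqrt(evals)          # (N, m)
        rho = r_vecs / sqrt_m[:, None]                   # M^(-1/2) r_i
        # sign convention: first nonzero DOF positive
        for j in range(rho.shape[1]):
            col = rho[:, j]
            nz = np.nonzero(np.abs(col) > 1e-12 * np.abs(col).max())[0]
            if nz.size and col[nz[0]] < 0:
                rho[:, j] = -col
        modes = rho.T
        variances = evals
    return DeformationModel(DGVectorField.from_flat(basis, mean),
                            modes, variances, float(shrinkage), fp)


def project(model: DeformationModel, u: DGVectorField) -> np.ndarray:
    """Coefficients beta_i = int (u - mean) . rho_i dx."""
    model.check_basis(u)
    diff = u.flat - model.mean.flat
    m_diag = model.basis.mass_diagonal()
    return model.modes @ (m_diag * diff)


def covariance_apply(model: DeformationModel, w: DGVectorField) -> DGVectorField:
    """Action of the reconstructed covariance operator
    C[w] = sum_i sigma_i^2 rho_i int rho_i . w."""
    model.check_basis(w)
    m_diag = model.basis.mass_diagonal()
    coeff = model.modes @ (m_diag * w.flat)
    out = model.modes.T @ (model.variances * coeff)
    return DGVectorField.from_flat(model.basis, out)


def pseudoinverse_apply(model: DeformationModel,
                        w: DGVectorField) -> DGVectorField:
    """Action of the covariance pseudoinverse on the model span."""
    model.check_basis(w)
    m_diag = model.basis.mass_diagonal()
    coeff = model.modes @ (m_diag * w.flat)
    out = model.modes.T @ (coeff / model.variances)
    return DGVectorField.from_flat(model.basis, out)


def prior_energy(model: DeformationModel, u: DGVectorField,
                 gamma: float) -> float:
    """P[u] = (gamma/2) [ sum_i beta_i^2 / sigma_i^2 + |u - mean|_L2^2 / sigma^2 ].

    The shrinkage term acts on the whole space, including the model span.
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    beta = project(model, u)
    diff = u.flat - model.mean.flat
    m_diag = model.basis.mass_diagonal()
    l2 = float(diff @ (m_diag * diff))
    mahal = float(np.sum(beta ** 2 / model.variances)) if beta.size else 0.0
    return 0.5 * gamma * (mahal + l2 / model.shrinkage)


def prior_gradient(model: DeformationModel, u: DGVectorField,
                   gamma: float) -> np.ndarray:
    """Weak derivative P'[u, .] as a dual DOF vector (linear in u)."""
    model.check_basis(u)
    beta = project(model, u)
    diff = u.flat - model.mean.flat
    m_diag = model.basis.mass_diagonal()
    out = gamma / model.shrinkage * (m_diag * diff)
    if beta.size:
        out = out + gamma * (m_diag * (model.modes.T @ (beta / model.variances)))
    return out


def prior_operator(model: DeformationModel, gamma: float) -> LinearOperator:
    """Matrix-free symmetric operator A_P with P'[u, .] = A_P u - A_P mean.

    A_P w = gamma [ sum_i sigma_i^(-2) (M rho_i)(rho_i^T M w) + sigma^(-2) M w ]
    -- a low-rank update of a scaled mass matrix, used on the implicit side
    of the semi-implicit scheme.
    """
    m_diag = model.basis.mass_diagonal()
    modes = model.modes
    inv_var = 1.0 / model.variances

    def matvec(w: np.ndarray) -> np.ndarray:
        out = gamma / model.shrinkage * (m_diag * w)
        if modes.shape[0]:
            coeff = modes @ (m_diag * w)
            out = out + gamma * (m_diag * (modes.T @ (inv_var * coeff)))
        return out

    n = model.basis.n_dofs
    return LinearOperator((n, n), matvec=matvec, rmatvec=matvec, dtype=float)


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------

def save_model(model: DeformationModel, path) -> None:
    """Write the model (mesh, mean, modes, variances, shrinkage) to HDF5."""
    import h5py

    basis = model.basis
    mesh = basis.mesh
    with h5py.File(path, "w") as f:
        f.attrs["fingerprint"] = model.fingerprint
        f.attrs["order"] = basis.order
        f.attrs["shrinkage"] = model.shrinkage
        g = f.create_group("mesh")
        g.create_dataset("origin", data=mesh.origin)
        g.create_dataset("size", data=mesh.size)
        g.create_dataset("levels", data=np.array([k[0] for k in mesh.leaves]))
        g.create_dataset("indices",
                         data=np.array([k[1] for k in mesh.leaves], dtype=int))
        f.create_dataset("mean", data=model.mean.flat)
        f.create_dataset("modes", data=model.modes)
        f.create_dataset("variances", data=model.variances)


def load_model(path, basis: DGBasis | None = None) -> DeformationModel:
    """Load a model; refuses to attach to a mismatched basis if one is given."""
    import h5py

    from .mesh import Tessellation

    with h5py.File(path, "r") as f:
        fp = str(f.attrs["fingerprint"])
        order = int(f.attrs["order"])
        shrink = float(f.attrs["shrinkage"])
        origin = f["mesh/origin"][...]
        size = f["mesh/size"][...]
        levels = f["mesh/levels"][...]
        indices = f["mesh/indices"][...]
        mean = f["mean"][...]
        modes = f["modes"][...]
        variances = f["variances"][...]
    if basis is None:
        leaves = [(int(l), tuple(int(i) for i in idx))
                  for l, idx in zip(levels, indices)]
        basis = DGBasis(Tessellation(origin, size, leaves), order)
    if basis.fingerprint() != fp:
        raise ValueError("model fingerprint does not match the target basis")
    return DeformationModel(DGVectorField.from_flat(basis, mean),
                            modes, variances, shrink, fp)
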