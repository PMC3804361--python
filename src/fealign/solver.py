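"""Minimization of the registration functional by semi-implicit gradient flow.

The descent flow du/dt = -J'[u] is discretized in pseudo-time with the stiff
linear terms (DG elastic operator, statistical prior) implicit and the
nonlinear image-distance term explicit:

    (M + tau (L_reg + A_P)) u^{n+1} = M u^n - tau g_dist(u^n) + tau A_P mean,

solved with BiCGStab each step; the implicit treatment removes the
tau = O(h^2) stability restriction of the elliptic term.  The outer loop is
a locally adaptive multiresolution strategy: solve on a coarse uniform mesh,
refine all elements with |I_0| < Theta around the reference surface, project
the solution onto the refined mesh, and continue with decreasing Theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, bicgstab

from .basis import DGBasis, DGVectorField, prolong
from .energy import (RegistrationConfig, distance_gradient, distance_value)
from .images import (FeatureChannel, RasterImage, Surface,
                     check_surface_margin, sample_image,
                     surface_feature_channels, RobustWeightSpec)
from .ldg import assemble_elliptic
from .mesh import Tessellation
from .prior import DeformationModel, prior_energy, prior_operator


class KrylovError(RuntimeError):
    """Raised when the inner linear solve fails to converge."""


@dataclass
class SolverState:
    """Current iterate of the gradient flow on one mesh level."""

    u: DGVectorField
    operator: sparse.csr_matrix          # DG elastic operator L_reg
    tau: float
    time: float = 0.0
    level: int = 0
    energy_history: list[dict] = field(default_factory=list)
    backtrack_count: int = 0
    step_count: int = 0
    stagnated: bool = False

    @property
    def basis(self) -> DGBasis:
        return self.u.basis


def make_state(basis: DGBasis, config: RegistrationConfig,
               u0: DGVectorField | None = None, level: int = 0,
               history: list[dict] | None = None,
               backtracks: int = 0) -> SolverState:
    L = assemble_elliptic(basis, config.mu, config.nu, config.penalty)
    h = float(basis.mesh.widths.min())
    tau = config.tau if config.tau is not None else 0.1 * h
    return SolverState(u0 or DGVectorField.zeros(basis), L, tau, level=level,
                       energy_history=history if history is not None else [],
                       backtrack_count=backtracks)


def _objective(state: SolverState, channels: list[FeatureChannel],
               model: DeformationModel | None,
               config: RegistrationConfig) -> tuple[float, dict[str, float]]:
    """Discrete descent objective: D + (1/2) u^T L u + P.

    The regularization energy here is the DG operator's quadratic form
    (including face jump/penalty terms), the quantity the implicit step
    actually decreases.
    """
    u = state.u
    d_val = distance_value(channels, u) if channels else 0.0
    r_val = 0.5 * float(u.flat @ (state.operator @ u.flat))
    p_val = prior_energy(model, u, config.gamma) \
        if (model is not None and config.gamma > 0) else 0.0
    total = d_val + r_val + p_val
    return total, {"distance": d_val, "regularizer": r_val, "prior": p_val,
                   "total": total}


def _solve_implicit(state: SolverState, rhs: np.ndarray, tau: float,
                    model: DeformationModel | None,
                    config: RegistrationConfig) -> np.ndarray:
    n = state.basis.n_dofs
    m_diag = state.basis.mass_diagonal()
    L = state.operator
    if model is not None and config.gamma > 0:
        a_p = prior_operator(model, config.gamma)

        def matvec(w):
            return m_diag * w + tau * (L @ w) + tau * a_p.matvec(w)
        A = LinearOperator((n, n), matvec=matvec, dtype=float)
        M_prec = None
    else:
        A = sparse.diags(m_diag) + tau * L
        M_prec = sparse.diags(1.0 / (m_diag + tau * L.diagonal()))
    x, info = bicgstab(A, rhs, x0=state.u.flat, rtol=config.krylov_tol,
                       atol=0.0, maxiter=config.krylov_maxiter, M=M_prec)
    if info != 0:
        raise KrylovError(
            f"BiCGStab did not converge (info={info}, level={state.level}, "
            f"tau={tau:g}, N={n})")
    return x


def step(state: SolverState, channels: list[FeatureChannel],
         model: DeformationModel | None,
         config: RegistrationConfig) -> SolverState:
    """One semi-implicit pseudo-time step (with energy backtracking).

    If the objective increases at the current tau, the step is retried with
    tau halved (up to ``config.max_backtracks`` times); the reduced tau is
    kept for subsequent steps on this level.
    """
    if state.tau <= 0:
        raise ValueError("tau must be positive")
    m_diag = state.basis.mass_diagonal()
    g = distance_gradient(channels, state.u) if channels else \
        np.zeros(state.basis.n_dofs)
    j_old, _ = _objective(state, channels, model, config)
    tau = state.tau
    mean_term = None
    if model is not None and config.gamma > 0:
        mean_term = prior_operator(model, config.gamma).matvec(model.mean.flat)
    backtracked = False
    best = None
    for attempt in range(config.max_backtracks + 1):
        rhs = m_diag * state.u.flat - tau * g
        if mean_term is not None:
            rhs = rhs + tau * mean_term
        x = _solve_implicit(state, rhs, tau, model, config)
        candidate = SolverState(
            DGVectorField.from_flat(state.basis, x), state.operator, tau,
            time=state.time + tau, level=state.level,
            energy_history=state.energy_history,
            backtrack_count=state.backtrack_count + (1 if backtracked else 0),
            step_count=state.step_count + 1)
        j_new, breakdown = _objective(candidate, channels, model, config)
        if best is None or j_new < best[0]:
            best = (j_new, candidate, breakdown)
        if not config.backtrack or j_new <= j_old + 1e-12 * max(1.0, abs(j_old)):
            breakdown["tau"] = tau
            breakdown["level"] = state.level
            breakdown["step"] = candidate.step_count
            candidate.energy_history.append(breakdown)
            return candidate
        tau *= 0.5
        backtracked = True
    # No strictly descending step exists at any tau: the iterate sits at the
    # discrete energy floor.  Flag stagnation so the level loop can stop.
    if best is not None and best[0] <= j_old * (1.0 + 1e-8) + 1e-18:
        _, candidate, breakdown = best
        breakdown.update(tau=candidate.tau, level=state.level,
                         step=candidate.step_count)
        candidate.energy_history.append(breakdown)
        candidate.stagnated = True
        return candidate
    state.stagnated = True
    return state


def run_level(state: SolverState, channels: list[FeatureChannel],
              model: DeformationModel | None, config: RegistrationConfig,
              max_steps: int | None = None) -> SolverState:
    """Iterate steps until the step budget is exhausted or the relative
    energy decrease per step falls below ``config.energy_tol``."""
    n_steps = config.steps_per_level if max_steps is None else max_steps
    if n_steps <= 0:
        return state
    j_prev, _ = _objective(state, channels, model, config)
    for _ in range(n_steps):
        state = step(state, channels, model, config)
        if state.stagnated:
            break
        j_new = state.energy_history[-1]["total"]
        if abs(j_prev - j_new) <= config.energy_tol * max(abs(j_prev), 1e-30):
            break
        j_prev = j_new
    return state


@dataclass
class RegistrationResult:
    """Final deformation field, warped reference surface and a run report."""

    u: DGVectorField
    warped_reference: Surface
    report: dict


def theta_schedule(config: RegistrationConfig,
                   domain_size: float) -> list[float]:
    """Decreasing refinement thresholds: by default 2 h_level per level."""
    if config.theta is not None:
        return list(config.theta)
    out = []
    for lvl in range(1, config.levels):
        h = domain_size / 2 ** (config.base_level + lvl - 1)
        out.append(2.0 * h)
    return out


def register(reference: Surface, target: Surface, grid_shape: int,
             config: RegistrationConfig,
             model: DeformationModel | None = None,
             extra_channels: list | None = None,
             domain: tuple[tuple[float, ...], tuple[float, ...]] | None = None,
             ) -> RegistrationResult:
    """Full multiresolution registration of two pre-aligned closed surfaces.

    Builds the bounded distance (+ curvature) feature images on a
    ``grid_shape``-nodes-per-axis grid over the domain (default unit
    square/cube), then runs the semi-implicit flow on a hierarchy of meshes
    refined around the reference surface (|I_0| < Theta).  Returns the final
    field, the warped reference surface (vertices mapped x -> x + u(x)) and
    a per-level energy report.
    """
    from .images import GridGeometry

    dim = reference.dim
    if domain is None:
        grid = GridGeometry.unit(dim, grid_shape)
    else:
        origin, size = domain
        spacing = tuple(s / (grid_shape - 1) for s in size)
        grid = GridGeometry(tuple(origin), spacing, (grid_shape,) * dim)
    check_surface_margin(reference, grid, config.bound)
    check_surface_margin(target, grid, config.bound)

    robust = RobustWeightSpec(config.robust_mode, config.robust_C) \
        if config.robust_mode != "none" else RobustWeightSpec()
    crobust = RobustWeightSpec(config.curvature_robust_mode,
                               config.curvature_robust_C) \
        if config.curvature_robust_mode != "none" else RobustWeightSpec()
    channels, dist0 = surface_feature_channels(
        reference, target, grid, config.bound, alpha=config.alpha,
        beta=config.beta, robust=robust, curvature_robust=crobust)
    if extra_channels:
        channels = channels + list(extra_channels)

    origin = grid.origin
    size = grid.extent
    mesh = Tessellation(origin, size,
                        Tessellation.uniform(origin, size,
                                             config.base_level).leaves)
    basis = DGBasis(mesh, config.order)
    state = make_state(basis, config, level=0)
    thetas = theta_schedule(config, float(max(size)))
    levels_report = []

    for level in range(config.levels):
        if level > 0:
            theta = thetas[min(level - 1, len(thetas) - 1)]
            mesh = refine_near_surface(mesh, dist0, theta)
            basis = DGBasis(mesh, config.order)
            u0 = prolong(state.u, basis)
            state = make_state(basis, config, u0=u0, level=level,
                               history=state.energy_history,
                               backtracks=state.backtrack_count)
        state = run_level(state, channels, _model_on_basis(model, basis),
                          config)
        levels_report.append({
            "level": level,
            "elements": basis.mesh.n_elements,
            "dofs": basis.n_dofs,
            "steps": state.step_count,
            "final_energy": state.energy_history[-1]["total"]
            if state.energy_history else None,
        })

    verts = reference.vertices
    disp = state.u(verts)
    warped = Surface(verts + disp, reference.cells)
    report = {
        "levels": levels_report,
        "energy_history": state.energy_history,
        "backtracks": state.backtrack_count,
        "steps": sum(l["steps"] for l in levels_report),
    }
    return RegistrationResult(state.u, warped, report)


def _model_on_basis(model: DeformationModel | None,
                    basis: DGBasis) -> DeformationModel | None:
    """Resample a model built on a different mesh onto the current basis.

    Mean and modes are carried over by L2 projection (exact on pure
    refinements); eigen-orthonormality is preserved up to projection error.
    """
    if model is None:
        return None
    if model.basis.fingerprint() == basis.fingerprint():
        return model
    mean = prolong(model.mean, basis)
    modes = np.stack([prolong(model.mode_field(i), basis).flat
                      for i in range(model.n_modes)]) \
        if model.n_modes else np.zeros((0, basis.n_dofs))
    return DeformationModel(mean, modes, model.variances.copy(),
                            model.shrinkage, basis.fingerprint())


def refine_near_surface(mesh: Tessellation, distance: RasterImage,
                        theta: float) -> Tessellation:
    """Split every element whose sampled min |I_0| < theta; restore balance.

    The predicate samples |I_0| at the element's corners and center (the
    distance image is 1-Lipschitz, so this is a reliable min estimate at the
    refinement scale).
    """
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    if theta == 0:
        return mesh
    flags = np.zeros(mesh.n_elements, dtype=bool)
    offsets = np.array(list(np.ndindex(*([2] * mesh.dim))), dtype=float)
    for e in range(mesh.n_elements):
        corners = mesh.corners[e] + offsets * mesh.widths[e]
        pts = np.vstack([corners, mesh.centers[e]])
        if np.abs(sample_image(distance, pts)).min() < theta:
            flags[e] = True
    return mesh.refine(flags)
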