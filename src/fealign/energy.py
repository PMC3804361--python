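"""Registration functional: distance and regularization terms and derivatives.

The functional is J[u] = D[u] + R[u] + P[u]: a weighted sum of per-channel
image distances D, the smoothness + linearized volume-change regularizer
R[u] = (mu/2) int |grad u|^2 + (nu/2) int (div u)^2, and an optional
statistical deformation prior P (see :mod:`fealign.prior`).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .basis import DGBasis, DGVectorField
from .images import FeatureChannel, robust_weight, sample_image


@dataclass
class RegistrationConfig:
    """Parameters of the registration functional and its minimization.

    Weights are in the functional's units: ``alpha`` scales the distance
    channel, ``beta`` the curvature channel, ``mu``/``nu`` the gradient and
    divergence regularizers, ``gamma`` the statistical prior with shrinkage
    variance ``sigma2``.  ``bound`` is the distance-image cutoff b (physical
    length); ``robust_C`` the Geman-McClure constant.  Mesh/solver knobs:
    polynomial ``order`` q, coarse ``base_level``, number of refinement
    ``levels``, refinement thresholds ``theta`` (decreasing, physical
    length), pseudo-time step ``tau`` (None: 0.1 * h_level), a per-level
    step budget and Krylov tolerance.
    """

    alpha: float = 1.0
    beta: float = 0.0
    mu: float = 1.0
    nu: float = 0.0
    gamma: float = 0.0
    sigma2: float = 1.0
    bound: float = 0.1
    robust_mode: str = "none"
    robust_C: float = 0.05
    curvature_robust_mode: str = "geman_mcclure"
    curvature_robust_C: float = 10.0
    order: int = 1
    base_level: int = 3
    levels: int = 3
    theta: tuple[float, ...] | None = None
    tau: float | None = None
    steps_per_level: int = 50
    energy_tol: float = 1e-6
    krylov_tol: float = 1e-8
    krylov_maxiter: int = 500
    penalty: float | None = None
    backtrack: bool = True
    max_backtracks: int = 10

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive (problem is ill-posed otherwise)")
        for name in ("alpha", "beta", "nu", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not np.isfinite([self.alpha, self.beta, self.mu, self.nu,
                            self.gamma, self.sigma2]).all():
            raise ValueError("weights must be finite")
        if self.sigma2 <= 0:
            raise ValueError("shrinkage variance sigma2 must be positive")
        if self.bound <= 0:
            raise ValueError("bound b must be positive")


def _check_channels(channels: list[FeatureChannel]) -> None:
    if not channels:
        raise ValueError("at least one feature channel is required")
    g = channels[0].reference.grid
    for ch in channels[1:]:
        if ch.reference.grid != g:
            raise ValueError("feature channels must share one grid geometry")


def _channel_samples(channel: FeatureChannel, points: np.ndarray,
                     warped_points: np.ndarray):
    """Residuals, robust weights and (if needed) warped target gradients."""
    x0 = sample_image(channel.reference, points)
    x1 = sample_image(channel.target, warped_points)
    resid = x1 - x0
    grad_w = None
    if channel.robust.mode == "demons":
        grad_w = np.stack([sample_image(g, warped_points)
                           for g in channel.target_gradient], axis=-1)
    q = robust_weight(channel.robust, resid, grad_w)
    return resid, q


def distance_value(channels: list[FeatureChannel], u: DGVectorField) -> float:
    """D[u] = sum_k (alpha_k/2) int (1/Q_k) (X1_k(x+u) - X0_k(x))^2 dx."""
    _check_channels(channels)
    basis = u.basis
    pts, w, vals = basis.volume_quadrature()
    uq = u.at_quadrature(vals)
    flat_pts = pts.reshape(-1, basis.dim)
    flat_warp = flat_pts + uq.reshape(-1, basis.dim)
    wflat = w.reshape(-1)
    total = 0.0
    for ch in channels:
        if ch.weight == 0.0:
            continue
        resid, q = _channel_samples(ch, flat_pts, flat_warp)
        total += 0.5 * ch.weight * float(wflat @ (resid ** 2 / q))
    return total


def distance_gradient(channels: list[FeatureChannel],
                      u: DGVectorField) -> np.ndarray:
    """Weak derivative D'[u, .] as a dual DOF vector.

    For each channel: int (alpha/Q)(X1(x+u) - X0) grad(X1)(x+u) . phi dx,
    with the target gradient precomputed on the grid by central differences
    and itself sampled at the warped points; the robust weight Q is frozen
    at the current iterate (no differentiation through Q).
    """
    _check_channels(channels)
    basis = u.basis
    pts, w, vals = basis.volume_quadrature()
    s, n_q, _ = pts.shape
    uq = u.at_quadrature(vals)
    flat_pts = pts.reshape(-1, basis.dim)
    flat_warp = flat_pts + uq.reshape(-1, basis.dim)
    out = np.zeros(basis.shape)
    for ch in channels:
        if ch.weight == 0.0:
            continue
        resid, q = _channel_samples(ch, flat_pts, flat_warp)
        grad_w = np.stack([sample_image(g, flat_warp)
                           for g in ch.target_gradient], axis=-1)
        force = (ch.weight * resid / q)[:, None] * grad_w   # (n, d)
        force = force.reshape(s, n_q, basis.dim)
        out += np.einsum("eq,eqc,qm->ecm", w, force, vals)
    return out.reshape(-1)


def regularizer_value(u: DGVectorField, mu: float, nu: float) -> float:
    """(mu/2) int |grad u|_F^2 + (nu/2) int (div u)^2, element-wise gradients.

    Face jump terms enter only through the assembled DG operator, not this
    broken-gradient energy.
    """
    basis = u.basis
    ref_grads = basis.reference_gradients()
    _, w, _ = basis.volume_quadrature()
    g = u.gradient_at_quadrature(ref_grads)     # (s, nq, c, a)
    frob = np.einsum("eqca,eqca->eq", g, g)
    div = np.einsum("eqcc->eq", g)
    return 0.5 * float(np.sum(w * (mu * frob + nu * div ** 2)))


def regularizer_bilinear(u: DGVectorField, v: DGVectorField,
                         mu: float, nu: float) -> float:
    """Symmetric form int mu grad(u):grad(v) + nu div(u) div(v) dx
    (element-wise); equals the directional derivative of
    :func:`regularizer_value` and satisfies a(u,u) = 2 R[u]."""
    basis = u.basis
    if v.basis is not basis and v.basis.shape != basis.shape:
        raise ValueError("fields must share the DG basis")
    ref_grads = basis.reference_gradients()
    _, w, _ = basis.volume_quadrature()
    gu = u.gradient_at_quadrature(ref_grads)
    gv = v.gradient_at_quadrature(ref_grads)
    frob = np.einsum("eqca,eqca->eq", gu, gv)
    div = np.einsum("eqcc->eq", gu) * np.einsum("eqcc->eq", gv)
    return float(np.sum(w * (mu * frob + nu * div)))


def total_energy(channels: list[FeatureChannel], u: DGVectorField,
                 model=None, config: RegistrationConfig | None = None,
                 ) -> tuple[float, dict[str, float]]:
    """J[u] = D[u] + R[u] + P[u] with a per-term breakdown for logging."""
    config = config or RegistrationConfig()
    breakdown: dict[str, float] = {}
    breakdown["distance"] = distance_value(channels, u) if channels else 0.0
    breakdown["regularizer"] = regularizer_value(u, config.mu, config.nu)
    if config.gamma > 0:
        if model is None:
            raise ValueError("gamma > 0 requires a deformation model")
        from .prior import prior_energy
        breakdown["prior"] = prior_energy(model, u, config.gamma)
    else:
        breakdown["prior"] = 0.0
    total = sum(breakdown.values())
    return total, breakdown
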