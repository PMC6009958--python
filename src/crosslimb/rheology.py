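"""Carreau shear-thinning blood rheology and strain-rate machinery.

Blood is modelled as a generalized Newtonian fluid whose viscosity follows
the Carreau law

    eta(gdot) = eta_inf + (eta_0 - eta_inf) * [1 + (lambda*gdot)^2]^((n-1)/2)

interpolating between the zero-shear plateau ``eta_0`` and the infinite-shear
plateau ``eta_inf`` with relaxation time ``lambda`` and power index ``n``.
For n < 1 the law is shear thinning.  The strain-rate magnitude entering the
law is gdot = sqrt(2 D:D) with D = (grad u + grad u^T)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RheologyParams",
    "carreau_viscosity",
    "newtonian",
    "strain_rate_tensor",
    "cell_centered_velocity",
]


@dataclass(frozen=True)
class RheologyParams:
    """Carreau parameters for blood plus density.

    Defaults are the standard whole-blood Carreau fit:
    eta_inf = 3.45e-3 Pa s, eta_0 = 5.6e-2 Pa s, lambda = 3.313 s,
    n = 0.3568, rho = 1050 kg/m^3.
    """

    eta_inf: float = 3.45e-3
    eta_0: float = 5.6e-2
    lambda_relax: float = 3.313
    n_index: float = 0.3568
    rho: float = 1050.0

    def __post_init__(self) -> None:
        if not (self.eta_0 >= self.eta_inf > 0.0):
            raise ValueError("require eta_0 >= eta_inf > 0")
        if self.lambda_relax < 0.0:
            raise ValueError("lambda_relax must be >= 0")
        if self.rho <= 0.0:
            raise ValueError("rho must be positive")

    @property
    def is_newtonian(self) -> bool:
        return self.eta_0 == self.eta_inf


def newtonian(viscosity: float, rho: float = 1050.0) -> RheologyParams:
    """Constant-viscosity parameter set (eta_0 = eta_inf shortcut).

    Used by the analytic verification fixtures (Poiseuille, Womersley),
    which are exact only for Newtonian fluids.
    """
    if viscosity <= 0.0:
        raise ValueError("viscosity must be positive")
    return RheologyParams(
        eta_inf=viscosity, eta_0=viscosity, lambda_relax=1.0, n_index=1.0, rho=rho
    )


def carreau_viscosity(gamma_dot, params: RheologyParams):
    """Carreau viscosity (Pa s) at strain rate ``gamma_dot`` (1/s).

    Accepts scalars or arrays; gamma_dot must be non-negative.
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0.0):
        raise ValueError("strain rate must be non-negative")
    if params.is_newtonian:
        return np.broadcast_to(np.float64(params.eta_0), g.shape).copy() if g.ndim else float(params.eta_0)
    lam_g = params.lambda_relax * g
    eta = params.eta_inf + (params.eta_0 - params.eta_inf) * (
        1.0 + lam_g * lam_g
    ) ** ((params.n_index - 1.0) / 2.0)
    return eta if g.ndim else float(eta)


def cell_centered_velocity(u, v, w):
    """Average staggered face velocities to cell centers.

    u has shape (nx+1, ny, nz), v (nx, ny+1, nz), w (nx, ny, nz+1);
    returns three (nx, ny, nz) arrays.
    """
    uc = 0.5 * (u[:-1, :, :] + u[1:, :, :])
    vc = 0.5 * (v[:, :-1, :] + v[:, 1:, :])
    wc = 0.5 * (w[:, :, :-1] + w[:, :, 1:])
    return uc, vc, wc


def strain_rate_tensor(uc, vc, wc, spacing):
    """Strain-rate tensor D and modulus gdot = sqrt(2 D:D) at cell centers.

    ``uc, vc, wc`` are cell-centered velocity components (including any ghost
    values the caller has populated); derivatives are second-order central in
    the interior, one-sided at array edges (numpy.gradient).

    Returns
    -------
    D : ndarray, shape (3, 3) + field shape
    gamma_dot : ndarray, field shape
    """
    h = float(spacing)
    comps = (uc, vc, wc)
    grad = np.empty((3, 3) + uc.shape)
    for i, c in enumerate(comps):
        gx, gy, gz = np.gradient(c, h, h, h)
        grad[i, 0], grad[i, 1], grad[i, 2] = gx, gy, gz
    D = 0.5 * (grad + grad.transpose(1, 0, 2, 3, 4))
    gamma_dot = np.sqrt(2.0 * np.einsum("ij...,ij...->...", D, D))
    return D, gamma_dot
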