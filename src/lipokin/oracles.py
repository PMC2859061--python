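"""Brute-force reference solvers used to validate the closed/series forms.

These deliberately share no numerical machinery with the production
solvers: the sphere-diffusion oracle is a Crank-Nicolson finite
difference scheme (the production path is an eigenfunction series), the
ODE oracle is fixed-step classical RK4 with step halving (the production
reactor integrator is adaptive DOP853), and the projection oracle is
composite-Simpson quadrature (the production coefficients are closed
form).  Correctness over speed throughout; test-suite use only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import simpson
from scipy.sparse import diags
from scipy.sparse.linalg import splu

from .errors import NumericalError, ValidationError
from .leakage import MLVSpec

__all__ = [
    "GridSolution",
    "fd_sphere_diffusion",
    "fd_fraction_remaining",
    "ode_integrate",
    "project_initial_condition",
]


@dataclass
class GridSolution:
    """Finite-difference solution on a fixed space-time grid."""

    eta: np.ndarray          # node coordinates in [0, 1]
    taus: np.ndarray         # output times (dimensionless)
    theta: np.ndarray        # shape (len(taus), len(eta))
    n_nodes: int
    dtau: float

    def mean(self) -> np.ndarray:
        """Volume-averaged concentration 3*int(theta eta^2) at each time."""
        return 3.0 * simpson(self.theta * self.eta**2, x=self.eta, axis=1)


def _robin_operator(n_nodes: int, bi: float):
    """Tridiagonal spatial operator for the sphere with a Robin surface.

    Second-order central differences on a uniform eta grid; symmetry at
    the center (Laplacian -> 6 (theta_1 - theta_0)/h^2) and a ghost node
    at the surface encoding -d theta/d eta = Bi * theta.
    """
    h = 1.0 / (n_nodes - 1)
    eta = np.linspace(0.0, 1.0, n_nodes)
    lower = np.zeros(n_nodes - 1)
    main = np.zeros(n_nodes)
    upper = np.zeros(n_nodes - 1)

    main[0] = -6.0 / h**2
    upper[0] = 6.0 / h**2
    for i in range(1, n_nodes - 1):
        lower[i - 1] = (1.0 - h / eta[i]) / h**2
        main[i] = -2.0 / h**2
        upper[i] = (1.0 + h / eta[i]) / h**2
    # Surface: ghost theta_{M+1} = theta_{M-1} - 2 h Bi theta_M, eta = 1.
    lower[-1] = 2.0 / h**2
    main[-1] = -2.0 / h**2 - 2.0 * bi * (1.0 / h + 1.0)
    return diags([lower, main, upper], [-1, 0, 1], format="csc"), eta


def fd_sphere_diffusion(
    spec: MLVSpec,
    n_nodes: int = 2000,
    tau_end: float = 1.0,
    taus: np.ndarray | None = None,
    dtau: float | None = None,
) -> GridSolution:
    """Finite-difference solution of the Robin-boundary sphere problem.

    Crank-Nicolson time stepping with a handful of initial
    backward-Euler steps to damp the startup discontinuity between the
    uniform interior and the leaking surface (important at large Biot
    number).  Stores the dimensionless concentration at the requested
    output times.
    """
    if n_nodes < 100:
        raise ValidationError("n_nodes must be >= 100 for a trustworthy oracle")
    bi = spec.biot
    if taus is None:
        taus = np.linspace(0.0, tau_end, 11)
    taus = np.asarray(sorted(set(np.round(np.asarray(taus, dtype=float), 15))))
    tau_end = float(taus[-1]) if len(taus) else 0.0
    if dtau is None:
        dtau = min(5e-5, tau_end / 10) if tau_end > 0 else 5e-5

    A, eta = _robin_operator(n_nodes, bi)
    identity = diags([np.ones(n_nodes)], [0], format="csc")

    theta = np.ones(n_nodes)
    out = np.empty((len(taus), n_nodes))
    tau = 0.0
    idx = 0
    while idx < len(taus) and taus[idx] <= tau + 1e-15:
        out[idx] = theta
        idx += 1

    be_lu = splu(identity - dtau * A)           # backward Euler (smoothing)
    cn_lhs = splu(identity - 0.5 * dtau * A)    # Crank-Nicolson
    cn_rhs = identity + 0.5 * dtau * A
    n_smooth = 8
    step = 0
    while idx < len(taus):
        target = taus[idx]
        # Step exactly onto each output time.
        next_tau = min(tau + dtau, target)
        h = next_tau - tau
        if abs(h - dtau) < 1e-15 * max(1.0, dtau):
            if step < n_smooth:
                theta = be_lu.solve(theta)
            else:
                theta = cn_lhs.solve(cn_rhs @ theta)
        else:
            # Irregular final step toward an output time: backward Euler,
            # unconditionally stable at any h.
            theta = splu(identity - h * A).solve(theta)
        tau = next_tau
        step += 1
        if np.min(theta) < -1e-6:
            raise NumericalError(
                f"instability detected (min theta {np.min(theta):.3e}) at "
                f"tau={tau:g}; reduce dtau={dtau:g}"
            )
        while idx < len(taus) and taus[idx] <= tau + 1e-12:
            out[idx] = theta
            idx += 1
    return GridSolution(eta=eta, taus=taus, theta=out, n_nodes=n_nodes, dtau=dtau)


def fd_fraction_remaining(
    spec: MLVSpec, taus, n_nodes: int = 2000, dtau: float | None = None
) -> np.ndarray:
    """Volume-averaged remaining fraction from the finite-difference oracle."""
    sol = fd_sphere_diffusion(spec, n_nodes=n_nodes, taus=np.asarray(taus), dtau=dtau)
    return sol.mean()


def ode_integrate(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0,
    t_grid,
    tol: float = 1e-10,
    max_halvings: int = 20,
) -> np.ndarray:
    """Fixed-step classical RK4 trajectory on ``t_grid``.

    The step is halved (substeps between grid points doubled) until two
    successive trajectories agree to ``tol`` pointwise-relative (with a
    small absolute floor so exact zeros do not stall convergence).
    """
    t = np.asarray(t_grid, dtype=float)
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))

    def run(substeps: int) -> np.ndarray:
        out = np.empty((len(t), len(y0)))
        y = y0.copy()
        out[0] = y
        for i in range(len(t) - 1):
            h = (t[i + 1] - t[i]) / substeps
            ti = t[i]
            for _ in range(substeps):
                k1 = np.asarray(rhs(ti, y))
                k2 = np.asarray(rhs(ti + h / 2, y + h / 2 * k1))
                k3 = np.asarray(rhs(ti + h / 2, y + h / 2 * k2))
                k4 = np.asarray(rhs(ti + h, y + h * k3))
                y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                ti += h
            out[i + 1] = y
        return out

    # The first coarse passes may overflow on stiff fields; that only
    # delays convergence, so arithmetic warnings are silenced here.
    with np.errstate(over="ignore", invalid="ignore"):
        substeps = 1
        prev = run(substeps)
        scale = max(1.0, float(np.nanmax(np.abs(prev[np.isfinite(prev)]), initial=1.0)))
        for _ in range(max_halvings):
            substeps *= 2
            cur = run(substeps)
            denom = np.maximum(np.abs(cur), 1e-12 * scale)
            if np.all(np.isfinite(cur)) and np.max(np.abs(cur - prev) / denom) < tol:
                return cur
            prev = cur
    raise NumericalError(
        f"RK4 oracle did not converge to {tol:g} after {max_halvings} halvings"
    )


def project_initial_condition(
    bi: float, eigenvalues, n_panels: int = 10_000
) -> np.ndarray:
    """Expansion coefficients of the uniform IC by Simpson quadrature.

    Computes a_n = int(eta sin(lam eta)) / int(sin^2(lam eta)) on [0, 1]
    numerically, independent of the closed-form expressions.
    """
    if n_panels < 1000:
        raise ValidationError("n_panels must be >= 1000")
    if n_panels % 2:
        n_panels += 1
    lam = np.asarray(eigenvalues, dtype=float)
    eta = np.linspace(0.0, 1.0, n_panels + 1)
    coeffs = np.empty(len(lam))
    for i, l in enumerate(lam):
        s = np.sin(l * eta)
        num = simpson(eta * s, x=eta)
        den = simpson(s * s, x=eta)
        coeffs[i] = num / den
    return coeffs
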