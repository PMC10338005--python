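"""Leading-order oscillatory (Womersley-type) flow in the wavy channel.

With a harmonic pressure difference imposed between the channel ends, the
leading-order velocity is harmonic in the fast time t and is recovered from
complex amplitudes as

    u0 = Re(i e^{it} U),   v0 = Re(i e^{it} V),   p0 = Re(e^{it} P).

U satisfies the Womersley balance -U = -dP/dx + (i/alpha^2) d2U/dy2 with
no-slip at both walls, giving U = (dP/dx) * G(x, y) with

    G = 1 - cosh(Lambda*(2y/H - 1))/cosh(Lambda),
    Lambda = alpha*H*(1 + i)/(2*sqrt(2))    (Lambda^2 = i*alpha^2*H^2/4).

V follows from continuity using the closed-form transverse integral of G,
and the pressure gradient is fixed by P(0) = 0, P(n) = n, which makes the
complex flow rate Q a constant independent of the number of cells.

All fields are cell-periodic and are computed on a single cell [0, 1] in the
mapped (x, eta = y/H) plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channel import (
    Grid,
    ModelParams,
    channel_width,
    channel_width_slope,
    diff4,
    diff4_periodic,
    trapezoid_integral,
)

__all__ = [
    "OscillatoryBaseFlow",
    "womersley_lambda",
    "profile_G",
    "profile_G_integral",
    "flow_rate_and_pressure",
    "base_velocities",
]

_SQRT2 = np.sqrt(2.0)


def womersley_lambda(x, params: ModelParams):
    """Complex Womersley parameter Lambda(x) = alpha*H(x)*(1+i)/(2*sqrt(2)).

    The branch with Re(Lambda) > 0 satisfying Lambda^2 = i*alpha^2*H^2/4 is
    the one for which U = (dP/dx)*G solves the momentum balance under the
    phase convention u0 = Re(i e^{it} U); cosh being even, only Lambda^2
    matters for G.  |Lambda| = alpha*H/2.
    """
    H = channel_width(x, params.beta)
    return params.alpha * H * (1.0 + 1.0j) / (2.0 * _SQRT2)


def profile_G(x, y, params: ModelParams):
    """Womersley velocity profile G = 1 - cosh(Lambda*(2y/H-1))/cosh(Lambda)."""
    H = channel_width(x, params.beta)
    y = np.asarray(y, dtype=float)
    if np.any(y < -1e-12) or np.any(y > H + 1e-12):
        raise ValueError("y outside the channel [0, H(x)]")
    lam = womersley_lambda(x, params)
    return 1.0 - np.cosh(lam * (2.0 * y / H - 1.0)) / np.cosh(lam)


def profile_G_integral(x, y, params: ModelParams):
    """Closed-form transverse integral of G from the flat wall to y."""
    H = channel_width(x, params.beta)
    lam = womersley_lambda(x, params)
    s = 2.0 * np.asarray(y, dtype=float) / H - 1.0
    return y - (H / (2.0 * lam)) * (np.sinh(lam * s) + np.sinh(lam)) / np.cosh(lam)


def _lambda_H(params: ModelParams, x):
    H = channel_width(x, params.beta)
    lam = params.alpha * H * (1.0 + 1.0j) / (2.0 * _SQRT2)
    return lam, H


def flow_rate_and_pressure(params: ModelParams, grid: Grid):
    """Complex flow rate Q and pressure-gradient profile dP/dx on one cell.

    Q = [ integral_0^1 dx / (H*(1 - tanh(Lambda)/Lambda)) ]^{-1} and
    dP/dx = Q / (H*(1 - tanh(Lambda)/Lambda)); the reconstructed pressure
    satisfies P(0) = 0, P(1) = 1 regardless of beta, so the result is
    independent of the number of cells.
    """
    lam, H = _lambda_H(params, grid.x_cell)
    denom = H * (1.0 - np.tanh(lam) / lam)
    inv = 1.0 / denom
    integral = trapezoid_integral(inv, grid.dx)
    if not np.isfinite(integral):
        raise FloatingPointError("quadrature for the flow rate did not converge")
    Q = 1.0 / integral
    return Q, Q * inv


@dataclass(frozen=True)
class OscillatoryBaseFlow:
    """Complex amplitudes of the leading-order oscillatory flow on one cell.

    Fields are sampled on the mapped grid (x_cell, eta) with y = eta*H(x).
    ``IU`` is the transverse integral of U from the flat wall (closed form),
    from which V = -dIU/dx|_y follows by continuity.
    """

    params: ModelParams
    grid: Grid
    H: np.ndarray = field(repr=False)
    dHdx: np.ndarray = field(repr=False)
    Lambda: np.ndarray = field(repr=False)
    G: np.ndarray = field(repr=False)
    U: np.ndarray = field(repr=False)
    V: np.ndarray = field(repr=False)
    IU: np.ndarray = field(repr=False)
    dPdx: np.ndarray = field(repr=False)
    Q: complex = 0j

    # -- mapped-coordinate calculus helpers used by the drift modules -----

    def ddx_at_fixed_y(self, f):
        """x-derivative at fixed y of a cell-periodic field on (x, eta)."""
        return diff4_periodic(f, self.grid.dx, axis=0) - (
            self.grid.eta[None, :] * (self.dHdx / self.H)[:, None]
        ) * diff4(f, self.grid.deta, axis=1)

    def ddy(self, f):
        """y-derivative of a field on (x, eta)."""
        return diff4(f, self.grid.deta, axis=1) / self.H[:, None]


def base_velocities(params: ModelParams, grid: Grid) -> OscillatoryBaseFlow:
    """Assemble the oscillatory base flow U, V, dP/dx, Q on one cell."""
    x = grid.x_cell
    eta = grid.eta
    lam, H = _lambda_H(params, x)
    dHdx = channel_width_slope(x, params.beta)
    Q, dPdx = flow_rate_and_pressure(params, grid)

    s = 2.0 * eta[None, :] - 1.0  # 2y/H - 1, x-independent in eta
    lam2 = lam[:, None]
    with np.errstate(over="raise"):
        try:
            cosh_ratio = np.cosh(lam2 * s) / np.cosh(lam2)
            sinh_term = (np.sinh(lam2 * s) + np.sinh(lam2)) / np.cosh(lam2)
        except FloatingPointError as exc:  # pragma: no cover - alpha >~ 70
            raise FloatingPointError(
                "cosh overflow in Womersley profile; alpha too large for "
                "direct evaluation"
            ) from exc
    G = 1.0 - cosh_ratio
    y = eta[None, :] * H[:, None]
    Gint = y - (H / (2.0 * lam))[:, None] * sinh_term

    U = dPdx[:, None] * G
    IU = dPdx[:, None] * Gint  # integral of U from the flat wall to y
    # continuity: V = -d/dx|_y IU = -d/dx|_eta IU + U * eta * dH/dx
    V = -diff4_periodic(IU, grid.dx, axis=0) + U * eta[None, :] * dHdx[:, None]

    if not (np.all(np.isfinite(U)) and np.all(np.isfinite(V))):
        raise FloatingPointError("non-finite oscillatory base-flow fields")

    return OscillatoryBaseFlow(
        params=params,
        grid=grid,
        H=H,
        dHdx=dHdx,
        Lambda=lam,
        G=G,
        U=U,
        V=V,
        IU=IU,
        dPdx=dPdx,
        Q=complex(Q),
    )
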