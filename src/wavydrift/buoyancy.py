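"""Concentration-driven mean buoyancy flow on the full n-cell channel.

A solute of density differing from the carrier fluid forces a slow mean flow
through the same lubrication balance as the steady streaming, with the
Reynolds forcing replaced by Ri*c(x, y, tau).  Because the concentration is
not spatially periodic, the pressure closure uses the end conditions
pB = 0 at x = 0 and x = n, which leaves a non-zero "chimney draft": a net
flow rate

    QB = -alpha^2*Ri * [int_0^n H^-3 m dx] / (2 n int_0^1 H^-3 dx),
    m(x) = int_0^H c y (H - y) dy,

negative (directed toward the upper end x = 0) for a light solute (Ri > 0).
The solve is a pure function of the instantaneous concentration; all
transverse integrals use the trapezoidal rule on the mapped eta grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channel import Grid, ModelParams, cumtrapz, diff4, trapezoid_integral

__all__ = [
    "BuoyancyFields",
    "buoyancy_moment",
    "buoyancy_pressure_gradient",
    "buoyancy_velocity",
]


@dataclass(frozen=True)
class BuoyancyFields:
    """Buoyancy-induced mean flow evaluated from a concentration field."""

    m: np.ndarray = field(repr=False)
    dpBdx_over_Ri: np.ndarray = field(repr=False)
    uB: np.ndarray = field(repr=False)
    vB: np.ndarray = field(repr=False)
    psiB: np.ndarray = field(repr=False)
    wB: np.ndarray = field(repr=False)
    QB: float = 0.0


def _width(grid: Grid, params: ModelParams):
    return 1.0 + params.beta * np.cos(2 * np.pi * grid.x)


def buoyancy_moment(c: np.ndarray, grid: Grid, params: ModelParams) -> np.ndarray:
    """First wall-weighted moment m(x) = H^3 * int_0^1 c eta (1-eta) deta."""
    H = _width(grid, params)
    w = grid.eta * (1.0 - grid.eta)
    return H**3 * trapezoid_integral(c * w[None, :], grid.deta, axis=1)


def buoyancy_pressure_gradient(m: np.ndarray, grid: Grid, params: ModelParams) -> np.ndarray:
    """(1/Ri) dpB/dx from the end conditions pB(0) = pB(n) = 0.

    (1/Ri) dpB/dx = (6/H^3) [ (int_0^n H^-3 m dx)/(n int_0^1 H^-3 dx) - m ].
    Its cumulative integral over the full channel vanishes by construction.
    """
    H = _width(grid, params)
    Hc = 1.0 + params.beta * np.cos(2 * np.pi * grid.x_cell)
    I3_cell = trapezoid_integral(Hc**-3, grid.dx)
    A = trapezoid_integral(m / H**3, grid.dx) / (grid.n * I3_cell)
    return (6.0 / H**3) * (A - m)


def buoyancy_velocity(c: np.ndarray, params: ModelParams, grid: Grid,
                      flux_rtol: float = 0.25,
                      need_transverse: bool = True) -> BuoyancyFields:
    """Buoyancy-induced mean velocity, streamfunction and flow rate.

    uB solves (1/alpha^2) d2uB/dy2 = dpB/dx + Ri*c with no-slip walls; vB
    follows from continuity with vB = 0 at the flat wall; wB is the
    contravariant transverse velocity in mapped coordinates used by the
    transport solver.  uB, vB and QB are jointly linear in Ri*c.  The
    section flux of uB must be x-independent; a drift beyond ``flux_rtol``
    of its magnitude signals an inconsistency.
    """
    if c.shape != (grid.n * grid.Nx_cell + 1, grid.Neta):
        raise ValueError(
            f"concentration shape {c.shape} does not match the full grid "
            f"({grid.n * grid.Nx_cell + 1}, {grid.Neta})"
        )
    params_alpha2Ri = params.alpha**2 * params.Ri
    H = _width(grid, params)
    eta, deta = grid.eta, grid.deta
    m = buoyancy_moment(c, grid, params)
    g = buoyancy_pressure_gradient(m, grid, params)  # (1/Ri) dpB/dx

    a = H[:, None] * cumtrapz(c, deta, axis=1)              # int_0^y c dyhat
    b = (H**2)[:, None] * cumtrapz(c * eta[None, :], deta, axis=1)
    Ic = a[:, -1] - b[:, -1] / H                            # int c (1 - yhat/H)
    y = eta[None, :] * H[:, None]
    uB = params_alpha2Ri * (
        -g[:, None] * 0.5 * (H[:, None] - y) * y + y * a - b - y * Ic[:, None]
    )

    psiB = H[:, None] * cumtrapz(uB, deta, axis=1)
    flux = psiB[:, -1]
    # closed-form chimney draft, re-derived from the averaged momentum balance
    Hc = 1.0 + params.beta * np.cos(2 * np.pi * grid.x_cell)
    I3_cell = trapezoid_integral(Hc**-3, grid.dx)
    QB = -0.5 * params_alpha2Ri * trapezoid_integral(m / H**3, grid.dx) / (
        grid.n * I3_cell
    )
    scale = max(np.max(np.abs(flux)), abs(QB))
    if scale > 0 and np.max(np.abs(flux - QB)) > flux_rtol * scale:
        raise FloatingPointError(
            f"buoyancy flux varies along x by {np.max(np.abs(flux - QB)):.3e} "
            f"(scale {scale:.3e}); quadrature/sign inconsistency"
        )

    if need_transverse:
        dHdx = -2 * np.pi * params.beta * np.sin(2 * np.pi * grid.x)
        dpsi = diff4(psiB, grid.dx, axis=0)
        vB = -dpsi + uB * eta[None, :] * dHdx[:, None]
        wB = -dpsi / H[:, None]
    else:  # streamfunction-based callers derive transverse transport from psiB
        vB = wB = None
    return BuoyancyFields(m=m, dpBdx_over_Ri=g, uB=uB, vB=vB, psiB=psiB,
                          wB=wB, QB=float(QB))
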