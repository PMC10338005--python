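"""Channel geometry, parameter container, grids and quadrature/differencing helpers.

The channel is a slender two-dimensional vertical duct bounded by a flat wall at
y = 0 and a wavy wall at y = H(x) = 1 + beta*cos(2*pi*x), with x measured
downward from the upper end in units of the wall wavelength and y in units of
the mean gap width.  The channel spans x in [0, n] and therefore contains n
identical cells.  All other modules consume the grids and the trapezoidal
quadrature defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "InvalidGeometryError",
    "ModelParams",
    "Grid",
    "channel_width",
    "channel_width_slope",
    "make_grid",
    "trapezoid_integral",
    "cumtrapz",
    "diff4_periodic",
    "diff4",
]


class InvalidGeometryError(ValueError):
    """Raised when the wall amplitude would pinch the channel shut."""


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless control parameters of the oscillating-channel problem.

    Parameters
    ----------
    alpha : float
        Womersley number, ratio of the transverse viscous time to the
        oscillation time, (omega*h0^2/nu)**0.5.  Must be positive.
    beta : float
        Relative amplitude of the wavy wall, 0 <= beta < 1.  The channel
        width is H(x) = 1 + beta*cos(2*pi*x).
    Ri : float
        Richardson number comparing the effective gravitational acceleration
        g*(rho - rho_s)/rho with the convective acceleration u_c^2/lambda.
        Positive for a solute lighter than the carrier fluid; may take any
        sign.
    sigma : float
        Reduced Schmidt number eps^2*nu/kappa, an order-unity grouping
        expressing the very small solute diffusivity.  Must be positive.
    n : int
        Number of identical cells; the channel spans x in [0, n].
    epsilon : float
        Stroke-length ratio u_c/(omega*lambda).  Metadata only: it converts
        the slow time tau to fast-time units t = tau/epsilon**2 and thence to
        oscillation counts, and never enters the reduced equations.
    """

    alpha: float = 4.0
    beta: float = 0.2
    Ri: float = 1.0
    sigma: float = 1.0
    n: int = 3
    epsilon: float = 0.02

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not 0 <= self.beta:
            raise ValueError(f"beta must be non-negative, got {self.beta}")
        if self.beta >= 1:
            raise InvalidGeometryError(
                f"beta must be < 1 (channel would pinch shut), got {self.beta}"
            )
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"n must be a positive integer, got {self.n}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")


@dataclass(frozen=True)
class Grid:
    """Uniform tensor grid on [0, n] x [0, 1] in the mapped (x, eta) plane.

    eta = y/H(x) maps the wavy channel onto a rectangle.  Both coordinate
    arrays include their endpoints so boundary conditions are imposed on
    nodes.  ``x_cell`` is the single-cell grid [0, 1] with the same spacing,
    used for the cell-periodic oscillatory and drift fields.
    """

    n: int
    Nx_cell: int
    Neta: int
    x: np.ndarray = field(repr=False)
    x_cell: np.ndarray = field(repr=False)
    eta: np.ndarray = field(repr=False)
    dx: float
    deta: float


def channel_width(x, beta):
    """Channel width H(x) = 1 + beta*cos(2*pi*x); raises if beta >= 1."""
    if beta < 0 or beta >= 1:
        raise InvalidGeometryError(f"require 0 <= beta < 1, got {beta}")
    return 1.0 + beta * np.cos(2 * np.pi * np.asarray(x, dtype=float))


def channel_width_slope(x, beta):
    """dH/dx = -2*pi*beta*sin(2*pi*x)."""
    return -2 * np.pi * beta * np.sin(2 * np.pi * np.asarray(x, dtype=float))


def make_grid(params: ModelParams, Nx_cell: int = 200, Neta: int = 101) -> Grid:
    """Build the uniform mapped grid: n*Nx_cell+1 x-points, Neta eta-points."""
    if Nx_cell < 16:
        raise ValueError(f"Nx_cell must be >= 16, got {Nx_cell}")
    if Neta < 9:
        raise ValueError(f"Neta must be >= 9, got {Neta}")
    n = params.n
    x = np.linspace(0.0, float(n), n * Nx_cell + 1)
    x_cell = np.linspace(0.0, 1.0, Nx_cell + 1)
    eta = np.linspace(0.0, 1.0, Neta)
    return Grid(
        n=n,
        Nx_cell=Nx_cell,
        Neta=Neta,
        x=x,
        x_cell=x_cell,
        eta=eta,
        dx=1.0 / Nx_cell,
        deta=1.0 / (Neta - 1),
    )


def trapezoid_integral(values, spacing, axis: int = -1):
    """Composite trapezoid of uniformly sampled values; exact for affine data."""
    values = np.asarray(values)
    if values.shape[axis] < 2:
        raise ValueError("trapezoid_integral needs at least 2 samples")
    return np.trapezoid(values, dx=spacing, axis=axis)


def cumtrapz(values, spacing, axis: int = -1):
    """Cumulative trapezoid with a leading zero (same shape as input)."""
    return cumulative_trapezoid(values, dx=spacing, axis=axis, initial=0.0)


# -- fourth-order first-derivative stencils ---------------------------------

def diff4_periodic(f, dx: float, axis: int = 0):
    """4th-order central x-derivative of a cell-periodic field.

    ``f`` includes the duplicated endpoint (f[..., -1] == f[..., 0] along
    ``axis``); the returned array has the same shape with the duplicate
    restored.
    """
    f = np.moveaxis(np.asarray(f), axis, 0)
    g = f[:-1]
    d = (
        8.0 * (np.roll(g, -1, axis=0) - np.roll(g, 1, axis=0))
        - (np.roll(g, -2, axis=0) - np.roll(g, 2, axis=0))
    ) / (12.0 * dx)
    d = np.concatenate([d, d[:1]], axis=0)
    return np.moveaxis(d, 0, axis)


def diff4(f, dx: float, axis: int = 0):
    """4th-order first derivative on a non-periodic uniform grid.

    Central five-point stencil in the interior, one-sided five-point
    stencils of the same order at the two nodes nearest each boundary.
    """
    f = np.moveaxis(np.asarray(f), axis, 0)
    if f.shape[0] < 5:
        raise ValueError("diff4 needs at least 5 samples")
    d = np.empty_like(f, dtype=np.result_type(f, float))
    d[2:-2] = (f[:-4] - 8 * f[1:-3] + 8 * f[3:-1] - f[4:]) / (12 * dx)
    d[0] = (-25 * f[0] + 48 * f[1] - 36 * f[2] + 16 * f[3] - 3 * f[4]) / (12 * dx)
    d[1] = (-3 * f[0] - 10 * f[1] + 18 * f[2] - 6 * f[3] + f[4]) / (12 * dx)
    d[-1] = (25 * f[-1] - 48 * f[-2] + 36 * f[-3] - 16 * f[-4] + 3 * f[-5]) / (12 * dx)
    d[-2] = (3 * f[-1] + 10 * f[-2] - 18 * f[-3] + 6 * f[-4] - f[-5]) / (12 * dx)
    return np.moveaxis(d, 0, axis)
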