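"""Time-averaged buoyancy-free mean flow: steady streaming and Stokes drift.

The O(eps) time-averaged Eulerian velocity (steady streaming) is forced by
the Reynolds stress of the oscillatory base flow,

    F = (1/2) Re[ d/dx (U conj(U)) + d/dy (V conj(U)) ],

and obeys a lubrication balance (1/alpha^2) d2u/dy2 = dpSS/dx + F with
no-slip walls and a periodic pressure correction fixed by zero net flux.
The Stokes drift of the oscillatory field is

    uSD = (1/2) Im[ d/dx (U conj(U)) + d/dy (V conj(U)) ],
    vSD = (1/2) Im[ d/dx (U conj(V)) + d/dy (V conj(V)) ].

Both contributions carry zero net flux across every section; their sum is
the steady part of the mean Lagrangian velocity that advects the solute.
Streamfunction/vorticity diagnostics and grid-converged peak extraction
reproduce the peak tables used to validate the reduced model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baseflow import OscillatoryBaseFlow, base_velocities
from .channel import Grid, ModelParams, cumtrapz, diff4, diff4_periodic, make_grid, trapezoid_integral

__all__ = [
    "MeanDriftFields",
    "FlowDiagnostics",
    "reynolds_forcing",
    "steady_streaming",
    "stokes_drift",
    "compute_mean_drift",
    "streamfunction_vorticity",
    "converged_peaks",
]


@dataclass(frozen=True)
class MeanDriftFields:
    """Cell-periodic steady drift fields on the mapped one-cell grid."""

    params: ModelParams
    grid: Grid
    H: np.ndarray = field(repr=False)
    F: np.ndarray = field(repr=False)
    uSS: np.ndarray = field(repr=False)
    vSS: np.ndarray = field(repr=False)
    dpSSdx: np.ndarray = field(repr=False)
    uSD: np.ndarray = field(repr=False)
    vSD: np.ndarray = field(repr=False)

    @property
    def u_lagrangian(self) -> np.ndarray:
        return self.uSS + self.uSD

    @property
    def v_lagrangian(self) -> np.ndarray:
        return self.vSS + self.vSD


@dataclass(frozen=True)
class PeakRecord:
    value: float
    x: float
    eta: float
    sign: int


@dataclass(frozen=True)
class FlowDiagnostics:
    """Streamfunction (psi = 0 at the flat wall) and vorticity of a u-field."""

    psi: np.ndarray = field(repr=False)
    Omega: np.ndarray = field(repr=False)
    psi_peak: PeakRecord = None
    Omega_peak: PeakRecord = None


def reynolds_forcing(base: OscillatoryBaseFlow) -> np.ndarray:
    """Steady Reynolds forcing F of the time-averaged momentum balance.

    Real, cell-periodic and antisymmetric about x = 1/2; identically zero
    for a straight channel (beta = 0).
    """
    UUc = base.U * np.conj(base.U)  # real
    VUc = base.V * np.conj(base.U)
    return 0.5 * np.real(base.ddx_at_fixed_y(UUc) + base.ddy(VUc))


def _transverse_integrals(fld: np.ndarray, H: np.ndarray, eta: np.ndarray, deta: float):
    """Return cumulative integrals of fld dy and fld*y dy from the flat wall."""
    a = H[:, None] * cumtrapz(fld, deta, axis=1)  # int_0^y fld dyhat
    b = (H**2)[:, None] * cumtrapz(fld * eta[None, :], deta, axis=1)
    return a, b


def _lubrication_velocity(forcing, dpdx, H, eta, deta, alpha):
    """Solve (1/alpha^2) u'' = dpdx + forcing, u(0) = u(H) = 0, in closed form."""
    a, b = _transverse_integrals(forcing, H, eta, deta)
    I1 = a[:, -1] - b[:, -1] / H  # int_0^H forcing*(1 - yhat/H) dyhat
    y = eta[None, :] * H[:, None]
    u = alpha**2 * (
        -dpdx[:, None] * 0.5 * (H[:, None] - y) * y
        + y * a
        - b
        - y * I1[:, None]
    )
    return u


def steady_streaming(base: OscillatoryBaseFlow, grid: Grid, F: np.ndarray | None = None,
                     flux_rtol: float = 0.25):
    """Steady-streaming velocity (uSS, vSS) and pressure gradient dpSS/dx.

    The periodic pressure correction follows from the zero-net-flux theorem,
    dpSS/dx = -(6/H^3) * int_0^H F y (H - y) dy; the transverse component is
    recovered from continuity with vSS = 0 at the flat wall.  The section
    flux of uSS vanishes analytically; discretely it carries the quadrature
    error, so a flux exceeding ``flux_rtol`` times the streamfunction
    magnitude signals a sign or quadrature defect rather than resolution.
    """
    if F is None:
        F = reynolds_forcing(base)
    H, eta, deta = base.H, grid.eta, grid.deta
    mF = (H**3) * trapezoid_integral(F * (eta * (1 - eta))[None, :], deta, axis=1)
    dpSSdx = -6.0 * mF / H**3
    uSS = _lubrication_velocity(F, dpSSdx, H, eta, deta, base.params.alpha)
    psi = H[:, None] * cumtrapz(uSS, deta, axis=1)
    QSS = psi[:, -1]
    scale = np.max(np.abs(psi))
    if scale > 0 and np.max(np.abs(QSS)) > flux_rtol * scale:
        raise FloatingPointError(
            f"steady-streaming section flux {np.max(np.abs(QSS)):.3e} exceeds "
            f"{flux_rtol:.2f} x streamfunction scale {scale:.3e}; "
            "sign/quadrature inconsistency"
        )
    vSS = -diff4_periodic(psi, grid.dx, axis=0) + uSS * eta[None, :] * base.dHdx[:, None]
    return uSS, vSS, dpSSdx


def stokes_drift(base: OscillatoryBaseFlow):
    """Stokes-drift velocity (uSD, vSD) of the oscillatory base flow."""
    UUc = base.U * np.conj(base.U)  # real: no Im contribution from d/dx
    VUc = base.V * np.conj(base.U)
    UVc = base.U * np.conj(base.V)
    uSD = 0.5 * np.imag(base.ddx_at_fixed_y(UUc) + base.ddy(VUc))
    vSD = 0.5 * np.imag(base.ddx_at_fixed_y(UVc))  # d/dy(V conj(V)) is real
    return uSD, vSD


def compute_mean_drift(params: ModelParams, grid: Grid | None = None,
                       Nx_cell: int = 200, Neta: int = 201) -> MeanDriftFields:
    """Convenience driver: base flow then steady streaming and Stokes drift."""
    if grid is None:
        one_cell = ModelParams(alpha=params.alpha, beta=params.beta, Ri=params.Ri,
                               sigma=params.sigma, n=1, epsilon=params.epsilon)
        grid = make_grid(one_cell, Nx_cell=Nx_cell, Neta=Neta)
    base = base_velocities(params, grid)
    F = reynolds_forcing(base)
    uSS, vSS, dpSSdx = steady_streaming(base, grid, F=F)
    uSD, vSD = stokes_drift(base)
    return MeanDriftFields(params=params, grid=grid, H=base.H, F=F,
                           uSS=uSS, vSS=vSS, dpSSdx=dpSSdx, uSD=uSD, vSD=vSD)


def _peak(fld: np.ndarray, x: np.ndarray, eta: np.ndarray) -> PeakRecord:
    idx = np.unravel_index(np.argmax(np.abs(fld)), fld.shape)
    val = fld[idx]
    return PeakRecord(value=float(abs(val)), x=float(x[idx[0]]),
                      eta=float(eta[idx[1]]), sign=int(np.sign(val)))


def streamfunction_vorticity(u: np.ndarray, H: np.ndarray, grid: Grid) -> FlowDiagnostics:
    """Streamfunction psi (psi = 0 at y = 0) and vorticity Omega = -du/dy.

    psi(x, y) is the cumulative transverse integral of u, so psi at the wavy
    wall equals the net section flux of the diagnosed field (zero for the
    steady streaming and Stokes drift).  Extrema occur in +/- pairs for the
    antisymmetric drift fields; the records report magnitude, location and
    the sign at the located extremum.
    """
    psi = H[:, None] * cumtrapz(u, grid.deta, axis=1)
    Omega = -diff4(u, grid.deta, axis=1) / H[:, None]
    xcoord = grid.x_cell if u.shape[0] == grid.Nx_cell + 1 else grid.x
    return FlowDiagnostics(
        psi=psi,
        Omega=Omega,
        psi_peak=_peak(psi, xcoord, grid.eta),
        Omega_peak=_peak(Omega, xcoord, grid.eta),
    )


def converged_peaks(params: ModelParams, which: str = "ss", rtol: float = 1e-3,
                    Nx0: int = 64, Neta0: int = 129, max_levels: int = 5):
    """Peak |psi| and |Omega| of a drift field on a x2 refinement ladder.

    ``which`` selects the diagnosed velocity: "ss" (steady streaming), "sd"
    (Stokes drift) or "lagrangian" (their sum).  Refinement stops when both
    peaks change by less than ``rtol``; returns a dict with the converged
    values and the grid sizes used.
    """
    if which not in {"ss", "sd", "lagrangian"}:
        raise ValueError(f"unknown field selector {which!r}")
    prev = None
    Nx, Neta = Nx0, Neta0
    for level in range(max_levels):
        drift = compute_mean_drift(params, Nx_cell=Nx, Neta=Neta)
        u = {"ss": drift.uSS, "sd": drift.uSD, "lagrangian": drift.u_lagrangian}[which]
        diag = streamfunction_vorticity(u, drift.H, drift.grid)
        cur = (diag.psi_peak.value, diag.Omega_peak.value)
        if prev is not None and all(
            abs(c - p) <= rtol * max(abs(p), 1e-300) for c, p in zip(cur, prev)
        ):
            break
        prev = cur
        Nx, Neta = 2 * Nx, 2 * (Neta - 1) + 1
    return {
        "psi_peak": cur[0],
        "Omega_peak": cur[1],
        "Nx_cell": drift.grid.Nx_cell,
        "Neta": drift.grid.Neta,
        "levels": level + 1,
    }
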