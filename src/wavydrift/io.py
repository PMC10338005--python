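"""File exports: columnar text for profiles/series, netCDF for fields.

Field containers are self-describing xarray datasets (coordinates, units
and the full config echo in the attributes) written with the scipy netCDF
backend; one-dimensional profiles and time series go to plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import xarray as xr

from .config import RunConfig, config_to_dict
from .meandrift import FlowDiagnostics, MeanDriftFields
from .transport import SimulationResult

__all__ = [
    "meanflow_dataset",
    "export_meanflow",
    "transport_dataset",
    "export_transport",
    "write_qb_series",
]

#: Streamline contour spacings used in the reference figures: the fine one
#: for the alpha=4 / transport plots, the coarse one for alpha=16.
CONTOUR_SPACING = {"fine": 0.003, "coarse": 0.03}


def _attrs(cfg: RunConfig | None) -> dict:
    if cfg is None:
        return {}
    return {"config": json.dumps(config_to_dict(cfg))}


def meanflow_dataset(drift: MeanDriftFields, diag_ss: FlowDiagnostics,
                     diag_lag: FlowDiagnostics, cfg: RunConfig | None = None) -> xr.Dataset:
    """Bundle the steady drift fields and diagnostics on the one-cell grid."""
    g = drift.grid
    coords = {"x": g.x_cell, "eta": g.eta}
    dims = ("x", "eta")
    ds = xr.Dataset(
        {
            "H": ("x", drift.H),
            "F": (dims, drift.F),
            "uSS": (dims, drift.uSS),
            "vSS": (dims, drift.vSS),
            "uSD": (dims, drift.uSD),
            "vSD": (dims, drift.vSD),
            "dpSSdx": ("x", drift.dpSSdx),
            "psi_ss": (dims, diag_ss.psi),
            "Omega_ss": (dims, diag_ss.Omega),
            "psi_lagrangian": (dims, diag_lag.psi),
            "Omega_lagrangian": (dims, diag_lag.Omega),
        },
        coords=coords,
        attrs={
            "alpha": drift.params.alpha,
            "beta": drift.params.beta,
            "contour_spacing_psi": CONTOUR_SPACING[
                "coarse" if drift.params.alpha >= 10 else "fine"],
            **_attrs(cfg),
        },
    )
    return ds


def export_meanflow(drift: MeanDriftFields, diag_ss: FlowDiagnostics,
                    diag_lag: FlowDiagnostics, outdir: str | Path,
                    cfg: RunConfig | None = None) -> None:
    """Write fields.csv, fields.nc and peaks.json into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    g = drift.grid
    X = np.repeat(g.x_cell, g.Neta)
    ETA = np.tile(g.eta, g.Nx_cell + 1)
    Y = ETA * np.repeat(drift.H, g.Neta)
    cols = np.column_stack([
        X, Y, drift.uSS.ravel(), drift.vSS.ravel(), drift.uSD.ravel(),
        drift.vSD.ravel(), diag_lag.psi.ravel(), diag_lag.Omega.ravel(),
    ])
    np.savetxt(out / "fields.csv", cols, delimiter=",",
               header="x,y,uSS,vSS,uSD,vSD,psi_lagrangian,Omega_lagrangian",
               comments="")
    meanflow_dataset(drift, diag_ss, diag_lag, cfg).to_netcdf(
        out / "fields.nc", engine="scipy")
    peaks = {
        "steady_streaming": {"psi": diag_ss.psi_peak.value,
                             "Omega": diag_ss.Omega_peak.value},
        "lagrangian": {"psi": diag_lag.psi_peak.value,
                       "Omega": diag_lag.Omega_peak.value},
    }
    (out / "peaks.json").write_text(json.dumps(peaks, indent=2))


def transport_dataset(result: SimulationResult, cfg: RunConfig | None = None) -> xr.Dataset:
    """Snapshot stack c(tau, x, eta) with conservation diagnostics."""
    g = result.grid
    taus = [s.tau for s in result.snapshots]
    ds = xr.Dataset(
        {
            "c": (("tau", "x", "eta"), np.stack([s.c for s in result.snapshots])),
            "C": (("tau", "x"), np.stack([s.diagnostics.C for s in result.snapshots])),
            "phi": (("tau", "x"), np.stack([s.diagnostics.phi for s in result.snapshots])),
            "M": ("tau", np.array([s.diagnostics.M for s in result.snapshots])),
            "QB": ("tau", np.array([s.QB for s in result.snapshots])),
            "cell_masses": (("tau", "cell"), np.stack(
                [s.diagnostics.cell_masses for s in result.snapshots])),
        },
        coords={"tau": taus, "x": g.x, "eta": g.eta,
                "cell": np.arange(g.n)},
        attrs={"alpha": result.params.alpha, "beta": result.params.beta,
               "Ri": result.params.Ri, "sigma": result.params.sigma,
               **_attrs(cfg)},
    )
    return ds


def export_transport(result: SimulationResult, outdir: str | Path,
                     cfg: RunConfig | None = None) -> None:
    """Write snapshots.nc, profiles C(x) per snapshot and the QB series."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    transport_dataset(result, cfg).to_netcdf(out / "snapshots.nc", engine="scipy")
    g = result.grid
    prof = np.column_stack(
        [g.x] + [s.diagnostics.C for s in result.snapshots])
    header = "x," + ",".join(f"C_tau={s.tau:g}" for s in result.snapshots)
    np.savetxt(out / "solute_per_length.csv", prof, delimiter=",",
               header=header, comments="")
    write_qb_series(result, out / "qb_series.csv")


def write_qb_series(result: SimulationResult, path: str | Path) -> None:
    np.savetxt(path, result.qb_series, delimiter=",", header="tau,QB",
               comments="")
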