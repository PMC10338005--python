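"""Run configuration: validated parameter sets, presets and time conversions.

A run is fully specified by the dimensionless control parameters, the grid
sizes, the initial-bolus parameters and the time horizon.  Presets encode
the canonical scenarios used to exercise the model: the buoyancy-free
mean-flow cases (``fig2-*``), the trapped-bolus and buoyant-bolus transport
cases (``fig3``, ``fig4-base``) and one-parameter sweeps about the base
case (``fig5-*``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import yaml

from .channel import ModelParams
from .transport import ICSpec

__all__ = ["RunConfig", "PRESETS", "SWEEPS", "load_config", "cycles_from_tau"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a transport or mean-flow run."""

    params: ModelParams = field(default_factory=ModelParams)
    Nx_cell: int = 200
    Neta: int = 101
    ic: ICSpec = field(default_factory=ICSpec)
    tau_end: float = 8.0
    snapshot_dt: float = 1.0
    outdir: str = "wavydrift-out"
    preset: str | None = None

    def __post_init__(self) -> None:
        if not self.tau_end > 0:
            raise ValueError(f"tau_end must be positive, got {self.tau_end}")
        if not self.snapshot_dt > 0:
            raise ValueError(f"snapshot_dt must be positive, got {self.snapshot_dt}")


def _preset(alpha, beta, Ri, sigma, n=3, x0=1.75, delta=0.2, tau_end=8.0):
    return RunConfig(
        params=ModelParams(alpha=alpha, beta=beta, Ri=Ri, sigma=sigma, n=n),
        ic=ICSpec(x0=x0, delta=delta),
        tau_end=tau_end,
    )


#: Canonical scenario presets.  The transport base case is
#: beta=0.2, alpha=4, sigma=Ri=1 on a three-cell channel with the truncated
#: Gaussian bolus centred at x0=1.75 with width delta=0.2.
PRESETS: dict[str, RunConfig] = {
    "fig2-alpha4": _preset(alpha=4, beta=0.4, Ri=0.0, sigma=1.0, n=1),
    "fig2-alpha16": _preset(alpha=16, beta=0.4, Ri=0.0, sigma=1.0, n=1),
    "fig3": _preset(alpha=4, beta=0.2, Ri=0.0, sigma=1.0),
    "fig4-base": _preset(alpha=4, beta=0.2, Ri=1.0, sigma=1.0),
}

#: One-parameter sweeps about the base case (parameter name, values).
SWEEPS: dict[str, tuple[str, tuple[float, ...]]] = {
    "fig5-beta": ("beta", (0.1, 0.2, 0.3, 0.4)),
    "fig5-sigma": ("sigma", (0.25, 1.0, 8.0)),
    "fig5-Ri": ("Ri", (0.25, 1.0, 4.0)),
    "fig5-alpha": ("alpha", (4.0, 16.0)),
}

_SECTIONS = {
    "preset": None,
    "params": {"alpha", "beta", "Ri", "sigma", "n", "epsilon"},
    "grid": {"Nx_cell", "Neta"},
    "ic": {"x0", "delta"},
    "run": {"tau_end", "snapshot_dt", "outdir"},
}


def _validate_keys(mapping: dict, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file and/or flat override values.

    The file uses the sections ``preset``, ``params``, ``grid``, ``ic`` and
    ``run``; unknown keys are rejected with an itemised error.  Overrides
    (flat names such as ``alpha``, ``Nx_cell``, ``tau_end``) win over the
    file, which wins over the preset, which wins over the defaults.
    """
    doc: dict = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"config root must be a mapping, got {type(doc).__name__}")
        _validate_keys(doc, set(_SECTIONS), "config")
        for section, allowed in _SECTIONS.items():
            if allowed is not None and section in doc:
                if not isinstance(doc[section], dict):
                    raise ValueError(f"config section {section!r} must be a mapping")
                _validate_keys(doc[section], allowed, f"section {section!r}")

    preset_name = doc.get("preset")
    if overrides and "preset" in overrides:
        preset_name = overrides.pop("preset")
    if preset_name is not None and preset_name not in PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; available: {sorted(PRESETS)}"
        )
    cfg = PRESETS[preset_name] if preset_name else RunConfig()
    cfg = replace(cfg, preset=preset_name)

    flat: dict = {}
    for section in ("params", "grid", "ic", "run"):
        flat.update(doc.get(section, {}))
    if overrides:
        allowed = set().union(*(v for v in _SECTIONS.values() if v))
        _validate_keys(overrides, allowed, "overrides")
        flat.update({k: v for k, v in overrides.items() if v is not None})

    p = {f: getattr(cfg.params, f) for f in ("alpha", "beta", "Ri", "sigma", "n", "epsilon")}
    p.update({k: flat[k] for k in p if k in flat})
    i = {f: getattr(cfg.ic, f) for f in ("x0", "delta")}
    i.update({k: flat[k] for k in i if k in flat})
    return replace(
        cfg,
        params=ModelParams(**p),
        ic=ICSpec(**i),
        Nx_cell=int(flat.get("Nx_cell", cfg.Nx_cell)),
        Neta=int(flat.get("Neta", cfg.Neta)),
        tau_end=float(flat.get("tau_end", cfg.tau_end)),
        snapshot_dt=float(flat.get("snapshot_dt", cfg.snapshot_dt)),
        outdir=str(flat.get("outdir", cfg.outdir)),
    )


def config_to_dict(cfg: RunConfig) -> dict:
    """Round-trippable plain-dict form of a RunConfig (the config echo)."""
    return {
        "preset": cfg.preset,
        "params": {f: getattr(cfg.params, f)
                   for f in ("alpha", "beta", "Ri", "sigma", "n", "epsilon")},
        "grid": {"Nx_cell": cfg.Nx_cell, "Neta": cfg.Neta},
        "ic": {"x0": cfg.ic.x0, "delta": cfg.ic.delta},
        "run": {"tau_end": cfg.tau_end, "snapshot_dt": cfg.snapshot_dt,
                "outdir": cfg.outdir},
    }


def dump_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


class TimeConversion(NamedTuple):
    fast_time: float
    cycles: float


def cycles_from_tau(tau: float, epsilon: float) -> TimeConversion:
    """Convert slow time tau to fast-time units and oscillation counts.

    tau = epsilon^2 * t, so t = tau/epsilon^2 and the number of oscillation
    cycles is t/(2*pi).  With the reference stroke-length ratio
    epsilon = 0.02, tau = 8 corresponds to t = 20000 (about 3200 cycles).
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    import math

    t = tau / epsilon**2
    return TimeConversion(fast_time=t, cycles=t / (2 * math.pi))
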