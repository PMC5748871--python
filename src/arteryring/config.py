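"""TOML run configuration: parsing, unit handling, and output writers.

A run is specified either dimensionlessly (the normalized groups directly)
or physically (geometry + material + pulse, from which the groups are
derived). All internal computation is SI; pressures may be given in Pa,
kPa or mmHg and lengths in m or mm via explicit ``units`` keys.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .constitutive import (
    ArteryGeometry,
    HaritonParams,
    MooneyRivlinParams,
    SkalakParams,
)
from .dynamics import DimensionlessGroups, groups_from_physical
from .loading import PressurePulse, mmHg_to_Pa
from .solver import ResponseSummary, ResponseTrace, SolverSettings

__all__ = ["RunConfig", "load_config", "write_outputs", "ConfigError"]

_PRESSURE_UNITS = {"Pa": 1.0, "kPa": 1e3, "mmHg": None}
_LENGTH_UNITS = {"m": 1.0, "mm": 1e-3}


class ConfigError(ValueError):
    """Configuration schema violation; the message names the offending key."""


def _pressure_si(value, units):
    if units not in _PRESSURE_UNITS:
        raise ConfigError(f"unknown pressure units {units!r} "
                          "(expected Pa, kPa or mmHg)")
    if units == "mmHg":
        return mmHg_to_Pa(value)
    return float(value) * _PRESSURE_UNITS[units]


def _length_si(value, units):
    if units not in _LENGTH_UNITS:
        raise ConfigError(f"unknown length units {units!r} (expected m or mm)")
    return float(value) * _LENGTH_UNITS[units]


@dataclass
class RunConfig:
    """Validated run description ready for the solver."""

    mode: str
    law: str
    groups: DimensionlessGroups
    geometry: ArteryGeometry | None = None
    params: object | None = None
    pulse: PressurePulse | None = None
    settings: SolverSettings = None  # type: ignore[assignment]
    outputs: dict = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.settings is None:
            self.settings = SolverSettings()
        if self.outputs is None:
            self.outputs = {}


def _require(table, key, where):
    if key not in table:
        raise ConfigError(f"missing required key {where}.{key}")
    return table[key]


def _build_pulse(table) -> PressurePulse:
    units = table.get("units", "Pa")
    ps = _pressure_si(_require(table, "ps", "pulse"), units)
    pd_ = _pressure_si(_require(table, "pd", "pulse"), units)
    if ps < pd_:
        raise ConfigError("pulse.ps must be >= pulse.pd")
    return PressurePulse(
        ps=ps, pd=pd_,
        ts=float(table.get("ts", 0.35)),
        tcp=float(table.get("tcp", 1.0)),
        n_cycles=int(table.get("n_cycles", 1)),
    )


def _build_params(law, table):
    units = table.get("units", "Pa")
    if law == "skalak":
        # B and C are membrane moduli [N/m]; no unit scaling applied
        return SkalakParams(B=float(_require(table, "B", "material")),
                            C=float(_require(table, "C", "material")))
    if law == "hariton":
        return HaritonParams(
            a=_pressure_si(_require(table, "a", "material"), units),
            b=float(_require(table, "b", "material")))
    if law == "mooney_rivlin":
        return MooneyRivlinParams(
            mu=_pressure_si(_require(table, "mu", "material"), units),
            beta=float(table.get("beta", 0.0)))
    raise ConfigError(f"unknown law {law!r}")


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    mode = raw.get("mode", "dimensionless")
    if mode not in ("dimensionless", "physical"):
        raise ConfigError(f"mode must be 'dimensionless' or 'physical', "
                          f"got {mode!r}")
    law = _require(raw, "law", "<top level>")
    if ("groups" in raw) == (mode == "physical"):
        raise ConfigError("dimensionless mode requires a [groups] table; "
                          "physical mode requires [geometry]/[material]/"
                          "[pulse] instead")

    sset = raw.get("solver", {})
    settings = SolverSettings(
        method=sset.get("method", "LSODA"),
        rtol=float(sset.get("rtol", 1e-8)),
        atol=float(sset.get("atol", 1e-10)),
        samples_per_cycle=int(sset.get("samples_per_cycle", 5000)),
    )

    geometry = params = pulse = None
    if mode == "dimensionless":
        g = raw["groups"]
        groups = DimensionlessGroups(
            law=law,
            material_ratio=float(g.get("material_ratio", 0.0)),
            p_hat_s=float(_require(g, "p_hat_s", "groups")),
            lam_z0=float(g.get("lam_z0", 1.0)),
            time_ratio=float(_require(g, "time_ratio", "groups")),
            duty=float(g.get("duty", 0.35)),
            pressure_ratio=float(g.get("pressure_ratio", 10660.0 / 16000.0)),
            n_cycles=int(g.get("n_cycles", 1)),
            order=int(g.get("order", 3)),
            tcp_seconds=float(g.get("tcp_seconds", 1.0)),
        )
    else:
        gt = _require(raw, "geometry", "<top level>")
        lu = gt.get("units", "m")
        geometry = ArteryGeometry(
            R=_length_si(_require(gt, "R", "geometry"), lu),
            H=_length_si(_require(gt, "H", "geometry"), lu),
            rho0=float(gt.get("rho0", 1160.0)),
            lam_z0=float(gt.get("lam_z0", 1.0)),
        )
        params = _build_params(law, _require(raw, "material", "<top level>"))
        pulse = _build_pulse(raw.get("pulse", {"ps": 16000.0, "pd": 10660.0}))
        groups = groups_from_physical(law, params, geometry, pulse)

    return RunConfig(mode=mode, law=law, groups=groups, geometry=geometry,
                     params=params, pulse=pulse, settings=settings,
                     outputs=raw.get("output", {}))


def write_outputs(trace: ResponseTrace, summary: ResponseSummary,
                  trace_csv=None, summary_json=None, log_path=None,
                  config_echo=None):
    """Write the trace CSV, summary JSON, and a provenance log."""
    written = {}
    if trace_csv:
        trace.to_dataframe().to_csv(trace_csv, index=False)
        written["trace_csv"] = str(trace_csv)
    if summary_json:
        payload = {
            name: {"peak": pk.value, "t_peak_s": pk.t_peak_s}
            for name, pk in summary.peaks.items()
        }
        payload["diverged"] = summary.diverged
        with open(summary_json, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        written["summary_json"] = str(summary_json)
    if log_path:
        g = trace.groups
        lines = [
            f"arteryring {__version__}",
            f"law={g.law} material_ratio={g.material_ratio} "
            f"p_hat_s={g.p_hat_s} lam_z0={g.lam_z0} "
            f"time_ratio={g.time_ratio} duty={g.duty} "
            f"pressure_ratio={g.pressure_ratio} n_cycles={g.n_cycles} "
            f"order={g.order}",
            f"samples={len(trace.tau)} diverged={trace.diverged} "
            f"termination={trace.termination}",
        ]
        if config_echo:
            lines.append(f"config: {config_echo}")
        with open(log_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        written["log"] = str(log_path)
    return written
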