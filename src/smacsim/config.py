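"""Run configuration: TOML parsing, validation and round-tripping.

A run config is a TOML file with sections ``[physical]``, ``[grid]``,
``[bc]``, ``[ic]``, ``[solver]``, ``[analysis]``, ``[output]`` and optionally
``[groups]`` (explicit dimensionless numbers overriding those derived from
the physical parameters, e.g. to run at a nominal B = 2e-9).  Unknown keys
are rejected.  Dot-path overrides (``grid.n=64``) come from the command
line.  Times may be given either dimensionless (``t_end``, tau_mu units) or
in dimensional minutes (``t_end_minutes``).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass

from .boundary import BoundaryCondition
from .engine import InitialCondition, SolverConfig
from .grid import Grid
from .parameters import (
    DimensionlessGroups,
    InvalidParameterError,
    PhysicalParameters,
    default_parameters,
    dimensionless_groups,
    parameters_from_dict,
)
from .patterns import AnalysisConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "config_from_dict", "parse_overrides"]

_SECTIONS = ("physical", "groups", "grid", "bc", "ic", "solver", "analysis", "output")


class ConfigError(ValueError):
    """Raised for malformed run configurations."""


@dataclass
class RunConfig:
    params: PhysicalParameters
    grid: Grid
    bc: BoundaryCondition
    ic: InitialCondition
    solver: SolverConfig
    analysis: AnalysisConfig
    groups: DimensionlessGroups | None = None
    output: str = "run.h5"
    eval_time_minutes: float = 40.0

    def resolved_groups(self) -> DimensionlessGroups:
        return self.groups if self.groups is not None else dimensionless_groups(self.params)


def _check_keys(section: str, raw: dict, allowed) -> None:
    unknown = set(raw) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")


def _build(cls, section: str, raw: dict, extra_allowed=()):
    names = [f.name for f in dataclasses.fields(cls)]
    _check_keys(section, raw, list(names) + list(extra_allowed))
    kwargs = {k: v for k, v in raw.items() if k in names}
    try:
        return cls(**kwargs), {k: v for k, v in raw.items() if k not in names}
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{section}] section: {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    _check_keys("<top level>", data, _SECTIONS)

    phys_raw = data.get("physical", {})
    if phys_raw:
        # a partial [physical] table would silently mix user values with the
        # packaged defaults, so demand the full set (use [groups] for
        # dimensionless tweaks instead)
        required = {f.name for f in dataclasses.fields(PhysicalParameters)}
        missing = required - set(phys_raw)
        if missing:
            raise ConfigError(f"missing key(s) in [physical]: {sorted(missing)}")
    try:
        params = parameters_from_dict(phys_raw) if phys_raw else default_parameters()
    except InvalidParameterError as exc:
        raise ConfigError(f"invalid [physical] section: {exc}") from exc

    groups = None
    if "groups" in data:
        base = dataclasses.asdict(dimensionless_groups(params))
        _check_keys("groups", data["groups"], base.keys())
        base.update(data["groups"])
        groups = DimensionlessGroups(**base)

    grid_raw = dict(data.get("grid", {}))
    _check_keys("grid", grid_raw, ("n", "geometry", "ny"))
    try:
        grid = Grid(**{**{"n": 64, "geometry": "disk"}, **grid_raw})
    except ValueError as exc:
        raise ConfigError(f"invalid [grid] section: {exc}") from exc

    bc, _ = _build(BoundaryCondition, "bc", data.get("bc", {}))
    ic_raw = dict(data.get("ic", {}))
    if "amp_range" in ic_raw:
        ic_raw["amp_range"] = tuple(ic_raw["amp_range"])
    ic, _ = _build(InitialCondition, "ic", ic_raw)

    solver_raw = dict(data.get("solver", {}))
    tau_mu = params.tau_mu
    if "t_end_minutes" in solver_raw:
        solver_raw["t_end"] = float(solver_raw.pop("t_end_minutes")) * 60.0 / tau_mu
    if "snapshot_every_minutes" in solver_raw:
        solver_raw["snapshot_every"] = (
            float(solver_raw.pop("snapshot_every_minutes")) * 60.0 / tau_mu
        )
    solver_raw.setdefault("t_end", 40.0 * 60.0 / tau_mu)
    solver_raw.setdefault("snapshot_every", solver_raw["t_end"] / 8.0)
    solver, _ = _build(SolverConfig, "solver", solver_raw)

    analysis_raw = dict(data.get("analysis", {}))
    eval_time = float(analysis_raw.pop("eval_time_minutes", 40.0))
    analysis, _ = _build(AnalysisConfig, "analysis", analysis_raw)

    out_raw = data.get("output", {})
    _check_keys("output", out_raw, ("path",))

    return RunConfig(
        params=params,
        grid=grid,
        bc=bc,
        ic=ic,
        solver=solver,
        analysis=analysis,
        groups=groups,
        output=out_raw.get("path", "run.h5"),
        eval_time_minutes=eval_time,
    )


def parse_overrides(pairs) -> dict:
    """Turn ``section.key=value`` strings into a nested dict."""
    out: dict = {}
    for pair in pairs:
        if "=" not in pair:
            raise ConfigError(f"override {pair!r} is not of the form section.key=value")
        dotted, value = pair.split("=", 1)
        parts = dotted.strip().split(".")
        if len(parts) != 2:
            raise ConfigError(f"override key {dotted!r} must be section.key")
        section, key = parts
        try:
            parsed = tomllib.loads(f"v = {value}")["v"]
        except tomllib.TOMLDecodeError:
            parsed = value  # bare string
        out.setdefault(section, {})[key] = parsed
    return out


def _merge(base: dict, override: dict) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for sec, vals in override.items():
        if isinstance(vals, dict):
            out.setdefault(sec, {}).update(vals)
        else:
            out[sec] = vals
    return out


def load_config(path=None, overrides=None) -> RunConfig:
    """Load a TOML run config, applying dot-path overrides on top."""
    data: dict = {}
    if path is not None:
        try:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if overrides:
        data = _merge(data, parse_overrides(overrides) if not isinstance(overrides, dict) else overrides)
    return config_from_dict(data)
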