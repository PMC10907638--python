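"""Structured run configuration with unit-bearing key names.

The configuration is YAML with five sections — ``cell_model``,
``regulation``, ``drug``, ``solver``, ``experiment`` — every key carrying
its unit in the name (e.g. ``tau_m_mM_ms``), which keeps the two
differently-united protein time constants apart. Unknown keys are rejected
with the offending key named; an empty file yields the full defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError, InvalidParameterError
from .regulation import RegulationParams

__all__ = ["RunConfig", "load_config", "save_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "cell_model": {
        "variant": "minimal_hipsc_cm",
        "scale_factors": {},  # protein label -> density factor
    },
    "regulation": {
        "tau_m_mM_ms": 400.0,
        "tau_n_traffic_ms": 1000.0,
        "tau_scalar_mM_ms": 400.0,
        "c_target_mM": None,  # None: computed from the default limit cycle
        "n_minus": 0.1,
        "n_plus": 3.0,
        "eps_n": 0.01,
        "eps_c_mM": 1e-7,
    },
    "drug": {
        "dose_block_table": {"0.1uM": 0.45, "1uM": 0.12},
    },
    "solver": {
        "method": "LSODA",
        "rtol": 1e-6,
        "atol_voltage": 1e-8,
        "atol_calcium": 1e-10,
    },
    "experiment": {
        "horizon_h": 16.0,
        "snapshot_times_h": [2.0, 4.0, 6.0, 8.0, 13.0, 16.0],
        "seed": 0,
    },
    "output": {
        "directory": "out",
    },
}


@dataclass
class RunConfig:
    """Validated configuration; sections mirror :data:`DEFAULT_CONFIG`."""

    cell_model: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG["cell_model"]))
    regulation: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG["regulation"]))
    drug: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG["drug"]))
    solver: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG["solver"]))
    experiment: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG["experiment"]))
    output: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG["output"]))

    def regulation_params(self, c_target_mM: float | None = None) -> RegulationParams:
        """Build RegulationParams; the calcium target may be supplied late."""
        reg = dict(self.regulation)
        c_star = reg.pop("c_target_mM")
        if c_target_mM is not None:
            c_star = c_target_mM
        if c_star is None:
            raise ConfigurationError(
                "c_target_mM unset: compute it from the cell model first"
            )
        try:
            return RegulationParams(c_target_mM=float(c_star), **reg)
        except InvalidParameterError as exc:
            raise ConfigurationError(f"regulation section invalid: {exc}") from exc

    def to_dict(self) -> dict:
        return asdict(self)


def _merge_section(name: str, defaults: dict, user: dict) -> dict:
    out = dict(defaults)
    for key, value in user.items():
        if key not in defaults:
            raise ConfigurationError(f"unknown key {name}.{key}")
        if isinstance(defaults[key], dict) and not isinstance(value, dict):
            raise ConfigurationError(f"{name}.{key} must be a mapping")
        out[key] = value
    return out


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; missing keys take the defaults.

    Numeric sanity checks (positive time scales, bound ordering, block
    factors in (0, 1]) run at load time so errors surface with the file,
    not deep inside a simulation.
    """
    user: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        user = yaml.safe_load(raw) or {}
        if not isinstance(user, dict):
            raise ConfigurationError("config root must be a mapping")
    for section in user:
        if section not in DEFAULT_CONFIG:
            raise ConfigurationError(f"unknown section {section!r}")
    sections = {
        name: _merge_section(name, DEFAULT_CONFIG[name], user.get(name, {}))
        for name in DEFAULT_CONFIG
    }
    cfg = RunConfig(**sections)

    for key in ("tau_m_mM_ms", "tau_n_traffic_ms", "tau_scalar_mM_ms"):
        if not cfg.regulation[key] > 0:
            raise ConfigurationError(f"regulation.{key} must be strictly positive")
    if not (0 < cfg.regulation["n_minus"] < cfg.regulation["n_plus"]):
        raise ConfigurationError("regulation bounds must satisfy 0 < n_minus < n_plus")
    for key in ("eps_n", "eps_c_mM"):
        if not cfg.regulation[key] > 0:
            raise ConfigurationError(f"regulation.{key} must be strictly positive")
    c_star = cfg.regulation["c_target_mM"]
    if c_star is not None and not c_star > 0:
        raise ConfigurationError("regulation.c_target_mM must be positive when set")
    for dose, b in cfg.drug["dose_block_table"].items():
        if not 0 < b <= 1:
            raise ConfigurationError(
                f"drug.dose_block_table[{dose!r}] must lie in (0, 1]"
            )
    if not cfg.solver["rtol"] > 0:
        raise ConfigurationError("solver.rtol must be positive")
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    """Write a config back to YAML (round-trips through load_config)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
    return path
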