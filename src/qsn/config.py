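"""Structured-text run configuration: parsing, validation, serialization.

Configs are TOML with one block per model plus run/experiment settings.
Quantity values may be plain numbers (SI) or strings with a unit suffix
("375 us", "1.5 pF", "60 pA", "26 mV"), normalized to SI on load. Unknown
keys are rejected with the path to the offending key.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig", "load_config", "dump_config", "parse_quantity",
           "ConfigError"]


class ConfigError(ValueError):
    pass


_UNITS = {
    "V": 1.0, "mV": 1e-3, "uV": 1e-6,
    "A": 1.0, "mA": 1e-3, "uA": 1e-6, "nA": 1e-9, "pA": 1e-12, "fA": 1e-15,
    "s": 1.0, "ms": 1e-3, "us": 1e-6, "ns": 1e-9,
    "F": 1.0, "uF": 1e-6, "nF": 1e-9, "pF": 1e-12, "fF": 1e-15,
    "Hz": 1.0, "kHz": 1e3,
}


def parse_quantity(value):
    """'375 us' -> 3.75e-4; bare numbers pass through unchanged."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if not isinstance(value, str):
        raise ConfigError(f"cannot interpret {value!r} as a quantity")
    parts = value.split()
    if len(parts) == 1:  # maybe '375us'
        for u in sorted(_UNITS, key=len, reverse=True):
            if value.endswith(u):
                num = value[: -len(u)].strip()
                try:
                    return float(num) * _UNITS[u]
                except ValueError:
                    break
        try:
            return float(value)
        except ValueError:
            raise ConfigError(f"malformed quantity {value!r}") from None
    if len(parts) == 2 and parts[1] in _UNITS:
        return float(parts[0]) * _UNITS[parts[1]]
    raise ConfigError(f"malformed quantity {value!r}")


_SCHEMA = {
    "run": {"model", "preset", "dt", "T", "seed", "scheme", "out_dir",
            "I_stim", "spike_threshold", "v0", "n0", "q0"},
    "analog_sn": {"C_v", "I_a", "tau_n", "tau_q", "M_m", "delta_m", "M_n",
                  "delta_n", "M_q", "delta_q", "S", "theta_v", "U_T",
                  "kappa"},
    "ulp_sn": {"C_v", "C_n", "I_av", "I_an", "I_0P", "M_v", "delta_v",
               "Rv20", "Rv21", "theta_gv", "M_n", "delta_n", "Rn20",
               "Rn21", "theta_gn", "theta_r", "U_T", "kappa"},
    "dssn": {"phi", "tau", "I_0", "a_fn", "b_fn", "c_fn", "a_fp", "b_fp",
             "c_fp", "a_gn", "b_gn", "c_gn", "a_gp", "b_gp", "c_gp", "r_g",
             "fixed_point"},
    "dssn.fixed_point": {"total_bits", "frac_bits", "rounding", "overflow"},
    "synapse": {"alpha", "beta"},
    "stdp": {"A_plus", "A_minus", "tau_plus", "tau_minus"},
    "experiment": {"kind", "error_levels", "trials_per_level", "n_patterns",
                   "max_pairwise_overlap", "I_ext", "pulse_amp",
                   "pulse_duration", "c", "T_total", "theta_M",
                   "theta_other", "mode"},
}
_STRING_KEYS = {"model", "preset", "scheme", "out_dir", "rounding",
                "overflow", "kind", "mode"}
_INT_KEYS = {"seed", "total_bits", "frac_bits", "trials_per_level",
             "n_patterns"}


@dataclass
class RunConfig:
    """Fully resolved configuration: nested dict of SI-valued blocks."""

    blocks: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.blocks[key]

    def get(self, key, default=None):
        return self.blocks.get(key, default)

    def manifest(self) -> dict:
        from . import __version__
        return {"config": self.blocks, "qsn_version": __version__}


def _normalize(block_name: str, block: dict) -> dict:
    allowed = _SCHEMA.get(block_name)
    if allowed is None:
        raise ConfigError(f"unknown config block [{block_name}]")
    out = {}
    for key, val in block.items():
        if key not in allowed:
            raise ConfigError(f"unknown key '{block_name}.{key}'")
        if isinstance(val, dict):
            out[key] = _normalize(f"{block_name}.{key}", val)
        elif key in _STRING_KEYS:
            if not isinstance(val, str):
                raise ConfigError(f"'{block_name}.{key}' must be a string")
            out[key] = val
        elif key in _INT_KEYS:
            out[key] = int(val)
        elif isinstance(val, list):
            out[key] = [parse_quantity(v) for v in val]
        else:
            out[key] = parse_quantity(val)
    return out


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    try:
        raw = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from None
    blocks = {name: _normalize(name, blk) for name, blk in raw.items()}
    return RunConfig(blocks)


def _toml_value(v):
    if isinstance(v, str):
        return '"' + v.replace('"', '\\"') + '"'
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, int):
        return str(v)
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, list):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise ConfigError(f"cannot serialize {v!r}")


def dump_config(cfg: RunConfig, path) -> None:
    """Write a config back out; load(dump(load(x))) is identity."""
    lines = []
    def emit(name, block):
        sub = {k: v for k, v in block.items() if isinstance(v, dict)}
        flat = {k: v for k, v in block.items() if not isinstance(v, dict)}
        lines.append(f"[{name}]")
        for k, v in flat.items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
        for k, v in sub.items():
            emit(f"{name}.{k}", v)
    for name, block in cfg.blocks.items():
        emit(name, block)
    Path(path).write_text("\n".join(lines))
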