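"""Versioned mode presets: tuner-derived parameter sets for each model.

Each preset file records the parameters, the analysis fixtures frozen at
first characterization, and the simulation protocol (dt, sweep grids) the
characterization used.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources

from .analog import (AnalogFastSubsystem, AnalogSNParams, SigmoidSpec,
                     TanhSpec)
from .common import ThermalConstants
from .dssn import DSSNParams, DSSNPlanar
from .ulp import ULPCurveSpec, ULPPlanar, ULPSNParams

__all__ = ["Preset", "load_preset", "available_presets"]


@dataclass
class Preset:
    name: str
    model: str       # 'analog' | 'ulp' | 'dssn'
    mode: str        # 'class1' | 'class2' | 'square_wave' | ...
    params: object
    protocol: dict
    analysis: dict
    network: dict
    meta: dict

    def planar(self):
        """Dynamics-toolkit adapter (the fast subsystem for the analog
        model, with q at its preset resting value)."""
        proto = self.protocol
        kw = dict(v_range=tuple(proto.get("v_range", ())) or None,
                  dt=proto.get("dt"),
                  spike_threshold=proto.get("spike_threshold", 0.0))
        kw = {k: v for k, v in kw.items() if v is not None}
        if self.model == "dssn":
            return DSSNPlanar(self.params, **kw)
        if self.model == "ulp":
            return ULPPlanar(self.params, **kw)
        q = self.analysis.get("q_rest", 0.0)
        return AnalogFastSubsystem(self.params, q=q, **kw)


def available_presets():
    files = resources.files("qsn.presets")
    return sorted(f.name[:-5] for f in files.iterdir()
                  if f.name.endswith(".toml"))


def _analog_params(d: dict) -> AnalogSNParams:
    consts = ThermalConstants(d.get("U_T", 0.026), d.get("kappa", 0.7))
    return AnalogSNParams(
        C_v=d["C_v"], I_a=d["I_a"], tau_n=d["tau_n"], tau_q=d["tau_q"],
        fm=SigmoidSpec(d["M_m"], d["delta_m"]),
        fn=SigmoidSpec(d["M_n"], d["delta_n"]),
        fq=SigmoidSpec(d["M_q"], d["delta_q"]),
        g=TanhSpec(d["S"], d["theta_v"]), consts=consts)


def _ulp_params(d: dict) -> ULPSNParams:
    consts = ThermalConstants(d.get("U_T", 0.026), d.get("kappa", 0.7))
    return ULPSNParams(
        C_v=d["C_v"], C_n=d["C_n"], I_av=d["I_av"], I_an=d["I_an"],
        I_0P=d["I_0P"],
        curve_v=ULPCurveSpec(d["M_v"], d["delta_v"], d["Rv20"], d["Rv21"],
                             d["theta_gv"]),
        curve_n=ULPCurveSpec(d["M_n"], d["delta_n"], d["Rn20"], d["Rn21"],
                             d["theta_gn"]),
        theta_r=d["theta_r"], consts=consts)


def _dssn_params(d: dict) -> DSSNParams:
    return DSSNParams(**d)


def load_preset(name: str) -> Preset:
    path = resources.files("qsn.presets").joinpath(name + ".toml")
    try:
        data = tomllib.loads(path.read_text())
    except FileNotFoundError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{available_presets()}") from None
    meta = data.get("meta", {})
    model = meta["model"]
    builder = {"analog": _analog_params, "ulp": _ulp_params,
               "dssn": _dssn_params}[model]
    return Preset(name=name, model=model, mode=meta.get("mode", ""),
                  params=builder(data["params"]),
                  protocol=data.get("protocol", {}),
                  analysis=data.get("analysis", {}),
                  network=data.get("network", {}),
                  meta=meta)
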