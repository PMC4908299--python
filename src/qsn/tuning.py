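"""Default tuner search spaces per model family."""

from __future__ import annotations

from .analog import AnalogFastSubsystem
from .dssn import DSSNPlanar
from .ulp import ULPPlanar

__all__ = ["default_search"]


def default_search(preset, budget: int = 200) -> dict:
    """Bounds and builder for tune_mode, seeded at a preset's parameters."""
    params = preset.params
    if preset.model == "dssn":
        bounds = {
            "phi": (0.05, 4.0, "log"),
            "I_0": (-1.5, 0.5, "lin"),
            "a_gn": (0.05, 10.0, "log"),
            "b_gn": (-2.0, 0.0, "lin"),
            "c_gn": (-4.0, 0.0, "lin"),
        }
        builder = DSSNPlanar
    elif preset.model == "ulp":
        bounds = {
            "I_av": (1e-10, 1e-8, "log"),
            "I_an": (1e-11, 1e-9, "log"),
            "M_v": (5e-10, 1e-8, "log"),
            "M_n": (5e-10, 1e-8, "log"),
            "delta_n": (0.4, 0.7, "lin"),
        }
        builder = ULPPlanar
    else:
        bounds = {
            "M_m": (5e-10, 1e-8, "log"),
            "M_n": (5e-10, 1e-8, "log"),
            "delta_n": (-0.1, 0.1, "lin"),
            "S": (2e-10, 5e-9, "log"),
            "theta_v": (-0.18, 0.0, "lin"),
            "I_a": (1e-11, 1e-9, "log"),
        }
        builder = AnalogFastSubsystem
    return {"base": params, "builder": builder, "bounds": bounds,
            "budget": budget,
            "q_probe": [k * 2e-10 for k in range(11)]}
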