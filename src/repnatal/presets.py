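"""Shipped simulator presets for the four sorted pro B cell subsets.

The presets encode the qualitative contrasts the analyses are built to
expose: fetal-liver (FL) subsets run Tdt-off (no N-addition), bone-marrow
(BM) subsets Tdt-on; the FCRL6+ subsets carry heavier junctional trimming
(hence lower productivity and shorter CDR-H3s), stronger distal/domain-4 V
usage, more D-less joins, and a lower Y101 target than their FCRL6-
counterparts. Quantities are study conditions, not fitted values.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .simulate import SimulatorConfig

__all__ = ["PRESET_NAMES", "list_presets", "load_preset"]

PRESET_NAMES = ("FL_FCRL6pos", "FL_FCRL6neg", "BM_FCRL6pos", "BM_FCRL6neg")


def list_presets() -> list[str]:
    return list(PRESET_NAMES)


def load_preset(name: str) -> SimulatorConfig:
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    text = resources.files("repnatal").joinpath(f"presets/{name}.yaml").read_text()
    return SimulatorConfig(**yaml.safe_load(text))
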