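"""Access to the packaged default constants (``data/defaults.yaml``)."""

from __future__ import annotations

import functools
from importlib import resources

import yaml

__all__ = ["defaults", "bilinear_defaults"]


@functools.lru_cache(maxsize=1)
def defaults() -> dict:
    """The parsed default-constants file (cached; treat as read-only)."""
    text = resources.files("apatitemap.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def bilinear_defaults() -> tuple[float, float, float]:
    """(mu_water_511, breakpoint_hu, bone_slope) of the default HU->mu model."""
    phys = defaults()["physics"]
    return (
        float(phys["mu_water_511_cm"]),
        float(phys["hu_breakpoint"]),
        float(phys["hu_bone_slope"]),
    )
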