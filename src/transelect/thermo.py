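"""Enantiomeric excess <-> activation free-energy difference.

At fixed temperature the enantiomer ratio produced under kinetic control is
set by the difference in activation free energy between the two diastereomeric
transition states:

    DDG = R T ln((1 + x) / (1 - x)),   x = ee / 100

The transform spreads the heavily top-skewed ee distribution (most measured
values >= 95%) onto a scale better suited to linear regression, and is
strictly monotone, so rank-ordering enzymes by predicted DDG is equivalent to
rank-ordering by predicted ee.

Convention: DDG is an unsigned magnitude (>= 0); the direction (which
enantiomer is favoured) is carried by the enzyme's S/R selectivity class.
ee = 100% is clipped (default 99.9%) to keep the transform finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import R_KCAL

DEFAULT_TEMPERATURE = 308.15  # K; reactions run at 35 C
DEFAULT_EE_CLIP = 99.9        # percent


@dataclass(frozen=True)
class DDGValue:
    """Activation free-energy difference, kcal/mol, magnitude convention."""

    value: float
    temperature: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(f"DDG must be finite and >= 0, got {self.value!r}")


def ee_to_ddg(
    ee: float,
    temperature: float = DEFAULT_TEMPERATURE,
    clip: float = DEFAULT_EE_CLIP,
) -> DDGValue:
    """Convert percent ee to DDG (kcal/mol).

    Monotone increasing; 0 at ee = 0; ee above `clip` percent is clipped so
    ee = 100 maps to a finite value.
    """
    if not 0.0 <= ee <= 100.0:
        raise ValueError(f"ee must be in [0, 100], got {ee!r}")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    x = min(ee, clip) / 100.0
    value = R_KCAL * temperature * math.log((1.0 + x) / (1.0 - x))
    return DDGValue(value=value, temperature=temperature)


def ddg_to_ee(ddg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert DDG (kcal/mol, >= 0) back to percent ee.

    Inverse of :func:`ee_to_ddg` below the clip; approaches 100% as DDG grows.
    """
    if ddg < 0:
        raise ValueError(f"DDG must be >= 0, got {ddg!r}")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    # 100 * (e^(g/RT) - 1) / (e^(g/RT) + 1) = 100 * tanh(g / (2 R T))
    return 100.0 * math.tanh(ddg / (2.0 * R_KCAL * temperature))
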