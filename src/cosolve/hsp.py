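"""Hansen solubility parameters: totals and binary-mixture values.

The total Hansen parameter is the Euclidean norm of the dispersion,
polar and hydrogen-bonding components, delta^2 = dd^2 + dp^2 + dh^2
(all in MPa^(1/2)).  For a binary solvent blend the mixture parameter
is the linear combination delta_mix = f*delta_1 + (1-f)*delta_2.

The mixing rule is classically written with volume fractions; for the
bundled DMSO + water reference system the published mixture values are
reproduced exactly by using the mass fraction as the blending fraction,
so either entry mode can be used — the caller chooses what ``fraction``
means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import InvalidInputError


@dataclass(frozen=True)
class HSPComponents:
    """Dispersion / polar / hydrogen-bonding partial parameters, MPa^(1/2)."""

    delta_d: float
    delta_p: float
    delta_h: float

    def __post_init__(self) -> None:
        if min(self.delta_d, self.delta_p, self.delta_h) < 0:
            raise InvalidInputError("HSP components must be non-negative")


@dataclass(frozen=True)
class MixtureHSP:
    """Mixture Hansen parameter at one blending fraction."""

    fraction_cosolvent: float
    delta_mix: float
    delta_1: float
    delta_2: float


def total_hsp(c: HSPComponents) -> float:
    """Total Hansen parameter sqrt(dd^2 + dp^2 + dh^2), MPa^(1/2)."""
    return math.sqrt(c.delta_d**2 + c.delta_p**2 + c.delta_h**2)


def mix_hsp(fraction: float, delta_1: float, delta_2: float) -> float:
    """Linear blend fraction*delta_1 + (1-fraction)*delta_2.

    ``delta_1`` is the co-solvent's and ``delta_2`` the anti-solvent's
    total Hansen parameter; ``fraction`` is the co-solvent's blending
    fraction (mass or volume, per the caller's convention).
    """
    if not 0.0 <= fraction <= 1.0:
        raise InvalidInputError(f"fraction must be in [0, 1], got {fraction}")
    if delta_1 < 0 or delta_2 < 0:
        raise InvalidInputError("solubility parameters must be non-negative")
    return fraction * delta_1 + (1.0 - fraction) * delta_2


def mixture_table(
    fractions: Iterable[float] | Sequence[float],
    delta_1: float,
    delta_2: float,
) -> pd.DataFrame:
    """Mixture parameters over a composition sweep, as a tidy frame."""
    fr = list(fractions)
    return pd.DataFrame(
        {
            "fraction_cosolvent": fr,
            "delta_mix": [mix_hsp(f, delta_1, delta_2) for f in fr],
        }
    )
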