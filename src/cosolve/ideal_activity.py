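"""Ideal solubility from fusion properties, and activity coefficients.

The ideal mole-fraction solubility of a crystalline solute below its
melting point follows from its fusion thermodynamics alone:

    ln x_idl = -dH_fus (T_fus - T) / (R T_fus T)
               + (dCp / R) [ (T_fus - T)/T + ln(T / T_fus) ]

The activity coefficient is the ratio of ideal to experimental
solubility, gamma = x_idl / x_e: values above 1 indicate weaker, below 1
stronger, solute-solvent interaction than the ideal solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset_io import SolubilityGrid
from .exceptions import InvalidInputError, OutOfDomainError

#: Universal gas constant, J/mol/K.
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class FusionProperties:
    """Fusion (melting) constants of the solute.

    Attributes
    ----------
    t_fus : float
        Fusion temperature, K.
    dh_fus : float
        Fusion enthalpy, J/mol.
    dcp : float
        Difference between liquid- and solid-state molar heat
        capacities of the solute, J/mol/K.
    """

    t_fus: float
    dh_fus: float
    dcp: float = 0.0

    def __post_init__(self) -> None:
        if not self.t_fus > 0:
            raise InvalidInputError(f"t_fus must be > 0 K, got {self.t_fus}")
        if not self.dh_fus > 0:
            raise InvalidInputError(
                f"dh_fus must be > 0 J/mol, got {self.dh_fus}")
        if self.dcp < 0:
            raise InvalidInputError(f"dcp must be >= 0, got {self.dcp}")


def ideal_solubility(fp: FusionProperties, temperature) -> float | np.ndarray:
    """Ideal mole-fraction solubility at ``temperature`` (K).

    Accepts a scalar or array temperature in (0, t_fus]; at the fusion
    temperature both terms vanish and the result is exactly 1.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise InvalidInputError("temperature must be positive")
    if np.any(t > fp.t_fus):
        raise OutOfDomainError(
            f"temperature above fusion temperature {fp.t_fus} K"
        )
    ln_x = (
        -fp.dh_fus * (fp.t_fus - t) / (GAS_CONSTANT * fp.t_fus * t)
        + (fp.dcp / GAS_CONSTANT)
        * ((fp.t_fus - t) / t + np.log(t / fp.t_fus))
    )
    out = np.exp(ln_x)
    return float(out) if np.isscalar(temperature) else out


def activity_coefficient(x_ideal: float, x_exp: float) -> float:
    """gamma = x_idl / x_e for one (ideal, experimental) solubility pair."""
    if not 0 < x_ideal <= 1:
        raise InvalidInputError(f"x_ideal must be in (0, 1], got {x_ideal}")
    if not 0 < x_exp <= 1:
        raise InvalidInputError(f"x_exp must be in (0, 1], got {x_exp}")
    return x_ideal / x_exp


def activity_table(grid: SolubilityGrid, fp: FusionProperties) -> pd.DataFrame:
    """Activity coefficients for every sample of a grid.

    Returns a tidy frame with one row per sample and columns
    ``mass_fraction_cosolvent, temperature_K, x_exp, x_ideal, gamma``.
    """
    rows = []
    for s in grid.samples:
        x_idl = ideal_solubility(fp, s.temperature)
        rows.append(
            {
                "mass_fraction_cosolvent": s.mass_fraction_cosolvent,
                "temperature_K": s.temperature,
                "x_exp": s.x_exp,
                "x_ideal": x_idl,
                "gamma": activity_coefficient(x_idl, s.x_exp),
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["mass_fraction_cosolvent", "temperature_K"], ignore_index=True
    )
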