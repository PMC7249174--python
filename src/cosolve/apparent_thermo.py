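"""Apparent dissolution thermodynamics and enthalpy-entropy compensation.

For each solvent composition, the temperature dependence of the
saturation mole fraction is analysed with the van't Hoff equation
centred at the harmonic-mean temperature T_hm = n / sum(1/T_i):

    ln x_e = intercept + slope * (1/T - 1/T_hm)

    dH = -R * slope            (apparent standard dissolution enthalpy)
    dG = -R * T_hm * intercept (apparent standard dissolution Gibbs energy)
    dS = (dH - dG) / T_hm      (apparent standard dissolution entropy)

Centring at T_hm decorrelates the slope and intercept estimates, so dG
is read directly off the intercept.  The analysis assumes solution
ideality over the temperature window, hence "apparent".

Enthalpy-entropy compensation regresses dH on dG across compositions;
a slope above ~0.5-1 is conventionally read as enthalpy-driven solvation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import SolubilityGrid
from .exceptions import (
    DegenerateRegressionError,
    InsufficientDataError,
    InvalidInputError,
)
from .ideal_activity import GAS_CONSTANT


@dataclass(frozen=True)
class ThermoResult:
    """Apparent dissolution thermodynamics for one solvent composition.

    Energies are in J/mol (dH, dG) and J/mol/K (dS); the identity
    dS * t_hm == dH - dG holds by construction.
    """

    mass_fraction_cosolvent: float
    dH: float
    dG: float
    dS: float
    r_squared: float
    t_hm: float
    n_points: int


@dataclass(frozen=True)
class CompensationResult:
    """OLS of dH on dG across compositions: slope, intercept (J/mol), R^2."""

    slope: float
    intercept: float
    r_squared: float


def harmonic_mean_temperature(temps: Iterable[float]) -> float:
    """Harmonic mean n / sum(1/T_i) of a collection of temperatures (K)."""
    t = np.asarray(list(temps), dtype=float)
    if t.size == 0:
        raise InvalidInputError("temperature collection is empty")
    if np.any(t <= 0):
        raise InvalidInputError("temperatures must be positive")
    return float(t.size / np.sum(1.0 / t))


def fit_thermo(
    temperatures: Sequence[float],
    x_exp: Sequence[float],
    t_hm: float | None = None,
    mass_fraction_cosolvent: float = float("nan"),
) -> ThermoResult:
    """Van't Hoff analysis of one composition series.

    Ordinary least squares of ln x_e on (1/T - 1/T_hm).  If ``t_hm`` is
    not given it is the harmonic mean of the series' own temperatures.
    """
    t = np.asarray(temperatures, dtype=float)
    x = np.asarray(x_exp, dtype=float)
    if t.shape != x.shape:
        raise InvalidInputError("temperatures and x_exp differ in length")
    if np.unique(t).size < 2:
        raise InsufficientDataError(
            "need >= 2 distinct temperatures for a van't Hoff fit"
        )
    if np.any((x <= 0) | (x >= 1)):
        raise InvalidInputError("x_exp values must lie in (0, 1)")
    if t_hm is None:
        t_hm = harmonic_mean_temperature(t)

    reg = stats.linregress(1.0 / t - 1.0 / t_hm, np.log(x))
    dH = -GAS_CONSTANT * reg.slope
    dG = -GAS_CONSTANT * t_hm * reg.intercept
    dS = (dH - dG) / t_hm
    return ThermoResult(
        mass_fraction_cosolvent=mass_fraction_cosolvent,
        dH=dH,
        dG=dG,
        dS=dS,
        r_squared=reg.rvalue**2,
        t_hm=t_hm,
        n_points=int(t.size),
    )


def thermo_table(
    grid: SolubilityGrid, t_hm: float | None = None
) -> list[ThermoResult]:
    """Per-composition van't Hoff analysis of a whole grid.

    A single T_hm (by default the harmonic mean of the grid's distinct
    temperatures) is shared by every composition so that the resulting
    dG values are comparable across the mixture series.
    """
    if t_hm is None:
        t_hm = harmonic_mean_temperature(grid.temperatures())
    return [
        fit_thermo(*grid.series(m), t_hm=t_hm, mass_fraction_cosolvent=m)
        for m in grid.compositions()
    ]


def thermo_frame(results: Sequence[ThermoResult]) -> pd.DataFrame:
    """Report frame in the conventional units: kJ/mol, kJ/mol, J/mol/K."""
    return pd.DataFrame(
        {
            "mass_fraction_cosolvent": [
                r.mass_fraction_cosolvent for r in results],
            "dH_kJ_mol": [r.dH / 1000.0 for r in results],
            "dG_kJ_mol": [r.dG / 1000.0 for r in results],
            "dS_J_mol_K": [r.dS for r in results],
            "R2": [r.r_squared for r in results],
        }
    )


def compensation_analysis(
    dG: Sequence[float] | Sequence[ThermoResult],
    dH: Sequence[float] | None = None,
) -> CompensationResult:
    """OLS of dissolution enthalpy on Gibbs energy across compositions.

    Accepts either a collection of :class:`ThermoResult` or two
    parallel sequences of dG and dH (any consistent energy unit; the
    slope is dimensionless, the intercept carries the input unit).
    """
    if dH is None:
        results = list(dG)  # type: ignore[arg-type]
        g = np.array([r.dG for r in results], dtype=float)
        h = np.array([r.dH for r in results], dtype=float)
    else:
        g = np.asarray(dG, dtype=float)
        h = np.asarray(dH, dtype=float)
    if g.shape != h.shape:
        raise InvalidInputError("dG and dH differ in length")
    if np.unique(g).size < 2:
        raise DegenerateRegressionError(
            "compensation regression needs >= 2 distinct dG values"
        )
    reg = stats.linregress(g, h)
    return CompensationResult(
        slope=reg.slope, intercept=reg.intercept, r_squared=reg.rvalue**2
    )
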