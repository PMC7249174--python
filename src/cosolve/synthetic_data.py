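"""Synthetic solubility surfaces for parameter-recovery testing.

The generative model is the combined Jouyban-Acree-van't Hoff surface:

    ln x(m, T) = m (A1 + B1/T) + (1-m) (A2 + B2/T)
                 + (m (1-m) / T) sum_i J_i (2m - 1)^i

with multiplicative lognormal measurement noise on x.  The noise is
mean-zero on the ln scale (sigma^2 = ln(1 + cv^2)), which matches the
log-space least-squares assumption of every correlation model in this
package and makes coefficient recovery unbiased in expectation.

Defaults mimic the bundled DMSO + water reference system: the endpoint
van't Hoff coefficients are that system's fitted pure-solvent lines,
the grid is 11 compositions x 5 temperatures, and the noise coefficient
of variation is 0.012, the reference study's mean relative uncertainty
in the measured mole fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import SolubilityGrid, SolubilitySample
from .exceptions import InvalidInputError
from . import reference


@dataclass(frozen=True)
class SurfaceSpec:
    """Parameters of a synthetic ln-solubility surface.

    A1, B1 are the van't Hoff coefficients (dimensionless, K) of the
    pure co-solvent series, A2, B2 of the pure anti-solvent series;
    j_coeffs are up to three interaction coefficients (K); noise_cv is
    the coefficient of variation of the multiplicative lognormal noise.
    """

    A1: float = 18.21
    B1: float = -6445.3
    A2: float = 15.53
    B2: float = -7808.8
    j_coeffs: tuple[float, ...] = (600.0, 200.0, 100.0)
    compositions: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))
    temperatures: tuple[float, ...] = reference.TEMPERATURES_K
    noise_cv: float = 0.012
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise InvalidInputError("noise_cv must be >= 0")
        if len(self.j_coeffs) > 3:
            raise InvalidInputError("at most 3 interaction coefficients")
        if any(not 0 <= m <= 1 for m in self.compositions):
            raise InvalidInputError("compositions must lie in [0, 1]")
        if any(t <= 0 for t in self.temperatures):
            raise InvalidInputError("temperatures must be positive")


def true_surface(spec: SurfaceSpec, m: float, temperature: float) -> float:
    """Noise-free mole-fraction solubility of the surface at (m, T).

    At m = 1 this is exactly exp(A1 + B1/T) and at m = 0 exactly
    exp(A2 + B2/T), independent of the interaction coefficients.
    """
    if not 0 <= m <= 1:
        raise InvalidInputError(f"m must be in [0, 1], got {m}")
    if temperature <= 0:
        raise InvalidInputError("temperature must be positive")
    m2 = 1.0 - m
    ln_x = m * (spec.A1 + spec.B1 / temperature) + m2 * (
        spec.A2 + spec.B2 / temperature
    )
    ln_x += (m * m2 / temperature) * sum(
        j * (m - m2) ** i for i, j in enumerate(spec.j_coeffs)
    )
    x = float(np.exp(ln_x))
    if x >= 1.0:
        raise InvalidInputError(
            f"spec implies non-physical solubility x={x:.3g} >= 1 at "
            f"(m={m}, T={temperature})"
        )
    return x


def generate_grid(spec: SurfaceSpec) -> SolubilityGrid:
    """Sample a noisy solubility grid from the surface.

    Each cell is true_surface(m, T) times a lognormal factor whose ln
    is N(0, ln(1 + cv^2)); with noise_cv = 0 the grid equals the exact
    surface.  The generator and seed are recorded in the grid's
    provenance notes, so identical specs yield identical grids.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
    samples = []
    for m in spec.compositions:
        for t in spec.temperatures:
            x = true_surface(spec, m, t)
            if sigma > 0:
                x *= float(np.exp(rng.normal(0.0, sigma)))
            if not x < 1.0:
                raise InvalidInputError(
                    f"noise pushed x to {x:.3g} >= 1 at (m={m}, T={t})"
                )
            samples.append(SolubilitySample(m, t, x))
    return SolubilityGrid(
        samples=tuple(samples),
        solute_name="synthetic",
        cosolvent_name="synthetic-cosolvent",
        antisolvent_name="synthetic-antisolvent",
        pressure_mpa=0.1,
        provenance_notes=[
            "synthetic surface: combined Jouyban-Acree-van't Hoff form, "
            f"A1={spec.A1}, B1={spec.B1}, A2={spec.A2}, B2={spec.B2}, "
            f"J={list(spec.j_coeffs)}, lognormal noise cv={spec.noise_cv}, "
            f"numpy PCG64 seed={spec.seed}",
        ],
    )
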