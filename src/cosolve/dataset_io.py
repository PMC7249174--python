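"""Solubility-grid data model, CSV I/O, and mole-fraction arithmetic.

The central container is :class:`SolubilityGrid`: a collection of
(co-solvent mass fraction, temperature, mole-fraction solubility)
samples over a binary solvent mixture.  Grids are read and written as
plain long-format CSV with ``#``-prefixed metadata header lines.

Units are fixed throughout the package: temperatures in kelvin, masses
in grams, compositions as solute-free mass fractions of the co-solvent,
solubilities as mole fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateKeyError,
    InvalidInputError,
    RangeError,
    SchemaError,
)
from . import reference

CSV_COLUMNS = ["mass_fraction_cosolvent", "temperature_K", "x_exp", "sd"]


@dataclass(frozen=True)
class SolubilitySample:
    """One saturation measurement: composition, temperature, solubility.

    Parameters
    ----------
    mass_fraction_cosolvent
        Solute-free mass fraction of the co-solvent in the mixed
        solvent, in [0, 1] (0 = pure anti-solvent, 1 = pure co-solvent).
    temperature
        Absolute temperature, K.
    x_exp
        Experimental mole-fraction solubility, in the open interval (0, 1).
    sd
        Optional standard deviation of ``x_exp`` (mole fraction).
    """

    mass_fraction_cosolvent: float
    temperature: float
    x_exp: float
    sd: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mass_fraction_cosolvent <= 1.0:
            raise InvalidInputError(
                f"mass_fraction_cosolvent must be in [0, 1], "
                f"got {self.mass_fraction_cosolvent}"
            )
        if not self.temperature > 0:
            raise InvalidInputError(
                f"temperature must be positive, got {self.temperature}"
            )
        if not 0.0 < self.x_exp < 1.0:
            raise RangeError(
                f"x_exp must lie in (0, 1), got {self.x_exp} at "
                f"(m={self.mass_fraction_cosolvent}, T={self.temperature})"
            )
        if self.sd is not None and (not math.isfinite(self.sd) or self.sd < 0):
            raise InvalidInputError(f"sd must be >= 0, got {self.sd}")


@dataclass
class SolubilityGrid:
    """A (composition x temperature) mole-fraction solubility surface."""

    samples: tuple[SolubilitySample, ...]
    solute_name: str = ""
    cosolvent_name: str = ""
    antisolvent_name: str = ""
    pressure_mpa: float = 0.1
    provenance_notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        keys = [(s.mass_fraction_cosolvent, s.temperature) for s in self.samples]
        if len(set(keys)) != len(keys):
            seen: set[tuple[float, float]] = set()
            for k in keys:
                if k in seen:
                    raise DuplicateKeyError(
                        f"duplicate (m, T) pair {k} in grid"
                    )
                seen.add(k)

    def __len__(self) -> int:
        return len(self.samples)

    def compositions(self) -> list[float]:
        """Distinct co-solvent mass fractions, ascending."""
        return sorted({s.mass_fraction_cosolvent for s in self.samples})

    def temperatures(self) -> list[float]:
        """Distinct temperatures, ascending, K."""
        return sorted({s.temperature for s in self.samples})

    def series(self, mass_fraction: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (temperatures, x_exp) for one composition, sorted by T."""
        rows = sorted(
            (s for s in self.samples
             if s.mass_fraction_cosolvent == mass_fraction),
            key=lambda s: s.temperature,
        )
        if not rows:
            raise InvalidInputError(
                f"no samples at mass fraction {mass_fraction}"
            )
        return (np.array([s.temperature for s in rows]),
                np.array([s.x_exp for s in rows]))

    def get(self, mass_fraction: float, temperature: float) -> SolubilitySample:
        for s in self.samples:
            if (s.mass_fraction_cosolvent == mass_fraction
                    and s.temperature == temperature):
                return s
        raise InvalidInputError(
            f"no sample at (m={mass_fraction}, T={temperature})"
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mass_fraction_cosolvent": [
                    s.mass_fraction_cosolvent for s in self.samples],
                "temperature_K": [s.temperature for s in self.samples],
                "x_exp": [s.x_exp for s in self.samples],
                "sd": [s.sd for s in self.samples],
            }
        )


@dataclass(frozen=True)
class SoluteConstants:
    """Molar masses of solute, co-solvent and anti-solvent, g/mol."""

    molar_mass_solute: float = reference.MOLAR_MASS_SOLUTE
    molar_mass_cosolvent: float = reference.MOLAR_MASS_COSOLVENT
    molar_mass_antisolvent: float = reference.MOLAR_MASS_ANTISOLVENT

    def __post_init__(self) -> None:
        for name in ("molar_mass_solute", "molar_mass_cosolvent",
                     "molar_mass_antisolvent"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(
                    f"{name} must be positive, got {getattr(self, name)}"
                )


@dataclass(frozen=True)
class MassComposition:
    """Weighed masses (g) of solute, co-solvent and anti-solvent."""

    mass_solute: float
    mass_cosolvent: float
    mass_antisolvent: float = 0.0

    def __post_init__(self) -> None:
        if min(self.mass_solute, self.mass_cosolvent,
               self.mass_antisolvent) < 0:
            raise InvalidInputError("masses must be non-negative")
        if self.mass_solute + self.mass_cosolvent + self.mass_antisolvent <= 0:
            raise InvalidInputError("total mass must be positive")


def mole_fraction(mc: MassComposition, sc: SoluteConstants) -> float:
    """Mole fraction of the solute from weighed masses.

    Converts each mass to moles, n_i = m_i / M_i, and returns
    n_solute / (n_solute + n_cosolvent + n_antisolvent).  With no
    anti-solvent this reduces to the two-component mole fraction.
    """
    if mc.mass_cosolvent <= 0 and mc.mass_antisolvent <= 0:
        raise InvalidInputError("at least one solvent mass must be positive")
    n1 = mc.mass_solute / sc.molar_mass_solute
    n2 = mc.mass_cosolvent / sc.molar_mass_cosolvent
    n3 = mc.mass_antisolvent / sc.molar_mass_antisolvent
    return n1 / (n1 + n2 + n3)


def write_grid(grid: SolubilityGrid, path: str | Path) -> None:
    """Write a grid to long-format CSV with ``#`` metadata header lines.

    The output round-trips through :func:`read_grid` exactly.
    """
    path = Path(path)
    lines = [
        f"# solute: {grid.solute_name}",
        f"# cosolvent: {grid.cosolvent_name}",
        f"# antisolvent: {grid.antisolvent_name}",
        f"# pressure_MPa: {grid.pressure_mpa!r}",
    ]
    for note in grid.provenance_notes:
        lines.append(f"# note: {note}")
    lines.append(",".join(CSV_COLUMNS))
    for s in grid.samples:
        sd = "" if s.sd is None else repr(s.sd)
        lines.append(
            f"{s.mass_fraction_cosolvent!r},{s.temperature!r},"
            f"{s.x_exp!r},{sd}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_grid(path: str | Path) -> SolubilityGrid:
    """Read a long-format solubility CSV into a validated grid.

    Required columns: ``mass_fraction_cosolvent, temperature_K, x_exp``;
    ``sd`` is optional and may be empty.  Lines starting with ``#`` are
    metadata (``key: value``); recognised keys are solute, cosolvent,
    antisolvent, pressure_MPa and note.  Rows violating the physical
    invariants are rejected with the offending row number in the message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    notes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        raw = fh.readlines()
    body_start = 0
    for i, line in enumerate(raw):
        if line.startswith("#"):
            body_start = i + 1
            text = line.lstrip("#").strip()
            if ":" in text:
                key, _, value = text.partition(":")
                key = key.strip().lower()
                if key == "note":
                    notes.append(value.strip())
                else:
                    meta[key] = value.strip()
        else:
            break
    df = pd.read_csv(path, skiprows=body_start, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if "sd" not in df.columns:
        df["sd"] = np.nan

    samples = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 1  # 1-based data row number
        try:
            sd = None if pd.isna(row["sd"]) else float(row["sd"])
            samples.append(
                SolubilitySample(
                    mass_fraction_cosolvent=float(
                        row["mass_fraction_cosolvent"]),
                    temperature=float(row["temperature_K"]),
                    x_exp=float(row["x_exp"]),
                    sd=sd,
                )
            )
        except RangeError as err:
            raise RangeError(f"row {rowno}: {err}") from err
        except InvalidInputError as err:
            raise InvalidInputError(f"row {rowno}: {err}") from err
        except (TypeError, ValueError) as err:
            raise SchemaError(f"row {rowno}: unparseable value ({err})") from err

    pressure = float(meta.get("pressure_mpa", "0.1") or 0.1)
    return SolubilityGrid(
        samples=tuple(samples),
        solute_name=meta.get("solute", ""),
        cosolvent_name=meta.get("cosolvent", ""),
        antisolvent_name=meta.get("antisolvent", ""),
        pressure_mpa=pressure,
        provenance_notes=notes,
    )


def load_reference_dataset(corrected: bool = True) -> SolubilityGrid:
    """The bundled baricitinib / DMSO / water solubility surface.

    Eleven DMSO mass fractions by five temperatures (55 samples) with
    reported standard deviations.  By default the single cell whose
    published value breaks the monotone temperature trend,
    (m = 0.2, T = 323.2 K), is stored with its power-of-ten correction
    (7.05e-4 instead of the printed 7.05e-5) and a machine-readable
    provenance note; pass ``corrected=False`` for the verbatim table.
    """
    samples = []
    for m, xs in reference.SOLUBILITY_X.items():
        sds = reference.SOLUBILITY_SD[m]
        for t, x, sd in zip(reference.TEMPERATURES_K, xs, sds):
            if not corrected and (m, t) == reference.UNCORRECTED_CELL:
                x = reference.UNCORRECTED_VALUE
            samples.append(SolubilitySample(m, t, x, sd))
    notes = [reference.CORRECTION_NOTE] if corrected else [
        "verbatim published table requested; the (m=0.2, T=323.2 K) cell "
        "retains its non-monotone published value 7.05e-5"
    ]
    return SolubilityGrid(
        samples=tuple(samples),
        solute_name=reference.SOLUTE_NAME,
        cosolvent_name=reference.COSOLVENT_NAME,
        antisolvent_name=reference.ANTISOLVENT_NAME,
        pressure_mpa=reference.PRESSURE_MPA,
        provenance_notes=notes,
    )
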