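"""Per-metabolite physicochemistry.

Each root-exudate metabolite is described by its elemental formula
C_a H_b N_c O_d with net charge z, from which the module derives

* the nominal oxidation state of carbon (NOSC),
* electrons available per C-mol (4 - NOSC),
* an aqueous diffusivity estimate (Wilke-Chang molar-volume correlation),
* the catabolic Gibbs energy of full aerobic oxidation, via an
  energy-per-electron bookkeeping.

These quantities feed the thermodynamic yield and the diffusion-limited
uptake kinetics. The six chemical classes handled are sugars, organic
acids, amino acids, fatty acids, nucleotides (incl. nucleosides) and
auxins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .config import ChemistryConfig

__all__ = [
    "ChemClass",
    "Formula",
    "SubstrateProperties",
    "parse_formula",
    "nosc",
    "diffusivity",
    "catabolic_energy",
    "build_substrate_properties",
    "substrate_table_properties",
]

ATOMIC_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999}


class ChemClass(str, Enum):
    sugar = "sugar"
    organic_acid = "organic_acid"
    amino_acid = "amino_acid"
    fatty_acid = "fatty_acid"
    nucleotide = "nucleotide"
    auxin = "auxin"


class CompositionError(ValueError):
    """Raised when an elemental formula is undefined or out of range."""


@dataclass(frozen=True)
class Formula:
    """Elemental composition C_a H_b N_c O_d with net charge z."""

    a: int  # C
    b: int  # H
    c: int  # N
    d: int  # O
    z: int = 0  # net charge

    @property
    def molar_mass(self) -> float:
        return (
            self.a * ATOMIC_MASS["C"]
            + self.b * ATOMIC_MASS["H"]
            + self.c * ATOMIC_MASS["N"]
            + self.d * ATOMIC_MASS["O"]
        )


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str, charge: int = 0) -> Formula:
    """Parse a Hill-notation formula string such as ``"C6H12O6"``.

    Only C, H, N and O are accepted; anything else is an error because the
    downstream electron bookkeeping covers CHNO compounds only.
    """
    counts = {"C": 0, "H": 0, "N": 0, "O": 0}
    pos = 0
    for m in _FORMULA_RE.finditer(text.strip()):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise CompositionError(f"unparsable formula: {text!r}")
        pos = m.end()
        elem, num = m.group(1), m.group(2)
        if elem not in counts:
            raise CompositionError(f"unsupported element {elem!r} in formula {text!r}")
        counts[elem] += int(num) if num else 1
    if pos != len(text.strip()):
        raise CompositionError(f"unparsable formula: {text!r}")
    return Formula(a=counts["C"], b=counts["H"], c=counts["N"], d=counts["O"], z=int(charge))


def nosc(formula: Formula) -> float:
    """Nominal oxidation state of carbon.

    NOSC = 4 - (4a + b - 3c - 2d - z) / a, the standard charge-corrected
    definition. Values outside [-4, 4] indicate an impossible composition
    and raise.
    """
    if formula.a < 1:
        raise CompositionError("NOSC undefined for a carbon-free composition")
    value = 4.0 - (4 * formula.a + formula.b - 3 * formula.c - 2 * formula.d - formula.z) / formula.a
    if not -4.0 <= value <= 4.0:
        raise CompositionError(
            f"NOSC {value:.3f} outside [-4, 4]; formula {formula} is not a valid organic composition"
        )
    return value


def electrons_per_cmol(formula: Formula) -> float:
    """Electrons transferred per C-mol on full oxidation: 4 - NOSC."""
    return 4.0 - nosc(formula)


def water_viscosity_Pa_s(temperature_K: float) -> float:
    """Dynamic viscosity of water (Vogel-type correlation), Pa s."""
    return 2.414e-5 * 10.0 ** (247.8 / (temperature_K - 140.0))


def diffusivity(
    molar_mass: float,
    temperature_K: float = 298.15,
    config: ChemistryConfig | None = None,
) -> float:
    """Aqueous diffusivity (m^2 s^-1) from the Wilke-Chang correlation.

    The solute molar volume is estimated as molar_mass / solute density;
    the correlation is strictly decreasing in molar mass at fixed
    temperature. Default constants give ~7e-10 m^2/s for a glucose-sized
    molecule, within the range of measured values.
    """
    cfg = config or ChemistryConfig()
    if molar_mass <= 0:
        raise ValueError(f"molar mass must be positive, got {molar_mass}")
    if not 253.0 < temperature_K < 403.0:
        raise ValueError(f"temperature {temperature_K} K outside physiological range")
    v_a = molar_mass / cfg.solute_density_g_cm3  # cm^3 / mol
    mu_cP = water_viscosity_Pa_s(temperature_K) * 1.0e3
    d_cm2_s = (
        7.4e-8
        * np.sqrt(cfg.wilke_chang_phi * cfg.solvent_molar_mass)
        * temperature_K
        / (mu_cP * v_a**0.6)
    )
    return float(d_cm2_s * 1.0e-4)


def catabolic_energy(formula: Formula, config: ChemistryConfig | None = None) -> float:
    """Catabolic Gibbs energy of full aerobic oxidation, kJ per mol substrate.

    Electrons transferred = (4 - NOSC) * a; each electron delivered to O2
    releases ``energy_per_electron_kJ``. Always negative for CHNO
    compounds with NOSC < 4 (every viable electron donor).
    """
    cfg = config or ChemistryConfig()
    electrons = electrons_per_cmol(formula) * formula.a
    return -cfg.energy_per_electron_kJ * electrons


@dataclass(frozen=True)
class SubstrateProperties:
    """Derived physicochemistry of one metabolite."""

    name: str
    chem_class: ChemClass
    formula: Formula
    molar_mass: float
    diffusivity: float  # m^2 s^-1
    nosc: float
    dG_cat: float  # kJ per mol substrate (catabolic, aerobic)
    electrons_per_cmol: float

    def __post_init__(self) -> None:
        if self.formula.a < 1:
            raise CompositionError(f"{self.name}: carbon-free composition")
        if self.molar_mass <= 0 or self.diffusivity <= 0:
            raise CompositionError(f"{self.name}: non-physical molar mass or diffusivity")


def build_substrate_properties(
    name: str,
    chem_class: ChemClass | str,
    formula: Formula | str,
    charge: int = 0,
    molar_mass: float | None = None,
    config: ChemistryConfig | None = None,
    dG_cat_override: float | None = None,
) -> SubstrateProperties:
    """Assemble the full property record for one metabolite."""
    cfg = config or ChemistryConfig()
    if isinstance(formula, str):
        formula = parse_formula(formula, charge)
    chem_class = ChemClass(chem_class)
    mm = float(molar_mass) if molar_mass is not None else formula.molar_mass
    return SubstrateProperties(
        name=name,
        chem_class=chem_class,
        formula=formula,
        molar_mass=mm,
        diffusivity=diffusivity(mm, cfg.temperature_K, cfg),
        nosc=nosc(formula),
        dG_cat=(
            float(dG_cat_override)
            if dG_cat_override is not None
            else catabolic_energy(formula, cfg)
        ),
        electrons_per_cmol=electrons_per_cmol(formula),
    )


def substrate_table_properties(
    table: pd.DataFrame, config: ChemistryConfig | None = None
) -> list[SubstrateProperties]:
    """Build property records for a validated substrate table.

    Expects columns name, class, formula, charge and optionally molar_mass
    and dG_cat (per-substrate thermodynamic override).
    """
    def _opt(row: pd.Series, key: str) -> float | None:
        val = row.get(key)
        return None if val is None or pd.isna(val) else float(val)

    out = []
    for _, row in table.iterrows():
        out.append(
            build_substrate_properties(
                name=row["name"],
                chem_class=row["class"],
                formula=str(row["formula"]),
                charge=int(row.get("charge", 0) or 0),
                molar_mass=_opt(row, "molar_mass"),
                config=config,
                dG_cat_override=_opt(row, "dG_cat"),
            )
        )
    return out
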