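"""Thermodynamic coupling of catabolism and anabolism.

Growth on a single organic substrate that serves as both carbon source
and electron donor is modelled as a catabolic reaction (full aerobic
oxidation, releasing dG_cat) coupled to an anabolic reaction (conversion
of substrate carbon into generalized reserve compounds, costing
dG_an = dG_block + dG_rho_porter, plus dissipation dG_diss = dG_syn/nu).
The coupling number

    lambda = (dG_an + dG_diss) / (-dG_cat)

counts how many times the catabolic reaction must run, per C-mol of
substrate assimilated, to fund one anabolic turn. Working per C-mol of
substrate on both routes (Y_cat = Y_an = 1/a mol substrate per C-mol),
the assimilation yield is

    y_ED = 1 / (Y_cat + lambda * Y_an) = a / (1 + lambda)

C-mol of reserve per mol of substrate, which can never exceed the
substrate's own carbon content a.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ThermoConfig
from .genome import CellGeometry
from .substrates import SubstrateProperties

__all__ = [
    "ThermoCoupling",
    "ThermodynamicInfeasibilityError",
    "coupling_lambda",
    "assimilation_yield",
    "porter_synthesis_cost",
    "thermo_coupling",
]

AVOGADRO = 6.02214076e23


class ThermodynamicInfeasibilityError(ValueError):
    """Raised when a substrate cannot serve as electron donor (dG_cat >= 0)."""


@dataclass(frozen=True)
class ThermoCoupling:
    """Energy and stoichiometry balance for one substrate-consumer pair."""

    Y_cat: float  # mol substrate per C-mol reserve, catabolic route
    Y_an: float  # mol substrate per C-mol reserve, anabolic route
    dG_cat: float  # kJ per C-mol substrate oxidized (< 0)
    dG_an: float  # kJ per C-mol reserve (= dG_block + dG_rho_porter)
    dG_diss: float  # kJ per C-mol reserve (= dG_syn / nu)
    lambda_coupling: float  # dimensionless >= 0
    y_ED: float  # C-mol reserve per mol substrate


def coupling_lambda(dG_an: float, dG_diss: float, dG_cat: float) -> float:
    """Catabolic coupling number lambda = (dG_an + dG_diss)/(-dG_cat).

    ``dG_cat`` must be negative (exergonic catabolism); poorer electron
    donors (dG_cat closer to zero) require more catabolic turns.
    """
    if dG_cat >= 0:
        raise ThermodynamicInfeasibilityError(
            f"catabolic reaction must be exergonic, got dG_cat={dG_cat:.3g} kJ"
        )
    lam = (dG_an + dG_diss) / (-dG_cat)
    return max(lam, 0.0)


def assimilation_yield(Y_cat: float, Y_an: float, lam: float) -> float:
    """Assimilation yield y_ED = 1/(Y_cat + lambda * Y_an), C-mol per mol."""
    if Y_cat <= 0 or Y_an <= 0:
        raise ValueError("stoichiometric coefficients must be positive")
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    return 1.0 / (Y_cat + lam * Y_an)


def porter_synthesis_cost(
    rho_porter: float,
    geometry: CellGeometry,
    porter_radius_m: float,
    config: ThermoConfig | None = None,
) -> float:
    """Synthesis cost of membrane binding-site proteins, kJ per C-mol biomass.

    Linear in the porter area fraction: (porters per cell) x (cells per
    C-mol) x (synthesis energy per mol porter). Zero at rho = 0.
    """
    cfg = config or ThermoConfig()
    if rho_porter < 0:
        raise ValueError(f"porter density must be non-negative, got {rho_porter}")
    porters_per_cell = 4.0 * geometry.r_c**2 * rho_porter / porter_radius_m**2
    mol_porter_per_cmol = porters_per_cell * geometry.lambda_B / AVOGADRO
    energy_per_mol_porter = cfg.porter_aa * cfg.atp_per_aa * cfg.dG_atp_kJ
    return mol_porter_per_cmol * energy_per_mol_porter


def thermo_coupling(
    substrate: SubstrateProperties,
    geometry: CellGeometry,
    rho_porter: float,
    porter_radius_m: float,
    config: ThermoConfig | None = None,
) -> ThermoCoupling:
    """Full thermodynamic closure for one substrate at porter density rho.

    Both catabolic and anabolic routes are booked per C-mol of substrate
    processed (Y_cat = Y_an = 1/a), and lambda uses dG_cat per C-mol.
    """
    cfg = config or ThermoConfig()
    a = substrate.formula.a
    dG_cat_cmol = substrate.dG_cat / a
    dG_diss = cfg.dG_syn_kJ / cfg.nu
    dG_block = cfg.dG_block_by_class.get(substrate.chem_class.value, cfg.dG_block_kJ)
    dG_an = dG_block + porter_synthesis_cost(rho_porter, geometry, porter_radius_m, cfg)
    lam = coupling_lambda(dG_an, dG_diss, dG_cat_cmol)
    y_cat = y_an = 1.0 / a
    y_ed = assimilation_yield(y_cat, y_an, lam)
    assert y_ed <= a + 1e-12
    return ThermoCoupling(
        Y_cat=y_cat,
        Y_an=y_an,
        dG_cat=dG_cat_cmol,
        dG_an=dG_an,
        dG_diss=dG_diss,
        lambda_coupling=lam,
        y_ED=y_ed,
    )
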