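"""Supply-demand closure for the porter area fraction.

The membrane area fraction rho that a consumer must devote to binding
sites for a given substrate is fixed by requiring that, at saturating
substrate and balanced growth, assimilation supports the genome-inferred
maximum specific growth rate. At saturation the ECA factor approaches 1,
so the assimilation rate per C-mol of total biomass is

    p(rho) = y_ED(rho) * k2 * N(rho)          [C-mol reserve / C-mol / h]

Reserve density relaxes to the balanced value m* satisfying
p * (1 + m*) = k_E * m*  (assimilation scales with total biomass E + V,
mobilization with structure), i.e. m* = p / (k_E - p), which is the
steady reserve capacity p_Am / k_E when assimilation is expressed per
structure. The saturated growth rate then follows from the growth
equation

    r_sat = (k_E m* - k_M) / (m* + y_EV (1 + z_X))

and rho* is the root of r_sat(rho) = r_max, found by bracketed
bisection (Brent). The porter synthesis cost feeds back on y_ED and is
evaluated inline, keeping the solve one-dimensional.

Transporter allocation across substrate classes follows the normalized
transporter gene frequencies z_rho: each substrate of a class receives an
equal share of the class allocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .config import RunConfig
from .genome import (
    CellGeometry,
    IsolateTraits,
    cell_geometry_from_genome,
    reserve_turnover_kE,
    translational_yield,
)
from .kinetics import binding_sites_per_molC
from .substrates import SubstrateProperties
from .thermo import thermo_coupling

__all__ = [
    "ConsumerParameters",
    "InfeasiblePhenotypeError",
    "solve_total_porter_density",
    "allocate_porters",
    "maintenance_rate",
    "saturated_growth_rate",
    "parameterize_consumer",
]


class InfeasiblePhenotypeError(ValueError):
    """r_max is unreachable for any feasible membrane allocation."""


@dataclass
class ConsumerParameters:
    """Fully closed DEB parameter set for one isolate."""

    isolate_id: str
    geometry: CellGeometry
    k_E: float  # 1/h
    y_VE: float  # C-mol structure per C-mol reserve
    y_EV: float  # = 1 / y_VE
    k_M: float  # 1/h, maintenance per C-mol structure
    z_X_rate: float  # constitutive enzyme production coefficient
    mu_E: float  # kJ per C-mol
    lambda_B: float  # cells per mol C
    rho_porter: dict[str, float]  # per-substrate porter area fractions
    y_ED: dict[str, float]  # per-substrate assimilation yields (C-mol/mol)
    gamma0: float  # turnover rate at reference density, 1/h
    B_ref: float  # reference density, mol C / L
    gamma_E_multiplier: float = 1.0
    starvation_overhead: float = 1.2
    response_group: str = "undefined"
    extras: dict = field(default_factory=dict)

    @property
    def rho_total(self) -> float:
        return float(sum(self.rho_porter.values()))


def maintenance_rate(geometry: CellGeometry, kappa_M: float = 1.0e-16) -> float:
    """Basal maintenance rate k_M (1/h), proportional to cell volume.

    kappa_M is the volume-specific maintenance demand (mol reserve C per
    um^3 of cell per hour); multiplying by cells per mol C converts to a
    per-C-mol-structure rate.
    """
    if geometry.V_c <= 0:
        raise ValueError("cell volume must be positive")
    return kappa_M * geometry.V_c * geometry.lambda_B


def saturated_growth_rate(
    rho: float,
    substrate: SubstrateProperties,
    geometry: CellGeometry,
    k_E: float,
    y_EV: float,
    k_M: float,
    z_X_rate: float,
    config: RunConfig,
) -> float:
    """Steady specific growth rate at saturating substrate for porter density rho.

    Returns the k_E asymptote when assimilation catches up with reserve
    turnover (reserve density diverges).
    """
    kin = config.kinetics
    coup = thermo_coupling(substrate, geometry, rho, kin.porter_radius_m, config.thermo)
    N = binding_sites_per_molC(
        rho, geometry.r_c, geometry.M_dry, kin.porter_radius_m,
        config.allometry.carbon_fraction,
    )
    # assimilated C per C-mol total biomass per hour
    p = coup.y_ED * kin.k2_per_s * 3600.0 * N
    if p >= k_E:
        return k_E
    m_star = p / (k_E - p)
    return (k_E * m_star - k_M) / (m_star + y_EV * (1.0 + z_X_rate))


def solve_total_porter_density(
    traits: IsolateTraits,
    substrate: SubstrateProperties,
    config: RunConfig | None = None,
    geometry: CellGeometry | None = None,
    kappa_M: float = 1.0e-16,
) -> float:
    """Porter area fraction rho* at which saturated growth equals r_max.

    The root is bracketed on (0, rho_max); absence of a sign change means
    the requested r_max is unreachable for any membrane allocation and
    raises :class:`InfeasiblePhenotypeError` with diagnostics.
    """
    cfg = config or RunConfig()
    geom = geometry or cell_geometry_from_genome(traits, cfg.allometry, cfg.ribosome)
    k_E = reserve_turnover_kE(traits, geom)
    y_VE = translational_yield(traits.rrn_copies, cfg.translation)
    y_EV = 1.0 / y_VE
    k_M = maintenance_rate(geom, kappa_M)
    z_X_rate = cfg.turnover.z_X_slope * traits.z_X

    def g(rho: float) -> float:
        return (
            saturated_growth_rate(
                rho, substrate, geom, k_E, y_EV, k_M, z_X_rate, cfg
            )
            - traits.r_max
        )

    lo, hi = 1.0e-12, cfg.kinetics.rho_max * (1.0 - 1.0e-9)
    g_lo, g_hi = g(lo), g(hi)
    if g_lo > 0:
        # even a vanishing porter allocation overshoots r_max; the root
        # is effectively zero membrane investment
        return lo
    if g_hi < 0:
        raise InfeasiblePhenotypeError(
            f"{traits.isolate_id}: r_max={traits.r_max:.3g}/h unreachable on "
            f"{substrate.name} (saturated growth at packing limit "
            f"{cfg.kinetics.rho_max}: {g_hi + traits.r_max:.3g}/h, k_E={k_E:.3g}/h)"
        )
    return float(brentq(g, lo, hi, rtol=1.0e-10, xtol=1.0e-16))


def allocate_porters(
    rho_total: float,
    z_rho: dict[str, float],
    substrates: list[SubstrateProperties],
) -> dict[str, float]:
    """Distribute a total porter budget across substrates via z_rho.

    Each substrate of class c receives rho_total * z_rho[c] / n_c where
    n_c is the number of substrates of that class in the table. Classes
    absent from z_rho receive zero. The allocation conserves rho_total up
    to the mass in absent classes.
    """
    class_counts: dict[str, int] = {}
    for s in substrates:
        class_counts[s.chem_class.value] = class_counts.get(s.chem_class.value, 0) + 1
    out: dict[str, float] = {}
    for s in substrates:
        cls = s.chem_class.value
        weight = z_rho.get(cls, 0.0)
        out[s.name] = rho_total * weight / class_counts[cls] if weight > 0 else 0.0
    return out


def parameterize_consumer(
    traits: IsolateTraits,
    substrates: list[SubstrateProperties],
    config: RunConfig | None = None,
    kappa_M: float = 1.0e-16,
    mode: str = "per_substrate",
) -> ConsumerParameters:
    """Close the DEB parameter set of one isolate over a substrate panel.

    ``mode='per_substrate'`` solves rho* independently for every substrate
    (each batch culture then carries the allocation sized for its own
    substrate). ``mode='z_rho'`` additionally redistributes the cumulative
    budget sum(rho*) across substrates by transporter gene frequencies,
    which is the allocation used in mixed-medium competition.
    """
    cfg = config or RunConfig()
    geom = cell_geometry_from_genome(traits, cfg.allometry, cfg.ribosome)
    k_E = reserve_turnover_kE(traits, geom)
    y_VE = translational_yield(traits.rrn_copies, cfg.translation)
    k_M = maintenance_rate(geom, kappa_M)
    z_X_rate = cfg.turnover.z_X_slope * traits.z_X

    rho_solved = {
        s.name: solve_total_porter_density(traits, s, cfg, geometry=geom, kappa_M=kappa_M)
        for s in substrates
    }
    if mode == "z_rho":
        rho_map = allocate_porters(sum(rho_solved.values()), traits.z_rho, substrates)
    elif mode == "per_substrate":
        rho_map = rho_solved
    else:
        raise ValueError(f"unknown allocation mode {mode!r}")

    rho_cap = cfg.kinetics.rho_max
    total = sum(rho_map.values())
    if total >= 1.0:
        raise InfeasiblePhenotypeError(
            f"{traits.isolate_id}: cumulative porter allocation {total:.3f} exceeds "
            "the whole membrane"
        )

    y_ED = {
        s.name: thermo_coupling(
            s, geom, min(rho_map[s.name], rho_cap), cfg.kinetics.porter_radius_m, cfg.thermo
        ).y_ED
        for s in substrates
    }
    return ConsumerParameters(
        isolate_id=traits.isolate_id,
        geometry=geom,
        k_E=k_E,
        y_VE=y_VE,
        y_EV=1.0 / y_VE,
        k_M=k_M,
        z_X_rate=z_X_rate,
        mu_E=geom.mu_E,
        lambda_B=geom.lambda_B,
        rho_porter=rho_map,
        y_ED=y_ED,
        gamma0=cfg.turnover.gamma0_per_h,
        B_ref=cfg.turnover.B_ref_molC_L,
        gamma_E_multiplier=cfg.turnover.reserve_multiplier,
        starvation_overhead=cfg.turnover.starvation_overhead,
        response_group=traits.response_group.value,
        extras={"rho_solved": rho_solved, "r_max": traits.r_max},
    )
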