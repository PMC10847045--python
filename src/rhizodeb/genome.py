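"""Genome-derived traits and the allometric cell model.

Raw genome quantities (genome size, rRNA operon copy number, inferred
maximum specific growth rate, transporter and glycoside-hydrolase gene
frequencies) are mapped onto a physical cell: volume, dry mass, protein
and ribosome inventories, elemental composition, and the derived DEB
quantities

* ``k_E``   reserve turnover rate, r_max * V_P / V_R, the asymptotic
            ceiling of the specific growth rate;
* ``y_VE``  translational yield (C-mol structure per C-mol reserve),
            predicted from rrn copy number;
* ``lambda_B`` cells per mol of biomass carbon (47% of dry mass is C).

The ribosome economy places a lower bound on the ribosomal volume needed
to sustain a growth rate r: every ribosome must replicate all proteins
and all ribosomes once per division cycle while also replacing degraded
copies. Balancing base-pair throughput gives the minimum ribosome count

    N_R = l_P * N_P * (phi/r + 1) / (r_R/r - l_R * (eta/r + 1))

and V_R = v_R * N_R. The bound diverges as r approaches the hard limit
r_R / l_R at which ribosomes can no longer replicate themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .config import AllometryConfig, RibosomeConfig, TranslationConfig
from .substrates import ATOMIC_MASS

__all__ = [
    "ResponseGroup",
    "IsolateTraits",
    "CellGeometry",
    "InfeasibleGrowthRateError",
    "cell_geometry_from_genome",
    "min_ribosome_volume",
    "reserve_turnover_kE",
    "translational_yield",
]

M_C = ATOMIC_MASS["C"]


class ResponseGroup(str, Enum):
    positive = "positive"
    negative = "negative"
    undefined = "undefined"


class InfeasibleGrowthRateError(ValueError):
    """The ribosome economy cannot support the requested growth rate."""


@dataclass(frozen=True)
class IsolateTraits:
    """Raw genome-derived quantities for one organism."""

    isolate_id: str
    genome_size_bp: float
    rrn_copies: int
    r_max: float  # 1/h, = ln 2 / minimum generation time
    z_rho: dict[str, float]  # per-substrate-class transporter gene frequencies
    z_X: float  # genome-size-normalized glycoside hydrolase gene frequency
    response_group: ResponseGroup = ResponseGroup.undefined

    def __post_init__(self) -> None:
        if self.genome_size_bp <= 0:
            raise ValueError(f"{self.isolate_id}: genome size must be positive")
        if self.rrn_copies < 1:
            raise ValueError(f"{self.isolate_id}: rrn copy number must be >= 1")
        if self.r_max <= 0:
            raise ValueError(f"{self.isolate_id}: r_max must be positive")
        if self.z_X < 0:
            raise ValueError(f"{self.isolate_id}: z_X must be non-negative")
        total = sum(self.z_rho.values())
        if self.z_rho and total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.isolate_id}: z_rho frequencies must sum to 1, got {total:.12f}"
            )
        if any(v < 0 for v in self.z_rho.values()):
            raise ValueError(f"{self.isolate_id}: z_rho entries must be non-negative")


@dataclass(frozen=True)
class CellGeometry:
    """Physical cell model derived from genome size."""

    V_c: float  # cell volume, um^3
    L_c: float  # volumetric length V_c^(1/3), um
    r_c: float  # spherical radius, m
    M_dry: float  # dry mass, g
    V_P: float  # total protein volume, um^3
    V_R: float  # ribosomal volume at r = r_max, um^3
    N_P: float  # total protein count
    composition: tuple[float, float, float, float]  # C,H,O,N per C-mol
    mu_E: float  # chemical potential of reserve, kJ per C-mol
    lambda_B: float  # cells per mol biomass C

    def __post_init__(self) -> None:
        if not (0.0 < self.V_R <= self.V_P < self.V_c):
            raise ValueError(
                f"geometry inconsistent: require 0 < V_R <= V_P < V_c, "
                f"got V_R={self.V_R:.3g}, V_P={self.V_P:.3g}, V_c={self.V_c:.3g}"
            )


def cell_mass_per_cmol(config: AllometryConfig) -> float:
    """Molar mass of generalized biomass, g per C-mol."""
    return (
        M_C
        + config.biomass_h * ATOMIC_MASS["H"]
        + config.biomass_o * ATOMIC_MASS["O"]
        + config.biomass_n * ATOMIC_MASS["N"]
    )


def min_ribosome_volume(
    r: float, n_proteins: float, config: RibosomeConfig | None = None
) -> float:
    """Minimum ribosomal volume (um^3) able to sustain growth rate r (1/h).

    Applies the ribosome self-replication bound at equality. Raises
    :class:`InfeasibleGrowthRateError` when the denominator is
    non-positive, i.e. when r exceeds the ribosome self-replication limit.
    """
    cfg = config or RibosomeConfig()
    if r <= 0:
        raise ValueError(f"growth rate must be positive, got {r}")
    denom = cfg.r_R_bp_per_h / r - cfg.l_R_bp * (cfg.eta_per_h / r + 1.0)
    if denom <= 0:
        raise InfeasibleGrowthRateError(
            f"growth rate {r:.3g}/h exceeds the ribosome self-replication limit "
            f"{(cfg.r_R_bp_per_h - cfg.l_R_bp * cfg.eta_per_h) / cfg.l_R_bp:.3g}/h"
        )
    n_ribosomes = cfg.l_P_bp * n_proteins * (cfg.phi_per_h / r + 1.0) / denom
    return cfg.v_R_um3 * n_ribosomes


def cell_geometry_from_genome(
    traits: IsolateTraits,
    allometry: AllometryConfig | None = None,
    ribosome: RibosomeConfig | None = None,
) -> CellGeometry:
    """Derive the cell model from genome size via configurable power laws."""
    cfg = allometry or AllometryConfig()
    rib = ribosome or RibosomeConfig()

    G_mbp = traits.genome_size_bp / 1.0e6
    V_c = cfg.volume_coeff * G_mbp**cfg.volume_exp  # um^3
    L_c = V_c ** (1.0 / 3.0)
    r_c = (3.0 * V_c / (4.0 * np.pi)) ** (1.0 / 3.0) * 1.0e-6  # m
    M_dry = cfg.drymass_coeff_fg * 1.0e-15 * V_c**cfg.drymass_exp  # g
    N_P = cfg.protein_count_coeff * V_c**cfg.protein_count_exp
    V_P = N_P * rib.v_P_um3
    V_R = min_ribosome_volume(traits.r_max, N_P, rib)
    lambda_B = M_C / (cfg.carbon_fraction * M_dry)

    if V_P >= V_c:
        raise ValueError(
            f"allometry produced protein volume {V_P:.3g} um^3 >= cell volume "
            f"{V_c:.3g} um^3; check allometry exponents"
        )
    if V_R > V_P:
        raise InfeasibleGrowthRateError(
            f"{traits.isolate_id}: ribosome volume needed for r_max={traits.r_max:.3g}/h "
            f"({V_R:.3g} um^3) exceeds the protein volume ({V_P:.3g} um^3)"
        )
    return CellGeometry(
        V_c=V_c,
        L_c=L_c,
        r_c=r_c,
        M_dry=M_dry,
        V_P=V_P,
        V_R=V_R,
        N_P=N_P,
        composition=(1.0, cfg.biomass_h, cfg.biomass_o, cfg.biomass_n),
        mu_E=cfg.mu_E_kJ_per_Cmol,
        lambda_B=lambda_B,
    )


def reserve_turnover_kE(traits: IsolateTraits, geometry: CellGeometry) -> float:
    """Reserve turnover rate k_E = r_max * V_P / V_R (1/h), >= r_max."""
    return traits.r_max * geometry.V_P / geometry.V_R


def translational_yield(
    rrn_copies: int, config: TranslationConfig | None = None
) -> float:
    """Translational yield y_VE from rrn copy number.

    Piecewise-linear in log(rrn) between the calibration bounds: a single
    operon maps to y_VE_max, ``rrn_at_min`` or more to y_VE_min. More
    operons buy translation speed at the cost of yield.
    """
    cfg = config or TranslationConfig()
    if rrn_copies < 1:
        raise ValueError(f"rrn copy number must be >= 1, got {rrn_copies}")
    frac = np.log(min(rrn_copies, cfg.rrn_at_min)) / np.log(cfg.rrn_at_min)
    return float(cfg.y_VE_max - (cfg.y_VE_max - cfg.y_VE_min) * frac)
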