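"""Diffusion-limited uptake kinetics and ECA flux partitioning.

Substrate binding at the cell surface is diffusion-limited: the apparent
half-saturation constant of a cell carrying B_T binding sites inflates
above the intrinsic constant of a single site,

    K = K0 * (1 + k+ * (B_T / n) / (4 pi D r_c)),

with K0 ~ k2 / k+ and the forward rate k+ defaulting to the
diffusion-limited encounter rate of one porter, 4 pi D r_p. The
equilibrium chemistry approximation (ECA) then partitions fluxes over a
network of I substrates and J consumers:

    j_D[i,j] = -k2 * N[i,j] * B_j * (D_i / K_ij) / (1 + F_r,i + F_c,j)

with F_c,j = sum_l D_l / K_lj (competition between substrates for
consumer j's sites) and F_r,i = sum_l N_il B_l / K_il (competition
between consumers for substrate i). In the dilute-consumer limit the
scalar form collapses to Michaelis-Menten.

Internal units: concentrations mM; biomass mol C per litre; fluxes mol
substrate per litre per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import KineticsConfig
from .genome import CellGeometry
from .substrates import SubstrateProperties
from .thermo import AVOGADRO

__all__ = [
    "KineticsGrid",
    "affinity",
    "binding_sites_per_molC",
    "eca_fluxes",
    "tradeoff_curve",
    "build_kinetics_grid",
]

M_C = 12.011


def affinity(
    K0: float,
    k_plus: float,
    B_total: float,
    diffusivity: float,
    r_c: float,
    n_cell: float,
) -> float:
    """Apparent substrate affinity K (mM) of a transporter-bearing cell.

    ``B_total`` is the total number of binding sites in the volume holding
    ``n_cell`` cells, so B_total / n_cell is the per-cell site count. K
    equals K0 when the cell carries no sites and grows linearly in the
    per-cell site count.
    """
    if min(K0, k_plus, diffusivity, r_c, n_cell) <= 0 or B_total < 0:
        raise ValueError("affinity arguments must be positive (B_total >= 0)")
    return K0 * (1.0 + k_plus * (B_total / n_cell) / (4.0 * np.pi * diffusivity * r_c))


def binding_sites_per_molC(
    rho_porter: float, r_c: float, M_dry: float, r_p: float, carbon_fraction: float = 0.47
) -> float:
    """Biomass-specific binding sites N (mol sites per mol biomass C).

    N = M_C * 4 pi r_c^2 * rho / (f_C * M_dry * pi r_p^2 * N_A); linear in
    the porter area fraction rho.
    """
    if rho_porter < 0 or not 0 <= rho_porter < 1:
        raise ValueError(f"rho_porter must be in [0, 1), got {rho_porter}")
    if min(r_c, M_dry, r_p) <= 0:
        raise ValueError("geometry arguments must be positive")
    return (
        M_C
        * 4.0
        * np.pi
        * r_c**2
        * rho_porter
        / (carbon_fraction * M_dry * np.pi * r_p**2 * AVOGADRO)
    )


@dataclass
class KineticsGrid:
    """Kinetic parameter matrices over substrates (rows) x consumers (cols)."""

    substrate_names: list[str]
    consumer_ids: list[str]
    K: np.ndarray  # mM
    K0: np.ndarray  # mM
    Vmax: np.ndarray  # mol substrate / mol C / h
    N: np.ndarray  # mol sites / mol C
    k_plus: np.ndarray  # m^3 / s
    k2_per_s: float
    porter_radius_m: float
    substrate_cmol: np.ndarray = field(default=None)  # C atoms per substrate

    def __post_init__(self) -> None:
        shape = (len(self.substrate_names), len(self.consumer_ids))
        for name in ("K", "K0", "Vmax", "N", "k_plus"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, arr)
        if np.any(self.K + 1e-30 < self.K0):
            raise ValueError("apparent K must be >= intrinsic K0")

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per substrate-consumer pair."""
        rows = []
        for i, s in enumerate(self.substrate_names):
            for j, c in enumerate(self.consumer_ids):
                rows.append(
                    {
                        "substrate": s,
                        "consumer": c,
                        "K_mM": self.K[i, j],
                        "Vmax": self.Vmax[i, j],
                        "N": self.N[i, j],
                    }
                )
        return pd.DataFrame(rows)


def eca_fluxes(D_mM: np.ndarray, B_molC: np.ndarray, grid: KineticsGrid) -> np.ndarray:
    """ECA flux matrix j_D (mol substrate / L / h), <= 0 for consumption.

    ``D_mM`` are substrate concentrations (mM) and ``B_molC`` consumer
    biomasses (mol C / L). Pairs with zero substrate or zero binding-site
    allocation carry zero flux.
    """
    D = np.asarray(D_mM, dtype=float)
    B = np.asarray(B_molC, dtype=float)
    if np.any(D < 0) or np.any(B < 0):
        raise ValueError("concentrations and biomasses must be non-negative")
    K = grid.K
    with np.errstate(divide="ignore", invalid="ignore"):
        DK = np.where(K > 0, D[:, None] / K, 0.0)
        # site concentrations in mM: (mol sites / mol C) * (mol C / L) * 1e3
        NBK = np.where(K > 0, grid.N * B[None, :] * 1.0e3 / K, 0.0)
    F_c = DK.sum(axis=0)  # per consumer j
    F_r = NBK.sum(axis=1)  # per substrate i
    k2_per_h = grid.k2_per_s * 3600.0
    denom = 1.0 + F_r[:, None] + F_c[None, :]
    return -k2_per_h * grid.N * B[None, :] * DK / denom


def tradeoff_curve(
    substrate: SubstrateProperties,
    geometry: CellGeometry,
    rho_grid: np.ndarray,
    config: KineticsConfig | None = None,
) -> pd.DataFrame:
    """V_max / K / specific-affinity trade-off along a porter-density grid.

    V_max grows linearly with rho while K inflates, so the specific
    affinity V_max / K (the low-concentration specific uptake rate)
    saturates: packing more than a small fraction of the surface with
    porters buys almost no extra affinity.
    """
    cfg = config or KineticsConfig()
    rho = np.asarray(rho_grid, dtype=float)
    if np.any(np.diff(rho) <= 0):
        raise ValueError("rho_grid must be strictly increasing")
    if rho[-1] >= cfg.rho_max:
        raise ValueError(f"rho_grid exceeds the packing limit {cfg.rho_max}")
    k_plus = 4.0 * np.pi * substrate.diffusivity * cfg.porter_radius_m
    K0 = grid_K0(cfg.k2_per_s, k_plus)
    sites_per_cell = 4.0 * geometry.r_c**2 * rho / cfg.porter_radius_m**2
    K = np.array(
        [
            affinity(K0, k_plus, s, substrate.diffusivity, geometry.r_c, 1.0)
            for s in sites_per_cell
        ]
    )
    N = np.array(
        [
            binding_sites_per_molC(r, geometry.r_c, geometry.M_dry, cfg.porter_radius_m)
            for r in rho
        ]
    )
    Vmax = cfg.k2_per_s * 3600.0 * N
    with np.errstate(divide="ignore"):
        spec_aff = np.where(K > 0, Vmax / K, 0.0)
    return pd.DataFrame(
        {"rho": rho, "Vmax": Vmax, "K_mM": K, "specific_affinity": spec_aff}
    )


def grid_K0(k2_per_s: float, k_plus: float) -> float:
    """Intrinsic half-saturation K0 = k2 / k+ expressed in mM.

    k2/k+ is a number density (m^-3); dividing by Avogadro gives
    mol m^-3, which is numerically mM.
    """
    return k2_per_s / (k_plus * AVOGADRO)


def build_kinetics_grid(
    substrates: list[SubstrateProperties],
    consumer_ids: list[str],
    geometries: list[CellGeometry],
    rho_matrix: np.ndarray,
    config: KineticsConfig | None = None,
) -> KineticsGrid:
    """Assemble the kinetics grid for substrates x consumers.

    ``rho_matrix[i, j]`` is the porter area fraction consumer j devotes to
    substrate i. The affinity inflation uses the per-cell site count,
    which is density-invariant (total sites and cell numbers scale
    together), so K is computed once per pair.
    """
    cfg = config or KineticsConfig()
    I, J = len(substrates), len(consumer_ids)
    rho = np.asarray(rho_matrix, dtype=float)
    if rho.shape != (I, J):
        raise ValueError(f"rho_matrix has shape {rho.shape}, expected {(I, J)}")
    K = np.zeros((I, J))
    K0 = np.zeros((I, J))
    N = np.zeros((I, J))
    kp = np.zeros((I, J))
    for i, sub in enumerate(substrates):
        k_plus = 4.0 * np.pi * sub.diffusivity * cfg.porter_radius_m
        k0 = grid_K0(cfg.k2_per_s, k_plus)
        for j, geom in enumerate(geometries):
            sites_per_cell = 4.0 * geom.r_c**2 * rho[i, j] / cfg.porter_radius_m**2
            K0[i, j] = k0
            kp[i, j] = k_plus
            K[i, j] = affinity(k0, k_plus, sites_per_cell, sub.diffusivity, geom.r_c, 1.0)
            N[i, j] = binding_sites_per_molC(
                rho[i, j], geom.r_c, geom.M_dry, cfg.porter_radius_m
            )
    Vmax = cfg.k2_per_s * 3600.0 * N
    return KineticsGrid(
        substrate_names=[s.name for s in substrates],
        consumer_ids=list(consumer_ids),
        K=K,
        K0=K0,
        Vmax=Vmax,
        N=N,
        k_plus=kp,
        k2_per_s=cfg.k2_per_s,
        porter_radius_m=cfg.porter_radius_m,
        substrate_cmol=np.array([s.formula.a for s in substrates], dtype=float),
    )
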