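"""Run configuration: all tunable model constants in one structured object.

Every constant that the model needs but that cannot be derived from the
input tables lives here, grouped by module. A configuration can be loaded
from YAML/JSON, is strictly validated (unknown keys are rejected), and
carries a content hash so that outputs can be traced back to the exact
constants that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ChemistryConfig",
    "AllometryConfig",
    "RibosomeConfig",
    "TranslationConfig",
    "ThermoConfig",
    "KineticsConfig",
    "TurnoverConfig",
    "ProtocolConfig",
    "IntegratorConfig",
    "RunConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised for malformed or inconsistent configuration input."""


@dataclass
class ChemistryConfig:
    """Substrate physicochemistry constants."""

    temperature_K: float = 298.15
    #: assumed density of dissolved organic solutes, used to estimate the
    #: molar volume entering the diffusivity correlation (g cm^-3)
    solute_density_g_cm3: float = 1.0
    #: Wilke-Chang association parameter for water
    wilke_chang_phi: float = 2.6
    solvent_molar_mass: float = 18.015
    #: Gibbs energy released per mol of electrons transferred to O2 during
    #: aerobic oxidation of organic matter (kJ / mol e-); 120 reproduces the
    #: textbook -2880 kJ/mol for full glucose oxidation (24 e-).
    energy_per_electron_kJ: float = 120.0


@dataclass
class AllometryConfig:
    """Power-law coefficients of the cell model.

    Cell volume from genome size, dry mass / protein count from cell
    volume. Coefficients are literature-informed defaults; each is a free
    parameter of the model.
    """

    #: V_c [um^3] = volume_coeff * (G [Mbp])^volume_exp
    volume_coeff: float = 0.2
    volume_exp: float = 1.07
    #: M_dry [fg] = drymass_coeff_fg * (V_c [um^3])^drymass_exp
    drymass_coeff_fg: float = 435.0
    drymass_exp: float = 0.86
    #: N_P = protein_count_coeff * (V_c [um^3])^protein_count_exp (sublinear)
    protein_count_coeff: float = 3.0e6
    protein_count_exp: float = 0.70
    #: generalized biomass composition C H_b O_d N_c per C-mol
    biomass_h: float = 1.8
    biomass_o: float = 0.5
    biomass_n: float = 0.2
    #: carbon fraction of dry biomass
    carbon_fraction: float = 0.47
    #: chemical potential of reserve (kJ per C-mol)
    mu_E_kJ_per_Cmol: float = 550.0


@dataclass
class RibosomeConfig:
    """Ribosome-economy constants of the translation model."""

    #: ribosome length in base pairs (~4566 nt of rRNA)
    l_R_bp: float = 4566.0
    #: maximum base-pair processing rate of a ribosome (bp / h); 63 bp/s
    r_R_bp_per_h: float = 226800.0
    #: average protein length in base pairs (~325 aa)
    l_P_bp: float = 975.0
    #: average protein volume (um^3)
    v_P_um3: float = 4.2e-8
    #: ribosome volume (um^3)
    v_R_um3: float = 3.4e-6
    #: specific ribosome degradation rate eta (1/h)
    eta_per_h: float = 0.02
    #: specific protein degradation rate phi (1/h)
    phi_per_h: float = 0.02


@dataclass
class TranslationConfig:
    """rrn copy number -> translational yield calibration bounds."""

    y_VE_max: float = 0.8
    y_VE_min: float = 0.3
    rrn_at_min: int = 15


@dataclass
class ThermoConfig:
    """Gibbs-energy bookkeeping of catabolism/anabolism coupling."""

    #: Gibbs energy of biomass-component synthesis from building blocks
    #: (kJ per C-mol); dG_diss = dG_syn / nu
    dG_syn_kJ: float = 150.0
    #: fraction of energy dissipated in all enzymatic synthesis steps
    nu: float = 0.4
    #: building-block conversion energy (kJ per C-mol reserve), fallback
    dG_block_kJ: float = 100.0
    #: per-class building-block conversion energies; sugars feed central
    #: metabolism directly while amino acids pay deamination/N handling
    #: and nucleotides/aromatics pay ring rearrangement costs
    dG_block_by_class: dict = field(
        default_factory=lambda: {
            "sugar": 80.0,
            "organic_acid": 100.0,
            "amino_acid": 160.0,
            "fatty_acid": 120.0,
            "nucleotide": 150.0,
            "auxin": 130.0,
        }
    )
    #: porter synthesis cost: amino acids per porter protein
    porter_aa: float = 500.0
    #: ATP per amino acid polymerized
    atp_per_aa: float = 4.2
    #: Gibbs energy per mol ATP (kJ)
    dG_atp_kJ: float = 50.0


@dataclass
class KineticsConfig:
    """Uptake kinetics constants."""

    #: maximum substrate processing rate of a bound site, k2 (1/s)
    k2_per_s: float = 20.0
    #: effective porter cross-section radius r_p (m)
    porter_radius_m: float = 1.0e-9
    #: membrane packing limit for the total porter area fraction
    rho_max: float = 0.25
    #: recompute the affinity from current cell density each step ("dynamic")
    #: or freeze it at inoculum density ("static")
    affinity_mode: str = "dynamic"


@dataclass
class TurnoverConfig:
    """Density-dependent turnover of reserve and structure."""

    #: first-order rate at the reference density (1/h)
    gamma0_per_h: float = 0.02
    #: reference biomass density (mol C / L)
    B_ref_molC_L: float = 1.0e-3
    #: multiplier on gamma0 for the reserve pool (gamma_E = mult * gamma_V)
    reserve_multiplier: float = 1.0
    #: overhead factor when maintenance is paid from structure
    starvation_overhead: float = 1.2
    #: slope mapping glycoside-hydrolase gene frequency to the constitutive
    #: enzyme production coefficient z_X_rate
    z_X_slope: float = 1.0


@dataclass
class ProtocolConfig:
    """Simulation protocol (batch / mixed medium)."""

    #: total substrate carbon in the medium (mg C / L)
    substrate_mgC_L: float = 125.0
    #: inoculum size; the per-gram-soil census is mapped 1:1 to per litre
    inoculum_cells_per_L: float = 1.0e6
    #: fraction of inoculum carbon in reserve (rest is structure)
    reserve_fraction: float = 0.9
    batch_hours: float = 500.0
    mixed_hours: float = 1500.0
    #: substrate-exhaustion threshold (mol C / L)
    exhaustion_molC_L: float = 1.0e-12
    #: number of stored trajectory points
    n_timepoints: int = 600


@dataclass
class IntegratorConfig:
    rtol: float = 1.0e-8
    atol: float = 1.0e-14
    method: str = "LSODA"


@dataclass
class RunConfig:
    """Top-level configuration with a named profile and content hash."""

    profile: str = "batch-default"
    chemistry: ChemistryConfig = field(default_factory=ChemistryConfig)
    allometry: AllometryConfig = field(default_factory=AllometryConfig)
    ribosome: RibosomeConfig = field(default_factory=RibosomeConfig)
    translation: TranslationConfig = field(default_factory=TranslationConfig)
    thermo: ThermoConfig = field(default_factory=ThermoConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    turnover: TurnoverConfig = field(default_factory=TurnoverConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError(f"configuration must be a mapping, got {type(data).__name__}")
        data = {k: v for k, v in data.items() if k != "config_hash"}
        sections = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key not in sections:
                raise ConfigError(f"unknown configuration section or key: {key!r}")
            f = sections[key]
            if f.name == "profile":
                kwargs[key] = str(value)
                continue
            section_cls = f.default_factory  # type: ignore[union-attr]
            kwargs[key] = _section_from_dict(section_cls, value, key)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        payload = self.to_dict()
        payload["config_hash"] = self.config_hash
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _section_from_dict(section_cls: Any, value: Any, section: str) -> Any:
    if isinstance(value, section_cls):
        return value
    if not isinstance(value, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    valid = {f.name for f in dataclasses.fields(section_cls)}
    unknown = set(value) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {section!r}: {', '.join(sorted(unknown))}"
        )
    return section_cls(**value)
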