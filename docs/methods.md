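# Methods

This note documents the model implemented in `rhizodeb`, the provenance
and defaults of every tunable constant, the numerical choices, what the
synthetic survey generator does and does not emulate, and the known
limitations.

## 1. State variables and fluxes

A population of one organism in a well-mixed liquid volume is described
by (all in mol C l⁻¹ unless noted):

| pool | meaning |
| --- | --- |
| `D_i` | dissolved substrate *i* (tracked per mol of molecule internally) |
| `E` | reserve biomass (growth machinery + storage; mobilizable) |
| `V` | structural biomass (maintained) |
| `X` | cumulative extracellular enzyme carbon |
| `CO2` | cumulative respired carbon |
| `necromass` | cumulative turnover losses |
| `BP` | cumulative gross production of E and V |

Reserve dynamics follow first-order mobilization at rate `k_E` when
expressed as the reserve density `m_E = E/V`. Mobilized power is
partitioned with maintenance priority into growth, maintenance and
constitutive extracellular enzyme production (`p_X` proportional to the
growth flux through the coefficient `z_X`). Eliminating the powers gives
the closed-form specific growth rate

    r = (k_E m_E − k_M) / (m_E + y_EV (1 + z_X))

which approaches `k_E` as `m_E → ∞`: reserve turnover is the hard
ceiling on growth. When `k_E m_E < k_M` the organism is starving; the
maintenance deficit is paid from structure with an overhead multiplier
(default 1.2 — the transformation of structure back into maintenance
work is less efficient than paying from reserve; the value is a model
constant, configurable).

Carbon bookkeeping per unit time (growth branch):

* uptake `U_i` (ECA, below) enters reserve at yield `y_ED,i`; the
  complement `(a_i − y_ED,i) U_i` is assimilation overhead → CO₂;
* growth consumes `y_EV r V` of reserve, produces `r V` of structure,
  respires the difference;
* enzyme production consumes `z_X y_EV r V`, deposits `z_X r V` into
  `X`, respires the difference;
* maintenance `k_M V` is respired;
* density-dependent turnover `γ = γ0 · B_tot / B_ref` moves reserve and
  structure to necromass (`B_tot = E + V`; both pools use the same rate
  by default, which also makes the balanced reserve density independent
  of turnover).

The right-hand side sums to zero over (substrate C + pools + CO₂ +
necromass), so carbon is conserved identically; the integrated balance
error is checked after every simulation (observed ≲ 1e-14 relative,
asserted < 1e-6).

**BP convention.** Carbon use efficiency is `CUE = BP/(BP+BR)` with
`BR` the cumulative respiration. `BP` counts *gross* synthesis of E and
V — turnover losses stay inside BP and flow to necromass, not CO₂. This
keeps CUE within [0, 1] by construction and cleanly separates the
fate-of-carbon question (necromass vs CO₂) from the efficiency
question. For regression analyses against respiration, production and
respiration are used as time-averaged *rates* (cumulative totals divided
by simulated duration); cumulative totals in a closed batch are
anti-correlated by mass balance and would not measure the power–yield
relationship.

**Phenotype summaries.** `r_realized` is the median of the instantaneous
`r(t)` over output times with `r > 1e-4 h⁻¹` ("the growth curve"); the
trajectory maximum is reported separately. Latency is the time of peak
mineralization rate (max `dCO2/dt`). Alternatives (mean, max) are one
line of code away; the median is robust to the initial reserve
transient of the 90/10 inoculum.

## 2. Genome traits → cell model

Power laws with configurable coefficients map genome size to cell
volume, and volume to dry mass and protein count:

* `V_c [µm³] = 0.2 · (G [Mbp])^1.07` — gives ≈1 µm³ for a 4.6 Mbp
  genome, 0.4–2.4 µm³ over the 2–10 Mbp survey range;
* `M_dry [fg] = 435 · V_c^0.86` (bacterial dry-mass allometry);
* `N_P = 3·10⁶ · V_c^0.70` proteins (sublinear — larger cells are
  relatively less proteinaceous), `V_P = N_P v̄_P` with
  `v̄_P = 4.2·10⁻⁸ µm³` (≈325 aa average protein).

These are literature-informed defaults, not fits; every coefficient
lives in `AllometryConfig`.

Biomass is the generalized compound CH₁.₈O₀.₅N₀.₂ (24.6 g per C-mol),
47 % of dry mass is carbon, and `λ_B = M_C / (0.47 M_dry)` converts
between cells and mol biomass C. The chemical potential of reserve is
`μ_E = 550 kJ` per C-mol (combustion-scale energy content of biomass).

**Ribosome economy.** Every ribosome must, per division cycle,
translate all proteins and all ribosomal proteins while replacing
degraded copies. Balancing base-pair throughput gives the minimum
ribosome count at growth rate `r`

    N_R = l̄_P N_P (φ/r + 1) / (r̄_R/r − l̄_R (η/r + 1))

and `V_R = v̄_R N_R` (`l̄_P = 975 bp`, `l̄_R = 4566 bp`,
`r̄_R = 63 bp s⁻¹`, `v̄_R = 3.4·10⁻⁶ µm³`, degradation rates
`η = φ = 0.02 h⁻¹`). The bound diverges at `r ≈ r̄_R/l̄_R ≈ 50 h⁻¹`,
far above bacterial growth rates. Applied at equality at `r = r_max` it
yields `k_E = r_max V_P / V_R`, which is ≥ `r_max` whenever the
ribosome inventory fits inside the protein inventory (checked; violation
raises an infeasibility error). Note the count/volume formulation here
is chosen to be dimensionally consistent: ribosome count × ribosome
volume, with the protein volume entering only through `V_P`.

**Translational yield.** `y_VE` maps *rrn* copy number piecewise-linearly
in log(rrn) from 0.8 (one operon) down to 0.3 (≥15 operons): many
operons buy translation speed at a per-C-mol yield cost. Bounds are
calibration constants in `TranslationConfig`.

**Maintenance.** `k_M = κ_M · V_c · λ_B` — per-cell maintenance power
proportional to cell volume, normalized per C-mol of structure;
`κ_M = 10⁻¹⁶ mol C µm⁻³ h⁻¹` gives k_M of order 10⁻³–10⁻² h⁻¹,
i.e. noticeable for slow growers and negligible for fast ones.

## 3. Substrate chemistry

From the elemental formula C_aH_bN_cO_d with net charge z:

* `NOSC = 4 − (4a + b − 3c − 2d − z)/a` (standard charge-corrected
  definition), validated to [−4, 4];
* electrons per C-mol on full aerobic oxidation: `4 − NOSC`;
* `ΔG_cat = −120 kJ × electrons` per mol substrate. The 120 kJ per mol
  electrons constant reproduces the textbook −2880 kJ mol⁻¹ for glucose
  (24 e⁻) and is configurable; per-substrate overrides can be supplied
  via a `dG_cat` column in the substrate table, which is the hook for
  substituting measured Gibbs energies;
* aqueous diffusivity from the Wilke–Chang correlation with the solute
  molar volume estimated as molar mass over an assumed solute density
  (1.0 g cm⁻³): ≈7.5·10⁻¹⁰ m² s⁻¹ for a glucose-sized molecule,
  strictly decreasing in molar mass. Water viscosity follows a
  Vogel-type correlation so the temperature dependence is physical.

## 4. Thermodynamic assimilation yield

Growth on a single organic substrate doubling as electron donor couples
a catabolic reaction (full oxidation, `ΔG_cat`) to an anabolic one
(substrate carbon → reserve carbon, `ΔG_an = ΔG_block + ΔG_ρporter`),
with dissipation `ΔG_diss = ΔG_syn/ν`. Booking both routes per C-mol of
substrate processed (`Y_cat = Y_an = 1/a`), the coupling number and
yield are

    λ = (ΔG_an + ΔG_diss) / (−ΔG_cat per C-mol)
    y_ED = 1 / (Y_cat + λ Y_an) = a / (1 + λ)   [C-mol reserve / mol substrate]

so `y_ED ≤ a` automatically, and the energy closure
`λ·(−ΔG_cat) = ΔG_an + ΔG_diss` holds to machine precision (asserted).
Defaults: `ΔG_syn = 150 kJ`, `ν = 0.4` (hence 375 kJ dissipated per
C-mol), and per-class building-block conversion energies
(sugar 80, organic acid 100, fatty acid 120, auxin 130, nucleotide 150,
amino acid 160 kJ per C-mol) reflecting that sugars feed central
metabolism directly while amino acids pay deamination and nitrogen
handling and heterocycles pay ring rearrangement. With these settings a
glucose-sized sugar assimilates at ≈0.5 C-mol per C-mol, placing
simulated CUE near the 0.4–0.6 range typical of aerobic heterotrophs.

The porter synthesis cost is linear in the porter area fraction:
(porters per cell) × (cells per C-mol) × (500 aa × 4.2 ATP/aa ×
50 kJ/mol ATP). At realistic densities it is a ≲1 % correction to
`ΔG_an`, which is why the supply–demand closure below stays effectively
one-dimensional.

## 5. Uptake kinetics

The apparent affinity of a transporter-bearing cell is diffusion-limited:

    K_ij = K0_ij (1 + k⁺_ij (B_T/n) / (4π D̃_i r_c,j))

with `K0 = k₂/k⁺` (expressed in mM via Avogadro) and the forward rate
defaulting to the per-site diffusion-limited encounter rate
`k⁺ = 4π D̃ r_p`. The maximum site turnover is `k₂ = 20 s⁻¹` and the
porter cross-section radius `r_p = 1 nm` — both order-of-magnitude
transporter constants, config-exposed. Because `B_T/n` is the *per-cell*
site count, the inflation term is invariant under population growth;
the dynamic/static affinity switch therefore has no effect in practice
and exists for sensitivity analysis.

Biomass-specific binding sites:

    N_ij = M_C 4π r_c² ρ_ij / (0.47 M_dry π r_p² N_A)   [mol sites / mol C]

and `V_max,ij = k₂ N_ij`. ECA partitions fluxes over the network:

    j_D,ij = −k₂ N_ij B_j (D_i/K_ij) / (1 + F_r,i + F_c,j)
    F_c,j = Σ_l D_l/K_lj          (substrates competing for consumer j)
    F_r,i = Σ_l N_il B_l / K_il   (consumers competing for substrate i)

Internally concentrations are mM and biomasses mol C l⁻¹; site
concentrations are converted to mM in `F_r`. The scalar form collapses
to Michaelis–Menten when `N B/K → 0` (tested to <1e-3 relative at
`NB/K < 1e-4`).

**Trade-off geometry.** Along a porter-density grid, `V_max ∝ ρ` while
`K` inflates linearly, so the specific affinity `V_max/K` saturates at
`ρ` of order `r_p/(4 r_c)` ≈ 0.04 %: packing much beyond ~0.1 % of the
surface buys almost no extra low-concentration uptake. The V_max–K
curve is (weakly) concave — affine in the present closure — matching
the concave placement of uptake strategies expected for soil organisms.

## 6. Supply–demand closure for ρ_porter

At saturating substrate the ECA factor → 1 and assimilation per C-mol
of *total* biomass is `p(ρ) = y_ED(ρ) k₂ N(ρ)`. Uptake scales with
total biomass (cells × sites per cell) while mobilization scales with
structure, so the balanced reserve density satisfies
`p (1 + m*) = k_E m*`, i.e. `m* = p/(k_E − p)` — equivalently, the
reserve capacity is assimilation-per-structure over turnover,
`m* = p_Am/k_E`. The saturated growth rate

    r_sat(ρ) = (k_E m* − k_M) / (m* + y_EV (1 + z_X))

is strictly increasing in ρ with asymptote `k_E`; the closure solves
`r_sat(ρ*) = r_max` by Brent bracketing on (0, ρ_max) with relative
tolerance 1e-10 (packing limit ρ_max = 0.25). The porter-cost feedback
on `y_ED` is evaluated inline; an alternating fixed-point formulation
converges to the same root in a few iterations (tested). No sign change
in the bracket means the genome-inferred `r_max` is unreachable on that
substrate for any membrane allocation; this raises a diagnostic
infeasibility error rather than clipping.

ρ* is solved **per substrate**: each single-substrate batch culture
carries the allocation sized for its own substrate, which makes
"saturated growth recovers r_max" an exact contract (verified to within
2 % by simulation for every synthetic isolate). For mixed-medium
competition the cumulative budget `Σ_i ρ*_i` is redistributed across
substrates by the normalized transporter gene frequencies `z_ρ` (equal
shares within a class); classes absent from the repertoire receive zero
porters and hence zero uptake. Solved per-substrate densities for the
synthetic survey fall in the 0.01–1 % range (median ≈ 0.1–0.3 %), with
cumulative budgets of order 10 % of the membrane.

**Recovery-check protocol.** The paper-style batch inoculum (90 %
reserve) starts far above `m*`, so `r(t)` transiently overshoots
`r_max` while the reserve burns down. The closure-recovery check
therefore inoculates reserve-poor (0.1 % reserve) at 100× substrate so
`r(t)` approaches the saturated rate from below and the trajectory
maximum measures `r_sat` itself. Production protocols keep the 90/10
split.

## 7. Simulation protocols

* **Batch**: one substrate at 125 mg C l⁻¹; inoculum 10³ cells per g
  soil mapped 1:1 to cells per litre (10⁶ l⁻¹; the soil-to-solution
  conversion is configurable), split 90 % reserve / 10 % structure;
  500 h or until substrate C < 1e-12 mol l⁻¹ (terminal event).
* **Mixed medium**: the same total carbon split evenly across the
  substrate panel; 1 500 h or until the *first* metabolite depletes;
  per-substrate uptake ledger (consumed fraction per substrate) and
  Levins niche breadth `B = 1/Σ p_i²` on normalized consumption shares.
  Mixed runs are per-isolate by default (one organism alone on the full
  panel); a community mode integrates all consumers against shared
  substrate pools through the same ECA network.
* Integrator: LSODA (stiff-capable), rtol 1e-8 / atol 1e-14; halving
  tolerances moves BP, BR and CUE by far less than 1e-4 relative
  (tested). Trajectories are stored on a 600-point grid plus the exact
  event state. ODEs are deterministic; seeds only enter fixture
  generation.

Turnover defaults `γ0 = 0.02 h⁻¹` at reference density
`B_ref = 10⁻³ mol C l⁻¹`: negligible at inoculation, of order the
growth rate near stationary phase — a simple stand-in for
density-dependent mortality (phage, protists) whose functional form is
a modelling choice, flagged as such.

## 8. Emergent-trait analysis

* Growth regimes split at 0.039 h⁻¹ (boundary closed on the high side),
  with an optional data-driven cut at the antimode of a two-component
  Gaussian mixture on log rates.
* BP–BR scaling: OLS of log₁₀ production rate on log₁₀ respiration rate
  per regime, with a t-test of the slope against 1. On the synthetic
  survey the low regime scales proportionally (slope ≈ 1.0) while the
  high regime scales disproportionally (slope < 1): energy dissipation
  grows faster than production at high rates.
* Rate–yield regression uses substrate-class medians as the unit of
  analysis.
* Variance explained: OLS of a phenotype on rrn, genome size and their
  interaction.
* Group preference differences: per-substrate group means of mixed-run
  depletion fractions, differenced in percentage points and ranked.
* Kruskal–Wallis plus BH-corrected pairwise rank tests are thin
  wrappers over scipy/statsmodels. Bimodality is asserted via mixture
  component separation rather than a dip test (no dip-test
  implementation in the dependency set; the mixture criterion tests the
  same structure more directly).

## 9. The synthetic survey

`rhizodeb.fixtures` generates deterministic (seeded) isolate and
substrate tables. Substrate formulas are drawn from small per-class
template sets of real metabolites (hexoses and di-/pentoses; C2–C9
aliphatic and aromatic acid anions; proteinogenic amino acids; C4–C18
fatty acid anions; ribo-/deoxyribonucleosides; indole and terpenoid
phytohormones), so NOSC class structure is chemically real. Isolates
span 2–10 Mbp genomes, 1–15 rrn operons, and bimodal generation times
(1–4 h fast band, 12–60 h slow band); negative root responders are
biased fast, rrn-rich, sugar-transporter- and glycoside-hydrolase-heavy,
positive responders slow and organic-acid/auxin-oriented, mirroring the
qualitative contrasts reported for rhizosphere response groups.

What the generator does **not** emulate: the empirical covariance
structure of any real isolate collection, real transporter gene counts,
measured Gibbs energies per metabolite, or soil-matrix effects. Tests
passing on this survey therefore demonstrate internal consistency and
qualitative trait-phenotype structure, not quantitative agreement with
any particular organism panel.

## 10. Numerical and degenerate-input conventions

* Root solve: Brent on a guaranteed bracket; absence of a sign change
  is an explicit infeasibility error carrying diagnostics.
* Negative pool excursions from the integrator are clipped in the RHS;
  non-finite derivatives abort with a state dump.
* Zero inoculum returns a flagged degenerate result (NaN CUE) rather
  than an error; zero-variance responses in regressions return r² = 0.
* The regime boundary is closed on the high side; ties in ranked
  preference tables keep pandas' stable order.

## 11. Known limitations

* Gibbs energies use a single energy-per-electron constant plus
  per-class block energies; no group-contribution thermochemistry, pH
  speciation or activity corrections. Per-substrate overrides exist for
  users with measured values.
* Only aerobic metabolism with the C source as electron donor; no
  N/P co-limitation (organic C and energy limitation assumed).
* Extracellular enzymes are a cost sink: the substrate panel is
  monomeric, so no polymer hydrolysis feedback.
* No soil matrix: no sorption, diffusion fields or spatial structure.
* The allometric and ribosome constants are defensible literature-scale
  defaults, not organism-specific calibrations; absolute phenotype
  values shift with them, while the trade-off structure (rate–yield,
  V_max–K, regime bimodality) is robust across reasonable settings.
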