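"""Diffusion-limited affinity, binding sites, ECA fluxes and the trade-off curve."""

import numpy as np
import pytest

from rhizodeb.config import KineticsConfig
from rhizodeb.genome import IsolateTraits, cell_geometry_from_genome
from rhizodeb.kinetics import (
    KineticsGrid,
    affinity,
    binding_sites_per_molC,
    eca_fluxes,
    tradeoff_curve,
)
from rhizodeb.substrates import build_substrate_properties
from rhizodeb.thermo import AVOGADRO


def eca_oracle(D, B, grid):
    """Literal, loop-wise transcription of the ECA flux network.

    Independent of the vectorized implementation: flux of substrate i to
    consumer j is -k2 N_ij B_j * (D_i/K_ij) / (1 + F_r,i + F_c,j) with
    F_c,j = sum_l D_l/K_lj and F_r,i = sum_l N_il B_l / K_il (site
    concentrations expressed in the same mM units as D).
    """
    I, J = grid.N.shape
    k2 = grid.k2_per_s * 3600.0
    out = np.zeros((I, J))
    for i in range(I):
        for j in range(J):
            F_c = sum(D[l] / grid.K[l, j] for l in range(I))
            F_r = sum(grid.N[i, l] * B[l] * 1e3 / grid.K[i, l] for l in range(J))
            out[i, j] = -k2 * grid.N[i, j] * B[j] * (D[i] / grid.K[i, j]) / (
                1.0 + F_r + F_c
            )
    return out


def random_grid(rng, I, J):
    K0 = 10.0 ** rng.uniform(-5, -2, size=(I, J))
    K = K0 * (1.0 + rng.uniform(0, 50, size=(I, J)))
    N = 10.0 ** rng.uniform(-8, -4, size=(I, J))
    # randomly annihilate some pairs
    mask = rng.random((I, J)) < 0.2
    N = np.where(mask, 0.0, N)
    return KineticsGrid(
        substrate_names=[f"s{i}" for i in range(I)],
        consumer_ids=[f"c{j}" for j in range(J)],
        K=K,
        K0=K0,
        Vmax=20.0 * 3600.0 * N,
        N=N,
        k_plus=np.full((I, J), 1e-18),
        k2_per_s=20.0,
        porter_radius_m=1e-9,
    )


@pytest.fixture(scope="module")
def geometry():
    tr = IsolateTraits(
        isolate_id="g", genome_size_bp=4e6, rrn_copies=4, r_max=0.3,
        z_rho={"sugar": 1.0}, z_X=0.0,
    )
    return cell_geometry_from_genome(tr)


class TestAffinity:
    def test_no_transporter_limit(self):
        assert affinity(1e-4, 1e-20, 0.0, 6.7e-10, 5e-7, 1e4) == pytest.approx(1e-4)

    def test_linearity_in_site_density(self):
        k0 = affinity(1e-4, 1e-20, 0.0, 6.7e-10, 5e-7, 1.0)
        k1 = affinity(1e-4, 1e-20, 1e4, 6.7e-10, 5e-7, 1.0)
        k2 = affinity(1e-4, 1e-20, 2e4, 6.7e-10, 5e-7, 1.0)
        assert (k2 - k0) == pytest.approx(2 * (k1 - k0), rel=1e-12)

    def test_hand_evaluated_inflation(self):
        # K = K0 (1 + k+ (B_T/n) / (4 pi D r_c))
        expected = 1e-4 * (1.0 + 1e-20 * 1e4 / (4 * np.pi * 6.7e-10 * 5e-7))
        got = affinity(1e-4, 1e-20, 1e4, 6.7e-10, 5e-7, 1.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.0237545e-4, rel=1e-6)


class TestBindingSites:
    def test_zero_density_zero_sites(self, geometry):
        assert binding_sites_per_molC(0.0, geometry.r_c, geometry.M_dry, 1e-9) == 0.0

    def test_linearity(self, geometry):
        n1 = binding_sites_per_molC(0.001, geometry.r_c, geometry.M_dry, 1e-9)
        n2 = binding_sites_per_molC(0.002, geometry.r_c, geometry.M_dry, 1e-9)
        assert n2 == pytest.approx(2 * n1, rel=1e-12)

    def test_hand_evaluated_value(self, geometry):
        rho = 0.001
        expected = (
            12.011 * 4 * np.pi * geometry.r_c**2 * rho
            / (0.47 * geometry.M_dry * np.pi * 1e-18 * AVOGADRO)
        )
        got = binding_sites_per_molC(rho, geometry.r_c, geometry.M_dry, 1e-9)
        assert got == pytest.approx(expected, rel=1e-12)


class TestEcaFluxes:
    def test_matches_literal_oracle_on_random_instances(self, rng):
        """Vectorized ECA equals the loop-wise transcription to 1e-12."""
        for _ in range(200):
            I = int(rng.integers(1, 6))
            J = int(rng.integers(1, 5))
            grid = random_grid(rng, I, J)
            D = 10.0 ** rng.uniform(-6, 0, size=I)
            B = 10.0 ** rng.uniform(-9, -2, size=J)
            got = eca_fluxes(D, B, grid)
            want = eca_oracle(D, B, grid)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=0)

    def test_scalar_collapse(self, rng):
        grid = random_grid(rng, 1, 1)
        grid.N[0, 0] = 1e-6
        D, B = np.array([0.01]), np.array([1e-3])
        j = eca_fluxes(D, B, grid)[0, 0]
        k2 = grid.k2_per_s * 3600
        K = grid.K[0, 0]
        expected = -k2 * grid.N[0, 0] * B[0] * (D[0] / K) / (
            1 + D[0] / K + grid.N[0, 0] * B[0] * 1e3 / K
        )
        assert j == pytest.approx(expected, rel=1e-12)

    def test_identical_consumers_split_flux_evenly(self, rng):
        g1 = random_grid(rng, 1, 1)
        g1.N[:] = 1e-6
        g2 = KineticsGrid(
            substrate_names=g1.substrate_names,
            consumer_ids=["c0", "c1"],
            K=np.repeat(g1.K, 2, axis=1),
            K0=np.repeat(g1.K0, 2, axis=1),
            Vmax=np.repeat(g1.Vmax, 2, axis=1),
            N=np.repeat(g1.N, 2, axis=1),
            k_plus=np.repeat(g1.k_plus, 2, axis=1),
            k2_per_s=g1.k2_per_s,
            porter_radius_m=g1.porter_radius_m,
        )
        D = np.array([0.05])
        whole = eca_fluxes(D, np.array([2e-3]), g1)[0, 0]
        halves = eca_fluxes(D, np.array([1e-3, 1e-3]), g2)[0]
        assert halves[0] == pytest.approx(halves[1], rel=1e-14)
        assert halves.sum() == pytest.approx(whole, rel=1e-12)

    def test_michaelis_menten_dilute_limit(self, rng):
        """ECA collapses to MM when NB/K is negligible."""
        grid = random_grid(rng, 1, 1)
        grid.N[0, 0] = 1e-9
        K = grid.K[0, 0]
        B = np.array([K * 1e-4 / (grid.N[0, 0] * 1e3) * 0.5])  # NB/K = 5e-5
        for D_val in (K * 0.1, K, K * 10):
            D = np.array([D_val])
            eca = eca_fluxes(D, B, grid)[0, 0]
            mm = -grid.k2_per_s * 3600 * grid.N[0, 0] * B[0] * D_val / (K + D_val)
            assert abs(eca - mm) / abs(mm) < 1e-3

    def test_conservation_and_sign(self, rng):
        grid = random_grid(rng, 4, 3)
        D = 10.0 ** rng.uniform(-5, -1, size=4)
        B = 10.0 ** rng.uniform(-6, -3, size=3)
        j = eca_fluxes(D, B, grid)
        assert np.all(j <= 0)
        # zero substrate or zero allocation kills the flux
        D2 = D.copy()
        D2[1] = 0.0
        assert np.all(eca_fluxes(D2, B, grid)[1] == 0.0)
        assert np.all(j[grid.N == 0] == 0.0)

    def test_flux_monotone_in_substrate_and_competitors(self, rng):
        grid = random_grid(rng, 2, 2)
        grid.N[:] = np.abs(grid.N) + 1e-6
        B = np.array([1e-3, 1e-3])
        j_lo = eca_fluxes(np.array([0.01, 0.01]), B, grid)
        j_hi = eca_fluxes(np.array([0.02, 0.01]), B, grid)
        assert j_hi[0, 0] <= j_lo[0, 0]  # more negative: more uptake
        # a bigger competitor reduces my share
        j_comp = eca_fluxes(np.array([0.01, 0.01]), np.array([1e-3, 5e-3]), grid)
        assert j_comp[0, 0] >= j_lo[0, 0]

    def test_negative_inputs_rejected(self, rng):
        grid = random_grid(rng, 1, 1)
        with pytest.raises(ValueError):
            eca_fluxes(np.array([-0.1]), np.array([1e-3]), grid)


@pytest.fixture(scope="module")
def curve(geometry):
    sub = build_substrate_properties("glucose", "sugar", "C6H12O6")
    rho = np.linspace(1e-5, 0.2, 50)
    return tradeoff_curve(sub, geometry, rho)


class TestTradeoffCurve:

    def test_vmax_and_K_increase_with_density(self, curve):
        assert (np.diff(curve["Vmax"]) > 0).all()
        assert (np.diff(curve["K_mM"]) > 0).all()

    def test_low_density_limits(self, geometry):
        sub = build_substrate_properties("glucose", "sugar", "C6H12O6")
        tiny = tradeoff_curve(sub, geometry, np.array([1e-12, 1e-11]))
        cfg = KineticsConfig()
        k_plus = 4 * np.pi * sub.diffusivity * cfg.porter_radius_m
        K0 = cfg.k2_per_s / (k_plus * AVOGADRO)
        assert tiny["Vmax"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert tiny["K_mM"].iloc[0] == pytest.approx(K0, rel=1e-3)

    def test_vmax_K_curve_concave(self, curve):
        v = curve["Vmax"].values
        k = curve["K_mM"].values
        slopes = np.diff(v) / np.diff(k)
        assert (np.diff(slopes) <= 1e-9 * np.abs(slopes[:-1])).all()

    def test_specific_affinity_saturates_early(self, curve):
        """Packing beyond ~1% of the surface buys <10% extra affinity."""
        sa = curve["specific_affinity"].values
        asymptote = sa[-1]
        at_001 = np.interp(0.01, curve["rho"].values, sa)
        assert at_001 >= 0.9 * asymptote
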