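"""DEB batch / mixed-medium integration: budgets, limits, trajectories."""

import copy

import numpy as np
import pytest

from rhizodeb import RunConfig, run_batch, run_community, run_mixed
from rhizodeb.closure import parameterize_consumer
from rhizodeb.genome import IsolateTraits
from rhizodeb.kinetics import build_kinetics_grid
from rhizodeb.simulate import GROWTH_RATE_FLOOR, deb_rhs
from rhizodeb.substrates import build_substrate_properties


def rhs_oracle(y, p, grid, a, y_ed):
    """Independent, scalar re-derivation of the single-consumer RHS.

    Follows the flux partitioning rules directly: ECA uptake into
    reserve at yield y_ED, mobilization k_E*E, growth equation for r,
    maintenance-priority starvation branch, density-dependent turnover.
    """
    I = len(a)
    D = np.maximum(y[:I], 0.0)
    E, V = max(y[I], 0.0), max(y[I + 1], 0.0)
    B = E + V
    k2 = grid.k2_per_s * 3600.0
    U = np.zeros(I)
    F_c = sum(D[l] * 1e3 / grid.K[l, 0] for l in range(I))
    for i in range(I):
        F_r = grid.N[i, 0] * B * 1e3 / grid.K[i, 0]
        U[i] = k2 * grid.N[i, 0] * B * (D[i] * 1e3 / grid.K[i, 0]) / (1 + F_r + F_c)
    dy = np.zeros_like(y)
    dy[:I] = -U
    if V <= 0:
        return dy
    m = E / V
    assim = float(np.dot(y_ed[:, 0], U))
    co2_assim = float(np.dot(a - y_ed[:, 0], U))
    gamma = p.gamma0 * B / p.B_ref
    r = (p.k_E * m - p.k_M) / (m + p.y_EV * (1 + p.z_X_rate))
    if r >= 0:
        dE = assim - (p.y_EV * (1 + p.z_X_rate) * r + p.k_M) * V - gamma * E
        dV = (r - gamma) * V
        dX = p.z_X_rate * r * V
        co2 = co2_assim + (p.y_EV - 1) * (1 + p.z_X_rate) * r * V + p.k_M * V
        bp = assim + r * V
    else:
        deficit = p.k_M - p.k_E * m
        dE = assim - p.k_E * E - gamma * E
        dV = -(p.starvation_overhead * deficit + gamma) * V
        dX = 0.0
        co2 = co2_assim + p.k_E * E + p.starvation_overhead * deficit * V
        bp = assim
    dy[I:] = (dE, dV, dX, co2, gamma * E + gamma * V, bp)
    return dy


@pytest.fixture(scope="module")
def glucose():
    return build_substrate_properties("glucose", "sugar", "C6H12O6")


@pytest.fixture(scope="module")
def panel_sugar(substrates):
    """A sugar that is actually part of the session substrate panel."""
    return next(s for s in substrates if s.chem_class.value == "sugar")


@pytest.fixture(scope="module")
def fast_consumer(substrates, run_config):
    tr = IsolateTraits(
        isolate_id="fast", genome_size_bp=5e6, rrn_copies=10, r_max=0.45,
        z_rho={c: 1 / 6 for c in ("sugar", "organic_acid", "amino_acid",
                                  "fatty_acid", "nucleotide", "auxin")},
        z_X=0.02,
    )
    return parameterize_consumer(tr, substrates, run_config)


class TestRhs:
    def test_matches_independent_transcription(self, consumers, substrates, run_config, rng):
        p = consumers[0]
        subs = substrates[:3]
        a = np.array([s.formula.a for s in subs], dtype=float)
        rho = np.array([[p.rho_porter[s.name]] for s in subs])
        grid = build_kinetics_grid(subs, [p.isolate_id], [p.geometry], rho,
                                   run_config.kinetics)
        y_ed = np.array([[p.y_ED[s.name]] for s in subs])
        for _ in range(25):
            y = 10.0 ** rng.uniform(-8, -2, size=3 + 6)
            got = deb_rhs(0.0, y, [p], grid, a, y_ed)
            want = rhs_oracle(y, p, grid, a, y_ed)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-30)

    def test_starvation_limit(self, consumers, substrates, run_config):
        """No substrate, no reserve: structure shrinks and respires."""
        p = consumers[0]
        subs = substrates[:1]
        a = np.array([float(subs[0].formula.a)])
        grid = build_kinetics_grid(subs, [p.isolate_id], [p.geometry],
                                   np.array([[p.rho_porter[subs[0].name]]]),
                                   run_config.kinetics)
        y_ed = np.array([[p.y_ED[subs[0].name]]])
        y = np.array([0.0, 0.0, 1e-4, 0.0, 0.0, 0.0, 0.0])
        dy = deb_rhs(0.0, y, [p], grid, a, y_ed)
        assert dy[2] < 0  # dV/dt
        assert dy[4] > 0  # dCO2/dt

    def test_saturating_growth_equation(self, consumers):
        """With maintenance and enzymes zeroed, r -> k_E m / (m + y_EV)."""
        p = copy.deepcopy(consumers[0])
        p.k_M = 0.0
        p.z_X_rate = 0.0
        from rhizodeb.simulate import _growth_rate

        for m in (0.1, 1.0, 10.0):
            assert _growth_rate(m, p) == pytest.approx(
                p.k_E * m / (m + p.y_EV), rel=1e-12
            )

    def test_growth_rate_never_exceeds_kE(self, consumers):
        from rhizodeb.simulate import _growth_rate

        p = consumers[0]
        rates = [_growth_rate(m, p) for m in 10.0 ** np.linspace(-3, 4, 40)]
        assert max(rates) < p.k_E


class TestBatch:
    def test_carbon_balance_closes(self, consumers, substrates, run_config):
        for p in consumers[:3]:
            res = run_batch(p, substrates[0], run_config)
            assert res.meta["carbon_balance_rel_error"] < 1e-6

    def test_fast_grower_sigmoidal_with_exhaustion(self, fast_consumer, panel_sugar, run_config):
        res = run_batch(fast_consumer, panel_sugar, run_config)
        assert "substrate_exhausted" in res.events
        assert res.events["substrate_exhausted"] < 500.0
        V = res.trajectory["V"].values
        assert V[-1] > V[0]
        # growth curve rises then saturates (sigmoidal structure pool)
        dV = np.diff(V)
        assert dV.max() > 0
        assert res.r_realized > GROWTH_RATE_FLOOR
        assert 0 < res.CUE < 1

    def test_realized_rate_below_kE(self, consumers, substrates, run_config):
        for p in consumers[:3]:
            res = run_batch(p, substrates[0], run_config)
            assert res.r_max_realized <= p.k_E

    def test_zero_inoculum_flagged(self, fast_consumer, panel_sugar):
        cfg = RunConfig()
        cfg.protocol.inoculum_cells_per_L = 0.0
        res = run_batch(fast_consumer, panel_sugar, cfg)
        assert res.degenerate
        assert np.isnan(res.CUE)

    def test_tolerance_convergence(self, fast_consumer, panel_sugar):
        """Halving integrator tolerances moves BP, BR, CUE by < 1e-4."""
        cfg1 = RunConfig()
        cfg2 = RunConfig()
        cfg2.integrator.rtol = cfg1.integrator.rtol / 2
        cfg2.integrator.atol = cfg1.integrator.atol / 2
        r1 = run_batch(fast_consumer, panel_sugar, cfg1)
        r2 = run_batch(fast_consumer, panel_sugar, cfg2)
        for attr in ("BP", "BR", "CUE"):
            a, b = getattr(r1, attr), getattr(r2, attr)
            assert abs(a - b) / abs(a) < 1e-4

    def test_closed_form_yield_partition(self, glucose, substrates, run_config):
        """Turnover and maintenance off, single substrate: the final carbon
        split follows the assimilation and growth yield chain."""
        tr = IsolateTraits(
            isolate_id="clean", genome_size_bp=5e6, rrn_copies=10, r_max=0.45,
            z_rho={"sugar": 1.0}, z_X=0.0,
        )
        cfg = RunConfig()
        cfg.turnover.gamma0_per_h = 0.0
        p = parameterize_consumer(tr, [glucose], cfg, kappa_M=0.0)
        assert p.k_M == 0.0 and p.z_X_rate == 0.0
        cfg.protocol.batch_hours = 3000.0
        res = run_batch(p, glucose, cfg)
        assert "substrate_exhausted" in res.events
        tail = res.trajectory.iloc[-1]
        head = res.trajectory.iloc[0]
        consumed_C = head[f"D:{glucose.name}"] - tail[f"D:{glucose.name}"]
        y_assim = p.y_ED[glucose.name] / glucose.formula.a  # C-mol per C-mol
        # all consumed carbon entered reserve at yield y_assim; reserve
        # (including the inoculum reserve) later became structure at yield
        # y_VE; CO2 is the complement
        E_prod = y_assim * consumed_C
        to_structure = head["E"] + E_prod - tail["E"]
        co2_expected = (1 - y_assim) * consumed_C + to_structure * (1 - p.y_VE)
        v_expected = to_structure * p.y_VE + head["V"]
        assert tail["V"] == pytest.approx(v_expected, rel=1e-6)
        assert tail["CO2"] == pytest.approx(co2_expected, rel=1e-6)


class TestMixed:
    def test_single_substrate_mixed_equals_batch(self, fast_consumer, panel_sugar):
        cfg = RunConfig()
        cfg.protocol.mixed_hours = cfg.protocol.batch_hours
        rb = run_batch(fast_consumer, panel_sugar, cfg)
        rm = run_mixed(fast_consumer, [panel_sugar], cfg)
        assert rm.BP == pytest.approx(rb.BP, rel=1e-10)
        assert rm.BR == pytest.approx(rb.BR, rel=1e-10)
        assert rm.CUE == pytest.approx(rb.CUE, rel=1e-10)

    def test_stops_at_first_depletion(self, fast_consumer, substrates, run_config):
        res = run_mixed(fast_consumer, substrates, run_config)
        assert res.events  # at least one depletion event
        assert res.meta["duration"] <= run_config.protocol.mixed_hours

    def test_ledger_matches_concentration_differences(self, fast_consumer, substrates, run_config):
        res = run_mixed(fast_consumer, substrates, run_config)
        led = res.uptake_ledger
        for i, s in enumerate(substrates):
            col = res.trajectory[f"D:{s.name}"]
            consumed_molC = col.iloc[0] - col.iloc[-1]
            row = led[led["substrate"] == s.name].iloc[0]
            assert row["consumed_molC"] == pytest.approx(consumed_molC, rel=1e-9, abs=1e-15)

    def test_disjoint_allocations_stay_disjoint(self, substrates, run_config):
        """Two consumers with non-overlapping transporter repertoires each
        deplete only their own substrate class."""
        sugar_only = IsolateTraits(
            isolate_id="sugars", genome_size_bp=4e6, rrn_copies=8, r_max=0.3,
            z_rho={"sugar": 1.0}, z_X=0.0,
        )
        acid_only = IsolateTraits(
            isolate_id="acids", genome_size_bp=4e6, rrn_copies=8, r_max=0.3,
            z_rho={"organic_acid": 1.0}, z_X=0.0,
        )
        cfg = RunConfig()
        ps = parameterize_consumer(sugar_only, substrates, cfg, mode="z_rho")
        pa = parameterize_consumer(acid_only, substrates, cfg, mode="z_rho")
        res = run_community([ps, pa], substrates, cfg)
        led = res.uptake_ledger
        for _, row in led.iterrows():
            cls = next(s.chem_class.value for s in substrates if s.name == row["substrate"])
            if cls not in ("sugar", "organic_acid"):
                assert row["consumed_fraction"] == pytest.approx(0.0, abs=1e-12)


class TestPopulationLevel:
    def test_bimodal_realized_growth_rates(self, consumers, substrates, run_config):
        """A population spanning fast and slow maximum growth rates on
        substrates differing in yield produces a bimodal realized-rate
        distribution (two well-separated mixture components)."""
        from sklearn.mixture import GaussianMixture

        rates = []
        for p in consumers:
            for s in substrates[:6]:
                res = run_batch(p, s, run_config)
                if res.r_realized > GROWTH_RATE_FLOOR:
                    rates.append(res.r_realized)
        x = np.log10(rates).reshape(-1, 1)
        gm = GaussianMixture(n_components=2, random_state=0, n_init=5).fit(x)
        mu = np.sort(gm.means_.ravel())
        assert mu[1] - mu[0] > 0.5  # modes separated by > 0.5 decades
        assert gm.weights_.min() > 0.15
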