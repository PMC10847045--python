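"""Batch and mixed-medium DEB simulations.

State pools (all mol C per litre unless noted): substrate concentrations
D_i (tracked per mol of substrate), reserve E, structure V, cumulative
extracellular enzyme X, cumulative respired CO2, cumulative necromass
from density-dependent turnover, and cumulative gross biomass production
BP. One ODE system covers a single consumer on one substrate (batch), a
single consumer on a substrate panel (mixed medium) and multiple
consumers competing for shared substrates (community mode); uptake is
always partitioned by the ECA.

Flux bookkeeping per C-mol of structure, with reserve density m = E/V:

    r = (k_E m - k_M) / (m + y_EV (1 + z_X))        growth allocation
    assimilation   y_ED,i * U_i  ->  E              (overhead respired)
    growth         y_EV r V  from E -> r V to V     (overhead respired)
    enzymes        z_X y_EV r V from E -> z_X r V   (overhead respired)
    maintenance    k_M V from E -> CO2; paid from V at an overhead
                   premium when reserve mobilization cannot cover it
    turnover       gamma_E E, gamma_V V -> necromass, with
                   gamma = gamma0 * B_tot / B_ref (density-dependent)

Uptake scales with total biomass E + V (cells per litre times sites per
cell). Carbon is conserved exactly: substrate + biomass + enzymes + CO2
+ necromass is constant along trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .closure import ConsumerParameters
from .config import RunConfig
from .kinetics import KineticsGrid, build_kinetics_grid, eca_fluxes
from .substrates import SubstrateProperties

__all__ = [
    "SimulationResult",
    "IntegrationError",
    "run_batch",
    "run_mixed",
    "run_community",
    "deb_rhs",
]

M_C = 12.011
#: growth-phase floor for the realized-rate statistics (1/h)
GROWTH_RATE_FLOOR = 1.0e-4


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last valid state."""


@dataclass
class SimulationResult:
    """Trajectories plus cumulative carbon budget and phenotype summaries."""

    trajectory: pd.DataFrame
    substrate_names: list[str]
    consumer_ids: list[str]
    BP: float
    BR: float
    CUE: float
    r_realized: float
    r_max_realized: float
    latency: float
    events: dict[str, float]
    uptake_ledger: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.CUE)


def _growth_rate(m: float, p: ConsumerParameters) -> float:
    return (p.k_E * m - p.k_M) / (m + p.y_EV * (1.0 + p.z_X_rate))


def deb_rhs(
    t: float,
    y: np.ndarray,
    consumers: list[ConsumerParameters],
    grid: KineticsGrid,
    substrate_cmol: np.ndarray,
    y_ED: np.ndarray,
) -> np.ndarray:
    """Time derivative of the full state vector.

    Layout: [D_1..D_I, then per consumer j: E, V, X, CO2, NEC, BP].
    ``y_ED[i, j]`` is the per-pair assimilation yield (C-mol reserve per
    mol substrate).
    """
    I = len(substrate_cmol)
    J = len(consumers)
    D = np.maximum(y[:I], 0.0)
    dy = np.zeros_like(y)

    states = y[I:].reshape(J, 6)
    E = np.maximum(states[:, 0], 0.0)
    V = np.maximum(states[:, 1], 0.0)
    B_tot = E + V

    U = -eca_fluxes(D * 1.0e3, B_tot, grid)  # mol substrate / L / h, >= 0
    dy[:I] = -U.sum(axis=1)

    for j, p in enumerate(consumers):
        if V[j] <= 0.0:
            continue
        m = E[j] / V[j]
        assim = float(y_ED[:, j] @ U[:, j])  # C-mol to reserve
        co2_assim = float((substrate_cmol - y_ED[:, j]) @ U[:, j])
        gamma = p.gamma0 * B_tot.sum() / p.B_ref
        gamma_E = p.gamma_E_multiplier * gamma
        r = _growth_rate(m, p)
        if r >= 0.0:
            dE = assim - (p.y_EV * (1.0 + p.z_X_rate) * r + p.k_M) * V[j] - gamma_E * E[j]
            dV = r * V[j] - gamma * V[j]
            dX = p.z_X_rate * r * V[j]
            co2 = (
                co2_assim
                + (p.y_EV - 1.0) * (1.0 + p.z_X_rate) * r * V[j]
                + p.k_M * V[j]
            )
            bp = assim + r * V[j]
        else:
            # starvation: reserve mobilization cannot cover maintenance;
            # the deficit is paid from structure at an overhead premium
            deficit = p.k_M - p.k_E * m
            dE = assim - p.k_E * E[j] - gamma_E * E[j]
            dV = -p.starvation_overhead * deficit * V[j] - gamma * V[j]
            dX = 0.0
            co2 = co2_assim + p.k_E * E[j] + p.starvation_overhead * deficit * V[j]
            bp = assim
        nec = gamma_E * E[j] + gamma * V[j]
        dy[I + 6 * j : I + 6 * j + 6] = (dE, dV, dX, co2, nec, bp)

    if not np.all(np.isfinite(dy)):
        raise IntegrationError(f"non-finite derivative at t={t:.4g}; state={y!r}")
    return dy


def _simulate(
    consumers: list[ConsumerParameters],
    substrates: list[SubstrateProperties],
    D0_molC: np.ndarray,
    duration: float,
    config: RunConfig,
    stop_on_any_depletion: bool,
) -> SimulationResult:
    cfg = config
    I, J = len(substrates), len(consumers)
    a = np.array([s.formula.a for s in substrates], dtype=float)

    rho = np.array(
        [[p.rho_porter.get(s.name, 0.0) for p in consumers] for s in substrates]
    )
    grid = build_kinetics_grid(
        substrates, [p.isolate_id for p in consumers],
        [p.geometry for p in consumers], rho, cfg.kinetics,
    )
    y_ed = np.array([[p.y_ED.get(s.name, 0.0) for p in consumers] for s in substrates])

    y0 = np.zeros(I + 6 * J)
    y0[:I] = D0_molC / a  # mol substrate / L
    for j, p in enumerate(consumers):
        b0 = cfg.protocol.inoculum_cells_per_L / p.lambda_B
        y0[I + 6 * j] = cfg.protocol.reserve_fraction * b0
        y0[I + 6 * j + 1] = (1.0 - cfg.protocol.reserve_fraction) * b0

    threshold = cfg.protocol.exhaustion_molC_L
    if stop_on_any_depletion:
        events = [
            (lambda i: (lambda t, y, *args: y[i] * a[i] - threshold))(i)
            for i in range(I)
        ]
    else:
        events = [lambda t, y, *args: float(y[:I] @ a) - threshold]
    for ev in events:
        ev.terminal = True
        ev.direction = -1

    args = (consumers, grid, a, y_ed)
    t_eval = np.linspace(0.0, duration, cfg.protocol.n_timepoints)
    sol = solve_ivp(
        deb_rhs,
        (0.0, duration),
        y0,
        args=args,
        method=cfg.integrator.method,
        rtol=cfg.integrator.rtol,
        atol=cfg.integrator.atol,
        t_eval=t_eval,
        events=events,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}; last state {sol.y[:, -1]!r}")

    t = sol.t
    Y = sol.y
    # append the event state so trajectories end exactly at depletion
    if sol.status == 1 and sol.t_events:
        for te, ye in zip(sol.t_events, sol.y_events):
            if len(te):
                t = np.append(t, te[0])
                Y = np.column_stack([Y, ye[0]])
        order = np.argsort(t)
        t, Y = t[order], Y[:, order]
        keep = np.concatenate([[True], np.diff(t) > 0])
        t, Y = t[keep], Y[:, keep]

    columns: dict[str, np.ndarray] = {"t": t}
    for i, s in enumerate(substrates):
        columns[f"D:{s.name}"] = Y[i] * a[i]  # report as mol C / L
    pool_names = ("E", "V", "X", "CO2", "necromass", "BP")
    for j, p in enumerate(consumers):
        suffix = "" if J == 1 else f":{p.isolate_id}"
        for k, name in enumerate(pool_names):
            columns[f"{name}{suffix}"] = Y[I + 6 * j + k]
    traj = pd.DataFrame(columns)

    # phenotype summaries (first consumer; community callers aggregate)
    E_t = Y[I]
    V_t = Y[I + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        m_t = np.where(V_t > 0, E_t / np.maximum(V_t, 1e-300), 0.0)
    p0 = consumers[0]
    r_t = np.array([_growth_rate(m, p0) for m in m_t])
    traj["r"] = r_t if J == 1 else np.nan

    BP = float(sum(Y[I + 6 * j + 5, -1] for j in range(J)))
    BR = float(sum(Y[I + 6 * j + 3, -1] for j in range(J)))
    CUE = BP / (BP + BR) if (BP + BR) > 0 else float("nan")

    growing = r_t > GROWTH_RATE_FLOOR
    r_realized = float(np.median(r_t[growing])) if growing.any() else 0.0
    r_max_realized = float(r_t.max()) if len(r_t) else 0.0

    # latency: timing of peak growth mineralization (max dCO2/dt)
    co2_total = np.sum([Y[I + 6 * j + 3] for j in range(J)], axis=0)
    dco2 = np.gradient(co2_total, t) if len(t) > 2 else np.zeros_like(t)
    latency = float(t[int(np.argmax(dco2))]) if len(t) else float("nan")

    event_times = {}
    if sol.status == 1:
        for i_ev, te in enumerate(sol.t_events):
            if len(te):
                name = substrates[i_ev].name if stop_on_any_depletion else "substrate_exhausted"
                event_times[name] = float(te[0])

    consumed = D0_molC / a - Y[:I, -1]
    ledger = pd.DataFrame(
        {
            "substrate": [s.name for s in substrates],
            "initial_mol": D0_molC / a,
            "consumed_mol": consumed,
            "consumed_fraction": np.where(D0_molC > 0, consumed / (D0_molC / a), 0.0),
            "consumed_molC": consumed * a,
        }
    )

    balance0 = float(D0_molC.sum() + sum(y0[I + 6 * j] + y0[I + 6 * j + 1] for j in range(J)))
    balance_end = float(
        (Y[:I, -1] * a).sum()
        + sum(Y[I + 6 * j + k, -1] for j in range(J) for k in range(5))
    )
    meta = {
        "carbon_balance_rel_error": abs(balance_end - balance0) / balance0 if balance0 else 0.0,
        "config_hash": cfg.config_hash,
        "duration": float(t[-1]) if len(t) else 0.0,
    }

    return SimulationResult(
        trajectory=traj,
        substrate_names=[s.name for s in substrates],
        consumer_ids=[p.isolate_id for p in consumers],
        BP=BP,
        BR=BR,
        CUE=CUE,
        r_realized=r_realized,
        r_max_realized=r_max_realized,
        latency=latency,
        events=event_times,
        uptake_ledger=ledger,
        meta=meta,
    )


def run_batch(
    consumer: ConsumerParameters,
    substrate: SubstrateProperties,
    config: RunConfig | None = None,
) -> SimulationResult:
    """Single-substrate batch culture.

    The medium carries the full protocol substrate concentration
    (default 125 mg C/L) of one metabolite; the inoculum is split into
    reserve and structure per protocol; integration stops at substrate
    exhaustion or the protocol horizon.
    """
    cfg = config or RunConfig()
    if cfg.protocol.inoculum_cells_per_L <= 0:
        return _degenerate_result(substrate, consumer, cfg)
    D0 = np.array([cfg.protocol.substrate_mgC_L * 1.0e-3 / M_C])
    return _simulate([consumer], [substrate], D0, cfg.protocol.batch_hours, cfg, False)


def run_mixed(
    consumer: ConsumerParameters,
    substrates: list[SubstrateProperties],
    config: RunConfig | None = None,
) -> SimulationResult:
    """Mixed medium: the batch carbon budget split evenly across substrates.

    Runs until the first metabolite is depleted or the mixed-protocol
    horizon, and reports the per-substrate uptake ledger.
    """
    cfg = config or RunConfig()
    n = len(substrates)
    D0 = np.full(n, cfg.protocol.substrate_mgC_L * 1.0e-3 / M_C / n)
    return _simulate([consumer], substrates, D0, cfg.protocol.mixed_hours, cfg, n > 1)


def run_community(
    consumers: list[ConsumerParameters],
    substrates: list[SubstrateProperties],
    config: RunConfig | None = None,
) -> SimulationResult:
    """All consumers compete for the shared mixed medium via the ECA."""
    cfg = config or RunConfig()
    n = len(substrates)
    D0 = np.full(n, cfg.protocol.substrate_mgC_L * 1.0e-3 / M_C / n)
    return _simulate(consumers, substrates, D0, cfg.protocol.mixed_hours, cfg, n > 1)


def _degenerate_result(
    substrate: SubstrateProperties, consumer: ConsumerParameters, cfg: RunConfig
) -> SimulationResult:
    """Zero inoculum: flat trajectories and NaN-flagged phenotypes."""
    traj = pd.DataFrame(
        {
            "t": [0.0, cfg.protocol.batch_hours],
            f"D:{substrate.name}": [cfg.protocol.substrate_mgC_L * 1e-3 / M_C] * 2,
            "E": [0.0, 0.0],
            "V": [0.0, 0.0],
        }
    )
    return SimulationResult(
        trajectory=traj,
        substrate_names=[substrate.name],
        consumer_ids=[consumer.isolate_id],
        BP=0.0,
        BR=0.0,
        CUE=float("nan"),
        r_realized=float("nan"),
        r_max_realized=float("nan"),
        latency=float("nan"),
        events={},
        meta={"degenerate": True},
    )
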