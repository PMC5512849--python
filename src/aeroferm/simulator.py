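"""Batch-culture ODE assembly and integration.

The dynamic state holds extracellular concentrations (g/l), biomass (gDW/l),
intracellular metabolites (mmol/gDW), the reduced/oxidized halves of the
conserved NADH/NAD+ and Q/QH2 pools, and two bookkeeping integrals (cumulative
CO2 and biomass-drain carbon, mmolC/l) used by the carbon balance.

Mass balances:

* intracellular  dC/dt = sum_j s_ij v_j - mu*C - mu*gamma_i*C/(C+K_drain)
  (growth dilution plus biomass precursor drain; the drain saturates at
  near-zero pools so it cannot push a concentration negative)
* extracellular  dP/dt = w_P * (sum_j s_Pj v_j) * X   (w_P: g/mmol)
* biomass        dX/dt = mu*X
* pool halves exchange only within their conserved pair, so pool totals are
  invariant along any trajectory.

Dissolved oxygen is a controlled boundary condition (a % of air-saturation
setpoint, constant or piecewise-constant in time); integration restarts at
each DO switching time so the discontinuity is handled exactly.  Glucose
depletion is an integration event located by the solver's root finder; the
stiff BDF method is used throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import CompiledModel
from .network import MetabolicNetwork, load_network
from .parameters import ParameterSet, load_parameters
from .physiology import ATP_COEFFS, CO2_COEFFS, NADH_COEFFS, NADPH_COEFFS, OP_COEFFS
from .regulation import classify_condition, do_percent_to_O2, fnr_activity
from .strains import WT, StrainSpec, apply_knockout

__all__ = [
    "DOSchedule",
    "CultivationProtocol",
    "Trajectory",
    "BatchSystem",
    "simulate_batch",
    "products_at_depletion",
    "PRODUCT_SPECIES",
]

PRODUCT_SPECIES = ("ACE", "LAC", "FOR", "ETH", "SUC")

#: default initial intracellular state (mmol/gDW); pools start mostly oxidized
DEFAULT_INTRACELLULAR = 0.05
DEFAULT_NADH_FRACTION = 0.1
DEFAULT_QH2_FRACTION = 0.1


@dataclass(frozen=True)
class DOSchedule:
    """Piecewise-constant DO setpoint: ((t_start, DO_percent), ...)."""

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if not self.segments or self.segments[0][0] != 0.0:
            raise ValueError("DO schedule must start at t = 0")
        starts = [s[0] for s in self.segments]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("DO schedule segment starts must be strictly increasing")
        for _, do in self.segments:
            if not 0 <= do <= 100:
                raise ValueError(f"DO percent outside [0, 100]: {do}")

    @classmethod
    def constant(cls, do_percent: float) -> "DOSchedule":
        return cls(((0.0, float(do_percent)),))

    @classmethod
    def dual_phase(cls, do_first: float, do_second: float, t_switch: float) -> "DOSchedule":
        if t_switch < 0:
            raise ValueError("switching time must be >= 0")
        if t_switch == 0.0:
            return cls.constant(do_second)
        return cls(((0.0, float(do_first)), (float(t_switch), float(do_second))))

    def do_at(self, t: float) -> float:
        do = self.segments[0][1]
        for t_start, value in self.segments:
            if t >= t_start:
                do = value
        return do


@dataclass(frozen=True)
class CultivationProtocol:
    glucose_0: float = 10.0  # g/l
    biomass_0: float = 0.1  # gDW/l
    do_schedule: DOSchedule = field(default_factory=lambda: DOSchedule.constant(40.0))
    strain: StrainSpec = WT
    glc_threshold: float = 0.01  # g/l, depletion event
    t_max: float = 80.0  # h
    initial_intracellular: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.glucose_0 < 0 or self.biomass_0 < 0:
            raise ValueError("initial concentrations must be non-negative")
        if self.glc_threshold <= 0 or self.t_max <= 0:
            raise ValueError("stop thresholds must be positive")


class BatchSystem:
    """Compiled ODE right-hand side for one (network, params) pair."""

    def __init__(self, network: MetabolicNetwork, params: ParameterSet):
        missing = [s for s in network.parameter_symbols() if s and s not in params]
        if missing:
            from .parameters import ParameterValidationError

            raise ParameterValidationError([f"missing parameter: {m}" for m in sorted(missing)])
        self.network = network
        self.params = params
        self.compiled = CompiledModel(network, params)
        comp = self.compiled

        self.ex_ids = network.species_in("extracellular")
        self.cyt_ids = network.species_in("cytoplasm")
        self.pool_first = [p.members[0] for p in network.conserved_pools]
        self.pool_second = [p.members[1] for p in network.conserved_pools]
        self.pool_totals = np.array([params[p.total] for p in network.conserved_pools])
        self.state_ids = self.ex_ids + ["X"] + self.cyt_ids + self.pool_first

        self.ex_pos = np.array([comp.species_index[s] for s in self.ex_ids], dtype=int)
        self.cyt_pos = np.array([comp.species_index[s] for s in self.cyt_ids], dtype=int)
        self.pf_pos = np.array([comp.species_index[s] for s in self.pool_first], dtype=int)
        self.ps_pos = np.array([comp.species_index[s] for s in self.pool_second], dtype=int)
        self.o2_pos = comp.species_index.get("O2")
        self.q_state = self.pool_first.index("Q") if "Q" in self.pool_first else None

        self.n_ex = len(self.ex_ids)
        self.n_cyt = len(self.cyt_ids)
        self.n_pool = len(self.pool_first)
        self.x_slot = self.n_ex
        self.n_state = self.n_ex + 1 + self.n_cyt + self.n_pool + 2  # + CO2_cum, BIOC_cum

        self.S_ex = comp.S[self.ex_pos, :]
        self.S_cyt = comp.S[self.cyt_pos, :]
        self.S_pool = comp.S[self.pf_pos, :]
        self.w_ex = np.array(
            [(network.species[s].mw or 0.0) / 1000.0 for s in self.ex_ids]
        )  # g per mmol

        def coeff_vector(coeffs: Mapping[str, float]) -> np.ndarray:
            vec = np.zeros(len(comp.reaction_ids))
            for name, c in coeffs.items():
                if name in comp.reaction_index:
                    vec[comp.reaction_index[name]] = c
            return vec

        self.atp_vec = coeff_vector(ATP_COEFFS)
        self.op_vec = coeff_vector(OP_COEFFS)
        self.co2_vec = coeff_vector(CO2_COEFFS)
        self.nadph_vec = coeff_vector(NADPH_COEFFS)
        self.nadh_vec = coeff_vector(NADH_COEFFS)

        # biomass precursor drain, normalized to the biomass carbon content
        gamma = np.zeros(self.n_cyt)
        n_carbon = np.array([network.species[s].carbon for s in self.cyt_ids], dtype=float)
        for sp, demand in network.biomass_drain.items():
            gamma[self.cyt_ids.index(sp)] = demand
        carbon_total = float(gamma @ n_carbon)
        if carbon_total > 0:
            gamma *= (params["X_carbon"] * 1000.0 / 12.011) / carbon_total
        self.gamma = gamma
        self.gamma_carbon = gamma * n_carbon
        self.drain_K = params["drain_K"]

        self.k_atp = params["k_ATP"]
        self.K_arca = params["K_ArcA"]
        self.m_hill = -params["n_hill"]
        self.arca_scale = params.tf_scale.get("ArcA", 1.0)
        self.glc_slot = self.ex_ids.index("GLC") if "GLC" in self.ex_ids else None

    # -- state helpers ----------------------------------------------------
    def initial_state(self, protocol: CultivationProtocol) -> np.ndarray:
        y0 = np.zeros(self.n_state)
        overrides = dict(protocol.initial_intracellular or {})
        for i, sp in enumerate(self.ex_ids):
            y0[i] = protocol.glucose_0 if sp == "GLC" else overrides.pop(sp, 0.0)
        y0[self.x_slot] = protocol.biomass_0
        for i, sp in enumerate(self.cyt_ids):
            y0[self.n_ex + 1 + i] = overrides.pop(sp, DEFAULT_INTRACELLULAR)
        for i, (first, total) in enumerate(zip(self.pool_first, self.pool_totals)):
            default = (
                DEFAULT_NADH_FRACTION * total
                if first == "NADH"
                else (1.0 - DEFAULT_QH2_FRACTION) * total
            )
            y0[self.n_ex + 1 + self.n_cyt + i] = overrides.pop(first, default)
        if overrides:
            raise ValueError(f"initial_intracellular names unknown species: {sorted(overrides)}")
        return y0

    def concentrations(self, y: np.ndarray, o2: float) -> np.ndarray:
        conc = np.zeros(len(self.compiled.species_ids))
        conc[self.ex_pos] = y[: self.n_ex]
        conc[self.cyt_pos] = y[self.n_ex + 1 : self.n_ex + 1 + self.n_cyt]
        pools = y[self.n_ex + 1 + self.n_cyt : self.n_ex + 1 + self.n_cyt + self.n_pool]
        conc[self.pf_pos] = pools
        conc[self.ps_pos] = self.pool_totals - pools
        if self.o2_pos is not None:
            conc[self.o2_pos] = o2
        return conc

    def tf_arca(self, q: float) -> float:
        q = max(q, 0.0)
        km = self.K_arca**self.m_hill
        return self.arca_scale * km / (km + q**self.m_hill)

    def rhs(self, t: float, y: np.ndarray, o2: float, tf_fnr: float) -> np.ndarray:
        conc = self.concentrations(y, o2)
        q = conc[self.pf_pos[self.q_state]] if self.q_state is not None else 0.0
        v = self.compiled.fluxes(conc, tf_fnr, self.tf_arca(q))
        if not np.all(np.isfinite(v)):
            bad = [self.compiled.reaction_ids[i] for i in np.where(~np.isfinite(v))[0]]
            raise FloatingPointError(f"non-finite flux in reactions {bad} at t={t:.4f}")
        mu = max(self.k_atp * float(self.atp_vec @ v), 0.0)
        X = y[self.x_slot]
        C = y[self.n_ex + 1 : self.n_ex + 1 + self.n_cyt]
        sat = np.maximum(C, 0.0) / (np.abs(C) + self.drain_K)
        dy = np.empty_like(y)
        dy[: self.n_ex] = (self.S_ex @ v) * self.w_ex * X
        dy[self.x_slot] = mu * X
        dy[self.n_ex + 1 : self.n_ex + 1 + self.n_cyt] = (
            self.S_cyt @ v - mu * C - mu * self.gamma * sat
        )
        dy[self.n_ex + 1 + self.n_cyt : self.n_ex + 1 + self.n_cyt + self.n_pool] = self.S_pool @ v
        dy[-2] = float(self.co2_vec @ v) * X
        dy[-1] = mu * X * float(self.gamma_carbon @ sat)
        return dy


@dataclass
class Trajectory:
    """Dense simulation record: states, fluxes, physiology and TF activities."""

    frame: pd.DataFrame
    t_dep: float | None
    depleted: bool
    protocol: CultivationProtocol
    network: MetabolicNetwork
    params: ParameterSet
    system: BatchSystem
    solver: dict = field(default_factory=dict)

    @property
    def final_state(self) -> pd.Series:
        return self.frame.iloc[-1]

    def manifest(self) -> dict:
        proto = self.protocol
        return {
            "protocol": {
                "glucose_0": proto.glucose_0,
                "biomass_0": proto.biomass_0,
                "do_schedule": [list(seg) for seg in proto.do_schedule.segments],
                "strain": proto.strain.name,
                "knockouts": sorted(proto.strain.knockouts),
                "glc_threshold": proto.glc_threshold,
                "t_max": proto.t_max,
            },
            "parameter_digest": self.params.digest(),
            "solver": self.solver,
            "t_dep": self.t_dep,
            "depleted": self.depleted,
        }

    def write(self, directory) -> None:
        """Tidy CSV of the trajectory plus a JSON run manifest."""
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(directory / "trajectory.csv", index=False)
        with open(directory / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


def _annotate(
    system: BatchSystem,
    protocol: CultivationProtocol,
    times: np.ndarray,
    states: np.ndarray,
    params: ParameterSet,
) -> pd.DataFrame:
    comp = system.compiled
    frame = pd.DataFrame(states.T, columns=system.state_ids + ["CO2_cum", "BIOC_cum"])
    frame.insert(0, "time", times)
    for i, (first, second) in enumerate(zip(system.pool_first, system.pool_second)):
        frame[second] = system.pool_totals[i] - frame[first]
    do = np.array([protocol.do_schedule.do_at(t) for t in times])
    frame["DO_percent"] = do
    frame["O2"] = do_percent_to_O2(do, params)
    frame["TF_Fnr"] = fnr_activity(frame["O2"].to_numpy(), params)
    frame["TF_ArcA"] = np.array([system.tf_arca(q) for q in frame["Q"]]) if "Q" in frame else 0.0
    flux_rows = np.empty((len(times), len(comp.reaction_ids)))
    for k in range(len(times)):
        conc = system.concentrations(states[:, k], frame["O2"].iat[k])
        flux_rows[k] = comp.fluxes(conc, frame["TF_Fnr"].iat[k], frame["TF_ArcA"].iat[k])
    for j, rid in enumerate(comp.reaction_ids):
        frame[f"v_{rid}"] = flux_rows[:, j]
    frame["v_ATP"] = flux_rows @ system.atp_vec
    frame["OP"] = flux_rows @ system.op_vec
    frame["mu"] = np.maximum(params["k_ATP"] * frame["v_ATP"], 0.0)
    frame["v_CO2"] = flux_rows @ system.co2_vec
    frame["v_NADPH"] = flux_rows @ system.nadph_vec
    frame["v_NADH"] = flux_rows @ system.nadh_vec
    if "Cyo" in comp.reaction_index:
        frame["qOUR"] = 0.5 * (
            flux_rows[:, comp.reaction_index["Cyo"]] + flux_rows[:, comp.reaction_index["Cyd"]]
        )
    if "NADH" in frame and "NAD" in frame:
        frame["NADH_ratio"] = frame["NADH"] / frame["NAD"]
    return frame


def simulate_batch(
    protocol: CultivationProtocol,
    network: MetabolicNetwork | None = None,
    params: ParameterSet | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-10,
    clamp_extracellular: bool = False,
    system: BatchSystem | None = None,
) -> Trajectory:
    """Integrate a batch culture until glucose depletion or ``t_max``.

    ``clamp_extracellular`` freezes the medium and biomass (used for
    steady-state analyses on fixture networks).  ``system`` may carry a
    pre-built :class:`BatchSystem` for the strain-applied model; otherwise it
    is constructed here (with the protocol's knockouts applied).
    """
    if system is None:
        network = network if network is not None else load_network()
        params = params if params is not None else load_parameters()
        network, params = apply_knockout(network, params, protocol.strain)
        system = BatchSystem(network, params)
    else:
        network, params = system.network, system.params

    y0 = system.initial_state(protocol)
    glc_idx = system.glc_slot
    times = [np.array([0.0])]
    states = [y0[:, None]]
    t_dep: float | None = None
    depleted = False
    nfev = 0

    if glc_idx is not None and protocol.glucose_0 <= protocol.glc_threshold:
        t_dep, depleted = 0.0, True
    else:
        boundaries = [seg[0] for seg in protocol.do_schedule.segments if seg[0] > 0]
        breakpoints = sorted(t for t in boundaries if t < protocol.t_max) + [protocol.t_max]
        t_start, y = 0.0, y0
        for t_end in breakpoints:
            do = protocol.do_schedule.do_at(t_start)
            o2 = do_percent_to_O2(do, params)
            tf_fnr = fnr_activity(o2, params)
            events = None
            if glc_idx is not None and not clamp_extracellular:

                def depletion(t, yy, *args):
                    return yy[glc_idx] - protocol.glc_threshold

                depletion.terminal = True
                depletion.direction = -1
                events = [depletion]
            if clamp_extracellular:

                def rhs(t, yy, o2=o2, tf=tf_fnr):
                    dy = system.rhs(t, yy, o2, tf)
                    dy[: system.n_ex] = 0.0
                    dy[system.x_slot] = 0.0
                    return dy

            else:

                def rhs(t, yy, o2=o2, tf=tf_fnr):
                    return system.rhs(t, yy, o2, tf)

            sol = solve_ivp(
                rhs,
                (t_start, t_end),
                y,
                method="BDF",
                rtol=rtol,
                atol=atol,
                events=events,
                dense_output=False,
            )
            nfev += sol.nfev
            if not sol.success:
                raise RuntimeError(
                    f"integrator failed at t={sol.t[-1]:.4f} h: {sol.message}; "
                    f"last state: {dict(zip(system.state_ids, sol.y[: len(system.state_ids), -1]))}"
                )
            times.append(sol.t[1:])
            states.append(sol.y[:, 1:])
            if sol.t_events and len(sol.t_events[0]):
                t_dep = float(sol.t_events[0][0])
                depleted = True
                break
            t_start, y = sol.t[-1], sol.y[:, -1]

    t_all = np.concatenate(times)
    y_all = np.concatenate(states, axis=1)
    # guard against integrator-induced negativity (concentration states only;
    # the cumulative CO2 integral may legitimately run negative under net fixation)
    conc_rows = y_all[: len(system.state_ids)]
    state_min = float(conc_rows.min())
    if state_min < -1e-9:
        worst = system.state_ids[int(np.unravel_index(conc_rows.argmin(), conc_rows.shape)[0])]
        raise RuntimeError(f"negative concentration beyond tolerance: {worst} = {state_min:g}")
    frame = _annotate(system, protocol, t_all, y_all, params)
    return Trajectory(
        frame=frame,
        t_dep=t_dep,
        depleted=depleted,
        protocol=protocol,
        network=network,
        params=params,
        system=system,
        solver={"method": "BDF", "rtol": rtol, "atol": atol, "nfev": nfev},
    )


def products_at_depletion(trajectory: Trajectory) -> pd.Series:
    """Fermentation-product concentrations (g/l) at the glucose-depletion event."""
    if not trajectory.depleted:
        raise ValueError("trajectory did not reach glucose depletion")
    last = trajectory.final_state
    out = last[list(PRODUCT_SPECIES)].astype(float)
    out.name = "g_per_l"
    return out


def condition_of(trajectory: Trajectory) -> str:
    """Aeration category of the final DO setpoint."""
    return classify_condition(trajectory.final_state["DO_percent"])
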