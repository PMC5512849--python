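"""In-silico cultivation experiments: DO sweeps and dual-phase design.

A DO sweep runs one batch culture per dissolved-oxygen setpoint and collects
the product spectrum at glucose depletion together with time-averaged
regulatory and respiratory read-outs.  The dual-phase scan searches the
aerobic-to-micro-aerobic switching time that maximizes lactate productivity
for a pfl-knockout producer strain: a longer aerobic phase builds catalyst
(biomass) faster but burns glucose to biomass/CO2/acetate, so yield falls as
productivity first rises then falls — an interior optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .network import MetabolicNetwork, load_network
from .parameters import ParameterSet, load_parameters
from .regulation import classify_condition
from .simulator import (
    BatchSystem,
    CultivationProtocol,
    DOSchedule,
    Trajectory,
    products_at_depletion,
    simulate_batch,
)
from .strains import StrainSpec, apply_knockout

__all__ = [
    "SweepResult",
    "DualPhaseResult",
    "DEFAULT_DO_GRID",
    "do_sweep",
    "find_peak",
    "dual_phase_scan",
]

#: dense below 20% where the regulatory transitions live, coarse above
DEFAULT_DO_GRID = tuple(range(0, 21)) + (25, 30, 35, 40)

_PRODUCT_COLS = {"ACE": "acetate", "LAC": "lactate", "FOR": "formate", "ETH": "ethanol", "SUC": "succinate"}
_FLUX_COLS = ("Pfl", "PDH", "LDH", "ADH", "Frd", "Cyo", "Cyd")


@dataclass
class SweepResult:
    strain: StrainSpec
    table: pd.DataFrame  # one row per DO level
    trajectories: dict[float, Trajectory] = field(default_factory=dict, repr=False)

    def column(self, name: str) -> pd.Series:
        return self.table.set_index("DO_percent")[name]


@dataclass
class DualPhaseResult:
    strain: StrainSpec
    do_aerobic: float
    do_microaerobic: float
    table: pd.DataFrame  # one row per switching time

    @property
    def optimal(self) -> pd.Series:
        ok = self.table[self.table["depleted"]]
        return ok.loc[ok["productivity"].idxmax()]


def _mean_over_time(traj: Trajectory, column: str) -> float:
    frame = traj.frame
    t = frame["time"].to_numpy()
    if len(t) < 2:
        return float(frame[column].iloc[-1])
    return float(np.trapezoid(frame[column].to_numpy(), t) / (t[-1] - t[0]))


def do_sweep(
    strain: StrainSpec | str,
    do_grid: Sequence[float] = DEFAULT_DO_GRID,
    protocol_base: CultivationProtocol | None = None,
    network: MetabolicNetwork | None = None,
    params: ParameterSet | None = None,
    keep_trajectories: bool = False,
) -> SweepResult:
    """One batch simulation per DO level; summary row per grid point.

    Non-depleted runs are flagged in the ``depleted`` column, never dropped.
    """
    if isinstance(strain, str):
        strain = StrainSpec.from_name(strain)
    do_grid = sorted(float(d) for d in do_grid)
    if len(set(do_grid)) != len(do_grid):
        raise ValueError("DO grid values must be distinct")
    base = protocol_base or CultivationProtocol()
    network = network if network is not None else load_network()
    params = params if params is not None else load_parameters()
    net_s, par_s = apply_knockout(network, params, strain)
    system = BatchSystem(net_s, par_s)

    rows = []
    trajectories: dict[float, Trajectory] = {}
    for do in do_grid:
        protocol = CultivationProtocol(
            glucose_0=base.glucose_0,
            biomass_0=base.biomass_0,
            do_schedule=DOSchedule.constant(do),
            strain=strain,
            glc_threshold=base.glc_threshold,
            t_max=base.t_max,
            initial_intracellular=base.initial_intracellular,
        )
        traj = simulate_batch(protocol, system=system)
        row: dict[str, float | str | bool] = {
            "DO_percent": do,
            "condition": classify_condition(do),
            "depleted": traj.depleted,
            "t_dep": traj.t_dep if traj.depleted else np.nan,
        }
        final = traj.final_state
        for sp, label in _PRODUCT_COLS.items():
            row[label] = float(final[sp]) if traj.depleted else np.nan
        row["biomass"] = float(final["X"])
        row["TF_Fnr"] = _mean_over_time(traj, "TF_Fnr")
        row["TF_ArcA"] = _mean_over_time(traj, "TF_ArcA")
        row["NADH_ratio"] = _mean_over_time(traj, "NADH_ratio")
        row["qOUR"] = _mean_over_time(traj, "qOUR")
        for flux in _FLUX_COLS:
            row[f"v_{flux}"] = _mean_over_time(traj, f"v_{flux}")
        rows.append(row)
        if keep_trajectories:
            trajectories[do] = traj
    return SweepResult(strain=strain, table=pd.DataFrame(rows), trajectories=trajectories)


def find_peak(sweep: SweepResult, product: str) -> dict:
    """DO% of the product-concentration maximum on the sweep grid.

    Grid argmax with quadratic refinement through the three surrounding
    points; ties broken toward the lower DO level.  A maximum at either end
    of the grid is reported with ``interior=False`` (no interior peak).
    """
    table = sweep.table[sweep.table["depleted"]].reset_index(drop=True)
    if table.empty:
        raise ValueError("sweep contains no depleted runs")
    values = table[product].to_numpy(dtype=float)
    do = table["DO_percent"].to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        return {"DO_percent": float(do[0]), "value": float(values[0]), "interior": False, "flat": True}
    best = int(np.flatnonzero(values == values.max())[0])  # tie -> lower DO
    result = {
        "DO_percent": float(do[best]),
        "value": float(values[best]),
        "interior": 0 < best < len(values) - 1,
        "flat": False,
    }
    if result["interior"]:
        x0, x1, x2 = do[best - 1 : best + 2]
        y0, y1, y2 = values[best - 1 : best + 2]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        if abs(denom) > 0:
            a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
            b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
            if a < 0:
                refined = -b / (2 * a)
                if x0 <= refined <= x2:
                    result["DO_refined"] = float(refined)
    return result


def dual_phase_scan(
    strain: StrainSpec | str,
    do_aerobic: float = 40.0,
    do_microaerobic: float = 1.0,
    switch_times: Sequence[float] = tuple(np.linspace(0.0, 12.0, 25)),
    protocol_base: CultivationProtocol | None = None,
    network: MetabolicNetwork | None = None,
    params: ParameterSet | None = None,
    product: str = "LAC",
) -> DualPhaseResult:
    """Yield/productivity of the target product versus DO switching time.

    For each switching time t_s the culture runs at ``do_aerobic`` on
    [0, t_s) and at ``do_microaerobic`` afterwards until glucose depletion.
    Yield is g product per g glucose consumed; productivity is the final
    product concentration divided by the cultivation (depletion) time.
    t_s = 0 degenerates exactly to the constant micro-aerobic batch.
    """
    if isinstance(strain, str):
        strain = StrainSpec.from_name(strain)
    base = protocol_base or CultivationProtocol()
    network = network if network is not None else load_network()
    params = params if params is not None else load_parameters()
    net_s, par_s = apply_knockout(network, params, strain)
    system = BatchSystem(net_s, par_s)

    rows = []
    for t_s in sorted(float(t) for t in switch_times):
        protocol = CultivationProtocol(
            glucose_0=base.glucose_0,
            biomass_0=base.biomass_0,
            do_schedule=DOSchedule.dual_phase(do_aerobic, do_microaerobic, t_s),
            strain=strain,
            glc_threshold=base.glc_threshold,
            t_max=base.t_max,
            initial_intracellular=base.initial_intracellular,
        )
        traj = simulate_batch(protocol, system=system)
        row = {"t_switch": t_s, "depleted": traj.depleted}
        if traj.depleted:
            final = traj.final_state
            consumed = base.glucose_0 - float(final["GLC"])
            row["t_dep"] = traj.t_dep
            row["product_conc"] = float(final[product])
            row["glucose_consumed"] = consumed
            row["yield"] = row["product_conc"] / consumed if consumed > 0 else np.nan
            row["productivity"] = row["product_conc"] / traj.t_dep if traj.t_dep else np.nan
            row["biomass"] = float(final["X"])
        else:
            row.update(
                t_dep=np.nan,
                product_conc=np.nan,
                glucose_consumed=np.nan,
                **{"yield": np.nan},
                productivity=np.nan,
                biomass=np.nan,
            )
        rows.append(row)
    return DualPhaseResult(
        strain=strain,
        do_aerobic=do_aerobic,
        do_microaerobic=do_microaerobic,
        table=pd.DataFrame(rows),
    )
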