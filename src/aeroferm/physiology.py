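"""Derived specific rates: ATP, growth, CO2, NADPH, NADH, and carbon balances.

The specific ATP production rate combines substrate-level phosphorylation with
oxidative phosphorylation.  OP converts respiratory proton pumping to ATP via
the H+/ATP = 3 stoichiometry with H+/e- ratios of 2 (Nuo), 2 (Cyo) and 1
(Cyd), two electrons per flux unit:

    OP    = (4 v_Nuo + 4 v_Cyo + 2 v_Cyd) / 3
    v_ATP = OP + v_L_Emp + v_Pyk + v_PTACK + v_aKGDH
               - v_Glk - v_Pfk - v_Pps - v_Pck - v_Acs

Growth is linearly coupled to ATP production (mu = k_ATP * v_ATP, floored at
zero), a relation observed to hold across aerobic, micro-aerobic and anaerobic
conditions.  CO2, NADPH and NADH rates are stoichiometric sums over the
decarboxylating, NADP-reducing and NAD-coupled reactions respectively; NADPH
is a diagnostic only (no consumption side is modeled).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

from .network import MetabolicNetwork
from .parameters import ParameterSet

if TYPE_CHECKING:  # pragma: no cover
    from .simulator import Trajectory

__all__ = [
    "ATP_COEFFS",
    "OP_COEFFS",
    "CO2_COEFFS",
    "NADPH_COEFFS",
    "NADH_COEFFS",
    "PhysiologyRates",
    "atp_rate",
    "growth_rate",
    "co2_rate",
    "nadph_rate",
    "nadh_rate",
    "physiology_rates",
    "carbon_balance",
]

OP_COEFFS = {"Nuo": 4.0 / 3.0, "Cyo": 4.0 / 3.0, "Cyd": 2.0 / 3.0}
ATP_SLP_COEFFS = {
    "L_Emp": 1.0,
    "Pyk": 1.0,
    "PTACK": 1.0,
    "aKGDH": 1.0,
    "Glk": -1.0,
    "Pfk": -1.0,
    "Pps": -1.0,
    "Pck": -1.0,
    "Acs": -1.0,
}
ATP_COEFFS = {**OP_COEFFS, **ATP_SLP_COEFFS}
CO2_COEFFS = {
    "PGDH": 1.0,
    "PDH": 1.0,
    "ICDH": 1.0,
    "aKGDH": 1.0,
    "Mez": 1.0,
    "Pck": 1.0,
    "Ppc": -1.0,
}
NADPH_COEFFS = {"G6PDH": 1.0, "PGDH": 1.0, "ICDH": 1.0, "Mez": 1.0}
NADH_COEFFS = {
    "L_Emp": 1.0,
    "PDH": 1.0,
    "aKGDH": 1.0,
    "MDH": 1.0,
    "LDH": -1.0,
    "ALDH": -1.0,
    "ADH": -1.0,
    "Nuo": -1.0,
    "Ndh": -1.0,
}


def _dot(coeffs: Mapping[str, float], fluxes: Mapping[str, float]) -> float:
    return float(sum(c * fluxes.get(name, 0.0) for name, c in coeffs.items()))


def atp_rate(fluxes: Mapping[str, float], params: ParameterSet | None = None):
    """(v_ATP, OP, per-term breakdown), mmol ATP/gDW/h."""
    op = _dot(OP_COEFFS, fluxes)
    slp = _dot(ATP_SLP_COEFFS, fluxes)
    breakdown = {"OP": op}
    breakdown.update(
        {name: c * fluxes.get(name, 0.0) for name, c in ATP_SLP_COEFFS.items()}
    )
    return op + slp, op, breakdown


def growth_rate(v_ATP: float, params: ParameterSet) -> float:
    """mu = k_ATP * v_ATP (1/h), floored at zero (no death term)."""
    return max(params["k_ATP"] * v_ATP, 0.0)


def co2_rate(fluxes: Mapping[str, float]) -> float:
    return _dot(CO2_COEFFS, fluxes)


def nadph_rate(fluxes: Mapping[str, float]) -> float:
    return _dot(NADPH_COEFFS, fluxes)


def nadh_rate(fluxes: Mapping[str, float]):
    """(net NADH rate, grouped production/consumption breakdown).

    Grouping follows the fermentation-physiology reading: glycolysis and PDH
    and the oxidative TCA arm produce NADH; lactate, ethanol, respiration and
    the reductive TCA arm (MDH running toward malate) consume it.
    """
    v = {name: fluxes.get(name, 0.0) for name in NADH_COEFFS}
    net = _dot(NADH_COEFFS, fluxes)
    mdh = v["MDH"]
    breakdown = {
        "glycolysis": v["L_Emp"],
        "PDH": v["PDH"],
        "TCA": v["aKGDH"] + max(mdh, 0.0),
        "lactate": -v["LDH"],
        "ethanol": -(v["ALDH"] + v["ADH"]),
        "respiration": -(v["Nuo"] + v["Ndh"]),
        "reductive_TCA": min(mdh, 0.0),
    }
    return net, breakdown


@dataclass(frozen=True)
class PhysiologyRates:
    v_ATP: float
    OP: float
    mu: float
    v_CO2: float
    v_NADPH: float
    v_NADH: float
    atp_breakdown: dict
    nadh_breakdown: dict


def physiology_rates(fluxes: Mapping[str, float], params: ParameterSet) -> PhysiologyRates:
    v_atp, op, atp_bd = atp_rate(fluxes, params)
    v_nadh, nadh_bd = nadh_rate(fluxes)
    return PhysiologyRates(
        v_ATP=v_atp,
        OP=op,
        mu=growth_rate(v_atp, params),
        v_CO2=co2_rate(fluxes),
        v_NADPH=nadph_rate(fluxes),
        v_NADH=v_nadh,
        atp_breakdown=atp_bd,
        nadh_breakdown=nadh_bd,
    )


def carbon_balance(trajectory: "Trajectory", network: MetabolicNetwork) -> pd.Series:
    """Apportion consumed glucose carbon over product/CO2/biomass/residual sinks.

    Fractions (of carbon moles of glucose consumed) for each extracellular
    product, CO2, biomass (cumulative precursor drain) and the residual held
    in intracellular pools.  They sum to 1 up to integrator tolerance.  If the
    trajectory did not reach glucose depletion the balance is computed over
    the consumed fraction.
    """
    frame = trajectory.frame
    labels = ["acetate", "lactate", "formate", "ethanol", "succinate", "CO2", "biomass", "residual"]
    if len(frame) < 2:
        return pd.Series(0.0, index=labels)
    first, last = frame.iloc[0], frame.iloc[-1]
    glc = network.species["GLC"]
    consumed_mmol_c = (first["GLC"] - last["GLC"]) / (glc.mw / 1000.0) * glc.carbon
    if consumed_mmol_c <= 0:
        return pd.Series(0.0, index=labels)

    def product_c(sp_id: str) -> float:
        sp = network.species[sp_id]
        return (last[sp_id] - first[sp_id]) / (sp.mw / 1000.0) * sp.carbon

    residual = 0.0
    for sp in network.species.values():
        if sp.compartment == "cytoplasm" and sp.carbon:
            residual += sp.carbon * (last[sp.id] * last["X"] - first[sp.id] * first["X"])
    out = pd.Series(
        {
            "acetate": product_c("ACE"),
            "lactate": product_c("LAC"),
            "formate": product_c("FOR"),
            "ethanol": product_c("ETH"),
            "succinate": product_c("SUC"),
            "CO2": last["CO2_cum"] - first["CO2_cum"],
            "biomass": last["BIOC_cum"] - first["BIOC_cum"],
            "residual": residual,
        }
    )
    return out / consumed_mmol_c


def breakdown_table(trajectories: Mapping[str, "Trajectory"], params: ParameterSet) -> pd.DataFrame:
    """Tidy (condition, source-term) table of time-averaged ATP/NADH breakdowns."""
    rows = []
    for label, traj in trajectories.items():
        frame = traj.frame
        weights = np.gradient(frame["time"].to_numpy()) if len(frame) > 1 else np.ones(len(frame))
        weights = weights / weights.sum()
        for kind, columns in (("ATP", ATP_SLP_COEFFS), ("NADH", NADH_COEFFS)):
            for term in columns:
                col = f"v_{term}"
                if col in frame:
                    rows.append(
                        {
                            "condition": label,
                            "kind": kind,
                            "source": term,
                            "rate": float((frame[col].to_numpy() * weights).sum()),
                        }
                    )
    return pd.DataFrame(rows)
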