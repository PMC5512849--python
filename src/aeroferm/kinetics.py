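"""Reaction-rate evaluation for the full network.

Rate laws are declared on the network (see :class:`aeroferm.network.RateLawSpec`)
and compiled here into flat index/constant arrays so that one flux evaluation
is a handful of vectorized numpy operations.  Forms:

* irreversible multiplicative Michaelis-Menten  v = vmax * prod_s S/(K_s+S)
* reversible MM                                 v = vmax * (prod_s S/K_s - prod_p P/K_p / Keq) / (1 + sum_s S/K_s + sum_p P/K_p)
* mass action, zero-order (fixture networks)

with optional multiplicative modifiers: activation (1 + beta*A/(K_A+A)),
inhibition 1/(1 + I/K_I), and the PTS phosphoenolpyruvate/pyruvate ratio term
PEP/(PEP + K*PYR).  Effective vmax values carry the transcription-factor
scaling of :func:`aeroferm.regulation.modulate_vmax` (activation edges
multiply by 1+a*TF, repression edges by 1/(1+r*TF)).

The respiratory chain couples to the conserved quinone pool: Nuo and Ndh
oxidize NADH while reducing Q to QH2; Cyo and Cyd oxidize QH2 back to Q with
Michaelis-Menten oxygen dependence.  Cyd has the higher oxygen affinity
(smaller K_O2) but the lower maximal rate, Cyo the reverse — so Cyo dominates
aerobically and Cyd under micro-aerobic conditions.  All respiratory fluxes
are in two-electron units (one NADH or one quinol per flux unit).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .network import MetabolicNetwork
from .parameters import ParameterSet
from .regulation import RedoxEnvironment

__all__ = ["CompiledModel", "evaluate_fluxes", "respiratory_o2_consumption"]

_TF_INDEX = {"Fnr": 0, "ArcA": 1}
_EPS = 1e-12


class CompiledModel:
    """Network + parameters flattened into arrays for fast flux evaluation."""

    def __init__(self, network: MetabolicNetwork, params: ParameterSet):
        self.network = network
        self.params = params
        self.species_ids = list(network.species)
        self.species_index = {s: i for i, s in enumerate(self.species_ids)}
        self.reaction_ids = list(network.reactions)
        self.reaction_index = {r: i for i, r in enumerate(self.reaction_ids)}
        n_rxn = len(self.reaction_ids)
        n_sp = len(self.species_ids)

        # stoichiometric matrix (species x reactions)
        self.S = np.zeros((n_sp, n_rxn))
        for j, rid in enumerate(self.reaction_ids):
            for sp, coef in network.reactions[rid].stoichiometry.items():
                self.S[self.species_index[sp], j] = coef

        self.vmax = np.array(
            [params[network.reactions[r].rate_law.vmax] for r in self.reaction_ids]
        )

        # regulation edges -> (reaction, tf, is_activation, strength)
        reg = []
        for j, rid in enumerate(self.reaction_ids):
            for edge in network.edges_for_gene(network.reactions[rid].gene):
                reg.append(
                    (j, _TF_INDEX[edge.tf], edge.sign == "activation", params[edge.strength])
                )
        self.reg_rxn = np.array([r[0] for r in reg], dtype=int)
        self.reg_tf = np.array([r[1] for r in reg], dtype=int)
        self.reg_act = np.array([r[2] for r in reg], dtype=bool)
        self.reg_strength = np.array([r[3] for r in reg])

        # Michaelis-Menten substrate terms (irreversible forms only)
        mm_idx, mm_rxn, mm_K = [], [], []
        hill_idx, hill_rxn, hill_K, hill_h = [], [], [], []
        ma_idx, ma_rxn = [], []
        act_idx, act_rxn, act_K, act_beta = [], [], [], []
        inh_idx, inh_rxn, inh_K = [], [], []
        rat_num, rat_den, rat_rxn, rat_K = [], [], [], []
        rev = []  # (rxn, sub_idx[], sub_K[], prod_idx[], prod_K[], keq)
        zero_order = np.zeros(n_rxn, dtype=bool)
        for j, rid in enumerate(self.reaction_ids):
            rl = network.reactions[rid].rate_law
            if rl.form == "mm":
                for sub in rl.substrates:
                    sp, ksym = sub[0], sub[1]
                    hsym = sub[2] if len(sub) > 2 else None
                    if hsym:
                        hill_idx.append(self.species_index[sp])
                        hill_rxn.append(j)
                        hill_K.append(params[ksym])
                        hill_h.append(params[hsym])
                    else:
                        mm_idx.append(self.species_index[sp])
                        mm_rxn.append(j)
                        mm_K.append(params[ksym])
            elif rl.form == "mass_action":
                for sub in rl.substrates:
                    ma_idx.append(self.species_index[sub[0]])
                    ma_rxn.append(j)
            elif rl.form == "constant":
                zero_order[j] = True
            elif rl.form == "rev":
                rev.append(
                    (
                        j,
                        np.array([self.species_index[s[0]] for s in rl.substrates], dtype=int),
                        np.array([params[s[1]] for s in rl.substrates]),
                        np.array([self.species_index[sp] for sp, _ in rl.products], dtype=int),
                        np.array([params[k] for _, k in rl.products]),
                        params[rl.keq],
                    )
                )
            else:
                raise ValueError(f"unknown rate-law form {rl.form!r} on reaction {rid}")
            for mod in rl.modifiers:
                if mod["type"] == "activation":
                    act_idx.append(self.species_index[mod["species"]])
                    act_rxn.append(j)
                    act_K.append(params[mod["K"]])
                    act_beta.append(params[mod["beta"]])
                elif mod["type"] == "inhibition":
                    inh_idx.append(self.species_index[mod["species"]])
                    inh_rxn.append(j)
                    inh_K.append(params[mod["K"]])
                elif mod["type"] == "ratio":
                    rat_num.append(self.species_index[mod["num"]])
                    rat_den.append(self.species_index[mod["den"]])
                    rat_rxn.append(j)
                    rat_K.append(params[mod["K"]])
                else:
                    raise ValueError(f"unknown modifier type {mod['type']!r} on {rid}")

        self.mm_idx = np.array(mm_idx, dtype=int)
        self.mm_rxn = np.array(mm_rxn, dtype=int)
        self.mm_K = np.array(mm_K)
        self.hill_idx = np.array(hill_idx, dtype=int)
        self.hill_rxn = np.array(hill_rxn, dtype=int)
        self.hill_K = np.array(hill_K)
        self.hill_h = np.array(hill_h)
        self.ma_idx = np.array(ma_idx, dtype=int)
        self.ma_rxn = np.array(ma_rxn, dtype=int)
        self.act_idx = np.array(act_idx, dtype=int)
        self.act_rxn = np.array(act_rxn, dtype=int)
        self.act_K = np.array(act_K)
        self.act_beta = np.array(act_beta)
        self.inh_idx = np.array(inh_idx, dtype=int)
        self.inh_rxn = np.array(inh_rxn, dtype=int)
        self.inh_K = np.array(inh_K)
        self.rat_num = np.array(rat_num, dtype=int)
        self.rat_den = np.array(rat_den, dtype=int)
        self.rat_rxn = np.array(rat_rxn, dtype=int)
        self.rat_K = np.array(rat_K)
        self.rev = rev
        self.zero_order = zero_order

    def fluxes(self, conc: np.ndarray, tf_fnr: float, tf_arca: float) -> np.ndarray:
        """Flux vector (mmol/gDW/h) from the full species concentration array."""
        v = self.vmax.copy()
        if self.reg_rxn.size:
            tf = np.where(self.reg_tf == 0, tf_fnr, tf_arca)
            factors = np.where(
                self.reg_act, 1.0 + self.reg_strength * tf, 1.0 / (1.0 + self.reg_strength * tf)
            )
            np.multiply.at(v, self.reg_rxn, factors)
        if self.mm_rxn.size:
            s = conc[self.mm_idx]
            np.multiply.at(v, self.mm_rxn, s / (self.mm_K + s))
        if self.hill_rxn.size:
            s = np.maximum(conc[self.hill_idx], 0.0) ** self.hill_h
            np.multiply.at(v, self.hill_rxn, s / (self.hill_K**self.hill_h + s))
        if self.ma_rxn.size:
            np.multiply.at(v, self.ma_rxn, conc[self.ma_idx])
        if self.act_rxn.size:
            a = conc[self.act_idx]
            np.multiply.at(v, self.act_rxn, 1.0 + self.act_beta * a / (self.act_K + a))
        if self.inh_rxn.size:
            i = conc[self.inh_idx]
            np.multiply.at(v, self.inh_rxn, 1.0 / (1.0 + i / self.inh_K))
        if self.rat_rxn.size:
            num = conc[self.rat_num]
            den = conc[self.rat_den]
            np.multiply.at(v, self.rat_rxn, num / (num + self.rat_K * den + _EPS))
        for j, s_idx, s_K, p_idx, p_K, keq in self.rev:
            snorm = conc[s_idx] / s_K
            pnorm = conc[p_idx] / p_K
            v[j] *= (snorm.prod() - pnorm.prod() / keq) / (1.0 + snorm.sum() + pnorm.sum())
        return v

    def flux_series(self, conc: np.ndarray, tf_fnr: float, tf_arca: float) -> pd.Series:
        return pd.Series(self.fluxes(conc, tf_fnr, tf_arca), index=self.reaction_ids, name="flux")

    def concentration_array(self, state: Mapping[str, float], O2: float) -> np.ndarray:
        """Full concentration array from a named state mapping.

        Pool partners absent from ``state`` are derived from the conserved
        totals; the boundary oxygen species is set from ``O2``.
        """
        conc = np.zeros(len(self.species_ids))
        for sp, val in state.items():
            if sp in self.species_index:
                conc[self.species_index[sp]] = val
        for pool in self.network.conserved_pools:
            first, second = pool.members
            total = self.params[pool.total]
            if second not in state and first in state:
                conc[self.species_index[second]] = total - state[first]
            elif first not in state and second in state:
                conc[self.species_index[first]] = total - state[second]
        if "O2" in self.species_index:
            conc[self.species_index["O2"]] = O2
        return conc


def evaluate_fluxes(
    state: Mapping[str, float],
    env: RedoxEnvironment,
    network: MetabolicNetwork,
    params: ParameterSet,
    compiled: CompiledModel | None = None,
) -> pd.Series:
    """All specific reaction rates for a named state under a redox environment.

    Raises on (materially) negative concentrations, which signal an upstream
    integrator failure rather than a meaningful state.
    """
    bad = {sp: val for sp, val in state.items() if val < -1e-9}
    if bad:
        raise ValueError(f"negative concentrations: {bad}")
    model = compiled or CompiledModel(network, params)
    conc = model.concentration_array(state, env.O2_cyt)
    return model.flux_series(conc, env.TF_Fnr, env.TF_ArcA)


def respiratory_o2_consumption(fluxes: Mapping[str, float]) -> float:
    """Specific oxygen uptake rate qOUR = (v_Cyo + v_Cyd)/2, mmol O2/gDW/h.

    Oxidase fluxes are in two-electron (per-quinol) units and one O2 accepts
    four electrons, hence the factor 1/2.
    """
    return 0.5 * (fluxes.get("Cyo", 0.0) + fluxes.get("Cyd", 0.0))
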