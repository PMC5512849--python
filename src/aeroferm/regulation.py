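"""Oxygen- and quinone-dependent transcription-factor activities.

Fnr senses cytoplasmic oxygen directly; ArcA activity follows the oxidized
quinone pool (quinone inhibits ArcB autophosphorylation, so low quinone means
phosphorylated — active — ArcA).  Both activities are modeled as repression-type
Hill functions with a shared negative Hill coefficient n:

    TF(x) = x^n / (x^n + K^n)          (n < 0)

evaluated through the singularity-free equivalent K^|n|/(K^|n| + x^|n|), which
is exact for x > 0 and extends continuously to TF(0) = 1.  Activities are
treated as instantaneous algebraic functions (quasi-steady state for the ArcB
phosphorelay and the Fnr Fe-S cluster), so they respond without delay to the
dissolved-oxygen setpoint and to the simulated quinone pool.

Effective maximal rates follow v_max = v_max' * f(TF) where each activation
edge contributes a factor (1 + a*TF) and each repression edge 1/(1 + r*TF);
f(0) = 1, so an inactive TF leaves the reaction at its baseline rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import MetabolicNetwork, ReactionSpec
from .parameters import ParameterSet

__all__ = [
    "RedoxEnvironment",
    "do_percent_to_O2",
    "hill_activity",
    "fnr_activity",
    "arcA_activity",
    "modulate_vmax",
    "classify_condition",
]


@dataclass(frozen=True)
class RedoxEnvironment:
    """Snapshot of the oxygen/quinone/TF state at one instant."""

    DO_percent: float
    DO_conc: float  # [DO2], mM
    O2_cyt: float  # cytoplasmic [O2], mM
    Q: float  # oxidized quinone, mmol/gDW
    TF_Fnr: float
    TF_ArcA: float

    @property
    def condition(self) -> str:
        return classify_condition(self.DO_percent)

    @classmethod
    def from_state(cls, DO_percent: float, Q: float, params: ParameterSet) -> "RedoxEnvironment":
        o2 = do_percent_to_O2(DO_percent, params)
        return cls(
            DO_percent=DO_percent,
            DO_conc=(DO_percent / 100.0) * params["DO2_star"],
            O2_cyt=o2,
            Q=Q,
            TF_Fnr=fnr_activity(o2, params),
            TF_ArcA=arcA_activity(Q, params),
        )


def do_percent_to_O2(DO_percent, params: ParameterSet):
    """Cytoplasmic O2 (mM) from the DO setpoint: k_O2 * (DO%/100) * [DO2]*."""
    DO_percent = np.asarray(DO_percent, dtype=float)
    if np.any(DO_percent < 0) or np.any(DO_percent > 100):
        raise ValueError(f"DO percent outside [0, 100]: {DO_percent}")
    out = params["k_O2"] * (DO_percent / 100.0) * params["DO2_star"]
    return float(out) if out.ndim == 0 else out


def hill_activity(x, K: float, n: float):
    """Repression-type Hill activity x^n/(x^n + K^n) for n < 0.

    Evaluated as K^|n|/(K^|n| + x^|n|): identical for x > 0, and continuous
    at x = 0 where the literal form is singular.
    """
    if K <= 0:
        raise ValueError(f"Hill affinity constant must be positive, got {K}")
    if n >= 0:
        raise ValueError(f"Hill coefficient must be negative, got {n}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"negative Hill argument: {x}")
    m = -n
    out = K**m / (K**m + x**m)
    return float(out) if out.ndim == 0 else out


def fnr_activity(O2, params: ParameterSet):
    """Fnr activity in [0,1]; high at low cytoplasmic oxygen."""
    act = hill_activity(O2, params["K_Fnr"], params["n_hill"])
    return act * params.tf_scale.get("Fnr", 1.0)


def arcA_activity(Q, params: ParameterSet):
    """ArcA activity in [0,1]; high when the oxidized quinone pool is small."""
    act = hill_activity(Q, params["K_ArcA"], params["n_hill"])
    return act * params.tf_scale.get("ArcA", 1.0)


def regulation_factor(
    network: MetabolicNetwork, reaction: ReactionSpec, env: RedoxEnvironment, params: ParameterSet
) -> float:
    """f(TF) for one reaction: product over its regulation edges."""
    tf_act = {"Fnr": env.TF_Fnr, "ArcA": env.TF_ArcA}
    factor = 1.0
    for edge in network.edges_for_gene(reaction.gene):
        strength = params[edge.strength]
        tf = tf_act[edge.tf]
        if edge.sign == "activation":
            factor *= 1.0 + strength * tf
        else:
            factor /= 1.0 + strength * tf
    return factor


def modulate_vmax(
    reaction: ReactionSpec,
    env: RedoxEnvironment,
    params: ParameterSet,
    network: MetabolicNetwork,
) -> float:
    """Effective v_max = v_max' * f(TF) for one reaction."""
    return params[reaction.rate_law.vmax] * regulation_factor(network, reaction, env, params)


def classify_condition(DO_percent: float) -> str:
    """Aeration category: I (DO=0), II (0<DO<7), III (7<=DO<20), IV (DO>=20)."""
    if not 0 <= DO_percent <= 100:
        raise ValueError(f"DO percent outside [0, 100]: {DO_percent}")
    if DO_percent == 0:
        return "I"
    if DO_percent < 7:
        return "II"
    if DO_percent < 20:
        return "III"
    return "IV"
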