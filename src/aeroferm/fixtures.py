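"""Synthetic fixture networks and golden-regression helpers.

The toy model is a 3-metabolite linear pathway

    S --(R1, TF-activated)--> A --(R2)--> B --(R3, cofactor-coupled)--> P

with a conserved two-member cofactor pair (COX/CRED; R3 reduces COX to CRED,
R4 regenerates it by first-order mass action) and a closed-form steady state,
used as the integrator/rate-law oracle: any refactor of the kinetics engine
or solver must still hit the analytic fixed point.

Golden regressions store compact summaries (products at depletion, depletion
time, mean TF activities) of canonical wild-type and knockout runs keyed by
the parameter digest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

from .network import (
    ConservedPool,
    MetabolicNetwork,
    RateLawSpec,
    ReactionSpec,
    RegulationEdge,
    Species,
)
from .parameters import ParameterSet, load_parameters
from .simulator import CultivationProtocol, DOSchedule, simulate_batch
from .strains import StrainSpec

__all__ = ["ToySteadyState", "make_toy", "golden_regression", "compare_golden", "GOLDEN_RUNS"]

_TOY_DIAL_RANGES = {
    "input_rate": (0.01, 5.0),
    "stiffness": (0.1, 1000.0),
    "tf_strength": (0.0, 20.0),
}


@dataclass(frozen=True)
class ToySteadyState:
    """Analytic fixed point of the toy pathway at clamped substrate."""

    A: float
    B: float
    COX: float
    CRED: float
    flux: float


def make_toy(
    input_rate: float = 1.0,
    stiffness: float = 1.0,
    tf_strength: float = 2.0,
    tf_fnr: float = 0.0,
    substrate_0: float = 50.0,
) -> tuple[MetabolicNetwork, ParameterSet, ToySteadyState]:
    """Build the toy network, its parameters, and the closed-form steady state.

    ``stiffness`` multiplies the cofactor-cycle rates (R3/R4), separating the
    fast cofactor timescale from the slow pathway timescale; ``tf_strength``
    is the activation strength a on R1 (flux factor 1 + a*TF_Fnr at the DO
    setpoint's Fnr activity).  Raises for dials outside the documented ranges
    or if no steady state exists for the dial combination.
    """
    for name, val in (("input_rate", input_rate), ("stiffness", stiffness), ("tf_strength", tf_strength)):
        lo, hi = _TOY_DIAL_RANGES[name]
        if not lo <= val <= hi:
            raise ValueError(f"toy dial {name}={val} outside [{lo}, {hi}]")

    species = {
        "GLC": Species("GLC", "extracellular", carbon=1, mw=100.0),  # pathway substrate
        "PRODUCT": Species("PRODUCT", "extracellular", carbon=1, mw=100.0),
        "A": Species("A", "cytoplasm", carbon=1),
        "B": Species("B", "cytoplasm", carbon=1),
        "COX": Species("COX", "pool", carbon=0),
        "CRED": Species("CRED", "pool", carbon=0),
    }
    reactions = {
        "R1": ReactionSpec(
            id="R1",
            stoichiometry={"GLC": -1, "A": 1},
            rate_law=RateLawSpec(
                form="mm", vmax="vmax_R1", substrates=(("GLC", "K_R1_S"),)
            ),
            gene="toyA",
        ),
        "R2": ReactionSpec(
            id="R2",
            stoichiometry={"A": -1, "B": 1},
            rate_law=RateLawSpec(form="mm", vmax="vmax_R2", substrates=(("A", "K_R2_A"),)),
        ),
        "R3": ReactionSpec(
            id="R3",
            stoichiometry={"B": -1, "PRODUCT": 1, "COX": -1, "CRED": 1},
            rate_law=RateLawSpec(
                form="mm",
                vmax="vmax_R3",
                substrates=(("B", "K_R3_B"), ("COX", "K_R3_COX")),
            ),
        ),
        "R4": ReactionSpec(
            id="R4",
            stoichiometry={"CRED": -1, "COX": 1},
            rate_law=RateLawSpec(form="mass_action", vmax="k_R4", substrates=(("CRED", ""),)),
        ),
    }
    network = MetabolicNetwork(
        species=species,
        reactions=reactions,
        regulation_edges=[RegulationEdge(tf="Fnr", gene="toyA", sign="activation", strength="a_toyA")],
        conserved_pools=[ConservedPool(members=("COX", "CRED"), total="C_total")],
        name="toy-linear-pathway",
    )
    values = {
        "vmax_R1": input_rate,
        "K_R1_S": 1.0,
        "vmax_R2": 4.0 * input_rate + 1.0,
        "K_R2_A": 0.5,
        "vmax_R3": (6.0 * input_rate + 2.0) * stiffness,
        "K_R3_B": 0.4,
        "K_R3_COX": 0.2,
        "k_R4": (8.0 * input_rate + 4.0) * stiffness,
        "C_total": 1.0,
        "a_toyA": tf_strength,
        # globals required of every parameter set; K_Fnr far below any
        # simulated O2 so the TF is numerically fully off at high DO and the
        # closed-form steady state is exact
        "K_Fnr": 1.0e-8,
        "K_ArcA": 0.35,
        "n_hill": -4.0,
        "k_O2": 0.1,
        "DO2_star": 0.21,
        "k_ATP": 1e-6,
        "X_carbon": 0.48,
        "drain_K": 0.01,
        "N_total": 1.0,
        "Q_total": 1.0,
    }
    params = ParameterSet(values=values, provenance={k: "synthetic fixture" for k in values})

    f_tf = 1.0 + tf_strength * tf_fnr
    v1 = input_rate * f_tf * substrate_0 / (values["K_R1_S"] + substrate_0)
    vmax2, K2 = values["vmax_R2"], values["K_R2_A"]
    vmax3, K3, KC = values["vmax_R3"], values["K_R3_B"], values["K_R3_COX"]
    k4, Ct = values["k_R4"], values["C_total"]
    if v1 >= vmax2 or v1 / k4 >= Ct:
        raise ValueError("no steady state for these dials (pathway saturated)")
    A = K2 * v1 / (vmax2 - v1)
    CRED = v1 / k4
    COX = Ct - CRED
    g = COX / (KC + COX)
    u = v1 / (vmax3 * g)
    if u >= 1:
        raise ValueError("no steady state for these dials (R3 saturated)")
    B = K3 * u / (1.0 - u)
    return network, params, ToySteadyState(A=A, B=B, COX=COX, CRED=CRED, flux=v1)


# --- golden regressions ---------------------------------------------------

GOLDEN_RUNS = tuple(
    (strain, do)
    for strain in ("WT", "fnr", "arcA", "pfl")
    for do in (0.0, 1.0, 3.0, 8.0, 40.0)
)

_SUMMARY_FIELDS = ("t_dep", "ACE", "LAC", "FOR", "ETH", "SUC", "X", "TF_Fnr_mean", "TF_ArcA_mean")


def _run_summary(strain: str, do: float) -> dict:
    protocol = CultivationProtocol(
        do_schedule=DOSchedule.constant(do), strain=StrainSpec.from_name(strain)
    )
    traj = simulate_batch(protocol)
    final = traj.final_state
    frame = traj.frame
    return {
        "t_dep": traj.t_dep,
        "ACE": float(final["ACE"]),
        "LAC": float(final["LAC"]),
        "FOR": float(final["FOR"]),
        "ETH": float(final["ETH"]),
        "SUC": float(final["SUC"]),
        "X": float(final["X"]),
        "TF_Fnr_mean": float(frame["TF_Fnr"].mean()),
        "TF_ArcA_mean": float(frame["TF_ArcA"].mean()),
    }


def golden_regression(runs=GOLDEN_RUNS) -> dict:
    """Recompute canonical run summaries (keyed 'strain@DO%') with digest."""
    summaries = {f"{strain}@{do:g}": _run_summary(strain, do) for strain, do in runs}
    return {"parameter_digest": load_parameters().digest(), "runs": summaries}


def regenerate_golden(path=None, runs=GOLDEN_RUNS) -> str:
    """Explicitly rewrite the stored golden file (bumps the digest)."""
    import pathlib

    if path is None:
        path = pathlib.Path(__file__).parent / "data" / "golden_runs.json"
    doc = golden_regression(runs)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
    return str(path)


def load_golden() -> dict:
    ref = resources.files("aeroferm.data").joinpath("golden_runs.json")
    with ref.open("r") as fh:
        return json.load(fh)


def compare_golden(runs, rel_tol: float = 1e-6) -> list[str]:
    """Diff report of recomputed summaries against the stored golden file.

    Empty list means no regression.  A parameter-digest mismatch is itself a
    reported difference (goldens are never regenerated silently).
    """
    stored = load_golden()
    current_digest = load_parameters().digest()
    diffs = []
    if stored["parameter_digest"] != current_digest:
        diffs.append(
            f"parameter digest changed: stored {stored['parameter_digest']}, "
            f"current {current_digest}"
        )
    for strain, do in runs:
        key = f"{strain}@{do:g}"
        if key not in stored["runs"]:
            diffs.append(f"run {key} missing from golden file")
            continue
        expected = stored["runs"][key]
        got = _run_summary(strain, do)
        for field in _SUMMARY_FIELDS:
            e, g = expected[field], got[field]
            if e is None or g is None:
                if e != g:
                    diffs.append(f"{key}.{field}: stored {e}, got {g}")
                continue
            scale = max(abs(e), 1e-9)
            if not math.isclose(e, g, rel_tol=rel_tol, abs_tol=rel_tol * scale):
                diffs.append(f"{key}.{field}: stored {e:.9g}, got {g:.9g}")
    return diffs
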