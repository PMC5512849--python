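"""Flux evaluation: rate-law behavior, respiratory coupling, continuity."""

import numpy as np
import pytest

from aeroferm.kinetics import CompiledModel, evaluate_fluxes, respiratory_o2_consumption
from aeroferm.regulation import RedoxEnvironment


def env_at(params, do_percent, q):
    return RedoxEnvironment.from_state(do_percent, q, params)


def base_state(network, params, level=0.5):
    state = {s: level for s in network.species_in("cytoplasm")}
    state.update({s: 1.0 for s in network.species_in("extracellular")})
    state["NADH"] = 0.5 * params["N_total"]
    state["Q"] = 0.5 * params["Q_total"]
    return state


def test_all_zero_substrates_give_zero_fluxes(network, params):
    state = {s: 0.0 for s in network.species_in("cytoplasm") + network.species_in("extracellular")}
    state["NADH"] = 0.0
    state["Q"] = 0.0
    # anaerobic, so the oxidases see no O2; NAD+/QH2 partners sit at their
    # pool totals but every reaction still has at least one zero substrate
    fluxes = evaluate_fluxes(state, env_at(params, 0.0, 0.0), network, params)
    assert np.allclose(fluxes.to_numpy(), 0.0, atol=1e-12)


def test_no_oxygen_silences_terminal_oxidases(network, params):
    state = base_state(network, params)
    fluxes = evaluate_fluxes(state, env_at(params, 0.0, state["Q"]), network, params)
    assert fluxes["Cyo"] == 0.0 and fluxes["Cyd"] == 0.0


def test_fully_reduced_quinone_pool_stops_dehydrogenases(network, params):
    state = base_state(network, params)
    state["Q"] = 0.0  # QH2 at pool total
    fluxes = evaluate_fluxes(state, env_at(params, 0.0, 0.0), network, params)
    assert fluxes["Nuo"] == 0.0 and fluxes["Ndh"] == 0.0


def test_adh_increases_with_redox_ratio(network, params):
    state = base_state(network, params)
    env = env_at(params, 0.0, state["Q"])
    rates = []
    for nadh in (0.2, 0.6, 1.2):
        state["NADH"] = nadh * params["N_total"] / 2.0
        rates.append(evaluate_fluxes(state, env, network, params)["ADH"])
    assert rates[0] < rates[1] < rates[2]


def test_negative_concentration_raises(network, params):
    state = base_state(network, params)
    state["PYR"] = -1e-3
    with pytest.raises(ValueError, match="negative"):
        evaluate_fluxes(state, env_at(params, 40.0, state["Q"]), network, params)


def test_cyd_has_higher_oxygen_affinity_than_cyo(network, params):
    """At equal quinol, Cyd reaches half-maximal rate at a lower DO than Cyo.

    TF activities are held at zero so the pure oxygen response of each
    oxidase is measured (both curves are then monotone saturating in DO).
    """
    from aeroferm.regulation import do_percent_to_O2

    state = base_state(network, params)
    compiled = CompiledModel(network, params)
    dos = np.linspace(0.0, 100.0, 2001)
    cyo = np.empty_like(dos)
    cyd = np.empty_like(dos)
    for i, do in enumerate(dos):
        conc = compiled.concentration_array(state, do_percent_to_O2(do, params))
        v = compiled.fluxes(conc, 0.0, 0.0)
        cyo[i] = v[compiled.reaction_index["Cyo"]]
        cyd[i] = v[compiled.reaction_index["Cyd"]]
    assert (np.diff(cyo) > 0).all() and (np.diff(cyd) > 0).all()
    # half-saturation DO of each oxidase (vmax from its K via the MM form)
    half_cyo = np.interp(0.5, cyo / (cyo[-1] * (1 + params["K_Cyo_O2"] /
                                                do_percent_to_O2(100.0, params))), dos)
    half_cyd = np.interp(0.5, cyd / (cyd[-1] * (1 + params["K_Cyd_O2"] /
                                                do_percent_to_O2(100.0, params))), dos)
    assert half_cyd < half_cyo
    assert params["K_Cyd_O2"] < params["K_Cyo_O2"]
    assert params["vmax_Cyd"] < params["vmax_Cyo"]


def test_qour_definition():
    assert respiratory_o2_consumption({"Cyo": 0.0, "Cyd": 0.0}) == 0.0
    assert respiratory_o2_consumption({"Cyo": 4.0, "Cyd": 0.0}) == pytest.approx(2.0)
    assert respiratory_o2_consumption({"Cyo": 3.0, "Cyd": 1.0}) == pytest.approx(2.0)


def test_zero_tf_activity_reproduces_unregulated_model(network, params):
    """f(TF)=1 at zero activity: fluxes equal those of an edge-free network."""
    state = base_state(network, params)
    compiled = CompiledModel(network, params)
    bare = network.copy()
    bare.regulation_edges = []
    compiled_bare = CompiledModel(bare, params)
    conc = compiled.concentration_array(state, 0.002)
    assert np.allclose(
        compiled.fluxes(conc, 0.0, 0.0), compiled_bare.fluxes(conc, 0.0, 0.0), rtol=0, atol=0
    )


def test_fluxes_are_continuous_in_concentrations(network, params):
    """Finite-difference refinement scan: no hidden discontinuities.

    Under grid refinement the largest single-step flux change must shrink
    proportionally (it would stay O(1) across a genuine jump).
    """
    compiled = CompiledModel(network, params)
    state = base_state(network, params)
    env = env_at(params, 3.0, state["Q"])

    def max_jumps(species, n):
        grid = np.linspace(0.0, 2.0, n)
        vals = []
        for x in grid:
            s = dict(state)
            s[species] = x if species != "NADH" else min(x, params["N_total"])
            conc = compiled.concentration_array(s, env.O2_cyt)
            vals.append(compiled.fluxes(conc, env.TF_Fnr, env.TF_ArcA))
        return np.abs(np.diff(np.array(vals), axis=0)).max(axis=0)

    for species in ("PYR", "FBP", "PEP", "NADH", "AcCoA"):
        coarse = max_jumps(species, 401)
        fine = max_jumps(species, 1601)
        mask = coarse > 1e-9
        assert (fine[mask] < 0.3 * coarse[mask] + 1e-9).all(), species
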