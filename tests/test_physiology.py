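"""Derived specific rates against independent stoichiometric oracles."""

import numpy as np
import pytest

from aeroferm.physiology import (
    atp_rate,
    carbon_balance,
    co2_rate,
    growth_rate,
    nadh_rate,
    nadph_rate,
)


def random_fluxes(network, seed=0):
    rng = np.random.default_rng(seed)
    return {rid: float(v) for rid, v in zip(network.reactions, rng.uniform(-5, 15, len(network.reactions)))}


def stoich_row_oracle(network, species, fluxes):
    """Independent oracle: dot product of a species' stoichiometric row with the fluxes."""
    total = 0.0
    for rxn in network.reactions.values():
        total += rxn.stoichiometry.get(species, 0.0) * fluxes[rxn.id]
    return total


@pytest.mark.parametrize("seed", range(5))
def test_co2_rate_matches_stoichiometric_row(network, seed):
    fluxes = random_fluxes(network, seed)
    assert co2_rate(fluxes) == pytest.approx(
        stoich_row_oracle(network, "CO2", fluxes), rel=1e-12, abs=1e-12
    )


@pytest.mark.parametrize("seed", range(5))
def test_nadh_rate_matches_stoichiometric_row(network, seed):
    fluxes = random_fluxes(network, seed)
    net, _ = nadh_rate(fluxes)
    assert net == pytest.approx(stoich_row_oracle(network, "NADH", fluxes), rel=1e-12, abs=1e-12)


def test_nadh_breakdown_sums_to_net(network):
    fluxes = random_fluxes(network, 7)
    net, breakdown = nadh_rate(fluxes)
    assert sum(breakdown.values()) == pytest.approx(net, rel=1e-12, abs=1e-12)


class TestAtpRate:
    def test_all_zero(self):
        v_atp, op, _ = atp_rate({})
        assert v_atp == 0.0 and op == 0.0

    def test_oxidative_phosphorylation_coefficients(self):
        # one flux unit through each respiratory complex: OP = (4+4+2)/3
        v_atp, op, _ = atp_rate({"Nuo": 1.0, "Cyo": 1.0, "Cyd": 1.0})
        assert op == pytest.approx(10.0 / 3.0, rel=1e-12)
        assert v_atp == pytest.approx(op)

    def test_substrate_level_terms(self):
        fluxes = {"Nuo": 3.75, "L_Emp": 2.0, "Pyk": 1.0, "PTACK": 1.0, "aKGDH": 1.0,
                  "Glk": 1.0, "Pfk": 1.0}
        v_atp, op, breakdown = atp_rate(fluxes)
        assert op == pytest.approx(5.0)
        assert v_atp == pytest.approx(8.0)
        assert breakdown["Pfk"] == -1.0


class TestCo2Examples:
    def test_decarboxylation_sum(self):
        fluxes = {"PGDH": 1.0, "PDH": 2.0, "ICDH": 1.0, "aKGDH": 1.0, "Ppc": 1.0}
        assert co2_rate(fluxes) == pytest.approx(4.0)

    def test_net_fixation_is_negative(self):
        assert co2_rate({"Ppc": 2.0}) == pytest.approx(-2.0)


class TestNadph:
    def test_sum(self):
        assert nadph_rate({"G6PDH": 1.0, "PGDH": 1.0}) == pytest.approx(2.0)

    def test_non_negative_for_non_negative_fluxes(self, network):
        rng = np.random.default_rng(3)
        fluxes = {rid: float(abs(v)) for rid, v in
                  zip(network.reactions, rng.uniform(0, 10, len(network.reactions)))}
        assert nadph_rate(fluxes) >= 0.0


class TestGrowthRate:
    def test_zero_and_linear(self, params):
        assert growth_rate(0.0, params) == 0.0
        p = params.with_values(k_ATP=0.1)
        assert growth_rate(8.0, p) == pytest.approx(0.8)

    def test_floored_at_zero(self, params):
        assert growth_rate(-5.0, params) == 0.0

    def test_exact_linearity_along_trajectory(self, wt_aerobic_traj, params):
        frame = wt_aerobic_traj.frame
        expected = np.maximum(params["k_ATP"] * frame["v_ATP"].to_numpy(), 0.0)
        assert np.allclose(frame["mu"].to_numpy(), expected, rtol=0, atol=0)


class TestCarbonBalance:
    def test_closure_on_completed_batches(self, wt_aerobic_traj, wt_microaerobic_traj, network):
        for traj in (wt_aerobic_traj, wt_microaerobic_traj):
            fractions = carbon_balance(traj, network)
            assert abs(1.0 - fractions.sum()) < 1e-3

    def test_zero_length_trajectory(self, wt_aerobic_traj, network):
        import dataclasses

        stub = dataclasses.replace(wt_aerobic_traj, frame=wt_aerobic_traj.frame.iloc[:1])
        assert (carbon_balance(stub, network) == 0).all()

    def test_aerobic_balance_dominated_by_biomass_co2_acetate(self, wt_aerobic_traj, network):
        fractions = carbon_balance(wt_aerobic_traj, network)
        dominant = fractions[["biomass", "CO2", "acetate"]].sum()
        others = fractions[["lactate", "formate", "ethanol", "succinate"]].sum()
        assert dominant > others
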