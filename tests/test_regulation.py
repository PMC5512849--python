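"""Transcription-factor activities, oxygen mapping and vmax modulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aeroferm.network import RateLawSpec, ReactionSpec, RegulationEdge
from aeroferm.regulation import (
    RedoxEnvironment,
    arcA_activity,
    classify_condition,
    do_percent_to_O2,
    fnr_activity,
    hill_activity,
    modulate_vmax,
)
from aeroferm.strains import StrainSpec, apply_knockout


class TestOxygenMapping:
    def test_anaerobic_endpoint(self, params):
        assert do_percent_to_O2(0.0, params) == 0.0

    def test_saturation_endpoint(self, params):
        assert do_percent_to_O2(100.0, params) == pytest.approx(
            params["k_O2"] * params["DO2_star"]
        )

    def test_direct_substitution(self, params):
        # DO = 40%, k_O2 = 0.5, [DO2]* = 0.21 mM  ->  [O2] = 0.042 mM
        p = params.with_values(k_O2=0.5, DO2_star=0.21)
        assert do_percent_to_O2(40.0, p) == pytest.approx(0.042)

    @pytest.mark.parametrize("do", [-1.0, 101.0])
    def test_out_of_range_rejected(self, do, params):
        with pytest.raises(ValueError):
            do_percent_to_O2(do, params)


class TestHillActivities:
    def test_half_activity_at_affinity_constant(self):
        assert hill_activity(0.3, K=0.3, n=-4.0) == pytest.approx(0.5, abs=1e-12)

    def test_full_activity_at_zero(self):
        assert hill_activity(0.0, K=0.3, n=-4.0) == 1.0

    def test_asymptote(self):
        assert hill_activity(1e6, K=0.3, n=-4.0) < 1e-10

    def test_singularity_free_form_matches_literal_hill(self):
        """K^|n|/(K^|n|+x^|n|) agrees with x^n/(x^n+K^n) for x > 0."""
        K, n = 0.45, -3.7
        for x in np.geomspace(1e-8, 1e4, 200):
            literal = x**n / (x**n + K**n)
            assert hill_activity(x, K, n) == pytest.approx(literal, rel=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(
        K=st.floats(1e-6, 1e3),
        n=st.floats(-8.0, -0.5),
        x1=st.floats(0.0, 1e3),
        x2=st.floats(0.0, 1e3),
    )
    def test_bounded_and_strictly_decreasing(self, K, n, x1, x2):
        lo, hi = sorted((x1, x2))
        a_lo, a_hi = hill_activity(lo, K, n), hill_activity(hi, K, n)
        assert 0.0 <= a_hi <= a_lo <= 1.0
        if hi > lo:
            # strictly decreasing wherever floating point can resolve the
            # difference (deep in saturation both round to exactly 0 or 1)
            saturated = a_lo in (0.0, 1.0) and a_hi == a_lo
            assert a_hi < a_lo or saturated

    def test_doubling_from_K_drops_below_half(self, params):
        half = arcA_activity(params["K_ArcA"], params)
        assert half == pytest.approx(0.5, abs=1e-12)
        assert arcA_activity(2 * params["K_ArcA"], params) < 0.5

    def test_negative_argument_rejected(self, params):
        with pytest.raises(ValueError):
            fnr_activity(-0.1, params)

    def test_knockout_silences_activity_at_all_oxygen(self, network, params):
        _, ko = apply_knockout(network, params, StrainSpec.from_name("fnr"))
        for o2 in (0.0, 1e-4, 1e-2):
            assert fnr_activity(o2, ko) == 0.0


class TestVmaxModulation:
    def _reaction(self, gene=None):
        return ReactionSpec(
            id="R",
            stoichiometry={"PYR": -1},
            rate_law=RateLawSpec(form="mm", vmax="vmax_LDH", substrates=(("PYR", "K_LDH_PYR"),)),
            gene=gene,
        )

    def _env(self, params, fnr=0.0, arca=0.0):
        return RedoxEnvironment(
            DO_percent=0.0, DO_conc=0.0, O2_cyt=0.0, Q=0.0, TF_Fnr=fnr, TF_ArcA=arca
        )

    def test_unregulated_reaction_keeps_baseline(self, network, params):
        rxn = self._reaction(gene=None)
        v = modulate_vmax(rxn, self._env(params, fnr=1.0, arca=1.0), params, network)
        assert v == params["vmax_LDH"]

    def test_zero_activity_keeps_baseline(self, network, params):
        rxn = self._reaction(gene="pfl")
        v = modulate_vmax(rxn, self._env(params, fnr=0.0, arca=0.0), params, network)
        assert v == params[rxn.rate_law.vmax]

    def test_unit_repression_halves_vmax(self, network, params):
        net = network.copy()
        net.regulation_edges = [
            RegulationEdge(tf="Fnr", gene="demo", sign="repression", strength="r_demo")
        ]
        p = params.with_values(r_demo=1.0)
        rxn = self._reaction(gene="demo")
        v = modulate_vmax(rxn, self._env(p, fnr=1.0), p, net)
        assert v == pytest.approx(params["vmax_LDH"] / 2)


class TestConditionCategories:
    @pytest.mark.parametrize(
        "do,category",
        [(0, "I"), (3, "II"), (6.9, "II"), (7, "III"), (8, "III"), (19.9, "III"), (20, "IV"), (40, "IV")],
    )
    def test_boundaries(self, do, category):
        assert classify_condition(do) == category

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_condition(-0.1)
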