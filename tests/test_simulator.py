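"""Batch integration: events, conservation, convergence, determinism."""

import numpy as np
import pandas as pd
import pytest

from aeroferm import CultivationProtocol, DOSchedule, StrainSpec, simulate_batch
from aeroferm.simulator import BatchSystem, products_at_depletion
from conftest import batch


def test_zero_glucose_depletes_immediately(network, params):
    traj = batch(glucose=0.005)
    assert traj.depleted and traj.t_dep == 0.0
    assert (products_at_depletion(traj) == 0).all()


def test_zero_biomass_freezes_medium(wt_system):
    protocol = CultivationProtocol(biomass_0=0.0)
    y0 = wt_system.initial_state(protocol)
    dy = wt_system.rhs(0.0, y0, o2=0.002, tf_fnr=0.0)
    assert np.allclose(dy[: wt_system.n_ex], 0.0)
    assert dy[wt_system.x_slot] == 0.0


def test_no_glucose_means_no_uptake(wt_system):
    protocol = CultivationProtocol(glucose_0=0.02)
    y0 = wt_system.initial_state(protocol)
    y0[wt_system.ex_ids.index("GLC")] = 0.0
    dy = wt_system.rhs(0.0, y0, o2=0.002, tf_fnr=0.0)
    assert dy[wt_system.ex_ids.index("GLC")] == pytest.approx(0.0, abs=1e-12)


def test_pool_rows_sum_to_zero_analytically(wt_system):
    """d(NADH+NAD)/dt and d(Q+QH2)/dt vanish identically from stoichiometry."""
    comp = wt_system.compiled
    for pool in wt_system.network.conserved_pools:
        rows = [comp.species_index[m] for m in pool.members]
        assert np.allclose(comp.S[rows, :].sum(axis=0), 0.0)


def test_pool_conservation_along_trajectory(wt_microaerobic_traj, params):
    frame = wt_microaerobic_traj.frame
    nad_sum = frame["NADH"] + frame["NAD"]
    q_sum = frame["Q"] + frame["QH2"]
    assert np.max(np.abs(nad_sum - params["N_total"])) < 1e-6 * params["N_total"]
    assert np.max(np.abs(q_sum - params["Q_total"])) < 1e-6 * params["Q_total"]
    assert frame[["NADH", "NAD", "Q", "QH2"]].min().min() > -1e-9


def test_event_location_accuracy(wt_aerobic_traj):
    final_glc = wt_aerobic_traj.final_state["GLC"]
    assert final_glc == pytest.approx(wt_aerobic_traj.protocol.glc_threshold, abs=1e-6)


def test_more_inoculum_depletes_faster():
    slow = batch(glucose=4.0, biomass=0.1)
    fast = batch(glucose=4.0, biomass=0.2)
    assert fast.t_dep < slow.t_dep


def test_tolerance_convergence():
    coarse = batch("WT", 3.0, glucose=4.0)
    fine = batch("WT", 3.0, glucose=4.0, rtol=0.5e-7, atol=0.5e-10)
    p1 = products_at_depletion(coarse)
    p2 = products_at_depletion(fine)
    rel = np.abs(p1 - p2) / np.maximum(np.abs(p2), 1e-6)
    assert rel.max() < 1e-4


def test_determinism_bit_identical():
    a = batch("WT", 8.0, glucose=3.0)
    b = batch("WT", 8.0, glucose=3.0)
    pd.testing.assert_frame_equal(a.frame, b.frame, rtol=0, atol=0)


def test_dual_phase_zero_switch_degenerates_to_constant():
    const = batch("pfl", 1.0, glucose=3.0)
    dual = batch("pfl", DOSchedule.dual_phase(40.0, 1.0, 0.0), glucose=3.0)
    pd.testing.assert_frame_equal(const.frame, dual.frame, rtol=0, atol=0)


def test_do_switch_is_applied():
    traj = batch("WT", DOSchedule.dual_phase(40.0, 1.0, 2.0), glucose=6.0)
    frame = traj.frame
    assert (frame.loc[frame["time"] < 2.0, "DO_percent"] == 40.0).all()
    assert (frame.loc[frame["time"] > 2.0, "DO_percent"] == 1.0).all()


def test_products_require_depletion():
    stalled = batch("WT", 1.0, glucose=10.0, biomass=0.001, t_max=0.5)
    assert not stalled.depleted
    with pytest.raises(ValueError):
        products_at_depletion(stalled)


def test_manifest_round_trip(wt_aerobic_traj, tmp_path):
    import json

    wt_aerobic_traj.write(tmp_path)
    manifest = json.loads((tmp_path / "manifest.json").read_text())
    assert manifest["depleted"] is True
    assert manifest["protocol"]["strain"] == "WT"
    frame = pd.read_csv(tmp_path / "trajectory.csv")
    assert {"time", "GLC", "X", "TF_Fnr", "TF_ArcA", "v_Pfl"} <= set(frame.columns)


class TestDOSchedule:
    def test_piecewise_lookup(self):
        sched = DOSchedule(((0.0, 40.0), (3.0, 1.0)))
        assert sched.do_at(0.0) == 40.0
        assert sched.do_at(2.999) == 40.0
        assert sched.do_at(3.0) == 1.0

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            DOSchedule(((1.0, 40.0),))  # must start at t=0
        with pytest.raises(ValueError):
            DOSchedule(((0.0, 40.0), (0.0, 1.0)))
        with pytest.raises(ValueError):
            DOSchedule.dual_phase(40.0, 1.0, -1.0)
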