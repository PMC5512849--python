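"""The 3-metabolite toy pathway and its closed-form steady state.

S -> A -> B -> P with a conserved cofactor pair and a TF-activated first
step. The analytic fixed point makes it an oracle for the kinetics engine
and the stiff integrator: the simulated long-time state must match the
formulas to 1e-8 even when the cofactor cycle is 1000x faster than the
pathway.
"""

import aeroferm as af
from aeroferm.fixtures import make_toy

for stiffness in (1.0, 1000.0):
    network, params, analytic = make_toy(stiffness=stiffness)
    protocol = af.CultivationProtocol(glucose_0=50.0, biomass_0=1.0,
                                      do_schedule=af.DOSchedule.constant(100.0),
                                      t_max=500.0)
    traj = af.simulate_batch(protocol, network, params,
                             clamp_extracellular=True, rtol=1e-11, atol=1e-13)
    final = traj.final_state
    print(f"\nstiffness x{stiffness:.0f}")
    for name, expected in (("A", analytic.A), ("B", analytic.B), ("COX", analytic.COX)):
        got = final[name]
        print(f"  {name}: simulated {got:.10f}  analytic {expected:.10f}  "
              f"rel err {abs(got-expected)/expected:.1e}")
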