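"""One batch culture: aerobic vs micro-aerobic product spectra.

Runs the wild-type strain on 10 g/l glucose at DO 40% (aerobic) and DO 1%
(micro-aerobic) and prints the fermentation products at glucose depletion.
Aerobically, most carbon goes to biomass and CO2 with acetate overflow;
micro-aerobically the mixed-acid pattern appears and lactate stays lowest.
"""

import aeroferm as af

for do in (40.0, 1.0):
    protocol = af.CultivationProtocol(do_schedule=af.DOSchedule.constant(do))
    traj = af.simulate_batch(protocol)
    products = af.products_at_depletion(traj)
    balance = af.carbon_balance(traj, traj.network)
    print(f"\nDO = {do:.0f}% ({traj.final_state['DO_percent']:.0f}% setpoint, "
          f"condition {af.classify_condition(do)})")
    print(f"  glucose depleted at t = {traj.t_dep:.2f} h, "
          f"final biomass {traj.final_state['X']:.2f} gDW/l")
    print("  products (g/l):", ", ".join(f"{k}={v:.2f}" for k, v in products.items()))
    print("  carbon fractions:", ", ".join(f"{k}={v:.2f}" for k, v in balance.items()))
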