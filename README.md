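# aeroferm

Kinetic simulation of *Escherichia coli* batch fermentation across dissolved
oxygen (DO) levels, with redox regulation by the transcription factors Fnr
and ArcA.

*E. coli* shifts between respiration, mixed-acid fermentation and everything
in between depending on how much oxygen the culture sees. That shift decides
which products accumulate — acetate under aerobic overflow; formate, ethanol,
lactate and succinate as oxygen runs out — and it is the design space for
microbial production of reduced chemicals: grow cells fast with air, then
throttle oxygen to make product. `aeroferm` is for metabolic engineers and
modelers who want to explore that space in silico: it predicts batch-culture
time courses, product spectra at glucose depletion, the behavior of
regulator knockouts (Δ*fnr*, Δ*arcA*) and producer strains (Δ*pfl*), and
dual-phase (aerobic → micro-aerobic) cultivation designs.

## Model

A stiff ODE system couples:

* **Central carbon metabolism** — PTS/non-PTS uptake, glycolysis (lumped
  GAPDH→enolase segment `L_Emp`), pentose phosphate pathway, TCA cycle,
  glyoxylate shunt, anaplerosis, and the fermentative branches (LDH, Pfl,
  ALDH/ADH, Pta–Ack, Acs, Frd), with the classical enzyme-level effectors
  (FBP → Pyk, Ppc; PEP ⊣ Pfk; O₂ ⊣ Pfl; pyruvate-cooperative LDH).
* **Respiratory chain** — NADH dehydrogenases Nuo/Ndh reduce a conserved
  quinone pool; terminal oxidases Cyo (low O₂ affinity, high rate) and Cyd
  (high affinity, low rate) reoxidize it.
* **Redox regulation** — TF activities are Hill functions with negative
  coefficient *n*: `TF_Fnr = [O₂]ⁿ/([O₂]ⁿ+K_Fnrⁿ)` on cytoplasmic oxygen,
  `TF_ArcA = [Q]ⁿ/([Q]ⁿ+K_ArcAⁿ)` on oxidized quinone; each regulated
  reaction's maximal rate is scaled, `v_max = v_max′·f(TF)`.
* **Physiology** — `OP = (4v_Nuo + 4v_Cyo + 2v_Cyd)/3`;
  `v_ATP = OP + v_L_Emp + v_Pyk + v_PTACK + v_αKGDH − v_Glk − v_Pfk − v_Pps
  − v_Pck − v_Acs`; growth `μ = k_ATP·v_ATP`; stoichiometric CO₂/NADPH/NADH
  rates and whole-culture carbon balances.

DO is a setpoint in % of air saturation (`[O₂] = k_O₂·(DO/100)·[DO₂]*`),
constant or switched at a chosen time. See `docs/methods.md` for the full
model description, parameter provenance and limitations.

## Worked example

```python
import aeroferm as af

protocol = af.CultivationProtocol(          # 10 g/l glucose, 0.1 gDW/l inoculum
    do_schedule=af.DOSchedule.constant(1.0) # micro-aerobic: DO = 1%
)
traj = af.simulate_batch(protocol)
print(f"glucose depleted at {traj.t_dep:.1f} h")
print(af.products_at_depletion(traj).round(2))
```

prints

```
glucose depleted at 13.6 h
ACE    2.32
LAC    0.00
FOR    4.35
ETH    2.24
SUC    0.07
```

— the classic mixed-acid pattern at DO 1%: formate, acetate and ethanol
dominate, lactate is the least abundant product (its pyruvate is consumed by
the Fnr/ArcA-activated pyruvate formate-lyase), and some succinate is formed
through the reductive TCA arm. Rerunning at `DOSchedule.constant(40.0)`
gives an aerobic culture that finishes in ~7.6 h with acetate as the primary
product (1.70 g/l) and little else.

The same API drives the in-silico experiments: `do_sweep` (product spectrum
vs DO for any strain), `find_peak` (e.g. the Δ*fnr* lactate maximum near 2–3%
DO), and `dual_phase_scan` (lactate yield/productivity of a Δ*pfl* producer
versus the aerobic→micro-aerobic switching time). Short narrative scripts in
`examples/` show each capability; a thin CLI (`aeroferm simulate|sweep|dualphase`)
wraps the same functions for shell use.

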