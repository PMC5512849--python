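# Methods

## Model overview

`aeroferm` simulates batch cultures of *Escherichia coli* on glucose with a
kinetic model of central carbon metabolism whose enzyme levels respond to
oxygen through the transcription factors **Fnr** (direct O₂ sensing) and
**ArcA** (quinone-pool sensing via the ArcB kinase).  The network comprises
glucose transport (PTS and a lumped non-PTS/glucokinase route), glycolysis
(with a lumped GAPDH→enolase segment, `L_Emp`), the pentose phosphate
pathway, the TCA cycle and glyoxylate shunt, anaplerosis (Ppc, Pck, Mez),
the fermentative branches (LDH; Pfl; ALDH/ADH to ethanol; lumped Pta–Ack to
acetate; Acs re-uptake; Frd to succinate) and a respiratory chain coupled to
a conserved quinone pool (NADH dehydrogenases Nuo and Ndh reduce Q to QH₂;
terminal oxidases Cyo and Cyd reoxidize QH₂ with Michaelis–Menten oxygen
dependence).  All respiratory fluxes are expressed per two-electron transfer.

Dynamic state: extracellular glucose, five fermentation products and biomass
(g/l, gDW/l); intracellular metabolites (mmol/gDW); the reduced halves of
the conserved NADH/NAD⁺ and Q/QH₂ pools.  Dissolved oxygen is a controlled
boundary condition expressed as % of air saturation at 37 °C
(`[DO₂] = DO%/100 · [DO₂]*`), and cytoplasmic oxygen is the scaled algebraic
value `[O₂] = k_O₂·[DO₂]` — there is no oxygen mass-transfer ODE, matching
the setpoint-style in-silico experiments the package performs.

## Regulation

TF activities are instantaneous Hill functions with a shared negative
coefficient *n*:

    TF_Fnr = [O₂]ⁿ/([O₂]ⁿ + K_Fnrⁿ),   TF_ArcA = [Q]ⁿ/([Q]ⁿ + K_ArcAⁿ)

evaluated through the singularity-free equivalent `K^|n|/(K^|n| + x^|n|)`
(identical for x > 0, continuous at x = 0).  Effective maximal rates are
`v_max = v_max′·f(TF)` with one factor per regulation edge: `(1 + a·TF)` for
activation, `1/(1 + r·TF)` for repression; `f(0) = 1`, so with no TF
activity the unregulated model is recovered exactly.  The edge table encodes
the canonical circuit: ArcA represses *cyoABCD*, *aceEF* and the TCA-cycle
genes and activates *cydAB* and *pfl*; Fnr activates *frdABCD* and *pfl* and
represses *cydAB*, the NADH dehydrogenases and the TCA-cycle genes.

Two enzyme-level mechanisms supplement transcriptional control and are
essential to the knockout phenotypes: Pfl activity is inhibited by oxygen
(its glycyl radical is O₂-labile), implemented as `1/(1 + [O₂]/K)`; and LDH
is cooperatively activated by its substrate pyruvate (Hill exponent 2 on
PYR), reflecting the homotropic activation of LdhA.  Without these, the
fnr-knockout — in which ArcA saturates at every micro-aerobic DO — shows no
interior lactate peak.

## Physiology

Specific rates are stoichiometric sums over the flux vector: ATP combines
oxidative phosphorylation `OP = (4·v_Nuo + 4·v_Cyo + 2·v_Cyd)/3` (H⁺/e⁻ of
2, 2, 1; H⁺/ATP = 3) with substrate-level terms
(+L_Emp +Pyk +PTACK +αKGDH −Glk −Pfk −Pps −Pck −Acs); CO₂, NADPH and NADH
rates are the corresponding decarboxylation/reduction sums.  Growth is
strictly ATP-coupled, μ = k_ATP·v_ATP (floored at zero); there is no
maintenance term and no independent biomass equation.  NADPH is a
diagnostic output only — no consumption side is modeled and it does not
enter the ODE state.

Biomass formation drains precursors (G6P, F6P, R5P, E4P, GAP, PEP, PYR,
AcCoA, OAA, AKG) in standard proportions, rescaled so the carbon-weighted
sum equals the biomass carbon-content parameter (0.48 gC/gDW).  Each drain
saturates as `C/(C + K_drain)` near empty pools so it cannot drive a
concentration negative; the carbon actually drained is integrated alongside
the state and used as the biomass sink of the carbon balance, which
therefore closes to integrator accuracy by construction.  This is a
deliberate design choice: a growth-rate-proportional precursor drain is the
minimal mechanism that makes whole-culture carbon accounting exact while
keeping growth itself ATP-coupled.

The SDH/Frd electron legs are *not* routed through the modeled quinone
pool: only Nuo/Ndh reduce and Cyo/Cyd oxidize Q/QH₂, so at a quasi-steady
quinone pool `v_Nuo + v_Ndh = v_Cyo + v_Cyd` holds identically, consistent
with the OP formula counting only Nuo/Cyo/Cyd and with the NADH balance
carrying no SDH/Frd term.  Frd is modeled as a TF-gated fumarate→succinate
step whose reducing equivalents are implicit.

## Rate laws and parameters

All rate laws are declared in the network file and compiled to vectorized
evaluators: irreversible multiplicative Michaelis–Menten (optionally with a
Hill exponent per substrate), reversible MM with a mass-action-ratio
numerator (Pgi, Fum, MDH, pentose-phosphate interconversions), the bounded
PTS factor `PEP/(PEP + K·PYR)`, and activation/inhibition modifiers (FBP
feed-forward on Pyk and Ppc; PEP feedback on Pfk; O₂ on Pfl).  Deliberately
absent, as modeling choices: NADH allosteric inhibition of PDH/CS/ICDH, and
acetyl-CoA/malate/aspartate effects on Ppc.

The shipped parameter table (`data/ecoli_params.csv`) is a curated set,
every entry flagged `provenance: refit`: saturation constants are
order-of-magnitude literature-typical values and maximal rates, regulation
strengths, Hill constants (K_Fnr = 6.3·10⁻⁴ mM ≈ 3% DO; K_ArcA at half the
quinone pool; n = −4) and k_ATP were calibrated once against the qualitative
and headline quantitative behaviors the model is meant to reproduce: the
wild-type product spectrum across DO (acetate dominant aerobically; formate,
ethanol and succinate rising toward anaerobiosis; lactate least abundant
below 2% DO), the knockout lactate peaks (fnr ≈ 2–3% DO, arcA ≈ 4% DO),
elevated arcA ethanol, absent fnr succinate, and the dual-phase design
numbers.  Default study conditions: 10 g/l glucose, 0.1 gDW/l inoculum.

## Numerics

The ODE system is stiff (fast cofactor pools against slow batch dynamics)
and is integrated with SciPy's BDF method at rtol 10⁻⁷ / atol 10⁻¹⁰.
Glucose depletion (threshold 0.01 g/l) is located by the solver's event
root-finder; DO switches restart the integration at the discontinuity, so
the piecewise protocol is handled exactly.  Concentrations are never
clipped; trajectories are rejected if any state falls below −10⁻⁹.  The
cumulative CO₂ integral may legitimately run negative under net anaplerotic
fixation.  Everything is deterministic — identical inputs give bit-identical
outputs — and the toy 3-metabolite pathway with closed-form steady state
(`aeroferm.fixtures.make_toy`) gates any refactor of the kinetics engine or
solver settings at 10⁻⁸ relative accuracy, including a ×1000 stiffness ramp.

## Known limitations

* The dual-phase productivity pair is only partially reproduced.  Because
  growth is strictly ATP-coupled with no maintenance energy, the ratio of
  aerobic to micro-aerobic biomass yield is pinned to the ATP-per-glucose
  ratio (≈ 7 : 2 here), which caps the achievable ratio of optimal-switch to
  micro-aerobic-throughout lactate productivity at ≈ 1.6–1.7.  The shipped
  calibration gives 0.40 g/l/h for micro-aerobic-throughout cultivation and
  an interior optimum at exactly 4.5 h of aerobic growth, but the optimum
  productivity is 0.64 g/l/h rather than ≈ 0.8; reproducing both endpoints
  simultaneously would require an additional ATP cost specific to slow
  growth (i.e., maintenance), which is outside this model's scope.
* Batch culture only: no fed-batch, pH, temperature or osmotic effects;
  oxygen is a setpoint, not a transported species, so phenomena driven by
  volumetric oxygen transfer (k_La) limits at high cell density are absent.
* The synthetic calibration targets are model behaviors, not measurements;
  agreement of the test suite says the implementation realizes this model
  faithfully, not that the model quantitatively predicts any particular
  fermentor run.
* The arcA knockout's NADH/NAD⁺ ratio runs very high under anaerobiosis —
  expected, since the NADH feedback inhibitions on PDH/CS/ICDH are
  deliberately not modeled.
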