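symbol,value,units,provenance
DO2_star,0.21,mM,refit (saturated DO at 37 C)
K_ADH_ACAL,0.1,mmol/gDW,refit
K_ADH_NADH,0.8,mmol/gDW,refit
K_ALDH_AcCoA,0.3,mmol/gDW,refit
K_ALDH_NADH,0.8,mmol/gDW,refit
K_Acs_ACE,0.3,g/l,refit
K_ArcA,0.5,mmol/gDW,refit (ArcA quinone affinity)
K_CS_AcCoA,0.2,mmol/gDW,refit
K_CS_OAA,0.03,mmol/gDW,refit
K_Cyd_O2,0.004,mM,refit
K_Cyd_QH2,0.15,mmol/gDW,refit
K_Cyo_O2,0.0063,mM,refit
K_Cyo_QH2,0.15,mmol/gDW,refit
K_Fba_FBP,0.2,mmol/gDW,refit
K_Fbp_FBP,0.5,mmol/gDW,refit
K_Fnr,0.00063,mM,refit (Fnr O2 affinity)
K_Frd_FUM,0.3,mmol/gDW,refit
K_Fum_FUM,0.1,mmol/gDW,refit
K_Fum_MAL,0.1,mmol/gDW,refit
K_G6PDH_G6P,0.2,mmol/gDW,refit
K_Glk_GLCin,0.1,mmol/gDW,refit
K_ICDH_CIT,0.06,mmol/gDW,refit
K_Icl_CIT,0.6,mmol/gDW,refit
K_LDH_NADH,0.45,mmol/gDW,refit
K_LDH_PYR,1.5,mmol/gDW,refit
K_L_Emp_GAP,0.2,mmol/gDW,refit
K_L_Emp_NAD,0.05,mmol/gDW,refit
K_MDH_MAL,0.15,mmol/gDW,refit
K_MDH_NAD,0.2,mmol/gDW,refit
K_MDH_NADH,0.2,mmol/gDW,refit
K_MDH_OAA,0.04,mmol/gDW,refit
K_MS_AcCoA,0.2,mmol/gDW,refit
K_MS_GOX,0.2,mmol/gDW,refit
K_Mez_MAL,0.4,mmol/gDW,refit
K_Ndh_NADH,0.3,mmol/gDW,refit
K_Ndh_Q,0.15,mmol/gDW,refit
K_Nuo_NADH,0.25,mmol/gDW,refit
K_Nuo_Q,0.12,mmol/gDW,refit
K_PDH_NAD,0.06,mmol/gDW,refit
K_PDH_PYR,0.25,mmol/gDW,refit
K_PGDH_PG6,0.2,mmol/gDW,refit
K_PTACK_AcCoA,0.2,mmol/gDW,refit
K_PTS_GLC,0.05,g/l,refit
K_PTS_ratio,0.05,-,refit (PEP/PYR ratio constant)
K_Pck_OAA,0.3,mmol/gDW,refit
K_Pfk_F6P,0.15,mmol/gDW,refit
K_Pfk_PEPi,1.5,mmol/gDW,refit (PEP feedback inhibition)
K_Pfl_O2i,0.00045,mM,refit (O2 inactivation of the Pfl glycyl radical)
K_Pfl_PYR,0.35,mmol/gDW,refit
K_Pgi_F6P,0.5,mmol/gDW,refit
K_Pgi_G6P,0.5,mmol/gDW,refit
K_Ppc_FBPa,0.2,mmol/gDW,refit
K_Ppc_PEP,0.3,mmol/gDW,refit
K_Pps_PYR,2.0,mmol/gDW,refit
K_Pyk_FBPa,0.2,mmol/gDW,refit
K_Pyk_PEP,0.3,mmol/gDW,refit
K_Rpe_RU5P,0.3,mmol/gDW,refit
K_Rpe_X5P,0.3,mmol/gDW,refit
K_Rpi_R5P,0.3,mmol/gDW,refit
K_Rpi_RU5P,0.3,mmol/gDW,refit
K_SDH_SUCin,0.06,mmol/gDW,refit
K_Tal_E4P,0.3,mmol/gDW,refit
K_Tal_F6P,0.3,mmol/gDW,refit
K_Tal_GAP,0.3,mmol/gDW,refit
K_Tal_S7P,0.3,mmol/gDW,refit
K_TktA_GAP,0.3,mmol/gDW,refit
K_TktA_R5P,0.3,mmol/gDW,refit
K_TktA_S7P,0.3,mmol/gDW,refit
K_TktA_X5P,0.3,mmol/gDW,refit
K_TktB_E4P,0.3,mmol/gDW,refit
K_TktB_F6P,0.3,mmol/gDW,refit
K_TktB_GAP,0.3,mmol/gDW,refit
K_TktB_X5P,0.3,mmol/gDW,refit
K_aKGDH_AKG,0.06,mmol/gDW,refit
K_aKGDH_NAD,0.15,mmol/gDW,refit
K_npts_GLC,0.2,g/l,refit
Keq_Fum,4.0,-,refit
Keq_MDH,1.0,-,refit (normalized)
Keq_Pgi,0.4,-,refit
Keq_Rpe,1.4,-,refit
Keq_Rpi,1.0,-,refit
Keq_Tal,1.05,-,refit
Keq_TktA,1.2,-,refit
Keq_TktB,1.2,-,refit
N_total,2.0,mmol/gDW,refit (NAD(H) pool total)
Q_total,1.0,mmol/gDW,refit (quinone pool total)
X_carbon,0.48,gC/gDW,refit (biomass carbon content)
a_ArcA_cydAB,0.8,-,refit
a_ArcA_pfl,45.0,-,refit
a_Fnr_frdABCD,15.0,-,refit
a_Fnr_pfl,120.0,-,refit
beta_Ppc_FBP,3.0,-,refit (FBP feed-forward activation)
beta_Pyk_FBP,2.0,-,refit (FBP feed-forward activation)
drain_K,0.01,mmol/gDW,refit (precursor-drain saturation)
h_LDH_PYR,2.0,-,refit (pyruvate cooperativity)
h_Pps_PYR,3.0,-,refit (pyruvate cooperativity)
k_ATP,0.0055,gDW/mmol,refit (growth yield on ATP)
k_O2,0.1,-,refit (cytoplasmic O2 scaling)
n_hill,-4.0,-,refit (shared negative Hill coefficient)
r_ArcA_aceEF,14.0,-,refit
r_ArcA_cyoABCD,2.5,-,refit
r_ArcA_gltA,2.5,-,refit
r_ArcA_icd,2.5,-,refit
r_ArcA_sdhCDAB,2.5,-,refit
r_ArcA_sucAB,2.5,-,refit
r_Fnr_cydAB,1.5,-,refit
r_Fnr_gltA,2.5,-,refit
r_Fnr_icd,2.5,-,refit
r_Fnr_ndh,2.5,-,refit
r_Fnr_nuo,2.0,-,refit
r_Fnr_sdhCDAB,2.5,-,refit
r_Fnr_sucAB,2.5,-,refit
vmax_ADH,120.0,mmol/gDW/h,refit
vmax_ALDH,90.0,mmol/gDW/h,refit
vmax_Acs,0.7,mmol/gDW/h,refit
vmax_CS,24.0,mmol/gDW/h,refit
vmax_Cyd,25.6,mmol/gDW/h,"refit (2e- units; high O2 affinity, low rate)"
vmax_Cyo,144.0,mmol/gDW/h,"refit (2e- units; low O2 affinity, high rate)"
vmax_Fba,30.0,mmol/gDW/h,refit
vmax_Fbp,0.2,mmol/gDW/h,refit
vmax_Frd,0.06,mmol/gDW/h,"refit (baseline, Fnr-activated)"
vmax_Fum,25.0,mmol/gDW/h,refit
vmax_G6PDH,0.8,mmol/gDW/h,refit
vmax_Glk,3.0,mmol/gDW/h,refit
vmax_ICDH,30.0,mmol/gDW/h,refit
vmax_Icl,1.0,mmol/gDW/h,refit
vmax_LDH,80.0,mmol/gDW/h,refit
vmax_L_Emp,60.0,mmol/gDW/h,refit
vmax_MDH,25.0,mmol/gDW/h,refit
vmax_MS,2.0,mmol/gDW/h,refit
vmax_Mez,0.15,mmol/gDW/h,refit
vmax_Ndh,25.0,mmol/gDW/h,refit (2e- units)
vmax_Nuo,208.0,mmol/gDW/h,refit (2e- units)
vmax_PDH,30.0,mmol/gDW/h,refit
vmax_PGDH,0.8,mmol/gDW/h,refit
vmax_PTACK,16.0,mmol/gDW/h,refit
vmax_PTS,11.0,mmol/gDW/h,refit
vmax_Pck,5.0,mmol/gDW/h,refit
vmax_Pfk,14.0,mmol/gDW/h,refit
vmax_Pfl,0.3,mmol/gDW/h,"refit (baseline, strongly TF-activated)"
vmax_Pgi,40.0,mmol/gDW/h,refit
vmax_Ppc,4.5,mmol/gDW/h,refit
vmax_Pps,4.0,mmol/gDW/h,refit
vmax_Pyk,18.0,mmol/gDW/h,refit
vmax_Rpe,15.0,mmol/gDW/h,refit
vmax_Rpi,15.0,mmol/gDW/h,refit
vmax_SDH,26.0,mmol/gDW/h,refit
vmax_Tal,10.0,mmol/gDW/h,refit
vmax_TktA,10.0,mmol/gDW/h,refit
vmax_TktB,10.0,mmol/gDW/h,refit
vmax_aKGDH,28.0,mmol/gDW/h,refit
vmax_npts,1.0,mmol/gDW/h,refit
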