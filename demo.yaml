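# End-to-end demo on synthetic data: three polymer chemistries, an ITC
# titration, a Laurdan emission spectrum and a Raman softening/splitting
# analysis. Any block may be set to null to skip the stage.
seed: 1
outdir: memint_out
log_level: INFO

md:
  kinds: [amide, ester, hexyl]
  hbond: {d_max: 4.0, a_max: 60.0}
  rdf: {r_max: 12.0, dr: 0.1}
  energy: {cutoff: 12.0, switch_on: 10.0}
  density_grid_spacing: 8.0

itc:
  n_injections: 40
  Ka_per_M: 1.0e6
  dH_kcal_per_mol: 2.5
  n_sites: 1.0
  noise_sd_ucal: 0.05

gp:
  i440: 600.0
  i490: 400.0

raman:
  doublet_window: [1078.0, 1114.0]
  softening_cm1: -4.0
  onset_C: 36.0
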