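# NFAT futile-cycle defaults (concentrations µM, times s).
#
# Rate constants are the composite-pathway fitted values.  PROVENANCE of
# the pool sizes: synthetic — the pathway description never prints the
# source model's NFAT or calcineurin pools, so N_tot and the initial
# (all phosphorylated, cytosolic) NFAT pool are package defaults chosen
# to keep the composite's predicted cytokines at a sub-µM scale.
values:
  kf_21: 0.0516   # µM⁻¹·s⁻¹, NFATp_c dephosphorylation by active CaN
  kr_21: 2.0772   # s⁻¹, reverse (inactive CaN) term
  kf_22: 0.0030   # s⁻¹, nuclear import of dephosphorylated NFAT
  kf_23: 0.0022   # s⁻¹, nuclear rephosphorylation
  kr_23: 0.3345   # µM⁻¹·s⁻¹, reverse rephosphorylation (active CaN)
  kf_24: 0.9844   # s⁻¹, nuclear export of phosphorylated NFAT
  N_tot: 1.0      # µM, total calcineurin (synthetic default)
  act_N: 0.5      # initial / clamped active-CaN fraction
pool_uM: 0.01     # total NFAT, initially NFATp_c (synthetic default)
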