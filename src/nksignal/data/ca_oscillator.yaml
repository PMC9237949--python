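# Ca²⁺ oscillator constants (concentrations µM, times s).
#
# PROVENANCE: synthetic reconstruction.  The pathway description prints
# only the cytosolic-Ca²⁺ balance equation; the remaining receptor-gate and
# IP3-turnover constants of the source oscillator live in an external model
# repository that is not redistributed here.  The values below are the
# standard two-gate IP3-receptor reduction constants plus IP3-turnover
# rates chosen once to place the model in its physiological oscillatory
# regime (sub-µM Ca²⁺ spikes, ~0.4 µM IP3, period of tens of seconds).
# Every value can be overridden through CaParams or run-time overrides.
values:
  k_1: 6.0        # s⁻¹, store→cytosol release scale
  b: 0.0183       # dimensionless basal leak fraction
  alpha: 0.185    # store/cytosol volume ratio
  VMP: 0.9        # µM·s⁻¹, max SERCA pump velocity
  Kp: 0.1         # µM, pump half-activation
  np: 2.0         # pump Hill coefficient
  Catot: 2.0      # µM, total exchangeable Ca²⁺ (closed cell)
  d1: 0.13        # µM, IP3 binding constant of the receptor
  d2: 1.049       # µM, Ca²⁺ inactivation constant
  d3: 0.9434      # µM, IP3 dependence of inactivation
  d5: 0.08234     # µM, Ca²⁺ activation constant
  a2: 0.2         # µM⁻¹·s⁻¹, inactivation gate rate
  tau_a: 0.2      # s, relaxation time of the active channel fraction
  Vplc: 0.03      # µM·s⁻¹, maximal PLC-driven IP3 synthesis
  stimulus: 1.0   # dimensionless PLC activity scaling (input port)
  V3k: 0.3        # µM·s⁻¹, maximal IP3 3-kinase velocity (zero in variant)
  K3k: 0.4        # µM, Ca²⁺ half-activation of the 3-kinase
  Km3: 1.0        # µM, IP3 Michaelis constant of the 3-kinase
  r5p: 0.05       # s⁻¹, IP3 5-phosphatase rate
  r4p: 0.05       # s⁻¹, IP4 degradation rate
initial_conditions:
  Ccyto: 0.1      # µM
  Ira: 0.01       # dimensionless
  h_gate: 0.8     # dimensionless
  IP4: 0.0        # µM; IP3 starts at its synthesis/degradation balance
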