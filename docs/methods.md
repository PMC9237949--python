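# Methods

## Scope and modelling frame

`nksignal` models the activation of peripheral-blood NK cells through the
KIR2DL4 receptor by soluble HLA-G, down to the production and release of
IFNγ and TNFα. Everything is deterministic mass-action/Hill kinetics in a
single well-mixed compartment picture: concentrations in µM, time in s,
unimolecular constants in s⁻¹, bimolecular in µM⁻¹·s⁻¹. Compartments
(cytosol vs nucleus, stores vs cytosol) appear as distinct species and
volume-ratio parameters, not as explicit geometry.

The package is organised around *composition*: each sub-model is
self-contained (species, parameters, reactions, named ports), and a
composite is produced by flattening sub-models wired through port
mappings. Identity mappings merge two species into one shared state;
flux couplings make a target parameter track `gain × [source species]`
at every instant. Parameters are namespaced `submodel/symbol` because
symbol names recur across components (there are two distinct `k_f2`:
`FCepsilonRI/k_f2` and `PI3K/k_f2`). Composition preserves reaction
count, and a sub-model simulated standalone or inside a composite with
no interacting mappings gives identical trajectories — both properties
are under test.

## The FCεRIγ cascade

The receptor module deliberately avoids the combinatorial receptor-state
expansion used in earlier detailed models (hundreds of phosphoform
states): the receptor pool is taken as already aggregated and
binding-competent, giving a seven-reaction scheme with ten rate
constants. Two structural decisions are worth making explicit:

- R5 releases free pSyk and regenerates pFC — the engaged receptor is
  catalytic. This is what lets tiny Syk pools (5 nM against 1 µM
  receptor) fully convert and sustain downstream signalling.
- R2 releases *unphosphorylated* Lyn, and R3 rephosphorylates it from a
  clamped phosphate pool Pi, closing the Lyn cycle. Pi is a
  constant-concentration species (default 1 µM, overridable): the
  published calibration treats it as a boundable constant, not a
  depletable substrate.

Four moieties are exactly conserved by construction (receptor core, Lyn,
Syk, Grb2); the test suite requires relative drift ≤ 1e-6 over the full
horizon at rel_tol = abs_tol = 1e-9, and in practice observes ~1e-15 to
1e-11.

Both published parameterisations ship as scenarios: the Tsang-protocol
fit (FCε 1 µM, Syk 0.005 µM, estimated Grb2 6.47 µM and pLyn 6.5 µM,
horizon 3600 s) and the Faeder-protocol fit (horizon 4000 s, `reported`
and `refit` initial-condition variants). Published tables disagree on
three constants (k_f2 0.0082 vs 0.0081; k_f4 10.5797 vs 10.597; k_r4
0.1174 vs 1.1174); the fixtures store **both** readings with conflict
flags, and the builders default to the readings consistent with each
scenario's own fit (the source horizon is likewise printed once as
3500 s and once as 3600 s; the builders use 3600 s). The `reported`
Faeder variant prints no Grb2 concentration; the refit value 0.01 µM is
used.

## The Ca²⁺ oscillator

The cytosolic calcium balance is

    d[Ccyto]/dt = k₁(b + Ira)(Catot − Ccyto(α+1)) − VMP·Ccyto^np/(Kp^np + Ccyto^np)

with `Ira` the fraction of active IP3-receptor channels, `α` the
store/cytosol volume ratio, `b` a basal leak and a Hill-type SERCA pump.
Only this equation is printed in the pathway description; the channel
and IP3 dynamics of the original curated source live in an external
repository that this package does not redistribute. They are
reconstructed here in the field's standard reduced form: `Ira` relaxes
quickly (τ_a = 0.2 s) toward m∞³h³, where m∞ = [IP3/(IP3+d1)]·[C/(C+d5)]
is instantaneous IP3/Ca²⁺ activation and `h` is the slow Ca²⁺-dependent
inactivation gate, dh/dt = a₂(Q₂ − (Q₂+C)h), Q₂ = d₂(IP3+d1)/(IP3+d3).
Fast positive feedback (Ca²⁺-induced release) against slow negative
feedback (inactivation) is what oscillates. IP3 is synthesised at
Vplc×stimulus (the `stimulus` port is how upstream PLC activity enters),
consumed by a Ca²⁺-activated 3-kinase (maximal velocity V3k, producing
IP4) and a first-order 5-phosphatase.

All gate and turnover constants are vendored in
`data/ca_oscillator.yaml`, flagged as synthetic provenance, and were
chosen once to put the model in its physiological oscillatory regime:
sub-µM spikes, IP3 near 0.4 µM, period of tens of seconds. The window
matters — the oscillator runs for steady IP3 roughly between 0.35 and
0.7 µM, which constrains Vplc = 0.03 µM/s against r5p = 0.05 s⁻¹
(balance 0.6 µM with the kinase off, ~0.36 µM with it on).

Two behaviours are structural, not tuned, and are the test surface:
with V3k = 0 the IP3→IP4 branch vanishes identically (IP4 stays 0, IP3
settles to the flat synthesis/degradation balance) while Ca²⁺
oscillations persist; with V3k > 0 each Ca²⁺ spike activates the
3-kinase, so IP3 oscillates passively with Ca²⁺.

## The NFAT futile cycle

Four pools (phosphorylated/dephosphorylated × cytosolic/nuclear) cycle
via dephosphorylation by active calcineurin (CaN), nuclear import,
nuclear rephosphorylation and export; translocations have no back
reactions, so total NFAT is conserved exactly. The reverse term of the
nuclear rephosphorylation step carries µM⁻¹·s⁻¹ units in the published
table; it is implemented as bimolecular with active CaN
(kr₂₃·NFATp_n·N_tot·act_N), the reading consistent with those units.
The activation fraction act_N ∈ [0,1] is an input port: clamped at a
constant standalone, driven by the composite's second-messenger coupling
otherwise. The NFAT pool size and total CaN are never printed in the
pathway description; package defaults (pool 0.01 µM, all initially
phosphorylated-cytosolic; N_tot 1 µM) are vendored in
`data/nfat_defaults.yaml` and flagged synthetic.

## The composite pathway

Connector reactions wire the three sub-models (published composite-fit
values in parentheses):

1. hG + 2DL4 ⇌ hG2DL4 (0.0141 µM⁻¹s⁻¹ / 0.0140 s⁻¹).
2. hG2DL4 + FC_free ⇌ hG2DL4·FC (0.0165 / 0.0517). The engaged complex
   is identity-mapped onto the cascade's FC species: it *is* the
   substrate pLyn phosphorylates. A separate FC_free pool (default 1 µM)
   holds resting receptor.
3. pGrb2 + PI3K ⇌ pGrb2·PI3K → PI3K_act + pGrb2 (8.9165 / 0.0061;
   14.6231 s⁻¹). pGrb2 is catalytic, so the Grb2 moiety stays closed.
4. PI3K_act catalyses plc → plc_act (package default 1 µM⁻¹·s⁻¹; the
   source states the PI3K→PLC enhancement only qualitatively), and
   plc_act/plc_total rescales the oscillator's IP3 synthesis through a
   flux-coupling port — replacing the oscillator's constant stimulus.
5. act_N relaxes toward a Hill function of a second messenger at rate
   k_f = 0.0065 s⁻¹ (half-activation 0.5 µM, cooperativity 3; both
   package choices). The published description of k_f is an "IP3–NFAT
   binding rate", and IP3 is the default driver: it is exactly zero at
   rest, which makes every downstream output strictly dependent on
   receptor engagement (severing any single connector silences the
   cytokines — a tested reachability property). The alternative
   diagram reading, cytosolic Ca²⁺ as the driver, is one switch away
   (`ConnectorParams(ca_coupling="Ccyto")`) but carries a basal
   activity of ~0.1% from resting calcium.
6. Cytokine production is proportional to nuclear dephosphorylated
   NFAT (IFNγ 0.0684 s⁻¹, TNFα 23.1163 s⁻¹), with first-order secretion
   into released pools (0.0291 and 0.0098 s⁻¹).

Initial conditions follow the published table (KIR2DL4 0.098, HLA-G
0.1052, PI3K 0.01, plc 1.3 µM; the running text swaps the first two —
`CompositeICs(text_reading=True)` selects that reading). Cascade pools
use the Tsang-protocol estimates; CaN starts inactive and IP3 at zero
(no second messenger before engagement).

With these defaults the 60000 s reference run engages the receptor,
phosphorylates essentially all Grb2, fully activates PLC, sustains Ca²⁺
oscillation, settles act_N near 0.28, and produces monotone released
cytokine pools in which TNFα's normalized release leads IFNγ's — the
ordering observed experimentally, though at these rate constants the
lead is tens of seconds on a 60000 s horizon, much weaker than the
hours-scale delay in the data. The intracellular TNFα:IFNγ ratio is
fixed near 114 by the printed production/secretion constants, echoing
the source's own observation that the multi-objective fit represented
IFNγ well and TNFα poorly.

## Calibration

Unknown constants span orders of magnitude, so bounds are base-10
exponents ((−3, 2) sweeps 1e-3 to 1e2) and all sampling and refinement
happens in log10 space. The multistart is sample-then-refine: a
Saltelli design of exactly N×(2D+2) points — built from a scrambled
Sobol base sequence as the A, B, AB_i, BA_i block construction —
is scored by the SSQ objective, ranked, and the top k (default 5)
starts are refined with bounded trust-region least squares (termination
tolerances default 1e-8). Simulation failures score +∞ and are logged;
refinement is clamped never to return a worse point than its start.
Multiple datasets combine by unweighted SSQ sum, with optional
per-dataset weights and per-point σ weighting.

Numerical choices that matter:

- finite-difference steps for the Jacobian (default 1e-5 in exponent
  space) must exceed the integrator's relative error, or the gradient is
  solver noise; fits therefore default to tighter simulation tolerances
  (1e-7) than exploratory runs, and the noiseless recovery experiment
  uses 1e-11 with a 3-point stencil and Jacobian-based variable scaling,
  which is what lets the optimiser traverse the shallow k_f2/k_f4 ridge
  to the exact optimum;
- the recovery experiment samples pGrb2 log-spaced from 0.5 s: the
  receptor-side constants act in the first seconds of the lag phase, and
  plateau-only sampling leaves them on an exact trade-off ridge (only
  their product identified).

## Sensitivity analysis and census

OAT sweeps vary one parameter over a log-spaced grid (default 25 points)
with the rest held at the reference, recording SSQ per point.
Classification: *flat* if (max−min)/max(min, ε) < 1% (the source
classifies visually; 1% is the package's threshold), *edge_minimum* if
the argmin falls within one grid step of a bound, else *sensitive*.
Classification is invariant under uniform rescaling of the curve.

The census Saltelli-samples the joint 23-parameter space of the
composite fit (the published bounds table lists 24 rows with one
duplicate) and accepts parameter sets whose predicted cytokines stay
within [0, multiplier × mean] at every checked time, bounds inclusive;
the multiplier (default 2) and the check times are configuration. The
published census (302 of 4800 accepted, SSQ 3.16e-9–1.90e-8) is not
reproducible here: it depends on the digitized experimental points and
an unrecorded sampling seed. The package's census is validated on
semantics instead — inclusivity of the bound, monotonicity of the
accepted count in the multiplier, seed reproducibility — at small N and
short horizons.

## Synthetic data

The experimental time courses behind the published fits (Grb2
phosphorylation, pFC/pSyk phosphorylation, cytokine secretion) were
digitized from figures and are not printed, so they are not bundled.
`generate_synthetic_timecourse` simulates a model at known parameters,
adds seeded additive Gaussian noise (σ in µM, or relative for a
heteroscedastic option — the true digitization error structure is
unknown), and embeds a generating-parameter hash for provenance checks.
Users with their own digitized points can supply them as
`time_s,value_uM[,sigma_uM]` CSVs.

What this does and does not show: noiseless closure (SSQ = 0 against
self-generated data) and parameter recovery validate the objective,
sampling and refinement machinery end to end, and the qualitative test
surfaces (plateau kinetics, oscillation retention, release ordering)
match the published figures' described behaviour. None of that certifies
the published RMSE values (0.0695 µM Grb2; 0.0089/0.0022 µM pFC/pSyk) or
fit quality against the real data — those require the digitized points.

## Numerics

LSODA (stiff-capable, automatic switching) with rel_tol = abs_tol = 1e-9
by default; the solver settings of the original implementation are not
documented, so these are package choices. Long composite runs default to
1e-8/1e-10 — the suite's conservation checks still observe ≤1e-11 drift
there, because mass-action conservation is structural and drift is pure
integration error. Concentrations are clipped at zero only inside rate
evaluation; outputs are never silently clipped, and any clipping beyond
−abs_tol is reported in the trajectory metadata. The derivative is
compiled per model instance into a single scalar-arithmetic closure
(generic interpreted evaluation is kept as a cross-checked reference
path); this is what keeps the ~35-state, 60000 s oscillating composite
integration around 80 s.

Problem sizes used by the test suite and examples — Saltelli N = 8 for
recovery (80 samples), N ≤ 4 for census demonstrations, 60-point
synthetic datasets — are chosen as the smallest sizes at which each
property is cleanly exercised; the design-count check (N = 500, D = 11 →
12000) runs the published size directly since sampling is cheap.

## Known limitations

- The Ca²⁺ oscillator's gate constants are a reconstruction of an
  unredistributable curated source; behaviour is faithful qualitatively
  (oscillation regimes, 3-kinase coupling), but individual constants
  should not be cited as the original model's.
- NFAT/CaN pool sizes are package defaults; absolute cytokine
  concentrations scale nearly linearly with the NFAT pool and should be
  read as relative kinetics, not absolute predictions.
- The hours-scale IFNγ transcriptional delay is only weakly reproduced:
  the model lumps nuclear mechanisms into two production constants, as
  the source does.
- Single well-mixed compartments; no receptor trafficking,
  internalisation kinetics, MAPK or LAT/ZAP70 branches (not
  parameterised in the source).
- The census acceptance band needs a user-supplied absolute scale (the
  published means) or a reference prediction; with the synthetic default
  pools the published absolute band and the model's TNFα scale are not
  mutually consistent, mirroring the source's own TNFα misfit.
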