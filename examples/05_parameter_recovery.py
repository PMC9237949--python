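"""Self-consistency of the calibration stack: recover known rate constants
from noiseless synthetic data.

Generates a pGrb2 time course from the published cascade fit, then
re-estimates the four sensitive forward constants (k_f2, k_f4, k_f6,
k_f7) from a Saltelli multistart (N = 8, 80 samples) with bounded
trust-region refinement, and compares the estimates with the generating
values.
"""

import numpy as np

from nksignal import FitSpec, SimulationSpec, multistart_fit
from nksignal.datasets import generate_synthetic_timecourse
from nksignal.fcepsilonri import TSANG_PARAMS, tsang_scenario

model, _ = tsang_scenario()
tight = SimulationSpec(t_end=3600.0, rel_tol=1e-11, abs_tol=1e-13)
times = np.geomspace(0.5, 3600.0, 60)  # log-spaced: the lag phase matters
(data,) = generate_synthetic_timecourse(model, ["FCepsilonRI/pGrb2"], times,
                                        sim=tight)

free = {f"FCepsilonRI/{k}": (-3.0, 2.0)
        for k in ("k_f2", "k_f4", "k_f6", "k_f7")}
spec = FitSpec(free=free, datasets=[data], n_scale=8, top_k=5,
               ftol=1e-14, xtol=1e-14, gtol=1e-14, sim=tight)
results = multistart_fit(model, spec, seed=1)

best = results[0]
print(f"samples evaluated: {8 * (2 * 4 + 2)}; best refined SSQ: {best.ssq:.2e} µM²")
print(f"{'parameter':22s} {'estimate':>12s} {'truth':>12s} {'error':>8s}")
for name, est in best.estimates.items():
    truth = TSANG_PARAMS[name.split("/")[1]]
    print(f"{name:22s} {est:12.5g} {truth:12.5g} "
          f"{100 * abs(est - truth) / truth:7.3f}%")
print("\nNoiseless data generated by the model itself has its optimum at")
print("the generating parameters; recovering them validates the sampling,")
print("ranking and refinement machinery end to end.")
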