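"""How q-axis calibration errors propagate into the size measurands.

Radii live in reciprocal space: a relative q-scale error epsilon rescales the
fitted radius by 1/(1+epsilon) exactly, while a fixed q shift (e.g. the
+/-0.035 nm^-1 practical calibration uncertainty) distorts the curve
non-uniformly and hits the width hardest.
"""

import saxsizer as sx
from saxsizer.preprocess import clip_q, rebin_log
from saxsizer.q_uncertainty import QPerturbation, resolution_budget, sensitivity_study

truth = sx.TruthSpec()
curve = sx.simulate_dataset(truth, sx.LabProfile(noise_level=0.005), seed=7)
rebinned = rebin_log(clip_q(curve))

perturbations = [QPerturbation("scale", 0.035),
                 QPerturbation("shift", 0.035),
                 QPerturbation("shift", -0.035)]
table = sensitivity_study(rebinned, "lsq", perturbations, contrast=truth.contrast)
print(table.to_string(index=False))
print("-> the scale error moves the mean by -3.4% (= 1/1.035 - 1); the fixed")
print("   shifts move the mean by only a few percent but the width by far more.")

budget = resolution_budget(divergence=1e-3, beam_width=0.3, bin_width=0.5,
                           detector_distance=300.0, energy_spread=0.01, q=1.0)
print("\nfractional q-resolution budget at q = 1 nm^-1:")
for name, val in budget.contributions.items():
    print(f"  {name:16s} {val:.4f}")
print(f"  {'total':16s} {budget.total:.4f}  (quadrature sum)")
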