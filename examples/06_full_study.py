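"""The full round-robin accuracy study: simulate 45 labs, analyze each curve
with all three inversion methods, and summarize inter-laboratory agreement.

The 2-SD relative spread across non-outlier labs quantifies how reproducibly
each measurand can be determined irrespective of the measuring instrument.
"""

from saxsizer.study import accuracy_study

study = accuracy_study(master_seed=1)
print(study.spreads.to_string(index=False,
                              float_format=lambda v: f"{v:.4g}"))
print(f"\nnon-outlier labs used: {study.n_used} of {study.n_labs}")
print(f"best 2-SD spread of the mean radius: "
      f"{study.best_spread(['R_n', 'R_v']):.2f}%  (claim: <= 1%)")
print(f"best 2-SD spread of the width:       "
      f"{study.best_spread(['sigma_n', 'sigma_v']):.2f}%  (claim: <= 10%)")
print("-> the distribution mean is reproducible to well under a percent with")
print("   the parametric fit; widths to a few percent; absolute-scale")
print("   quantities (c_n, c_v) inherit the labs' ~5% intensity-scale jitter.")
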