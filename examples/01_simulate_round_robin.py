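"""Simulate a synthetic inter-laboratory round robin and inspect the ensemble.

Forty-five labs measure the same silver nanoparticle dispersion (lognormal,
median radius 2.73 nm, width w = 0.229, volume fraction 2.7e-4); each lab has
its own intensity scale bias, q grid, q shift and noise. Two labs are flagged
as outliers with a deliberately distorted sample.
"""

import numpy as np

import saxsizer as sx
from saxsizer.preprocess import (
    _loglog_interp,
    clip_q,
    ensemble_bands,
    match_ensemble,
    rebin_log,
)

rr = sx.simulate_round_robin(n_labs=45, master_seed=1)
print(f"labs: {len(rr.curves)}; absolute units: "
      f"{sum(e.absolute_units for e in rr.manifest)}; "
      f"outliers: {sum(e.outlier for e in rr.manifest)}")

rebinned = [rebin_log(clip_q(sx.harmonize_units(c))) for c in rr.curves]

# absolute-unit subset on a common grid, no scale matching: the band shows
# the labs' ~5% (1-sigma) intensity-scale jitter directly
absolute = [r for r, e in zip(rebinned, rr.manifest) if e.absolute_units]
grid = np.geomspace(0.15, 2.5, 100)
unmatched = [
    sx.ScatteringCurve(c.dataset_id, grid, _loglog_interp(grid, c.q, c.intensity))
    for c in absolute
]
raw_band = ensemble_bands(unmatched)
raw = np.abs(np.vstack([raw_band["relative"]["lo_2sd"],
                        raw_band["relative"]["hi_2sd"]]))
print(f"unmatched absolute-unit curves, median |2-SD band|: "
      f"{100 * np.nanmedian(raw):.1f}% of the median intensity")

# all 45 curves after uncertainty-weighted scale matching to their median
matched = ensemble_bands(match_ensemble(rebinned))
rel = np.abs(np.vstack([matched["relative"]["lo_2sd"],
                        matched["relative"]["hi_2sd"]]))
print(f"scale-matched curves, median |2-SD band|:          "
      f"{100 * np.median(rel[:, 10:90]):.1f}%")
print("-> the unmatched band is dominated by the per-lab intensity-scale")
print("   jitter; after matching, only noise and q-calibration scatter remain.")
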