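"""Curve post-processing: q-window clipping, logarithmic rebinning with an
uncertainty floor, uncertainty-weighted scale matching and ensemble percentile
bands.

The rebinning rule: intensities falling in one logarithmic q bin are averaged;
the bin uncertainty is the larger of the propagated uncertainty of the mean,
sqrt(sum sigma_i^2)/n, and the standard error of the mean of the member
intensities. The result is then floored at 1% of |I| — unrealistically small
uncertainty estimates otherwise distort the fit weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .curve_io import ScatteringCurve


@dataclass
class RebinnedCurve(ScatteringCurve):
    bin_count: Optional[np.ndarray] = None       # members per output point
    floored_fraction: float = 0.0                # fraction raised to the floor

    def __post_init__(self):
        super().__post_init__()
        if not 0.0 <= self.floored_fraction <= 1.0:
            raise ValueError("floored_fraction must be in [0, 1]")


def clip_q(curve: ScatteringCurve, q_min: float = 0.1, q_max: float = 3.0,
           min_points: int = 20) -> ScatteringCurve:
    """Restrict a harmonized curve to the closed q window [q_min, q_max] nm^-1."""
    if curve.q_unit != "nm^-1":
        raise ValueError("clip_q expects a harmonized curve (q in nm^-1)")
    keep = (curve.q >= q_min) & (curve.q <= q_max)
    if keep.sum() < min_points:
        raise ValueError(
            f"{curve.dataset_id}: only {int(keep.sum())} points survive the "
            f"[{q_min}, {q_max}] nm^-1 window (< {min_points}); curve cannot "
            "constrain the model"
        )
    return curve.replace(
        q=curve.q[keep],
        intensity=curve.intensity[keep],
        sigma=curve.sigma[keep] if curve.sigma is not None else None,
    )


def rebin_log(curve: ScatteringCurve, n_bins: int = 100,
              floor_fraction: float = 0.01) -> RebinnedCurve:
    """Rebin to at most ``n_bins`` logarithmically spaced q bins.

    Bin q is the arithmetic mean of member q. Points without a supplied sigma
    contribute only to the standard-error branch. Empty bins are dropped;
    single-member bins pass through (subject to the floor). If the curve has
    no more points than bins, q and I pass through unchanged and only the
    uncertainty rule is applied.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    q, I = curve.q, curve.intensity
    sig = curve.sigma

    if len(q) <= n_bins:
        # nothing to average; apply the uncertainty floor only
        base = sig if sig is not None else np.zeros_like(I)
        floor = floor_fraction * np.abs(I)
        out_sig = np.maximum(base, floor)
        floored = float(np.mean(base < floor))
        # guard against zero sigma on zero intensity
        out_sig = np.where(out_sig > 0, out_sig, np.finfo(float).tiny)
        return RebinnedCurve(
            dataset_id=curve.dataset_id, q=q.copy(), intensity=I.copy(), sigma=out_sig,
            absolute_units=curve.absolute_units, photon_energy=curve.photon_energy,
            q_unit=curve.q_unit, i_unit=curve.i_unit,
            bin_count=np.ones(len(q), dtype=int), floored_fraction=floored,
        )

    edges = np.geomspace(q[0], q[-1], n_bins + 1)
    idx = np.clip(np.searchsorted(edges, q, side="right") - 1, 0, n_bins - 1)

    q_out, i_out, s_out, counts, floored = [], [], [], [], 0
    for b in range(n_bins):
        members = idx == b
        n = int(members.sum())
        if n == 0:
            continue
        qi, ii = q[members], I[members]
        q_out.append(qi.mean())
        i_mean = ii.mean()
        i_out.append(i_mean)
        if sig is not None:
            propagated = np.sqrt(np.sum(sig[members] ** 2)) / n
        else:
            propagated = 0.0
        sem = ii.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        u = max(propagated, sem)
        floor = floor_fraction * abs(i_mean)
        if u < floor:
            floored += 1
            u = floor
        s_out.append(u if u > 0 else np.finfo(float).tiny)
        counts.append(n)

    n_out = len(q_out)
    return RebinnedCurve(
        dataset_id=curve.dataset_id,
        q=np.array(q_out), intensity=np.array(i_out), sigma=np.array(s_out),
        absolute_units=curve.absolute_units, photon_energy=curve.photon_energy,
        q_unit=curve.q_unit, i_unit=curve.i_unit,
        bin_count=np.array(counts, dtype=int),
        floored_fraction=floored / n_out if n_out else 0.0,
    )


def _loglog_interp(q_target, q_src, i_src):
    """Linear interpolation of log I vs log q; no extrapolation (NaN outside).

    Non-positive intensities are interpolated linearly in I instead (log is
    undefined); this only matters in the rare negative-background-residual case.
    """
    q_target = np.asarray(q_target, dtype=float)
    out = np.full(q_target.shape, np.nan)
    inside = (q_target >= q_src[0]) & (q_target <= q_src[-1])
    if np.all(i_src > 0):
        out[inside] = np.exp(
            np.interp(np.log(q_target[inside]), np.log(q_src), np.log(i_src))
        )
    else:
        out[inside] = np.interp(np.log(q_target[inside]), np.log(q_src), i_src)
    return out


def scale_match(curve: ScatteringCurve, reference: ScatteringCurve) -> float:
    """Uncertainty-weighted least-squares scale factor matching curve to reference.

    Minimizes sum((s I_i - I_ref,i)^2 / sigma_ref,i^2) over the overlapping q
    range, after interpolating the curve onto the reference grid (linear in
    log-log). Closed form: s = sum(I I_ref / s^2) / sum(I^2 / s^2).
    """
    if reference.sigma is None:
        raise ValueError("reference curve needs uncertainties for weighted matching")
    i_interp = _loglog_interp(reference.q, curve.q, curve.intensity)
    ok = np.isfinite(i_interp)
    if ok.sum() < 3:
        raise ValueError("curves do not overlap in q")
    w = 1.0 / reference.sigma[ok] ** 2
    num = np.sum(w * i_interp[ok] * reference.intensity[ok])
    den = np.sum(w * i_interp[ok] ** 2)
    if den == 0:
        raise ValueError("degenerate (all-zero) curve cannot be scale-matched")
    return float(num / den)


def ensemble_bands(curves: Sequence[ScatteringCurve]) -> dict:
    """Pointwise median and percentile bands of scale-matched curves on a shared grid.

    Returns the median, the median +/-34.1 percentile band (two standard
    deviations total width for Gaussian scatter) and the median +/-45
    percentile band (90% of the data), plus each band's relative deviation
    from the median.
    """
    if len(curves) < 3:
        raise ValueError("need at least 3 curves for ensemble bands")
    q0 = curves[0].q
    for c in curves[1:]:
        if len(c.q) != len(q0) or not np.allclose(c.q, q0):
            raise ValueError("curves must share a common q grid; interpolate first")
    stack = np.vstack([c.intensity for c in curves])
    med = np.median(stack, axis=0)
    pct = {p: np.percentile(stack, p, axis=0) for p in (5.0, 15.9, 84.1, 95.0)}
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = {
            "lo_2sd": pct[15.9] / med - 1.0,
            "hi_2sd": pct[84.1] / med - 1.0,
            "lo_90": pct[5.0] / med - 1.0,
            "hi_90": pct[95.0] / med - 1.0,
        }
    return {
        "q": q0,
        "median": med,
        "band_2sd": (pct[15.9], pct[84.1]),
        "band_90": (pct[5.0], pct[95.0]),
        "relative": rel,
    }


def match_ensemble(curves: Sequence[RebinnedCurve], grid: Optional[np.ndarray] = None,
                   ) -> list[ScatteringCurve]:
    """Interpolate curves onto a common grid and scale-match them to their median.

    The common grid defaults to 100 log-spaced points inside the overlap of all
    curves. Returns new curves ready for :func:`ensemble_bands`.
    """
    if grid is None:
        lo = max(c.q[0] for c in curves)
        hi = min(c.q[-1] for c in curves)
        if hi <= lo:
            raise ValueError("curves have no common q overlap")
        grid = np.geomspace(lo, hi, 100)
    interped = []
    for c in curves:
        i_new = _loglog_interp(grid, c.q, c.intensity)
        s_new = np.interp(grid, c.q, c.sigma) if c.sigma is not None else None
        interped.append((i_new, s_new, c))
    med = np.median(np.vstack([i for i, _, _ in interped]), axis=0)
    med_sigma = np.maximum(0.01 * np.abs(med), np.finfo(float).tiny)
    reference = ScatteringCurve(
        "ensemble-median", grid, med, med_sigma,
        absolute_units=False, i_unit="arbitrary",
    )
    out = []
    for i_new, s_new, c in interped:
        tmp = ScatteringCurve(c.dataset_id, grid, i_new, s_new,
                              absolute_units=False, i_unit="arbitrary")
        s = scale_match(tmp, reference)
        out.append(tmp.replace(intensity=i_new * s,
                               sigma=s_new * s if s_new is not None else None))
    return out
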