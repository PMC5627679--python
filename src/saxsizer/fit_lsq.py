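"""Least-squares fit of the lognormal-sphere model to a rebinned curve.

The classical curve-fitting branch: a number-weighted lognormal distribution of
homogeneous spheres plus a flat background, minimized in chi-square with the
curve's own uncertainties as weights. Positivity of the median radius and of
the overall scale is enforced by fitting their logarithms. With absolute-unit
data and a contrast, the fitted scale is the particle number density [m^-3].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .curve_io import ScatteringCurve
from .scattering_models import (
    AVOGADRO,
    ContrastSpec,
    LognormalParams,
    guinier_radius,
    lognormal_grid,
    lognormal_moments,
    polydisperse_intensity,
)

_RESTART_R0 = (1.0, 2.0, 3.0, 5.0)  # nm


@dataclass
class LsqFitResult:
    params: LognormalParams
    background: float                 # m^-1 (or arbitrary units)
    scale: float                      # fitted prefactor; number density if absolute
    number_density: Optional[float]   # m^-3, absolute-unit fits only
    reduced_chi2: float
    param_uncertainties: dict = field(default_factory=dict)
    converged: bool = True
    dataset_id: str = ""

    @property
    def mean_radius(self) -> float:
        return lognormal_moments(self.params)[0]

    @property
    def radius_sd(self) -> float:
        return lognormal_moments(self.params)[1]


def _model(q, ln_scale, ln_r0, w, background, contrast, n_grid=200):
    p = LognormalParams(1.0, float(np.exp(ln_r0)), max(float(w), 1e-6))
    dist = lognormal_grid(p, n=n_grid)
    return polydisperse_intensity(q, dist, contrast,
                                  number_density=float(np.exp(ln_scale)),
                                  background=background)


def fit_lognormal_spheres(
    curve: ScatteringCurve,
    contrast: Optional[ContrastSpec] = None,
    fixed_w: Optional[float] = None,
    init: Optional[dict] = None,
) -> LsqFitResult:
    """Fit (scale, R0, w, background) of the lognormal-sphere model.

    Initialization: R0 from a Guinier estimate on the 10 lowest-q points,
    w = 0.2, background from the 10 highest-q intensities, scale from the
    lowest-q intensity. On poor convergence the fit is restarted from a grid
    of R0 values and the best restart kept; failure is flagged, never silent.
    """
    if curve.sigma is None:
        raise ValueError("fit requires intensity uncertainties (rebin the curve first)")
    q, I, sig = curve.q, curve.intensity, curve.sigma
    use_absolute = contrast is not None and curve.absolute_units

    b0 = float(np.mean(I[-10:]))
    try:
        r0_init = guinier_radius(q, I, background=b0)
        r0_init = float(np.clip(r0_init, 0.3, 50.0))
    except ValueError:
        r0_init = 3.0
    w0 = 0.2 if fixed_w is None else fixed_w

    if init:
        r0_init = init.get("R0", r0_init)
        w0 = init.get("w", w0) if fixed_w is None else w0
        b0 = init.get("background", b0)

    def scale_init(r0):
        shape = _model(q[:1], 0.0, np.log(r0), max(w0, 1e-3), 0.0, contrast)
        top = max(I[0] - b0, 1e-3 * abs(I[0]) + 1e-30)
        return float(np.log(top / shape[0]))

    def residuals(theta):
        if fixed_w is None:
            ln_s, ln_r0, w, b = theta
        else:
            ln_s, ln_r0, b = theta
            w = fixed_w
        return (_model(q, ln_s, ln_r0, abs(w), b, contrast) - I) / sig

    def run(r0_start):
        if fixed_w is None:
            x0 = [scale_init(r0_start), np.log(r0_start), w0, b0]
        else:
            x0 = [scale_init(r0_start), np.log(r0_start), b0]
        with np.errstate(over="ignore", invalid="ignore"):
            return least_squares(residuals, x0, method="lm", xtol=1e-12,
                                 ftol=1e-12, max_nfev=4000)

    best = run(r0_init)
    n_par = best.x.size
    dof = max(len(q) - n_par, 1)
    red = 2 * best.cost / dof
    if not best.success or not np.isfinite(red):
        red = np.inf
    if red > 10.0:  # poor fit: try the restart grid, keep the best
        for r0_try in _RESTART_R0:
            res = run(r0_try)
            if res.success and res.cost < best.cost:
                best = res
        red = 2 * best.cost / dof

    converged = bool(best.success and np.isfinite(red))
    if fixed_w is None:
        ln_s, ln_r0, w, b = best.x
    else:
        ln_s, ln_r0, b = best.x
        w = fixed_w
    w = abs(float(w))
    r0 = float(np.exp(ln_r0))
    scale = float(np.exp(ln_s))

    # covariance of the damped-least-squares solution, scaled by reduced chi2
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.inv(jtj) * max(red, np.finfo(float).tiny)
        errs = np.sqrt(np.maximum(np.diag(cov), 0.0))
        if fixed_w is None:
            unc = {"scale": scale * errs[0], "R0": r0 * errs[1],
                   "w": errs[2], "background": errs[3]}
        else:
            unc = {"scale": scale * errs[0], "R0": r0 * errs[1],
                   "w": 0.0, "background": errs[2]}
    except np.linalg.LinAlgError:
        unc = {}

    return LsqFitResult(
        params=LognormalParams(1.0, r0, w),
        background=float(b),
        scale=scale,
        number_density=scale if use_absolute else None,
        reduced_chi2=float(red),
        param_uncertainties=unc,
        converged=converged,
        dataset_id=curve.dataset_id,
    )


def number_concentration(result: LsqFitResult) -> float:
    """Particle number concentration c_n [mol/l] from an absolute-unit fit."""
    if result.number_density is None:
        raise ValueError(
            "number concentration requires an absolute-unit fit with a contrast"
        )
    return result.number_density / (AVOGADRO * 1e3)
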