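"""Per-dataset measurands and inter-laboratory ensemble statistics.

A MeasurandRecord collects, for one dataset and one analysis method, the
number- and/or volume-weighted distribution mean and width plus concentration
estimates. ``aggregate`` reduces a set of records to the ensemble summary
(mean, sample SD, median, quartiles, 5/95% whiskers), optionally excluding
outlier-flagged datasets. One-way ANOVA compares methods; a location-scale
Student-t goodness-of-fit check probes the distribution of a measurand over
laboratories. Concentration conversions route through each method's own size
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scattering_models import AVOGADRO, NM_TO_M, SizeDistribution, reweight_distribution


@dataclass
class MeasurandRecord:
    dataset_id: str
    method: str                      # "ift", "lsq" or "mc"
    R_n: Optional[float] = None      # number-weighted mean radius [nm]
    sigma_n: Optional[float] = None  # number-weighted width [nm]
    R_v: Optional[float] = None      # volume-weighted mean radius [nm]
    sigma_v: Optional[float] = None  # volume-weighted width [nm]
    c_n: Optional[float] = None      # mol/l
    c_v: Optional[float] = None      # g/l
    outlier: bool = False
    converged: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in ("ift", "lsq", "mc"):
            raise ValueError(f"unknown method {self.method!r}")
        for name in ("R_n", "R_v"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("sigma_n", "sigma_v"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


_QUANTITIES = ("R_n", "sigma_n", "R_v", "sigma_v", "c_n", "c_v")


def records_to_frame(records: Sequence[MeasurandRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dataset_id": r.dataset_id, "method": r.method,
                **{q: getattr(r, q) for q in _QUANTITIES},
                "outlier": r.outlier, "converged": r.converged,
            }
            for r in records
        ]
    )


def aggregate(
    records: Sequence[MeasurandRecord] | pd.DataFrame,
    exclude_outliers: bool = True,
) -> pd.DataFrame:
    """Ensemble statistics per (method, quantity).

    Quantiles use linear interpolation between order statistics (the usual
    box-plot convention); the SD is the sample SD (ddof=1).
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    if exclude_outliers and "outlier" in df:
        df = df[~df["outlier"].astype(bool)]
    rows = []
    for method, grp in df.groupby("method"):
        for qty in _QUANTITIES:
            vals = grp[qty].dropna().to_numpy(dtype=float)
            if vals.size < 3:  # too few laboratories to summarize
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            p5, p95 = np.percentile(vals, [5, 95])
            rows.append(
                {
                    "method": method, "quantity": qty, "n": vals.size,
                    "mean": vals.mean(), "sd": vals.std(ddof=1),
                    "median": med, "q1": q1, "q3": q3, "iqr": q3 - q1,
                    "p5": p5, "p95": p95,
                }
            )
    if not rows:
        raise ValueError("no values to aggregate")
    return pd.DataFrame(rows)


def one_way_anova(groups: Sequence[Sequence[float]], alpha: float = 0.05
                  ) -> tuple[float, float, bool]:
    """Classical one-way ANOVA; returns (F, p, reject at alpha)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 values")
    within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    means = [a.mean() for a in arrs]
    if within == 0.0:
        if np.ptp(means) == 0.0:
            return 0.0, 1.0, False
        return float("inf"), 0.0, True
    F, p = stats.f_oneway(*arrs)
    return float(F), float(p), bool(p < alpha)


def distribution_check(values: Sequence[float], alpha: float = 0.05
                       ) -> tuple[float, float, bool]:
    """Kolmogorov-Smirnov check of a fitted location-scale Student-t.

    Returns (KS statistic, p value, not_rejected flag). Parameters are fitted
    by maximum likelihood; with fitted parameters the KS p value is
    conservative, which suits a "not rejected" statement.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 8:
        raise ValueError("need at least 8 values")
    if np.ptp(vals) == 0.0:
        raise ValueError("degenerate constant input")
    df_, loc, scale = stats.t.fit(vals)
    ks = stats.kstest(vals, "t", args=(df_, loc, scale))
    return float(ks.statistic), float(ks.pvalue), bool(ks.pvalue >= alpha)


def mean_particle_volume(dist: SizeDistribution, r_min_cutoff: Optional[float] = None
                         ) -> float:
    """Number-weighted mean particle volume <V>_n [m^3] of a distribution."""
    if dist.weighting == "volume":
        dist = reweight_distribution(dist, "number", r_min_cutoff=r_min_cutoff)
    d = dist.normalized()
    r3 = np.trapezoid(d.radii ** 3 * d.density, d.radii)
    return float((4.0 / 3.0) * np.pi * r3 * NM_TO_M ** 3)


def convert_concentration(
    c: float,
    direction: str,
    dist: SizeDistribution,
    mass_density: float = 10.49,
    r_min_cutoff: Optional[float] = None,
) -> float:
    """Convert between number [mol/l] and mass [g/l] concentration.

    n->v: phi = c_n N_A 1e3 <V>_n, c_v = phi rho 1000. v->n divides by the
    same factor but requires a small-R cutoff when the distribution arrives
    volume-weighted, because the number reweighting diverges at small R (the
    reason this direction is discouraged in practice).
    """
    if direction not in ("n->v", "v->n"):
        raise ValueError("direction must be 'n->v' or 'v->n'")
    if direction == "v->n" and dist.weighting == "volume" and r_min_cutoff is None:
        raise ValueError("v->n conversion from a volume-weighted distribution "
                         "requires r_min_cutoff")
    vbar = mean_particle_volume(dist, r_min_cutoff=r_min_cutoff)
    factor = AVOGADRO * 1e3 * vbar * mass_density * 1000.0  # c_v per c_n
    return c * factor if direction == "n->v" else c / factor
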