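"""Forward models for dilute polydisperse spheres.

The scattering model throughout the package assumes dilute, non-interacting,
homogeneous spheres of non-uniform size. The size distribution is parameterized
as a lognormal in the radius R,

    D(R) = A / (sqrt(2 pi) w R) * exp(-ln^2(R/R0) / (2 w^2)),

with area A, median radius R0 [nm] and dimensionless log-space width w.
Its mean radius is R0 exp(w^2/2) and standard deviation
R0 exp(w^2/2) sqrt(exp(w^2) - 1).

The absolute intensity of a number-weighted distribution D_n (unit area) at
number density n [m^-3] and contrast delta_rho is

    I(q) = n * Int D_n(R) [delta_rho V(R)]^2 P(qR) dR + B,

with V(R) = (4 pi / 3) R^3 and the Rayleigh sphere form factor
P(x) = [3 (sin x - x cos x) / x^3]^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._elements import electrons_and_mass

AVOGADRO = 6.02214076e23          # 1/mol
R_E_ANGSTROM = 2.8179403262e-5    # classical electron radius [Å]
NM_TO_M = 1e-9
A2_TO_M2 = 1e20                   # Å^-2 -> m^-2 for scattering length density


@dataclass(frozen=True)
class LognormalParams:
    """Lognormal size-distribution parameters (area A, median R0 [nm], width w)."""

    A: float
    R0: float
    w: float

    def __post_init__(self):
        if self.A <= 0 or self.R0 <= 0 or self.w < 0:
            raise ValueError("require A > 0, R0 > 0, w >= 0")


@dataclass
class SizeDistribution:
    """Gridded radius distribution with an explicit weighting tag."""

    radii: np.ndarray           # nm, increasing
    density: np.ndarray         # per nm, >= 0 (scale depends on normalization)
    weighting: str = "number"   # "number" or "volume"

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.weighting not in ("number", "volume"):
            raise ValueError("weighting must be 'number' or 'volume'")
        if np.any(np.diff(self.radii) <= 0) or (self.radii.size and self.radii[0] < 0):
            raise ValueError("radii must be increasing and >= 0")
        if np.any(self.density < -1e-300):
            raise ValueError("density must be >= 0")

    def area(self) -> float:
        return float(np.trapezoid(self.density, self.radii))

    def normalized(self) -> "SizeDistribution":
        a = self.area()
        if a <= 0:
            raise ValueError("cannot normalize a zero distribution")
        return SizeDistribution(self.radii, self.density / a, self.weighting)

    def mean(self) -> float:
        a = self.area()
        return float(np.trapezoid(self.radii * self.density, self.radii) / a)

    def sd(self) -> float:
        m = self.mean()
        a = self.area()
        var = np.trapezoid((self.radii - m) ** 2 * self.density, self.radii) / a
        return float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class ContrastSpec:
    """X-ray contrast between particle and solvent.

    delta_rho is the scattering-length-density difference in Å^-2 (the
    customary unit in SAXS work); particle_mass_density [g/cm^3] is carried
    along for volume->mass concentration conversion.
    """

    delta_rho: float                  # Å^-2
    energy: float = 8.0               # keV
    particle_mass_density: float = 10.49  # g/cm^3 (bulk silver)

    def delta_rho_m2(self) -> float:
        return self.delta_rho * A2_TO_M2


def lognormal_pdf(R, p: LognormalParams):
    """Lognormal density at radius R [nm]; integrates to A over (0, inf)."""
    if p.w == 0:
        raise ValueError("w = 0 is a delta distribution; use lognormal_moments")
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("R must be > 0")
    return p.A / (np.sqrt(2 * np.pi) * p.w * R) * np.exp(
        -np.log(R / p.R0) ** 2 / (2 * p.w ** 2)
    )


def lognormal_moments(p: LognormalParams) -> tuple[float, float]:
    """Mean radius and standard deviation of the lognormal, closed form."""
    mean = p.R0 * np.exp(p.w ** 2 / 2)
    sd = mean * np.sqrt(np.expm1(p.w ** 2))
    return float(mean), float(sd)


def lognormal_raw_moment(p: LognormalParams, k: int) -> float:
    """k-th raw moment <R^k> of the unit-area lognormal: R0^k exp(k^2 w^2 / 2)."""
    return float(p.R0 ** k * np.exp(k ** 2 * p.w ** 2 / 2))


def lognormal_grid(p: LognormalParams, n: int = 200, span: float = 5.0) -> SizeDistribution:
    """Unit-area number-weighted lognormal sampled on a log-spaced radius grid.

    The grid spans [R0 e^{-span w}, R0 e^{span w}], covering >99.999% of the
    mass at the default span of 5 log-widths.
    """
    w = max(p.w, 1e-4)  # degenerate widths get a numerically narrow spike
    radii = np.geomspace(p.R0 * np.exp(-span * w), p.R0 * np.exp(span * w), n)
    dens = lognormal_pdf(radii, LognormalParams(1.0, p.R0, w))
    dist = SizeDistribution(radii, dens, "number")
    return dist.normalized()


def sphere_form_factor(q, R):
    """Normalized sphere form factor P(qR) = [3 (sin x - x cos x)/x^3]^2.

    Broadcasts q [nm^-1] against R [nm]; P(0) = 1 and 0 <= P <= 1.
    A series expansion is used below x = 1e-2 to avoid cancellation.
    """
    x = np.asarray(np.multiply.outer(np.asarray(q, dtype=float), np.asarray(R, dtype=float)))
    amp = np.empty_like(x)
    small = np.abs(x) < 1e-2
    xs = x[small]
    amp[small] = 1.0 - xs ** 2 / 10.0 + xs ** 4 / 280.0
    xl = x[~small]
    amp[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl ** 3
    out = amp ** 2
    return out if out.ndim else float(out)


def polydisperse_intensity(
    q_grid,
    dist: SizeDistribution,
    contrast: Optional[ContrastSpec],
    number_density: float = 1.0,
    background: float = 0.0,
):
    """Absolute intensity [m^-1] of a dilute polydisperse sphere population.

    ``dist`` is a number-weighted distribution of unit area; ``number_density``
    is in m^-3 and ``background`` in m^-1. With ``contrast=None`` the contrast
    factor is dropped and the returned values are shape-only (arbitrary units).
    Trapezoid quadrature on the distribution's own grid.
    """
    if dist.weighting != "number":
        raise ValueError("polydisperse_intensity expects a number-weighted distribution")
    q = np.asarray(q_grid, dtype=float)
    drho = contrast.delta_rho_m2() if contrast is not None else 1.0
    volumes = (4.0 / 3.0) * np.pi * (dist.radii * NM_TO_M) ** 3  # m^3
    # integrand over R for each q: D_n(R) (drho V)^2 P(qR)
    P = sphere_form_factor(q, dist.radii)            # (nq, nR)
    integrand = dist.density[None, :] * (drho * volumes[None, :]) ** 2 * P
    integral = np.trapezoid(integrand, dist.radii, axis=-1)
    return number_density * integral + background


def guinier_radius(q, intensity, background: float = 0.0, n_points: int = 10) -> float:
    """Sphere-equivalent radius from a Guinier fit to the lowest-q points.

    ln(I - B) vs q^2 slope = -Rg^2/3; for a homogeneous sphere R = sqrt(5/3) Rg.
    """
    q = np.asarray(q, dtype=float)[:n_points]
    y = np.asarray(intensity, dtype=float)[:n_points] - background
    ok = y > 0
    if ok.sum() < 3:
        raise ValueError("too few positive intensities for a Guinier estimate")
    slope = np.polyfit(q[ok] ** 2, np.log(y[ok]), 1)[0]
    if slope >= 0:
        raise ValueError("non-decaying low-q intensity; Guinier estimate undefined")
    rg = np.sqrt(-3.0 * slope)
    return float(np.sqrt(5.0 / 3.0) * rg)


def sld(formula: str, mass_density: float) -> float:
    """X-ray scattering length density [Å^-2] of a substance (non-anomalous)."""
    electrons, molar_mass = electrons_and_mass(formula)
    rho_e = mass_density / molar_mass * AVOGADRO * electrons / 1e24  # electrons/Å^3
    return rho_e * R_E_ANGSTROM


def xray_contrast(
    formula: str,
    mass_density: float,
    solvent_formula: str = "H2O",
    solvent_density: float = 0.997,
    energy: float = 8.0,
) -> ContrastSpec:
    """Contrast Δρ [Å^-2] between a particle material and its solvent.

    Uses non-anomalous electron counts, which at 8 keV reproduces the standard
    silver-in-water value of 6.8e-5 Å^-2. ``energy`` is recorded for provenance.
    """
    delta = sld(formula, mass_density) - sld(solvent_formula, solvent_density)
    return ContrastSpec(delta_rho=delta, energy=energy, particle_mass_density=mass_density)


def reweight_distribution(
    dist: SizeDistribution,
    target: str,
    r_min_cutoff: Optional[float] = None,
) -> SizeDistribution:
    """Convert between number and volume weighting, preserving the area.

    number->volume multiplies by R^3; volume->number divides by R^3 and
    requires ``r_min_cutoff`` because the operation diverges as R -> 0
    (the reason volume-to-number concentration conversion is discouraged).
    """
    if target not in ("number", "volume"):
        raise ValueError("target must be 'number' or 'volume'")
    if dist.weighting == target:
        return SizeDistribution(dist.radii.copy(), dist.density.copy(), target)
    area = dist.area()
    if target == "volume":
        dens = dist.density * dist.radii ** 3
        radii = dist.radii
    else:
        if r_min_cutoff is None:
            raise ValueError(
                "volume->number conversion requires r_min_cutoff "
                "(the transform diverges at small R)"
            )
        keep = dist.radii >= r_min_cutoff
        if keep.sum() < 2:
            raise ValueError("r_min_cutoff leaves too few grid points")
        radii = dist.radii[keep]
        dens = dist.density[keep] / radii ** 3
    new_area = np.trapezoid(dens, radii)
    if new_area <= 0:
        raise ValueError("degenerate distribution after reweighting")
    return SizeDistribution(radii, dens * (area / new_area), target)


def write_distribution(dist: SizeDistribution, path) -> None:
    """Write a distribution as 2-column text with a weighting tag header."""
    with open(path, "w") as fh:
        fh.write(f"# weighting: {dist.weighting}\n# columns: radius_nm density\n")
        for r, d in zip(dist.radii, dist.density):
            fh.write(f"{r:.11e} {d:.11e}\n")
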