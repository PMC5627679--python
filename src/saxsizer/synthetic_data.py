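"""Synthetic round-robin generator.

Emulates a multi-laboratory SAXS study of one silver-nanoparticle dispersion:
every lab measures the same lognormal sphere population but with its own
intensity scale bias, q grid, q-axis shift, noise level, uncertainty-reporting
habits and unit convention. Two labs are flagged as outliers and receive a
deliberately distorted particle population. The ground truth is recorded so
recovery can be tested end to end.

Defaults describe a poly(acrylic acid)-stabilized silver sol: number-weighted
lognormal with median radius 2.73 nm and width w = 0.229 (mean 2.80 nm,
relative width ~23%), volume fraction 2.7e-4, silver/water contrast at 8 keV.
The 5% log-normal scale jitter reproduces an inter-curve intensity band of
roughly +/-5-10% at two standard deviations; about 60% of labs report absolute
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .curve_io import Manifest, ManifestEntry, ScatteringCurve, write_curve, write_manifest
from .scattering_models import (
    ContrastSpec,
    LognormalParams,
    lognormal_grid,
    lognormal_raw_moment,
    NM_TO_M,
    polydisperse_intensity,
    xray_contrast,
)


def silver_water_contrast(energy: float = 8.0) -> ContrastSpec:
    return xray_contrast("Ag", 10.49, "H2O", 0.997, energy=energy)


@dataclass
class TruthSpec:
    """Ground-truth particle population of the simulated study."""

    R0: float = 2.73                 # nm, median radius
    w: float = 0.229                 # lognormal width
    volume_fraction: float = 2.7e-4
    contrast: ContrastSpec = field(default_factory=silver_water_contrast)
    background: float = 1.0          # m^-1, residual after solvent subtraction

    def __post_init__(self):
        if min(self.R0, self.w, self.volume_fraction) <= 0 or self.background < 0:
            raise ValueError("truth parameters must be positive")

    @property
    def params(self) -> LognormalParams:
        return LognormalParams(1.0, self.R0, self.w)

    def number_density(self) -> float:
        """n [m^-3] implied by the volume fraction: n = phi / <V>_n."""
        r3 = lognormal_raw_moment(self.params, 3)         # nm^3
        vbar = (4.0 / 3.0) * np.pi * r3 * NM_TO_M ** 3    # m^3
        return self.volume_fraction / vbar


@dataclass
class LabProfile:
    """One laboratory's measurement idiosyncrasies."""

    scale_bias: float = 1.0          # multiplicative intensity bias
    noise_level: float = 0.01        # fractional noise at mid-q
    n_points: int = 200
    grid: str = "log"                # "log" or "lin"
    q_min: float = 0.1               # nm^-1
    q_max: float = 3.0
    absolute_units: bool = True
    q_shift: float = 0.0             # nm^-1, q-axis calibration error
    sigma_report_factor: float = 1.0  # <1 under-reports the true noise
    report_sigma: bool = True
    outlier: bool = False
    arb_constant: float = 1.0        # undisclosed scale for arbitrary-unit labs
    photon_energy: float = 8.0

    def __post_init__(self):
        if self.noise_level <= 0:
            raise ValueError("noise_level must be > 0")
        if self.grid not in ("log", "lin"):
            raise ValueError("grid must be 'log' or 'lin'")


def simulate_dataset(
    truth: TruthSpec,
    lab: LabProfile,
    seed: int,
    dataset_id: Optional[str] = None,
) -> ScatteringCurve:
    """Simulate one lab's curve from the ground truth. Deterministic per seed.

    The model intensity is evaluated at the true q (reported grid plus the
    lab's q_shift), scaled by the lab's bias, and perturbed by Gaussian noise
    with sigma_i = noise_level * I(q_i) * (1 + q_i/q_max) — noise worsens
    toward high q as counting statistics do. The reported uncertainty equals
    the generating sigma, optionally under-reported.
    """
    rng = np.random.default_rng(seed)
    if lab.grid == "log":
        q = np.geomspace(lab.q_min, lab.q_max, lab.n_points)
    else:
        q = np.linspace(lab.q_min, lab.q_max, lab.n_points)

    eff_truth = replace(truth, R0=truth.R0 * 1.3) if lab.outlier else truth
    dist = lognormal_grid(eff_truth.params, n=400)
    q_true = q + lab.q_shift
    if q_true[0] <= 0:
        raise ValueError("q_shift drives q non-positive")
    ideal = polydisperse_intensity(
        q_true, dist, eff_truth.contrast,
        number_density=eff_truth.number_density(),
        background=eff_truth.background,
    )
    ideal = lab.scale_bias * ideal
    sigma_true = lab.noise_level * np.abs(ideal) * (1.0 + q / lab.q_max)
    noisy = ideal + rng.normal(0.0, 1.0, ideal.size) * sigma_true

    if not lab.absolute_units:
        noisy = noisy * lab.arb_constant
        sigma_true = sigma_true * lab.arb_constant

    reported_sigma = sigma_true * lab.sigma_report_factor if lab.report_sigma else None
    return ScatteringCurve(
        dataset_id=dataset_id or "synthetic",
        q=q,
        intensity=noisy,
        sigma=reported_sigma,
        absolute_units=lab.absolute_units,
        photon_energy=lab.photon_energy,
        q_unit="nm^-1",
        i_unit="m^-1" if lab.absolute_units else "arbitrary",
    )


def sample_lab_profile(rng: np.random.Generator, outlier: bool = False) -> LabProfile:
    """Draw one lab's profile from the study-level variability model."""
    grid = "log" if rng.random() < 0.5 else "lin"
    return LabProfile(
        scale_bias=float(np.exp(rng.normal(0.0, 0.05))),
        noise_level=float(np.clip(np.exp(rng.normal(np.log(0.01), 0.4)), 0.003, 0.03)),
        n_points=int(rng.integers(80, 401)),
        grid=grid,
        q_min=float(rng.uniform(0.08, 0.1)),
        q_max=float(rng.uniform(3.0, 3.6)),
        absolute_units=bool(rng.random() < 28.0 / 45.0),
        q_shift=float(rng.normal(0.0, 0.01)),
        sigma_report_factor=float(rng.uniform(0.1, 0.5)) if rng.random() < 0.4 else 1.0,
        report_sigma=bool(rng.random() < 0.85),
        outlier=outlier,
        arb_constant=float(np.exp(rng.uniform(np.log(1e-3), np.log(1e3)))),
    )


@dataclass
class RoundRobin:
    manifest: Manifest
    curves: list[ScatteringCurve]
    profiles: list[LabProfile]
    truth: TruthSpec
    master_seed: int


def simulate_round_robin(
    n_labs: int = 45,
    truth: Optional[TruthSpec] = None,
    master_seed: int = 0,
    n_outliers: int = 2,
) -> RoundRobin:
    """Simulate a full round robin: per-lab profiles, curves and a manifest.

    Fully reproducible from (truth, master_seed). Two labs are outlier-flagged
    by default and simulate a 30% oversized particle population.
    """
    if n_labs < 3:
        raise ValueError("need at least 3 labs")
    truth = truth or TruthSpec()
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 0xA11]))
    outlier_ids = set(rng.choice(n_labs, size=min(n_outliers, n_labs), replace=False).tolist())

    curves, profiles, entries = [], [], []
    for i in range(n_labs):
        profile = sample_lab_profile(rng, outlier=i in outlier_ids)
        seed_i = int(rng.integers(0, 2**31 - 1))
        dataset_id = f"lab{i:02d}"
        curve = simulate_dataset(truth, profile, seed_i, dataset_id=dataset_id)
        curves.append(curve)
        profiles.append(profile)
        entries.append(
            ManifestEntry(
                dataset_id=dataset_id,
                path=None,
                q_unit=curve.q_unit,
                i_unit=curve.i_unit,
                absolute_units=curve.absolute_units,
                photon_energy=curve.photon_energy,
                outlier=profile.outlier,
            )
        )
    return RoundRobin(
        manifest=Manifest(entries=entries),
        curves=curves,
        profiles=profiles,
        truth=truth,
        master_seed=master_seed,
    )


def write_round_robin(rr: RoundRobin, outdir: str | Path) -> Path:
    """Write curves, manifest CSV and a truth record to a directory."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for entry, curve in zip(rr.manifest, rr.curves):
        path = outdir / f"{entry.dataset_id}.dat"
        write_curve(curve, path)
        entry.path = str(path)
    write_manifest(rr.manifest, outdir / "manifest.csv")
    truth = {
        "R0_nm": rr.truth.R0,
        "w": rr.truth.w,
        "volume_fraction": rr.truth.volume_fraction,
        "delta_rho_A-2": rr.truth.contrast.delta_rho,
        "background_m-1": rr.truth.background,
        "master_seed": rr.master_seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return outdir / "manifest.csv"
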