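"""Reading, validation, unit harmonization and writing of 1-D scattering curves.

A curve is a (q, I, sigma) table. Internally the package works in q [nm^-1] and,
for absolutely calibrated data, differential scattering cross-section dSigma/dOmega
[m^-1 sr^-1]; curves supplied in Å^-1 or cm^-1 are converted on harmonization.
Arbitrary-unit curves keep their scale and are flagged ``absolute_units=False``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

Q_UNITS = ("nm^-1", "A^-1")
I_UNITS = ("m^-1", "cm^-1", "arbitrary")

# aliases accepted on input
_Q_ALIASES = {
    "nm^-1": "nm^-1", "nm-1": "nm^-1", "1/nm": "nm^-1", "nm⁻¹": "nm^-1",
    "a^-1": "A^-1", "a-1": "A^-1", "1/a": "A^-1", "å^-1": "A^-1",
    "å⁻¹": "A^-1", "angstrom^-1": "A^-1",
}
_I_ALIASES = {
    "m^-1": "m^-1", "1/m": "m^-1", "m-1": "m^-1", "m⁻¹": "m^-1",
    "cm^-1": "cm^-1", "1/cm": "cm^-1", "cm-1": "cm^-1", "cm⁻¹": "cm^-1",
    "arbitrary": "arbitrary", "arb": "arbitrary", "a.u.": "arbitrary", "au": "arbitrary",
}


def _canonical_q_unit(unit: str) -> str:
    key = unit.strip().lower()
    if key not in _Q_ALIASES:
        raise ValueError(f"unknown q unit {unit!r}; expected one of {Q_UNITS}")
    return _Q_ALIASES[key]


def _canonical_i_unit(unit: str) -> str:
    key = unit.strip().lower()
    if key not in _I_ALIASES:
        raise ValueError(f"unknown intensity unit {unit!r}; expected one of {I_UNITS}")
    return _I_ALIASES[key]


@dataclass
class ScatteringCurve:
    """One laboratory's background-subtracted scattering curve.

    Negative intensities are legal (background subtraction can produce them) and
    are retained; downstream stages handle them explicitly.
    """

    dataset_id: str
    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    absolute_units: bool = False
    photon_energy: float = 8.0  # keV
    q_unit: str = "nm^-1"
    i_unit: str = "arbitrary"

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        self.q_unit = _canonical_q_unit(self.q_unit)
        self.i_unit = _canonical_i_unit(self.i_unit)
        self.validate()

    def validate(self) -> None:
        if self.q.ndim != 1 or self.intensity.shape != self.q.shape:
            raise ValueError("q and intensity must be 1-D arrays of equal length")
        if self.q.size and self.q[0] <= 0:
            raise ValueError("all q must be > 0")
        if np.any(np.diff(self.q) <= 0):
            bad = int(np.argmax(np.diff(self.q) <= 0)) + 2
            raise ValueError(f"q must be strictly increasing (violation at row {bad})")
        if self.sigma is not None:
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length must match q")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma values must be > 0 where present")
        if self.absolute_units and self.i_unit == "arbitrary":
            raise ValueError("absolute_units=True is inconsistent with arbitrary intensity unit")

    def __len__(self) -> int:
        return self.q.size

    def replace(self, **kw) -> "ScatteringCurve":
        return replace(self, **kw)


@dataclass
class ManifestEntry:
    dataset_id: str
    path: Optional[str]
    q_unit: str = "nm^-1"
    i_unit: str = "arbitrary"
    absolute_units: bool = False
    photon_energy: float = 8.0
    outlier: bool = False


@dataclass
class Manifest:
    """Bookkeeping for a set of round-robin curves."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.dataset_id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate dataset_ids in manifest: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


_NUMERIC = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eEdD][+-]?\d+)?$")


def _split_row(line: str) -> list[str]:
    # participant files mix spaces, tabs and commas freely
    return [tok for tok in re.split(r"[,\s]+", line.strip()) if tok]


def read_curve(
    path: str | Path,
    q_unit: str = "nm^-1",
    i_unit: str = "arbitrary",
    dataset_id: Optional[str] = None,
    absolute_units: Optional[bool] = None,
    photon_energy: float = 8.0,
) -> ScatteringCurve:
    """Read a 2- or 3-column plain-text curve in its native units.

    Lines starting with '#' are comments. Any mix of spaces, tabs and commas
    delimits columns. A 2-column file yields a curve without uncertainties.
    """
    path = Path(path)
    i_unit = _canonical_i_unit(i_unit)
    rows: list[list[float]] = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = _split_row(line)
            if not all(_NUMERIC.match(t) for t in toks):
                raise ValueError(f"{path.name}: non-numeric row at line {lineno}: {line!r}")
            vals = [float(t.replace("D", "E").replace("d", "e")) for t in toks]
            if len(vals) < 2 or len(vals) > 3:
                raise ValueError(f"{path.name}: expected 2 or 3 columns at line {lineno}")
            if ncols is None:
                ncols = len(vals)
            elif len(vals) != ncols:
                raise ValueError(f"{path.name}: inconsistent column count at line {lineno}")
            rows.append(vals)
    if len(rows) < 10:
        raise ValueError(f"{path.name}: fewer than 10 data points ({len(rows)})")
    arr = np.array(rows)
    dq = np.diff(arr[:, 0])
    if np.any(dq <= 0):
        bad = int(np.argmax(dq <= 0)) + 2  # 1-based row among data rows
        raise ValueError(f"{path.name}: q not strictly increasing at data row {bad}")
    sigma = arr[:, 2] if arr.shape[1] == 3 else None
    if sigma is not None and np.any(sigma <= 0):
        # tolerate zero/negative uncertainties on read by dropping the column
        # would reject per-invariant; keep strict instead:
        bad = int(np.argmax(sigma <= 0)) + 1
        raise ValueError(f"{path.name}: non-positive sigma at data row {bad}")
    if absolute_units is None:
        absolute_units = i_unit != "arbitrary"
    return ScatteringCurve(
        dataset_id=dataset_id or path.stem,
        q=arr[:, 0],
        intensity=arr[:, 1],
        sigma=sigma,
        absolute_units=absolute_units,
        photon_energy=photon_energy,
        q_unit=q_unit,
        i_unit=i_unit,
    )


def harmonize_units(curve: ScatteringCurve) -> ScatteringCurve:
    """Convert to the package-standard units: q in nm^-1, absolute I in m^-1.

    Å^-1 -> nm^-1 multiplies q by 10; cm^-1 -> m^-1 multiplies I (and sigma)
    by 100. Arbitrary-unit intensities pass through unchanged. Idempotent.
    """
    q = curve.q
    intensity = curve.intensity
    sigma = curve.sigma
    if curve.q_unit == "A^-1":
        q = q * 10.0
    if curve.i_unit == "cm^-1":
        intensity = intensity * 100.0
        sigma = sigma * 100.0 if sigma is not None else None
        i_unit = "m^-1"
    elif curve.i_unit == "m^-1":
        i_unit = "m^-1"
    else:
        i_unit = "arbitrary"
    return curve.replace(
        q=q, intensity=intensity, sigma=sigma, q_unit="nm^-1", i_unit=i_unit,
        absolute_units=curve.absolute_units and i_unit != "arbitrary",
    )


def write_curve(curve: ScatteringCurve, path: str | Path, sidecar: bool = False) -> Path:
    """Write a curve as a 3-column (or 2-column) text table, 12 significant digits."""
    path = Path(path)
    cols = [curve.q, curve.intensity]
    header = [
        f"# dataset_id: {curve.dataset_id}",
        f"# q_unit: {curve.q_unit}",
        f"# i_unit: {curve.i_unit}",
        f"# absolute_units: {curve.absolute_units}",
        f"# photon_energy_keV: {curve.photon_energy}",
        "# columns: q intensity" + (" sigma" if curve.sigma is not None else ""),
    ]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    data = np.column_stack(cols)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for row in data:
            fh.write(" ".join(f"{v:.11e}" for v in row) + "\n")
    if sidecar:
        meta = {
            "dataset_id": curve.dataset_id,
            "q_unit": curve.q_unit,
            "i_unit": curve.i_unit,
            "absolute_units": curve.absolute_units,
            "photon_energy_keV": curve.photon_energy,
            "n_points": len(curve),
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))
    return path


_MANIFEST_COLUMNS = [
    "dataset_id", "path", "q_unit", "i_unit", "absolute_units", "photon_energy", "outlier",
]


def read_manifest(path: str | Path) -> Manifest:
    """Read a CSV manifest; file paths are resolved relative to the manifest."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = path.parent / p
        if not p.exists():
            raise ValueError(f"manifest path not resolvable: {p}")
        entries.append(
            ManifestEntry(
                dataset_id=str(row["dataset_id"]),
                path=str(p),
                q_unit=str(row["q_unit"]),
                i_unit=str(row["i_unit"]),
                absolute_units=bool(row["absolute_units"]),
                photon_energy=float(row["photon_energy"]),
                outlier=bool(row["outlier"]),
            )
        )
    return Manifest(entries=entries)


def write_manifest(manifest: Manifest, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "dataset_id": e.dataset_id,
                "path": e.path,
                "q_unit": e.q_unit,
                "i_unit": e.i_unit,
                "absolute_units": e.absolute_units,
                "photon_energy": e.photon_energy,
                "outlier": e.outlier,
            }
            for e in manifest
        ],
        columns=_MANIFEST_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path


def load_curves(manifest: Manifest, harmonize: bool = True) -> list[ScatteringCurve]:
    """Read (and by default unit-harmonize) every curve listed in a manifest."""
    curves = []
    for e in manifest:
        if e.path is None:
            raise ValueError(f"manifest entry {e.dataset_id} has no file path")
        c = read_curve(
            e.path, q_unit=e.q_unit, i_unit=e.i_unit, dataset_id=e.dataset_id,
            absolute_units=e.absolute_units, photon_energy=e.photon_energy,
        )
        curves.append(harmonize_units(c) if harmonize else c)
    return curves
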