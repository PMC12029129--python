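"""Chemical-shift grid and 1 mM metabolite reference spectra.

A reference spectrum is the absorption-mode 1H spectrum a metabolite would
produce at 1 mM, on a shared ppm grid.  Mixture simulation is then a linear
combination of references scaled by concentration.  References can be
synthesized from first-order multiplet descriptions (Lorentzian lineshapes,
binomial intensity ratios) or loaded from two-column delimited text.

Conventions: index 0 of every intensity vector is ``min_ppm`` and the grid
ascends; chemical shifts are in ppm, couplings and linewidths in Hz, converted
through the spectrometer frequency in MHz (1 ppm = ``field_strength`` Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PpmGrid",
    "MultipletSpec",
    "ReferenceSpectrum",
    "MetaboliteLibrary",
    "make_ppm_grid",
    "synth_reference",
    "combine_anomers",
    "load_reference",
    "save_reference",
    "default_library",
    "DEFAULT_GRID",
    "TSP_NAME",
]

#: Internal chemical-shift standard: 9 equivalent protons, singlet at 0.0 ppm.
TSP_NAME = "TSP-d4"

#: Area of a single proton's resonance at 1 mM, in (a.u. x ppm).  One global
#: constant for the whole library so that integrals encode stoichiometry.
UNIT_PROTON_AREA = 1.0

#: Default linewidth (FWHM, Hz) of a synthesized line before any broadening.
DEFAULT_LINEWIDTH_HZ = 1.0

# First-order multiplet patterns: binomial relative intensities.
_PATTERNS = {
    "singlet": (1.0,),
    "doublet": (1.0, 1.0),
    "triplet": (1.0, 2.0, 1.0),
    "quartet": (1.0, 3.0, 3.0, 1.0),
}


@dataclass(frozen=True)
class PpmGrid:
    """Uniform, ascending chemical-shift axis."""

    min_ppm: float
    max_ppm: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.min_ppm < self.max_ppm:
            raise ValueError(
                f"grid bounds must satisfy min < max, got ({self.min_ppm}, {self.max_ppm})"
            )
        if self.n_points < 2:
            raise ValueError(f"grid needs at least 2 points, got {self.n_points}")

    @property
    def spacing(self) -> float:
        """ppm per point."""
        return (self.max_ppm - self.min_ppm) / (self.n_points - 1)

    @property
    def ppm(self) -> np.ndarray:
        return np.linspace(self.min_ppm, self.max_ppm, self.n_points)

    def index_of(self, ppm: float) -> int:
        """Nearest grid index for a chemical shift."""
        return int(round((ppm - self.min_ppm) / self.spacing))

    def contains(self, ppm: float) -> bool:
        return self.min_ppm <= ppm <= self.max_ppm


def make_ppm_grid(min_ppm: float, max_ppm: float, n_points: int) -> PpmGrid:
    """Build a uniform ppm grid with exact endpoints."""
    return PpmGrid(float(min_ppm), float(max_ppm), int(n_points))


#: The working region used throughout: -0.32 to 10.21 ppm, 46,000 points.
DEFAULT_GRID = make_ppm_grid(-0.32, 10.21, 46000)


@dataclass(frozen=True)
class MultipletSpec:
    """One chemical environment: a first-order multiplet.

    ``pattern`` is a named multiplicity (singlet/doublet/triplet/quartet) or an
    explicit sequence of relative line intensities (normalized internally).
    ``J`` is the line spacing in Hz, ``linewidth`` the Lorentzian FWHM in Hz.
    """

    center: float
    n_protons: int
    pattern: str | Sequence[float] = "singlet"
    J: float = 0.0
    linewidth: float = DEFAULT_LINEWIDTH_HZ

    def __post_init__(self) -> None:
        if self.n_protons < 1:
            raise ValueError(f"n_protons must be >= 1, got {self.n_protons}")
        if self.J < 0:
            raise ValueError(f"J must be >= 0, got {self.J}")
        if self.linewidth <= 0:
            raise ValueError(f"linewidth must be > 0, got {self.linewidth}")
        self.relative_intensities()  # validates pattern

    def relative_intensities(self) -> np.ndarray:
        """Relative line intensities, normalized to sum to 1."""
        if isinstance(self.pattern, str):
            try:
                rel = np.asarray(_PATTERNS[self.pattern], dtype=float)
            except KeyError:
                raise ValueError(
                    f"unknown multiplet pattern {self.pattern!r}; "
                    f"use one of {sorted(_PATTERNS)} or explicit intensities"
                ) from None
        else:
            rel = np.asarray(self.pattern, dtype=float)
            if rel.ndim != 1 or rel.size < 1 or np.any(rel < 0) or rel.sum() <= 0:
                raise ValueError("explicit pattern must be non-negative with positive sum")
        return rel / rel.sum()

    def line_positions_ppm(self, field_strength: float) -> np.ndarray:
        """Line centers in ppm; the J splitting shrinks with field strength."""
        m = len(self.relative_intensities())
        offsets_hz = (np.arange(m) - (m - 1) / 2.0) * self.J
        return self.center + offsets_hz / field_strength


@dataclass
class ReferenceSpectrum:
    """One metabolite's 1 mM absorption spectrum on a shared grid."""

    name: str
    grid: PpmGrid
    intensity: np.ndarray
    unit_concentration: float = 1.0  # mM, fixed by convention

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.grid.n_points,):
            raise ValueError(
                f"intensity length {self.intensity.shape} does not match grid "
                f"({self.grid.n_points} points)"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError(f"non-finite intensities in reference {self.name!r}")

    def integral(self) -> float:
        """Total area in (a.u. x ppm)."""
        return float(np.trapezoid(self.intensity, dx=self.grid.spacing))

    def peak_height(self) -> float:
        return float(self.intensity.max())


def _lorentzian(ppm: np.ndarray, center: float, fwhm_ppm: float, area: float) -> np.ndarray:
    """Unit-area absorption Lorentzian scaled to ``area``."""
    hwhm = fwhm_ppm / 2.0
    return area * (hwhm / np.pi) / ((ppm - center) ** 2 + hwhm**2)


def synth_reference(
    name: str,
    multiplets: Sequence[MultipletSpec],
    grid: PpmGrid,
    field_strength: float,
) -> ReferenceSpectrum:
    """Render first-order multiplets as a sum of Lorentzians at 1 mM.

    Each multiplet's total area is ``n_protons * UNIT_PROTON_AREA`` so that
    integrals encode stoichiometry across the whole library.  Lines whose
    centers fall outside the grid are dropped (their area is lost) with a
    warning; there is no wrap-around.
    """
    if field_strength <= 0:
        raise ValueError(f"field_strength must be > 0 MHz, got {field_strength}")
    if not multiplets:
        warnings.warn(f"empty multiplet list for {name!r}: zero reference spectrum")
    ppm = grid.ppm
    intensity = np.zeros(grid.n_points)
    for m in multiplets:
        rel = m.relative_intensities()
        positions = m.line_positions_ppm(field_strength)
        fwhm_ppm = m.linewidth / field_strength
        total_area = m.n_protons * UNIT_PROTON_AREA
        for pos, frac in zip(positions, rel):
            if not grid.contains(pos):
                warnings.warn(
                    f"{name!r}: line at {pos:.4f} ppm outside grid "
                    f"[{grid.min_ppm}, {grid.max_ppm}]; truncated"
                )
                continue
            intensity += _lorentzian(ppm, pos, fwhm_ppm, total_area * frac)
    return ReferenceSpectrum(name=name, grid=grid, intensity=intensity)


#: Aqueous equilibrium fraction of the alpha anomer of D-glucose.
ALPHA_GLUCOSE_WEIGHT = 0.36


def combine_anomers(
    alpha: ReferenceSpectrum,
    beta: ReferenceSpectrum,
    w_alpha: float = ALPHA_GLUCOSE_WEIGHT,
) -> ReferenceSpectrum:
    """Merge two anomer references into one at their equilibrium ratio.

    Default weights 0.36/0.64 match the aqueous alpha/beta-D-glucose
    equilibrium; the combined spectrum stands in for total glucose at 1 mM.
    """
    if alpha.grid != beta.grid:
        raise ValueError("anomer references must share the same grid")
    if not 0.0 <= w_alpha <= 1.0:
        raise ValueError(f"w_alpha must be in [0, 1], got {w_alpha}")
    combined = w_alpha * alpha.intensity + (1.0 - w_alpha) * beta.intensity
    name = alpha.name.split("-", 1)[-1] if alpha.name == beta.name else f"{alpha.name}+{beta.name}"
    return ReferenceSpectrum(name=name, grid=alpha.grid, intensity=combined)


def save_reference(ref: ReferenceSpectrum, path: str | Path) -> None:
    """Write a reference as delimited text with ``ppm,intensity`` columns."""
    df = pd.DataFrame({"ppm": ref.grid.ppm, "intensity": ref.intensity})
    df.to_csv(path, index=False)


def load_reference(path: str | Path, grid: PpmGrid, name: str | None = None) -> ReferenceSpectrum:
    """Load a two-column (ppm, intensity) text file onto the target grid.

    Intensities are linearly interpolated; chemical shifts outside the file's
    range become zero.  The ppm column must be strictly monotone (either
    direction); the first offending data row is reported on failure.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    ppm = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    inten = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    bad = np.flatnonzero(~(np.isfinite(ppm) & np.isfinite(inten)))
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(f"{path}: non-numeric value at line {bad[0] + 2}")
    d = np.diff(ppm)
    if np.all(d < 0):
        ppm, inten = ppm[::-1], inten[::-1]
    elif not np.all(d > 0):
        idx = int(np.flatnonzero(~(d > 0))[0]) if np.any(d > 0) else 0
        raise ValueError(f"{path}: ppm column not strictly monotone at line {idx + 3}")
    resampled = np.interp(grid.ppm, ppm, inten, left=0.0, right=0.0)
    return ReferenceSpectrum(name=name or path.stem, grid=grid, intensity=resampled)


@dataclass
class MetaboliteLibrary:
    """Ordered panel of analyte references plus the non-analyte TSP standard.

    The analyte order is fixed and defines the output order of every
    quantification model trained against the library.
    """

    grid: PpmGrid
    references: list[ReferenceSpectrum]
    field_strength: float
    tsp: ReferenceSpectrum | None = None
    multiplet_table: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        names = [r.name for r in self.references]
        if len(set(names)) != len(names):
            raise ValueError("metabolite names must be unique")
        for r in self.references + ([self.tsp] if self.tsp is not None else []):
            if r.grid != self.grid:
                raise ValueError(f"reference {r.name!r} is not on the library grid")

    @property
    def n_analytes(self) -> int:
        return len(self.references)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.references]

    def matrix(self) -> np.ndarray:
        """(n_analytes, n_points) stack of reference intensities."""
        return np.stack([r.intensity for r in self.references])

    def save(self, directory: str | Path) -> None:
        """Write one CSV per reference plus a YAML manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = {}
        for ref in self.references + ([self.tsp] if self.tsp is not None else []):
            fname = f"{ref.name}.csv"
            save_reference(ref, directory / fname)
            entries[ref.name] = fname
        manifest = {
            "grid": {
                "min_ppm": self.grid.min_ppm,
                "max_ppm": self.grid.max_ppm,
                "n_points": self.grid.n_points,
            },
            "field_strength": self.field_strength,
            "tsp": self.tsp.name if self.tsp is not None else None,
            "analytes": self.names,
            "files": entries,
        }
        with open(directory / "library.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh)

    @classmethod
    def load(cls, directory: str | Path) -> "MetaboliteLibrary":
        directory = Path(directory)
        with open(directory / "library.yaml") as fh:
            manifest = yaml.safe_load(fh)
        grid = make_ppm_grid(**manifest["grid"])
        refs = [
            load_reference(directory / manifest["files"][n], grid, name=n)
            for n in manifest["analytes"]
        ]
        tsp = None
        if manifest.get("tsp"):
            tsp = load_reference(directory / manifest["files"][manifest["tsp"]], grid,
                                 name=manifest["tsp"])
        return cls(grid=grid, references=refs, field_strength=manifest["field_strength"], tsp=tsp)


def tsp_reference(grid: PpmGrid, field_strength: float) -> ReferenceSpectrum:
    """The 0.0-ppm internal standard: a 9-proton singlet at 1 mM."""
    spec = MultipletSpec(center=0.0, n_protons=9, pattern="singlet")
    return synth_reference(TSP_NAME, [spec], grid, field_strength)


def default_library(
    n_metabolites: int,
    field_strength: float = 400.0,
    seed: int = 0,
    grid: PpmGrid = DEFAULT_GRID,
) -> MetaboliteLibrary:
    """Generate a synthetic metabolite panel with realistic spectral crowding.

    Emulates the statistical structure of simulated small-molecule 1H spectra:
    1-4 multiplets per metabolite, proton-count-proportional areas, most
    resonances crowded into the 1-4.5 ppm aliphatic region, J couplings of
    2-12 Hz, and (for panels of 8 or more) at least one deliberately
    overlapping pair of metabolites.  The TSP singlet is attached as a
    non-analyte entry.  Deterministic for a fixed seed.
    """
    if n_metabolites < 1:
        raise ValueError(f"n_metabolites must be >= 1, got {n_metabolites}")
    rng = np.random.default_rng(seed)
    pattern_names = list(_PATTERNS)
    refs: list[ReferenceSpectrum] = []
    table: dict[str, list[MultipletSpec]] = {}
    for i in range(n_metabolites):
        n_mult = int(rng.integers(1, 5))
        mults = []
        for _ in range(n_mult):
            # crowding: three quarters of resonances in the aliphatic 1-4.5 ppm band
            if rng.random() < 0.75:
                center = rng.uniform(1.0, 4.5)
            else:
                center = rng.uniform(0.5, 9.5)
            mults.append(
                MultipletSpec(
                    center=float(center),
                    n_protons=int(rng.integers(1, 7)),
                    pattern=pattern_names[int(rng.integers(0, len(pattern_names)))],
                    J=float(rng.uniform(2.0, 12.0)),
                )
            )
        name = f"met{i:03d}"
        table[name] = mults
        refs.append(synth_reference(name, mults, grid, field_strength))
    if n_metabolites >= 8:
        # force one overlapping pair: re-render metabolite 1 with its first
        # multiplet moved next to metabolite 0's first multiplet
        anchor = table[refs[0].name][0]
        shifted = MultipletSpec(
            center=anchor.center + 0.01,
            n_protons=table[refs[1].name][0].n_protons,
            pattern=table[refs[1].name][0].pattern,
            J=table[refs[1].name][0].J,
        )
        mults = [shifted] + table[refs[1].name][1:]
        table[refs[1].name] = mults
        refs[1] = synth_reference(refs[1].name, mults, grid, field_strength)
    tsp = tsp_reference(grid, field_strength)
    return MetaboliteLibrary(
        grid=grid,
        references=refs,
        field_strength=field_strength,
        tsp=tsp,
        multiplet_table=table,
    )
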