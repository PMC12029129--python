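"""Mixture-spectrum simulation: composition, augmentation, datasets.

A mixture spectrum is the concentration-weighted sum of 1 mM reference
spectra plus the 0.3 mM TSP standard, passed through an augmentation chain
that imitates experimental variation:

1. per-analyte chemical-shift jitter (up to 3.4 ppb either direction),
2. exponential line broadening of the summed signal (0-1 Hz),
3. up to three interference singlets at random chemical shifts,
4. additive Gaussian noise (30-115% of a reference noise level),
5. a constant baseline offset (up to ~5.6% of the TSP peak height).

Datasets are max-normalized as a whole (global maximum becomes 1) and split
80:20 into training and validation.  Ground-truth concentrations are recorded
in mM before normalization; everything is reproducible from a single seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .distributions import (
    ConcentrationSampler,
    leave_out_mask,
    sample_interference,
)
from .reference import MetaboliteLibrary, PpmGrid, _lorentzian, make_ppm_grid

__all__ = [
    "AugmentationConfig",
    "MixtureSpectrum",
    "SpectralDataset",
    "compose_mixture",
    "apply_line_broadening",
    "shift_analyte",
    "add_noise",
    "add_baseline",
    "add_interference",
    "compute_snr",
    "field_noise_multiplier",
    "log_transform",
    "normalize_dataset",
    "build_dataset",
    "TSP_CONCENTRATION_MM",
    "DEFAULT_REFERENCE_NOISE_SIGMA",
]

#: The internal standard is always present at this concentration.
TSP_CONCENTRATION_MM = 0.3

#: Noise standard deviation (a.u.) at the 400-MHz reference field, chosen so a
#: 1 mM nine-proton singlet of 1 Hz width has SNR ~ 300 (order of magnitude of
#: a modern spectrometer); its analytic peak height is 9*2*400/pi ~ 2292 a.u.
DEFAULT_REFERENCE_NOISE_SIGMA = 7.64

#: Reference field strength (MHz) at which the noise constant is defined.
REFERENCE_FIELD_MHZ = 400.0


@dataclass
class AugmentationConfig:
    """Ranges for the augmentation chain; all draws are uniform within range."""

    noise_fraction_range: tuple[float, float] = (0.30, 1.15)
    lb_range_hz: tuple[float, float] = (0.0, 1.0)
    shift_max_ppb: float = 3.4
    baseline_fraction: float = 0.056  # of the in-spectrum TSP peak height
    max_interference_singlets: int = 3
    reference_noise_sigma: float = DEFAULT_REFERENCE_NOISE_SIGMA
    enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("noise_fraction_range", "lb_range_hz"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 <= lo <= hi):
                raise ValueError(f"{name} must be a finite non-negative range, got ({lo}, {hi})")
        if self.shift_max_ppb < 0 or self.baseline_fraction < 0:
            raise ValueError("shift_max_ppb and baseline_fraction must be >= 0")
        if self.max_interference_singlets < 0:
            raise ValueError("max_interference_singlets must be >= 0")

    @classmethod
    def disabled(cls) -> "AugmentationConfig":
        """No augmentation at all (clean linear mixtures)."""
        return cls(
            noise_fraction_range=(0.0, 0.0),
            lb_range_hz=(0.0, 0.0),
            shift_max_ppb=0.0,
            baseline_fraction=0.0,
            max_interference_singlets=0,
            enabled=False,
        )


@dataclass
class MixtureSpectrum:
    """One simulated sample with its ground truth and augmentation record."""

    intensity: np.ndarray
    concentrations: np.ndarray  # mM per analyte, 0 = left out
    augmentation_record: dict = field(default_factory=dict)
    source_tag: str = ""
    tsp_concentration: float = TSP_CONCENTRATION_MM


def compose_mixture(
    library: MetaboliteLibrary,
    concentrations: np.ndarray,
    include_tsp: bool = True,
) -> MixtureSpectrum:
    """Linear combination of references: sum_i c_i * ref_i (+ 0.3 mM TSP)."""
    concentrations = np.asarray(concentrations, dtype=float)
    if concentrations.shape != (library.n_analytes,):
        raise ValueError(
            f"expected {library.n_analytes} concentrations, got shape {concentrations.shape}"
        )
    if np.any(concentrations < 0):
        idx = int(np.argmin(concentrations))
        raise ValueError(f"negative concentration {concentrations[idx]} for analyte index {idx}")
    intensity = concentrations @ library.matrix()
    if include_tsp:
        if library.tsp is None:
            raise ValueError("library has no TSP reference")
        intensity = intensity + TSP_CONCENTRATION_MM * library.tsp.intensity
    return MixtureSpectrum(
        intensity=intensity,
        concentrations=concentrations,
        tsp_concentration=TSP_CONCENTRATION_MM if include_tsp else 0.0,
    )


def apply_line_broadening(
    intensity: np.ndarray,
    lb_hz: float,
    grid: PpmGrid,
    field_strength: float,
) -> np.ndarray:
    """Exponential apodization through a synthetic time-domain signal.

    The spectrum is inverse-Fourier-transformed to a synthetic FID, multiplied
    by exp(-pi*lb*|t|) and transformed back, which convolves the spectrum with
    a Lorentzian of FWHM ``lb_hz``.  The first FID point (the total integral)
    is untouched, so the integral is conserved and peak heights can only drop.
    """
    if lb_hz < 0:
        raise ValueError(f"line broadening must be >= 0 Hz, got {lb_hz}")
    if lb_hz == 0:
        return np.array(intensity, dtype=float)
    n = len(intensity)
    sweep_hz = (grid.max_ppm - grid.min_ppm) * field_strength
    dwell = 1.0 / sweep_hz
    k = np.arange(n)
    t = np.minimum(k, n - k) * dwell  # symmetric time axis of the circular FID
    fid = np.fft.ifft(intensity)
    return np.fft.fft(fid * np.exp(-np.pi * lb_hz * t)).real


def shift_analyte(
    intensity: np.ndarray,
    delta_ppb: float,
    grid: PpmGrid,
    max_ppb: float = 3.4,
) -> tuple[np.ndarray, int]:
    """Translate a reference along the ppm axis by a small chemical shift.

    The shift is rounded to an integer number of grid points (sub-point
    interpolation would distort the lineshape); vacated points are zero-filled.
    Returns the shifted spectrum and the number of points moved (signed,
    positive = towards higher ppm).
    """
    if abs(delta_ppb) > max_ppb + 1e-12:
        raise ValueError(f"|shift| {abs(delta_ppb)} ppb exceeds configured max {max_ppb} ppb")
    points = int(round(delta_ppb * 1e-3 / grid.spacing))
    if points == 0:
        return np.array(intensity, dtype=float), 0
    out = np.roll(intensity, points)
    if points > 0:
        out[:points] = 0.0
    else:
        out[points:] = 0.0
    return out, points


def add_noise(
    intensity: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise of standard deviation ``sigma``."""
    if sigma < 0:
        raise ValueError(f"noise sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return np.array(intensity, dtype=float)
    return intensity + rng.normal(0.0, sigma, size=len(intensity))


def add_baseline(intensity: np.ndarray, offset: float) -> np.ndarray:
    """Shift the whole baseline up or down by a constant."""
    return intensity + offset


def add_interference(
    intensity: np.ndarray,
    grid: PpmGrid,
    field_strength: float,
    rng: np.random.Generator,
    max_singlets: int = 3,
    force_k: int | None = None,
    linewidth_hz: float = 1.0,
) -> tuple[np.ndarray, list[dict]]:
    """Add up to ``max_singlets`` generic one-proton singlets at random shifts.

    Each singlet is a Lorentzian at a uniform random ppm position, scaled by a
    concentration drawn from the interference gamma law (mean 0.85 mM).
    Returns the augmented spectrum and a record of (position, concentration).
    """
    k = int(rng.integers(0, max_singlets + 1)) if force_k is None else int(force_k)
    out = np.array(intensity, dtype=float)
    record: list[dict] = []
    if k == 0:
        return out, record
    positions = rng.uniform(grid.min_ppm, grid.max_ppm, size=k)
    concs = sample_interference(k, rng)
    fwhm_ppm = linewidth_hz / field_strength
    for pos, conc in zip(positions, concs):
        out += _lorentzian(grid.ppm, pos, fwhm_ppm, conc)  # 1 proton => unit area per mM
        record.append({"ppm": float(pos), "concentration_mM": float(conc)})
    return out, record


#: Signal-free window (ppm) used to estimate noise for SNR in default libraries.
DEFAULT_NOISE_REGION = (9.6, 10.2)


def compute_snr(
    intensity: np.ndarray,
    grid: PpmGrid,
    noise_region: tuple[float, float] = DEFAULT_NOISE_REGION,
) -> float:
    """Tallest peak height over the noise standard deviation.

    The noise window must be free of analyte signal; its median is subtracted
    before measuring the spread so a baseline offset does not inflate the
    estimate.  A zero noise spread yields ``inf`` rather than an error.
    """
    lo, hi = noise_region
    ppm = grid.ppm
    sel = (ppm >= lo) & (ppm <= hi)
    if not np.any(sel):
        raise ValueError(f"noise region {noise_region} does not intersect the grid")
    noise = intensity[sel] - np.median(intensity[sel])
    sd = float(np.std(noise))
    if sd == 0.0:
        return float("inf")
    return float(np.max(intensity)) / sd


def field_noise_multiplier(field: float, reference_field: float = REFERENCE_FIELD_MHZ) -> float:
    """Noise scale factor at a given field: (reference/field)^(3/2).

    SNR grows with the 3/2 power of the spectrometer frequency, so relative to
    400 MHz the noise is multiplied by 8 at 100 MHz and divided by ~2.8 at
    800 MHz.
    """
    if field <= 0:
        raise ValueError(f"field strength must be > 0 MHz, got {field}")
    return float((reference_field / field) ** 1.5)


def log_transform(intensity: np.ndarray) -> np.ndarray:
    """Compress dynamic range: L = log10(1 + 1000 * S), pointwise."""
    intensity = np.asarray(intensity, dtype=float)
    arg = 1.0 + 1000.0 * intensity
    bad = np.flatnonzero(arg <= 0)
    if bad.size:
        raise ValueError(
            f"log transform undefined at index {bad[0]} (intensity {intensity.flat[bad[0]]})"
        )
    return np.log10(arg)


@dataclass
class SpectralDataset:
    """A set of simulated mixtures with ground truth, split and manifest.

    ``intensities`` is (n_spectra, n_points); ``truth_mM`` is
    (n_spectra, n_analytes) with zeros marking left-out analytes (recorded
    before normalization, in mM).  ``norm_constant`` is the dataset-wide
    maximum intensity by which every spectrum was divided.
    """

    grid: PpmGrid
    analyte_names: list[str]
    intensities: np.ndarray
    truth_mM: np.ndarray
    records: list[dict]
    source_tags: np.ndarray
    norm_constant: float = 1.0
    train_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    val_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    manifest: dict = field(default_factory=dict)

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.truth_mM.shape[1]

    def spectra(self) -> list[MixtureSpectrum]:
        """Materialize per-spectrum views (convenience, not the storage format)."""
        return [
            MixtureSpectrum(
                intensity=self.intensities[i],
                concentrations=self.truth_mM[i],
                augmentation_record=self.records[i],
                source_tag=str(self.source_tags[i]),
            )
            for i in range(self.n_spectra)
        ]

    def apply_log_transform(self) -> None:
        """Dataset modification: compress intensity dynamic range in place.

        Applies L = log10(1 + 1000*S) to every (normalized) spectrum and
        records the modification in the manifest.
        """
        self.intensities = log_transform(self.intensities).astype(
            self.intensities.dtype, copy=False
        )
        self.manifest["log_transformed"] = True

    def train_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.intensities[self.train_idx], self.truth_mM[self.train_idx]

    def val_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.intensities[self.val_idx], self.truth_mM[self.val_idx]

    def save(self, directory: str | Path, fmt: str = "npy") -> None:
        """Write manifest.yaml + truth.csv + spectra matrix (npy or csv)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = dict(self.manifest)
        manifest.update(
            grid={"min_ppm": self.grid.min_ppm, "max_ppm": self.grid.max_ppm,
                  "n_points": self.grid.n_points},
            analytes=self.analyte_names,
            norm_constant=float(self.norm_constant),
            train_idx=self.train_idx.tolist(),
            val_idx=self.val_idx.tolist(),
            source_tags=[str(t) for t in self.source_tags],
            spectra_format=fmt,
        )
        with open(directory / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh)
        pd.DataFrame(self.truth_mM, columns=self.analyte_names).to_csv(
            directory / "truth.csv", index=False
        )
        with open(directory / "records.json", "w") as fh:
            json.dump(self.records, fh, default=float)
        if fmt == "npy":
            np.save(directory / "spectra.npy", self.intensities)
        elif fmt == "csv":
            pd.DataFrame(self.intensities).to_csv(directory / "spectra.csv", index=False)
        else:
            raise ValueError(f"unknown spectra format {fmt!r}")

    @classmethod
    def load(cls, directory: str | Path) -> "SpectralDataset":
        directory = Path(directory)
        with open(directory / "manifest.yaml") as fh:
            manifest = yaml.safe_load(fh)
        grid = make_ppm_grid(**manifest["grid"])
        truth = pd.read_csv(directory / "truth.csv")
        with open(directory / "records.json") as fh:
            records = json.load(fh)
        if manifest.get("spectra_format", "npy") == "npy":
            intensities = np.load(directory / "spectra.npy")
        else:
            intensities = pd.read_csv(directory / "spectra.csv").to_numpy()
        return cls(
            grid=grid,
            analyte_names=list(manifest["analytes"]),
            intensities=intensities,
            truth_mM=truth.to_numpy(),
            records=records,
            source_tags=np.asarray(manifest["source_tags"], dtype=object),
            norm_constant=float(manifest["norm_constant"]),
            train_idx=np.asarray(manifest["train_idx"], dtype=int),
            val_idx=np.asarray(manifest["val_idx"], dtype=int),
            manifest=manifest,
        )


def normalize_dataset(dataset: SpectralDataset, norm_constant: float | None = None) -> float:
    """Divide all spectra by one scalar; default is the dataset-wide maximum.

    Returns the constant used.  Pass the training set's constant explicitly to
    normalize a test set against the training scale instead of its own.
    """
    if dataset.n_spectra < 1:
        raise ValueError("cannot normalize an empty dataset")
    c = float(np.max(dataset.intensities)) if norm_constant is None else float(norm_constant)
    if c <= 0:
        raise ValueError(f"normalization constant must be > 0, got {c}")
    dataset.intensities /= c
    dataset.norm_constant = c
    return c


def _library_hash(library: MetaboliteLibrary) -> str:
    h = hashlib.sha256()
    h.update(library.matrix().tobytes())
    if library.tsp is not None:
        h.update(library.tsp.intensity.tobytes())
    return h.hexdigest()[:16]


def build_dataset(
    library: MetaboliteLibrary,
    n_spectra: int,
    sampler: ConcentrationSampler,
    leave_out_scheme: str = "all_present",
    augmentation: AugmentationConfig | None = None,
    seed: int = 0,
    val_fraction: float = 0.2,
    normalize: bool = True,
    dtype=np.float64,
) -> SpectralDataset:
    """Generate a full dataset: sample, compose, augment, normalize, split.

    Per spectrum the order of operations is: presence mask -> concentration
    draw -> per-analyte shift of the references -> weighted summation (+TSP)
    -> line broadening -> interference singlets -> Gaussian noise -> baseline
    offset.  Normalization and the 80:20 split are dataset-level.  The ground
    truth table stores pre-normalization concentrations in mM.
    """
    if n_spectra < 1:
        raise ValueError("n_spectra must be >= 1")
    if not 0.0 <= val_fraction < 1.0:
        raise ValueError(f"val_fraction must be in [0, 1), got {val_fraction}")
    aug = augmentation if augmentation is not None else AugmentationConfig()
    rng = np.random.default_rng(seed)
    grid = library.grid
    refs = library.matrix()
    n_analytes = library.n_analytes
    if library.tsp is None:
        raise ValueError("library must carry a TSP reference")
    tsp_part = TSP_CONCENTRATION_MM * library.tsp.intensity
    tsp_height = float(tsp_part.max())
    field = library.field_strength
    noise_scale = aug.reference_noise_sigma * field_noise_multiplier(field)

    mask = leave_out_mask(n_spectra, n_analytes, leave_out_scheme, rng)
    concs, tags = sampler.sample_matrix(n_spectra, n_analytes, rng)
    concs = concs * mask

    X = np.empty((n_spectra, grid.n_points), dtype=dtype)
    records: list[dict] = []
    for i in range(n_spectra):
        c = concs[i]
        if aug.shift_max_ppb > 0:
            deltas = rng.uniform(-aug.shift_max_ppb, aug.shift_max_ppb, size=n_analytes)
        else:
            deltas = np.zeros(n_analytes)
        spec = tsp_part.copy()
        shifts_pts = np.zeros(n_analytes, dtype=int)
        for j in range(n_analytes):
            if c[j] == 0.0:
                continue
            shifted, pts = shift_analyte(refs[j], deltas[j], grid, max_ppb=aug.shift_max_ppb)
            shifts_pts[j] = pts
            spec += c[j] * shifted
        lb = rng.uniform(*aug.lb_range_hz)
        if lb > 0:
            spec = apply_line_broadening(spec, lb, grid, field)
        spec, interf = add_interference(
            spec, grid, field, rng, max_singlets=aug.max_interference_singlets
        )
        frac = rng.uniform(*aug.noise_fraction_range)
        sigma = frac * noise_scale
        spec = add_noise(spec, sigma, rng)
        offset = rng.uniform(-aug.baseline_fraction, aug.baseline_fraction) * tsp_height \
            if aug.baseline_fraction > 0 else 0.0
        spec = add_baseline(spec, offset)
        X[i] = spec
        records.append(
            {
                "lb_hz": float(lb),
                "noise_fraction": float(frac),
                "noise_sigma": float(sigma),
                "baseline_offset": float(offset),
                "shift_ppb": deltas.tolist(),
                "shift_points": shifts_pts.tolist(),
                "interference": interf,
            }
        )

    n_val = int(round(val_fraction * n_spectra))
    perm = rng.permutation(n_spectra)
    val_idx, train_idx = np.sort(perm[:n_val]), np.sort(perm[n_val:])
    dataset = SpectralDataset(
        grid=grid,
        analyte_names=library.names,
        intensities=X,
        truth_mM=concs,
        records=records,
        source_tags=tags,
        train_idx=train_idx,
        val_idx=val_idx,
        manifest={
            "seed": int(seed),
            "n_spectra": int(n_spectra),
            "sampler": {"kind": sampler.kind, "params": dict(sampler.params),
                        "range": list(sampler.range)},
            "leave_out_scheme": leave_out_scheme,
            "augmentation": asdict(aug),
            "field_strength": float(field),
            "library_hash": _library_hash(library),
            "tsp_concentration_mM": TSP_CONCENTRATION_MM,
        },
    )
    if normalize:
        normalize_dataset(dataset)
    return dataset
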