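"""Concentration samplers for simulated metabolite mixtures.

Five training distributions over the 0.005-20 mM range seen in aqueous tissue
extracts: uniform over the full range, a low-concentration mixture of three
uniforms, a tissue-mimicking mixture of two log-normals, a high-dynamic-range
mixture of two gammas plus a uniform, and a combined distribution that assigns
one of the four to each spectrum with equal probability.  A separate gamma
sampler (mean 0.85 mM, mostly below 5 mM) scales interference singlets.

All draws are clipped to the configured range; for the default parameters the
clipped probability mass is below 2%.  Exact mixture parameters for the
log-normal and gamma families are package defaults chosen to satisfy the
documented shape constraints (see docs/methods.md) and are user-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConcentrationSampler",
    "sample_uniform",
    "sample_low_concentration",
    "sample_mimic_tissue",
    "sample_high_dynamic",
    "sample_combined",
    "sample_interference",
    "leave_out_mask",
    "get_sampler",
    "CONCENTRATION_RANGE",
    "EXTENDED_RANGE",
    "MIMIC_TISSUE_DEFAULTS",
    "HIGH_DYNAMIC_DEFAULTS",
    "INTERFERENCE_DEFAULTS",
    "SAMPLER_KINDS",
]

#: Concentration range (mM) covered in data generation.
CONCENTRATION_RANGE = (0.005, 20.0)
#: "Extended range" training variant: upper limit raised to 24 mM.
EXTENDED_RANGE = (0.005, 24.0)

#: Two log-normal components (weight, log-mean, log-sd); medians 0.15 and 3 mM.
#: >=70% of mass below 1 mM with a heavy tail reaching 20 mM.
MIMIC_TISSUE_DEFAULTS = {
    "weights": (0.75, 0.25),
    "log_means": (float(np.log(0.15)), float(np.log(3.0))),
    "log_sds": (1.0, 0.8),
}

#: Two gamma components plus one uniform (weights sum to 1).
HIGH_DYNAMIC_DEFAULTS = {
    "weights": (0.45, 0.35, 0.20),
    "shapes": (1.2, 2.0),
    "scales": (0.3, 1.5),
    "uniform": CONCENTRATION_RANGE,
}

#: Interference singlet concentrations: gamma with mean 0.85 mM, mostly < 5 mM.
INTERFERENCE_DEFAULTS = {"shape": 1.5, "scale": 0.85 / 1.5}

SAMPLER_KINDS = ("uniform", "low_concentration", "mimic_tissue", "high_dynamic", "combined")


def _clip(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip(x, lo, hi)


def sample_uniform(
    n: int,
    lo: float = CONCENTRATION_RANGE[0],
    hi: float = CONCENTRATION_RANGE[1],
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """i.i.d. uniform concentrations on [lo, hi] mM."""
    if not 0 < lo <= hi:
        raise ValueError(f"need 0 < lo <= hi, got ({lo}, {hi})")
    rng = rng or np.random.default_rng()
    return rng.uniform(lo, hi, size=n)


def sample_low_concentration(n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Even mixture of U(0.005, 0.05), U(0.005, 0.1) and U(0.005, 0.2) mM."""
    rng = rng or np.random.default_rng()
    highs = np.asarray([0.05, 0.1, 0.2])
    comp = rng.integers(0, 3, size=n)
    return rng.uniform(0.005, highs[comp])


def sample_mimic_tissue(
    n: int,
    params: dict | None = None,
    rng: np.random.Generator | None = None,
    clip_range: tuple[float, float] = CONCENTRATION_RANGE,
) -> np.ndarray:
    """Tissue-like mixture of two log-normals, clipped to the working range."""
    p = {**MIMIC_TISSUE_DEFAULTS, **(params or {})}
    if any(s <= 0 for s in p["log_sds"]):
        raise ValueError(f"log-sds must be positive, got {p['log_sds']}")
    rng = rng or np.random.default_rng()
    w = np.asarray(p["weights"], dtype=float)
    w = w / w.sum()
    comp = rng.choice(len(w), size=n, p=w)
    mu = np.asarray(p["log_means"])[comp]
    sd = np.asarray(p["log_sds"])[comp]
    return _clip(np.exp(rng.normal(mu, sd)), *clip_range)


def sample_high_dynamic(
    n: int,
    params: dict | None = None,
    rng: np.random.Generator | None = None,
    clip_range: tuple[float, float] = CONCENTRATION_RANGE,
) -> np.ndarray:
    """Mixture of two gamma components and one uniform, clipped to range."""
    p = {**HIGH_DYNAMIC_DEFAULTS, **(params or {})}
    w = np.asarray(p["weights"], dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"mixture weights must sum to 1, got {w.tolist()}")
    rng = rng or np.random.default_rng()
    comp = rng.choice(3, size=n, p=w)
    out = np.empty(n)
    for k in (0, 1):
        sel = comp == k
        out[sel] = rng.gamma(p["shapes"][k], p["scales"][k], size=int(sel.sum()))
    sel = comp == 2
    lo, hi = p["uniform"]
    out[sel] = rng.uniform(lo, hi, size=int(sel.sum()))
    return _clip(out, *clip_range)


def sample_interference(n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Concentrations for interference singlets: gamma, mean 0.85 mM."""
    rng = rng or np.random.default_rng()
    return rng.gamma(INTERFERENCE_DEFAULTS["shape"], INTERFERENCE_DEFAULTS["scale"], size=n)


_STANDALONE = {
    "uniform": lambda n, rng, rg: sample_uniform(n, rg[0], rg[1], rng),
    "low_concentration": lambda n, rng, rg: sample_low_concentration(n, rng),
    "mimic_tissue": lambda n, rng, rg: sample_mimic_tissue(n, rng=rng, clip_range=rg),
    "high_dynamic": lambda n, rng, rg: sample_high_dynamic(n, rng=rng, clip_range=rg),
}
_COMBINED_SOURCES = ("uniform", "low_concentration", "mimic_tissue", "high_dynamic")


def sample_combined(
    n_spectra: int,
    n_analytes: int,
    rng: np.random.Generator | None = None,
    stratified: bool = False,
    clip_range: tuple[float, float] = CONCENTRATION_RANGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-spectrum mixture of the four base distributions.

    Each spectrum (not each analyte) is assigned one source with probability
    1/4; all analyte concentrations in that spectrum come from it.  With
    ``stratified=True`` sources cycle deterministically (round-robin), useful
    for exact 25% splits when ``n_spectra`` is a multiple of 4.

    Returns (concentrations of shape (n_spectra, n_analytes), source tags).
    """
    rng = rng or np.random.default_rng()
    if stratified:
        src_idx = np.arange(n_spectra) % 4
    else:
        src_idx = rng.integers(0, 4, size=n_spectra)
    out = np.empty((n_spectra, n_analytes))
    for k, name in enumerate(_COMBINED_SOURCES):
        rows = np.flatnonzero(src_idx == k)
        if rows.size:
            draws = _STANDALONE[name](rows.size * n_analytes, rng, clip_range)
            out[rows] = draws.reshape(rows.size, n_analytes)
    tags = np.asarray(_COMBINED_SOURCES, dtype=object)[src_idx]
    return out, tags


@dataclass
class ConcentrationSampler:
    """Named concentration sampler with an optional extended range.

    ``kind`` is one of ``uniform``, ``low_concentration``, ``mimic_tissue``,
    ``high_dynamic`` or ``combined``; ``params`` override the package mixture
    defaults; ``range`` is the clipping interval in mM.
    """

    kind: str = "uniform"
    params: dict = field(default_factory=dict)
    range: tuple[float, float] = CONCENTRATION_RANGE

    def __post_init__(self) -> None:
        if self.kind not in SAMPLER_KINDS:
            raise ValueError(f"unknown sampler kind {self.kind!r}; use one of {SAMPLER_KINDS}")
        if self.range[0] <= 0:
            raise ValueError("lower concentration bound must be > 0 mM")

    def sample_matrix(
        self, n_spectra: int, n_analytes: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw a (n_spectra, n_analytes) concentration matrix plus source tags."""
        if self.kind == "combined":
            return sample_combined(
                n_spectra, n_analytes, rng,
                stratified=bool(self.params.get("stratified", False)),
                clip_range=self.range,
            )
        if self.kind == "uniform":
            lo = self.params.get("lo", self.range[0])
            hi = self.params.get("hi", self.range[1])
            draws = sample_uniform(n_spectra * n_analytes, lo, hi, rng)
        elif self.kind == "low_concentration":
            draws = sample_low_concentration(n_spectra * n_analytes, rng)
        elif self.kind == "mimic_tissue":
            draws = sample_mimic_tissue(
                n_spectra * n_analytes, self.params or None, rng, clip_range=self.range
            )
        else:  # high_dynamic
            draws = sample_high_dynamic(
                n_spectra * n_analytes, self.params or None, rng, clip_range=self.range
            )
        tags = np.full(n_spectra, self.kind, dtype=object)
        return draws.reshape(n_spectra, n_analytes), tags


def get_sampler(kind: str, extended_range: bool = False, **params) -> ConcentrationSampler:
    """Convenience constructor; ``extended_range`` raises the ceiling to 24 mM."""
    rng_ = EXTENDED_RANGE if extended_range else CONCENTRATION_RANGE
    return ConcentrationSampler(kind=kind, params=params, range=rng_)


LEAVE_OUT_SCHEMES = ("all_present", "half50", "tiered")


def leave_out_mask(
    n_spectra: int,
    n_analytes: int,
    scheme: str = "all_present",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Boolean presence mask (n_spectra, n_analytes) for analyte leave-out.

    ``all_present``: every analyte in every spectrum.  ``half50``: the first
    half of spectra keep all analytes, the second half leave each analyte out
    with probability 0.5.  ``tiered``: thirds with per-analyte presence
    probabilities 1, 0.5 and 0.25.
    """
    if n_spectra < 1 or n_analytes < 1:
        raise ValueError("n_spectra and n_analytes must be >= 1")
    rng = rng or np.random.default_rng()
    mask = np.ones((n_spectra, n_analytes), dtype=bool)
    if scheme == "all_present":
        return mask
    if scheme == "half50":
        start = n_spectra // 2
        mask[start:] = rng.random((n_spectra - start, n_analytes)) < 0.5
        return mask
    if scheme == "tiered":
        b1, b2 = n_spectra // 3, 2 * n_spectra // 3
        mask[b1:b2] = rng.random((b2 - b1, n_analytes)) < 0.5
        mask[b2:] = rng.random((n_spectra - b2, n_analytes)) < 0.25
        return mask
    raise ValueError(f"unknown leave-out scheme {scheme!r}; use one of {LEAVE_OUT_SCHEMES}")
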