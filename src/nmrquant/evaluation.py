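"""Model comparison by mean absolute percent error (MAPE).

MAPE is computed per test spectrum (averaging relative errors over analytes
within the spectrum first), then summarized as a mean with a Student-t 95%
confidence interval over spectra.  Dataset-modification studies report MAPE
normalized by a baseline report on the same test set: values below 1 mark an
improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EvalReport", "mape_per_spectrum", "summarize", "normalize_report", "evaluate"]


def mape_per_spectrum(
    pred: np.ndarray, truth: np.ndarray, pooled: bool = False
) -> np.ndarray:
    """Percent error per spectrum: 100 * mean_analytes |p - t| / t.

    Truth must be strictly positive (test sets always contain all analytes).
    With ``pooled=True`` the relative errors of all analytes are returned
    flattened instead of averaged within each spectrum.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    bad = np.argwhere(truth <= 0)
    if bad.size:
        raise ValueError(f"zero/negative truth at (spectrum, analyte) {tuple(bad[0])}")
    rel = 100.0 * np.abs(pred - truth) / truth
    return rel.reshape(-1) if pooled else rel.mean(axis=1)


def summarize(per_spectrum_mape: np.ndarray, confidence: float = 0.95) -> dict:
    """Mean and Student-t confidence interval over test spectra.

    For a single spectrum the CI is undefined and flagged as such.
    """
    x = np.asarray(per_spectrum_mape, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("empty MAPE vector")
    mean = float(x.mean())
    if n < 2:
        return {"mean": mean, "ci95": None, "n": n, "ci_defined": False}
    se = float(x.std(ddof=1)) / np.sqrt(n)
    tq = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
    return {
        "mean": mean,
        "ci95": (mean - tq * se, mean + tq * se),
        "n": n,
        "ci_defined": True,
    }


@dataclass
class EvalReport:
    """Per-spectrum MAPE with its summary for one (model, test-set) pair."""

    per_spectrum_mape: np.ndarray
    model_id: str = ""
    test_set_id: str = ""
    baseline_id: str | None = None
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.per_spectrum_mape = np.asarray(self.per_spectrum_mape, dtype=float)
        if np.any(self.per_spectrum_mape < 0):
            raise ValueError("MAPE values must be non-negative")
        if not self.summary:
            self.summary = summarize(self.per_spectrum_mape)

    @property
    def mean_mape(self) -> float:
        return self.summary["mean"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spectrum": np.arange(self.per_spectrum_mape.size),
                "mape_percent": self.per_spectrum_mape,
                "model": self.model_id,
                "test_set": self.test_set_id,
            }
        )


def evaluate(pred: np.ndarray, truth: np.ndarray, model_id: str = "",
             test_set_id: str = "") -> EvalReport:
    """Build an :class:`EvalReport` from predictions and ground truth."""
    return EvalReport(
        per_spectrum_mape=mape_per_spectrum(pred, truth),
        model_id=model_id,
        test_set_id=test_set_id,
    )


def normalize_report(modified: EvalReport, baseline: EvalReport) -> np.ndarray:
    """Per-spectrum MAPE ratio relative to a pre-modification baseline.

    Both reports must refer to the same test set; a mean ratio below 1 means
    the modification improved accuracy, above 1 means it worsened it.
    """
    if modified.test_set_id != baseline.test_set_id:
        raise ValueError(
            f"test-set mismatch: {modified.test_set_id!r} vs {baseline.test_set_id!r}"
        )
    if modified.per_spectrum_mape.shape != baseline.per_spectrum_mape.shape:
        raise ValueError("reports cover different numbers of spectra")
    if np.any(baseline.per_spectrum_mape <= 0):
        raise ValueError("baseline MAPE must be strictly positive for normalization")
    return modified.per_spectrum_mape / baseline.per_spectrum_mape
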