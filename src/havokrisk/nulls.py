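"""Null models and statistical testing.

Two surrogate constructions destroy the temporal structure an empirical
result might exploit:

- label shuffling: a single global permutation of the hourly event series,
  preserving total event mass only;
- phase randomization: Fourier-amplitude-preserving surrogates of a series,
  destroying phase coupling (and hence nonlinear temporal structure) while
  keeping the full power spectrum and autocorrelation.

Significance machinery: Welch's two-sample t-test (replicate distributions
can have unequal variance by construction), an add-one permutation
p-value, and both Bonferroni and Benjamini-Hochberg corrections so each
analysis can report the correction its comparison family calls for.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .timeseries import EventSeries

__all__ = [
    "NullSpec",
    "TestResult",
    "shuffle_events",
    "shuffle_labels_null",
    "phase_randomize",
    "compare_to_null",
    "fdr_flags",
    "bonferroni_flags",
    "permutation_pvalue",
]


@dataclasses.dataclass(frozen=True)
class NullSpec:
    kind: str = "shuffle_labels"  # or "phase_randomize_series"
    n_iterations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("shuffle_labels", "phase_randomize_series"):
            raise ValueError(f"unknown null kind {self.kind!r}")
        if self.n_iterations < 2:
            raise ValueError("n_iterations must be >= 2")


@dataclasses.dataclass
class TestResult:
    p_value: float
    p_bonferroni: float
    significant_bonferroni: bool
    statistic: float


def shuffle_events(events: EventSeries, rng: np.random.Generator) -> EventSeries:
    """Globally permute the hourly event record (LE counts and seizure flags
    move together, so their coincidence structure is preserved)."""
    perm = rng.permutation(events.n_hours)
    return EventSeries(events.le_counts[perm], events.seizure_flags[perm])


def shuffle_labels_null(
    events: EventSeries,
    pipeline: Callable[[EventSeries], float],
    n: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Null AUC distribution from re-running a train+test closure on
    globally shuffled event series.

    ``pipeline`` maps an event series to a score (e.g. mean AUC) and may
    return NaN for degenerate permutations (single-class labels); those are
    recorded as missing.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = pipeline(shuffle_events(events, rng))
    return out


def phase_randomize(
    series: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Fourier-amplitude-preserving surrogate.

    Positive-frequency phases are drawn i.i.d. uniform; conjugate symmetry
    is enforced by construction (rfft/irfft), and the DC and Nyquist bins
    stay real, so the surrogate is real-valued with bin-wise identical
    amplitude spectrum and hence identical autocorrelation in expectation.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("series too short to phase-randomize")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.fft.rfft(x)
    n_bins = X.size
    # bins 1 .. n_bins-2 are strictly positive frequencies; the last bin is
    # the Nyquist bin for even-length inputs and must stay real then.
    last = n_bins - 1 if x.size % 2 == 0 else n_bins
    phases = rng.uniform(0, 2 * np.pi, size=max(last - 1, 0))
    X[1:last] = np.abs(X[1:last]) * np.exp(1j * phases)
    return np.fft.irfft(X, n=x.size)


def compare_to_null(
    empirical: Sequence[float],
    null: Sequence[float],
    m_comparisons: int = 1,
    alpha: float = 0.05,
) -> TestResult:
    """Welch's two-tailed t-test of empirical vs null replicates, with the
    Bonferroni-corrected p for a family of ``m_comparisons`` tests.

    Degenerate case: both groups constant with equal means -> p = 1.
    """
    a = np.asarray(empirical, dtype=float)
    b = np.asarray(null, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 finite values per group")
    if a.std() < 1e-30 and b.std() < 1e-30:
        if abs(a.mean() - b.mean()) < 1e-30:
            return TestResult(1.0, 1.0, False, 0.0)
        return TestResult(0.0, 0.0, True, np.inf)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    p_bonf = min(1.0, float(p) * m_comparisons)
    return TestResult(float(p), p_bonf, p_bonf < alpha, float(t))


def bonferroni_flags(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    return p * p.size < alpha


def fdr_flags(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg rejection flags over a p-value family."""
    p = np.asarray(p_values, dtype=float)
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def permutation_pvalue(observed: float, null_values: Sequence[float]) -> float:
    """Add-one permutation p: (1 + #{null >= observed}) / (1 + n)."""
    null = np.asarray(null_values, dtype=float)
    null = null[np.isfinite(null)]
    if null.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.sum(null >= observed)) / (1 + null.size))
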