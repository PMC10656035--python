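"""Cross-correlation histogram baseline estimator.

The naive comparison method: histogram the lags t_post - t_pre between all
spike pairs of a neuron pair, estimate a slowly varying baseline by
convolving the histogram with a *hollow* Gaussian kernel (center tap
down-weighted so the bin under test does not smooth itself), and report

* ``p_trans`` -- the spike "transmission probability", the baseline-excess
  counts summed over the 3-6 ms lag bins divided by the presynaptic spike
  count;
* ``p_fast`` -- Poisson (continuity-corrected) tail probability of the
  positive-lag peak against the hollow-Gaussian baseline at that bin;
* ``p_diff`` -- the same peak tested against the largest negative-lag bin
  (sensitive to asymmetry, i.e. directed interaction).

A pair is flagged significant when both p-values fall below 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Correlogram",
    "CchResult",
    "cross_correlogram",
    "hollow_gaussian_baseline",
    "poisson_continuity_pvalue",
    "significance_tests",
    "transmission_probability",
    "cch_estimate",
]


@dataclass
class Correlogram:
    """Pair counts per integer lag bin over [-max_lag, max_lag] ms."""

    counts: np.ndarray
    max_lag: int
    n_presyn: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size != 2 * self.max_lag + 1:
            raise ValueError("counts must cover [-max_lag, max_lag]")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def lags(self) -> np.ndarray:
        return np.arange(-self.max_lag, self.max_lag + 1)

    def at(self, lag: int) -> int:
        return int(self.counts[lag + self.max_lag])


@dataclass
class CchResult:
    p_trans: float
    p_fast: float
    p_diff: float
    significant: bool


def cross_correlogram(
    presyn_spikes, postsyn_spikes, max_lag: int = 50
) -> Correlogram:
    """Count spike pairs at each signed lag t_post - t_pre in [-max_lag, max_lag]."""
    pre = np.asarray(presyn_spikes, dtype=np.int64)
    post = np.sort(np.asarray(postsyn_spikes, dtype=np.int64))
    counts = np.zeros(2 * max_lag + 1, dtype=np.int64)
    if pre.size and post.size:
        for k, m in enumerate(range(-max_lag, max_lag + 1)):
            lo = np.searchsorted(post, pre + m, side="left")
            hi = np.searchsorted(post, pre + m, side="right")
            counts[k] = int((hi - lo).sum())
    return Correlogram(counts=counts, max_lag=max_lag, n_presyn=int(pre.size))


def hollow_gaussian_baseline(
    cch: Correlogram, kernel_sd: float = 10.0, hollow_fraction: float = 0.6
) -> np.ndarray:
    """Baseline: counts convolved with a unit-mass hollow Gaussian kernel.

    The center tap is multiplied by (1 - hollow_fraction) before the kernel
    is renormalized; edges are handled by reflection padding, so a flat
    histogram maps to itself.
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be positive")
    if not 0.0 <= hollow_fraction <= 1.0:
        raise ValueError("hollow_fraction must be in [0, 1]")
    radius = int(np.ceil(3 * kernel_sd))
    taps = np.exp(-0.5 * (np.arange(-radius, radius + 1) / kernel_sd) ** 2)
    taps[radius] *= 1.0 - hollow_fraction
    taps /= taps.sum()
    padded = np.pad(cch.counts.astype(float), radius, mode="reflect")
    return np.convolve(padded, taps, mode="valid")


def poisson_continuity_pvalue(observed_N: int, expected_lambda: float) -> float:
    """Upper-tail Poisson probability with a half-weight continuity correction.

    p = 1 - sum_{k<N} pmf(k; lambda) - pmf(N; lambda)/2, clipped to [0, 1].
    """
    if observed_N < 0 or expected_lambda < 0:
        raise ValueError("observed count and expected rate must be >= 0")
    p = (
        1.0
        - stats.poisson.cdf(observed_N - 1, expected_lambda)
        - 0.5 * stats.poisson.pmf(observed_N, expected_lambda)
    )
    return float(min(max(p, 0.0), 1.0))


def significance_tests(
    cch: Correlogram,
    baseline: np.ndarray,
    pos_lag_range: tuple[int, int] = (1, 10),
    neg_lag_range: tuple[int, int] = (-10, -1),
) -> tuple[float, float]:
    """(p_fast, p_diff) for the positive-lag peak; (1, 1) when empty.

    p_fast tests the peak against the smoothed baseline at the same bin;
    p_diff tests it against the maximum count in the negative-lag range.
    """
    lo, hi = pos_lag_range
    if not (-cch.max_lag <= lo <= hi <= cch.max_lag):
        raise ValueError("positive lag range outside the correlogram")
    nlo, nhi = neg_lag_range
    if not (-cch.max_lag <= nlo <= nhi <= cch.max_lag):
        raise ValueError("negative lag range outside the correlogram")
    pos = cch.counts[lo + cch.max_lag: hi + cch.max_lag + 1]
    if pos.sum() == 0:
        return 1.0, 1.0
    k = int(np.argmax(pos))
    peak = int(pos[k])
    lam_fast = float(baseline[lo + cch.max_lag + k])
    neg_max = int(cch.counts[nlo + cch.max_lag: nhi + cch.max_lag + 1].max())
    p_fast = poisson_continuity_pvalue(peak, lam_fast)
    p_diff = poisson_continuity_pvalue(peak, float(neg_max))
    return p_fast, p_diff


def transmission_probability(
    cch: Correlogram, baseline: np.ndarray, lag_window: tuple[int, int] = (3, 6)
) -> float:
    """Baseline-excess counts over the (inclusive) lag window per presynaptic spike."""
    lo, hi = lag_window
    if hi > cch.max_lag:
        raise ValueError("lag window exceeds the correlogram range")
    if cch.n_presyn == 0:
        return np.nan
    sl = slice(lo + cch.max_lag, hi + cch.max_lag + 1)
    return float((cch.counts[sl] - baseline[sl]).sum() / cch.n_presyn)


def cch_estimate(
    presyn_spikes,
    postsyn_spikes,
    max_lag: int = 50,
    kernel_sd: float = 10.0,
    hollow_fraction: float = 0.6,
    alpha: float = 0.01,
) -> CchResult:
    """Full CCH pipeline for one pair: p_trans plus the significance gate."""
    cch = cross_correlogram(presyn_spikes, postsyn_spikes, max_lag)
    base = hollow_gaussian_baseline(cch, kernel_sd, hollow_fraction)
    p_fast, p_diff = significance_tests(cch, base)
    p_trans = transmission_probability(cch, base)
    return CchResult(
        p_trans=p_trans,
        p_fast=p_fast,
        p_diff=p_diff,
        significant=bool(p_fast < alpha and p_diff < alpha),
    )
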