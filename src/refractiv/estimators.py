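"""Point estimators of pairwise effective connectivity.

All four estimators are simple functions of a trial table's stratum means:

* OLS: ``E[Y|X=1] - E[Y|X=0]`` -- the naive conditional difference, biased
  whenever X is confounded.
* IV (Wald): ``(E[Y|Z=0] - E[Y|Z=1]) / (E[X|Z=0] - E[X|Z=1])`` with the
  refractory indicator Z as instrument (note the flip: Z = 1 means the
  neuron could not comply with stimulation, so ``E[X|Z=1] = 0`` under
  absolute refractoriness).
* OLS/DiD: OLS with Y replaced by Y - Y*, cancelling additive trends shared
  by the treated and control strata.
* IV/DiD: the Wald ratio with both numerator and denominator corrected by
  the starred reference windows, exactly

      (E[Y|Z=1] - E[Y*|Z=1] - E[Y|Z=0] + E[Y*|Z=0])
      / (E[X|Z=1] - E[X*|Z=1] - E[X|Z=0] + E[X*|Z=0]).

Undefined estimates (an empty stratum or a zero denominator) propagate as
NaN, never as 0, so downstream aggregation can exclude and count them.
"""

from __future__ import annotations

import numpy as np

from .trials import TrialTable

__all__ = [
    "ols_estimate",
    "iv_estimate",
    "ols_did",
    "iv_did",
    "hit_rate",
    "estimate_all",
    "bootstrap_se",
    "ESTIMATOR_NAMES",
]

ESTIMATOR_NAMES = ("ols", "iv", "ols_did", "iv_did")


def _stratum_means(values: np.ndarray, strata: np.ndarray):
    """(mean | stratum == 1, mean | stratum == 0); NaN for empty strata."""
    m1 = strata == 1
    n1 = int(m1.sum())
    n0 = values.size - n1
    e1 = float(values[m1].mean()) if n1 else np.nan
    e0 = float(values[~m1].mean()) if n0 else np.nan
    return e1, e0


def ols_estimate(trials: TrialTable) -> float:
    """Naive conditional-difference (binary-regressor least squares) estimate."""
    e1, e0 = _stratum_means(trials.Y.astype(float), trials.X)
    return e1 - e0


def iv_estimate(trials: TrialTable) -> float:
    """Wald instrumental-variable estimate with refractoriness as instrument."""
    y1, y0 = _stratum_means(trials.Y.astype(float), trials.Z)
    x1, x0 = _stratum_means(trials.X.astype(float), trials.Z)
    den = x0 - x1
    if not np.isfinite(den) or den == 0.0:
        return np.nan
    return (y0 - y1) / den


def ols_did(trials: TrialTable) -> float:
    """OLS on the difference Y - Y*: cancels trends common to both strata."""
    d = trials.Y.astype(float) - trials.Ystar.astype(float)
    e1, e0 = _stratum_means(d, trials.X)
    return e1 - e0


def iv_did(trials: TrialTable) -> float:
    """IV/Wald estimate with difference-in-differences correction, as printed.

    With the default windows X* coincides with Z, so the denominator equals
    ``-(1 + E[X|Z=0])``; the starred terms in the numerator account for the
    transmission of the refractory-period spike itself, keeping the ratio
    consistent.  ``drop_xstar`` in :func:`iv_did_variant` removes the X*
    terms for sensitivity analysis.
    """
    return iv_did_variant(trials, drop_xstar=False)


def iv_did_variant(trials: TrialTable, drop_xstar: bool = False) -> float:
    dy = trials.Y.astype(float) - trials.Ystar.astype(float)
    y1, y0 = _stratum_means(dy, trials.Z)
    if drop_xstar:
        dx = trials.X.astype(float)
    else:
        dx = trials.X.astype(float) - trials.Xstar.astype(float)
    x1, x0 = _stratum_means(dx, trials.Z)
    den = x1 - x0
    if not np.isfinite(den) or den == 0.0:
        return np.nan
    return (y1 - y0) / den


def hit_rate(trials: TrialTable) -> float:
    """Fraction of trials in which the upstream neuron spiked during stimulation."""
    if len(trials) == 0:
        return np.nan
    return float(trials.X.mean())


_FUNCS = {
    "ols": ols_estimate,
    "iv": iv_estimate,
    "ols_did": ols_did,
    "iv_did": iv_did,
}


def estimate_all(trials: TrialTable) -> dict[str, float]:
    """All four estimators plus the hit rate for one trial table."""
    out = {name: _FUNCS[name](trials) for name in ESTIMATOR_NAMES}
    out["hit_rate"] = hit_rate(trials)
    return out


def bootstrap_se(
    trials: TrialTable,
    rng: np.random.Generator,
    n_boot: int = 200,
) -> dict[str, float]:
    """Nonparametric bootstrap standard errors for the four estimators.

    Trials are i.i.d., so resampling reduces to a multinomial redraw over
    the 32 joint categories of (Z, X, Y, X*, Y*) -- O(n_boot) work however
    many trials there are.  Replicates where an estimator is undefined are
    excluded from its SE.
    """
    n = len(trials)
    if n == 0:
        return {name: np.nan for name in ESTIMATOR_NAMES}
    code = (
        trials.Z.astype(np.int64) * 16
        + trials.X * 8
        + trials.Y * 4
        + trials.Xstar * 2
        + trials.Ystar
    )
    counts = np.bincount(code, minlength=32)
    cells = np.flatnonzero(counts)
    bits = ((cells[:, None] >> np.array([4, 3, 2, 1, 0])) & 1).astype(np.int8)
    probs = counts[cells] / n
    reps = {name: [] for name in ESTIMATOR_NAMES}
    for _ in range(n_boot):
        draw = rng.multinomial(n, probs)
        idx = np.repeat(np.arange(cells.size), draw)
        tt = TrialTable(
            Z=bits[idx, 0], X=bits[idx, 1], Y=bits[idx, 2],
            Xstar=bits[idx, 3], Ystar=bits[idx, 4],
            upstream_id=trials.upstream_id,
            downstream_id=trials.downstream_id,
        )
        for name in ESTIMATOR_NAMES:
            reps[name].append(_FUNCS[name](tt))
    out = {}
    for name in ESTIMATOR_NAMES:
        vals = np.asarray(reps[name], dtype=float)
        vals = vals[np.isfinite(vals)]
        out[name] = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
    return out
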