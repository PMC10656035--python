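"""Model / Results interface for pairwise effective-connectivity estimation.

`PairwiseConnectivity` is built from data (a spike raster plus stimulus
onsets); its :meth:`fit` extracts stimulus-aligned trials for every
requested neuron pair, evaluates the four causal estimators (OLS, IV,
OLS/DiD, IV/DiD) with bootstrap standard errors, optionally the
cross-correlogram baseline, and returns a :class:`ConnectivityResults`
carrying the per-pair table, diagnostics and a ``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import SpikeRaster
from .trials import WindowSpec, extract_trials
from . import estimators as _est
from .cch import cch_estimate
from .evaluation import condition_number

__all__ = ["PairwiseConnectivity", "ConnectivityResults"]


class PairwiseConnectivity:
    """Effective-connectivity model for stimulated neuron pairs.

    Parameters
    ----------
    raster : SpikeRaster
        Binary neuron x time spike matrix at 1-ms resolution.
    onsets : OnsetSchedule or array of int
        Stimulus onset times (ms).
    pairs : sequence of (upstream, downstream), optional
        Neuron pairs to score; defaults to every ordered pair of distinct
        neurons (quadratic -- pass an explicit list for large networks).
    windows : WindowSpec, optional
        Z/X/Y detection-window layout; default 2-ms windows at -2/0/2 ms.
    """

    def __init__(self, raster: SpikeRaster, onsets, pairs=None,
                 windows: WindowSpec | None = None):
        self.raster = raster
        self.onsets = onsets
        self.windows = windows or WindowSpec()
        if pairs is None:
            n = raster.n_neurons
            pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
        self.pairs = [(int(i), int(j)) for i, j in pairs]

    @classmethod
    def from_events(cls, events: pd.DataFrame, onsets, n_neurons=None,
                    n_steps=None, **kwargs) -> "PairwiseConnectivity":
        """Build from a long-format time_ms/neuron_id event table."""
        raster = SpikeRaster.from_events(events, n_neurons, n_steps)
        return cls(raster, onsets, **kwargs)

    def fit(self, include_cch: bool = True, n_boot: int = 200,
            max_lag: int = 50, seed=None) -> "ConnectivityResults":
        """Estimate all pairs; returns a :class:`ConnectivityResults`."""
        rng = np.random.default_rng(seed)
        rows = []
        spike_times = {}

        def times(i):
            if i not in spike_times:
                spike_times[i] = self.raster.spike_times(i)
            return spike_times[i]

        for up, down in self.pairs:
            tt = extract_trials(self.raster, self.onsets, self.windows,
                                up, down)
            row = {"upstream": up, "downstream": down, "n_trials": len(tt),
                   "n_dropped": tt.n_dropped}
            row.update(_est.estimate_all(tt))
            if n_boot:
                ses = _est.bootstrap_se(tt, rng, n_boot=n_boot)
                row.update({f"{k}_se": v for k, v in ses.items()})
            if include_cch:
                res = cch_estimate(times(up), times(down), max_lag=max_lag)
                row["cch"] = res.p_trans
                row["cch_p_fast"] = res.p_fast
                row["cch_p_diff"] = res.p_diff
                row["cch_significant"] = res.significant
            undefined = [n for n in _est.ESTIMATOR_NAMES
                         if not np.isfinite(row[n])]
            row["flags"] = ";".join(f"{n}_undefined" for n in undefined)
            rows.append(row)
        table = pd.DataFrame(rows)
        return ConnectivityResults(self, table)


class ConnectivityResults:
    """Estimates, uncertainties and diagnostics from a fitted model."""

    def __init__(self, model: PairwiseConnectivity, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def estimator_names(self):
        names = list(_est.ESTIMATOR_NAMES)
        if "cch" in self.table.columns:
            names.append("cch")
        return names

    def estimates(self, name: str) -> pd.Series:
        if name not in self.estimator_names:
            raise KeyError(name)
        return self.table.set_index(["upstream", "downstream"])[name]

    def condition_number(self) -> float:
        """Conditioning of the raster's population covariance (diagnostic)."""
        kappa, _ = condition_number(self.model.raster)
        return kappa

    def n_undefined(self) -> dict[str, int]:
        """Count of pairs where each estimator was undefined (excluded)."""
        return {
            name: int(self.table[name].isna().sum())
            for name in self.estimator_names
        }

    def summary(self) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        t = self.table
        lines = [
            "Pairwise effective connectivity".center(72),
            "=" * 72,
            f"pairs scored: {len(t):>6d}    trials/pair: "
            f"{int(t['n_trials'].median()) if len(t) else 0}"
            f"    mean hit rate: {t['hit_rate'].mean():.3f}",
            "-" * 72,
            f"{'pair':>12s} {'hit':>6s} "
            + " ".join(f"{n:>9s}" for n in self.estimator_names),
        ]
        for _, row in t.iterrows():
            cells = " ".join(
                f"{row[n]:>9.4f}" if np.isfinite(row[n]) else f"{'--':>9s}"
                for n in self.estimator_names
            )
            lines.append(
                f"{int(row['upstream']):>5d}->{int(row['downstream']):<5d} "
                f"{row['hit_rate']:>6.3f} {cells}"
            )
        lines.append("=" * 72)
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
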