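"""Desk-scale experiment designs wiring all modules together.

Each ``run_*`` function builds ground-truth networks, simulates them under
pulsed stimulation and confounders, fits the pairwise connectivity model
for the stimulated -> rest pairs, and returns a long-format results table
(one row per network x pair x estimator) with ground truth, errors and
diagnostics attached.  Defaults are reduced relative to the original
figure-scale studies (hundreds of networks, 10^6-trial convergence runs)
so that each experiment finishes in minutes on one CPU while preserving
the ordinal comparisons; pass larger ``n_steps`` / grids for full scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import (
    NetworkSpec, PulseSpec, DriveProtocol, drive_trace, simulate,
)
from .connectome import WeightMatrix, gaussian_weights, dale_split, sparsify
from .optics import FiberSpec, OpsinSpec, assign_stimulus_gains
from .trials import WindowSpec
from .model import PairwiseConnectivity
from .evaluation import (
    CALIBRATED_ALPHA, ground_truth_beta, pair_errors, condition_number, auroc,
)

__all__ = [
    "ExperimentConfig",
    "standard_drives",
    "confounder_drives",
    "run_network",
    "run_three_neuron",
    "run_drive_sweep",
    "run_size_stim_weight_sweep",
    "run_sparsity_stim_fraction",
    "run_distance_stim",
    "run_inhibitory",
    "EXPERIMENTS",
]

ESTIMATORS = ("ols", "ols_did", "iv", "iv_did", "cch")


@dataclass
class ExperimentConfig:
    """Name, seed and keyword overrides for one experiment run."""

    experiment: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            experiment=raw.pop("experiment"),
            seed=int(raw.pop("seed", 0)),
            params=raw,
        )

    def run(self) -> pd.DataFrame:
        fn = EXPERIMENTS[self.experiment]
        return fn(seed=self.seed, **self.params)


def standard_drives(gamma_S=5.0, gamma_ex=2.0, gamma_in=-5.0,
                stimulated=(0, 1), gains=None) -> DriveProtocol:
    """The standard drive set: 50-ms stimulus train clipped
    to [10, 200] ms plus 10-ms excitatory/inhibitory confounder pulses on
    100-ms trains clipped to [30, 400] ms."""
    return DriveProtocol(
        stimulus=PulseSpec(gamma_S, 2, 50.0, 10.0, 200.0),
        excitatory=PulseSpec(gamma_ex, 10, 100.0, 30.0, 400.0),
        inhibitory=PulseSpec(gamma_in, 10, 100.0, 30.0, 400.0),
        stimulated_ids=tuple(stimulated),
        stimulus_gain=gains,
    )


def confounder_drives(gamma_ex=2.0, gamma_in=-5.0) -> DriveProtocol:
    """Confounders only -- the baseline drive regime (~10 Hz population rate)."""
    return standard_drives(gamma_S=0.0, gamma_ex=gamma_ex, gamma_in=gamma_in,
                       stimulated=())


def run_network(
    weights: WeightMatrix,
    protocol: DriveProtocol,
    n_steps: int,
    rng: np.random.Generator,
    pairs=None,
    alpha_cal: float = CALIBRATED_ALPHA,
    windows: WindowSpec | None = None,
    n_boot: int = 0,
    include_cch: bool = True,
    bias_b: float = 5.0,
) -> tuple[pd.DataFrame, float]:
    """Simulate one network and estimate the requested pairs.

    Returns the per-pair wide table (one row per pair, one column per
    estimator, plus beta_true and per-estimator errors) and the condition
    number of the simulated raster.
    """
    n = weights.n_neurons
    spec = NetworkSpec(n_neurons=n, bias_b=bias_b)
    rng_sched, rng_sim, rng_boot = rng.spawn(3)
    schedules = protocol.sample_schedules(n_steps, rng_sched)
    U = drive_trace(protocol, schedules, n_steps, n)
    raster = simulate(spec, weights.weights, U, n_steps, rng_sim)
    if pairs is None:
        stim = protocol.stimulated_ids
        pairs = [(i, j) for i in stim for j in range(n) if j not in stim]
    model = PairwiseConnectivity(raster, schedules["stimulus"], pairs,
                                 windows=windows)
    res = model.fit(include_cch=include_cch, n_boot=n_boot,
                    seed=rng_boot)
    table = res.table
    w_pair = np.array(
        [weights.weights[j, i] for i, j in zip(table.upstream, table.downstream)]
    )
    table["weight"] = w_pair
    table["beta_true"] = ground_truth_beta(w_pair, bias_b, alpha_cal)
    for est in ESTIMATORS:
        if est in table.columns:
            table[f"err_{est}"] = table[est] - table["beta_true"]
    kappa, _ = condition_number(raster)
    return table, kappa


def _melt(table: pd.DataFrame, keys: dict) -> pd.DataFrame:
    """Wide per-pair table -> long (network, pair, estimator) rows."""
    rows = []
    for _, r in table.iterrows():
        for est in ESTIMATORS:
            if est not in table.columns:
                continue
            rows.append(
                {**keys, "upstream": int(r.upstream),
                 "downstream": int(r.downstream),
                 "n_trials": int(r.n_trials), "hit_rate": r.hit_rate,
                 "weight": r.weight, "beta_true": r.beta_true,
                 "estimator": est, "estimate": r[est],
                 "error": r[est] - r.beta_true}
            )
    return pd.DataFrame(rows)


def _summarize(long: pd.DataFrame, group_keys: Sequence[str]) -> pd.DataFrame:
    """Attach per-group MAE over valid estimates."""
    out = (
        long.dropna(subset=["estimate"])
        .assign(abs_error=lambda d: d.error.abs())
        .groupby([*group_keys, "estimator"], as_index=False)
        .agg(mae=("abs_error", "mean"), n_pairs=("estimate", "size"))
    )
    return out


def run_three_neuron(
    seed: int = 0,
    weight_grid=(0.0, 2.0, 4.0, 6.0, 7.0),
    n_steps: int = 400_000,
    gamma_S: float = 5.0,
    alpha_cal: float = CALIBRATED_ALPHA,
    n_boot: int = 100,
) -> pd.DataFrame:
    """Three neurons A, B, C: A and B stimulated, only B drives C.

    ``W_CA = 0`` while ``W_CB`` sweeps ``weight_grid``; the confounded A->C
    pair exposes the bias of OLS and CCH that IV/DiD removes.
    """
    rng = np.random.default_rng(seed)
    out = []
    for w_cb in weight_grid:
        W = np.zeros((3, 3))
        W[2, 1] = w_cb
        wm = WeightMatrix(W)
        protocol = standard_drives(gamma_S=gamma_S, stimulated=(0, 1))
        table, kappa = run_network(
            wm, protocol, n_steps, rng.spawn(1)[0],
            pairs=[(0, 2), (1, 2)], alpha_cal=alpha_cal, n_boot=n_boot,
        )
        long = _melt(table, {"network_id": 0, "w_cb": w_cb})
        long["condition_number"] = kappa
        se_cols = {f"{e}_se": e for e in ("ols", "iv", "ols_did", "iv_did")}
        ses = table.melt(
            id_vars=["upstream", "downstream"],
            value_vars=[c for c in se_cols if c in table.columns],
            var_name="se_of", value_name="se",
        )
        ses["estimator"] = ses.se_of.map(se_cols)
        long = long.merge(
            ses[["upstream", "downstream", "estimator", "se"]],
            on=["upstream", "downstream", "estimator"], how="left",
        )
        out.append(long)
    return pd.concat(out, ignore_index=True)


def run_drive_sweep(
    seed: int = 0,
    n_neurons: int = 60,
    gamma_ex_grid=(0.0, 2.0, 4.0),
    gamma_in_grid=(0.0, -2.0, -4.0),
    sigma: float = 5.0,
    gamma_S: float = 6.0,
    n_stimulated: int = 5,
    n_steps: int = 150_000,
    alpha_cal: float = CALIBRATED_ALPHA,
) -> pd.DataFrame:
    """Dale network under varying confounder drive strengths.

    Sweeps the excitatory amplitude at zero inhibition and vice versa,
    recording MAE(w >= 0), AUROC and the condition number per setting.
    """
    rng = np.random.default_rng(seed)
    settings = [(g, 0.0) for g in gamma_ex_grid]
    settings += [(0.0, g) for g in gamma_in_grid if g != 0.0]
    rows = []
    for net in range(1):
        half = gaussian_weights(n_neurons // 2, sigma, rng.spawn(1)[0])
        wm = dale_split(half)
        stim = tuple(wm.excitatory_ids()[:n_stimulated])
        for g_ex, g_in in settings:
            protocol = standard_drives(gamma_S=gamma_S, gamma_ex=g_ex,
                                   gamma_in=g_in, stimulated=stim)
            table, kappa = run_network(
                wm, protocol, n_steps, rng.spawn(1)[0], alpha_cal=alpha_cal
            )
            long = _melt(table, {"network_id": net, "gamma_ex": g_ex,
                                 "gamma_in": g_in})
            long["condition_number"] = kappa
            rows.append(long)
    return pd.concat(rows, ignore_index=True)


def run_size_stim_weight_sweep(
    seed: int = 0,
    size_grid=(30, 60),
    gamma_S_grid=(3.0, 6.0),
    sigma_grid=(5.0,),
    n_stimulated: int = 5,
    n_steps: int = 600_000,
    alpha_cal: float = CALIBRATED_ALPHA,
) -> pd.DataFrame:
    """Grid over network size, stimulus strength and connection scale
    (no confounders), comparing estimator errors and AUROC."""
    rng = np.random.default_rng(seed)
    rows = []
    for n in size_grid:
        for sigma in sigma_grid:
            half = gaussian_weights(n // 2, sigma, rng.spawn(1)[0])
            wm = dale_split(half)
            stim = tuple(wm.excitatory_ids()[:n_stimulated])
            for g in gamma_S_grid:
                protocol = standard_drives(gamma_S=g, gamma_ex=0.0, gamma_in=0.0,
                                       stimulated=stim)
                table, kappa = run_network(
                    wm, protocol, n_steps, rng.spawn(1)[0],
                    alpha_cal=alpha_cal,
                )
                long = _melt(table, {"network_id": 0, "n_neurons": n,
                                     "gamma_S": g, "sigma": sigma})
                long["condition_number"] = kappa
                rows.append(long)
    return pd.concat(rows, ignore_index=True)


def run_sparsity_stim_fraction(
    seed: int = 0,
    n_neurons: int = 100,
    sparsity_grid=(0.0, 0.9),
    stim_count_grid=(5, 30),
    sigma: float = 5.0,
    gamma_S: float = 6.0,
    n_steps: int = 150_000,
    alpha_cal: float = CALIBRATED_ALPHA,
) -> pd.DataFrame:
    """Error versus connectivity sparsity and stimulated fraction
    (no confounders)."""
    rng = np.random.default_rng(seed)
    rows = []
    half = gaussian_weights(n_neurons // 2, sigma, rng.spawn(1)[0])
    base = dale_split(half)
    for sparsity in sparsity_grid:
        wm = sparsify(base, sparsity, rng.spawn(1)[0])
        stim = tuple(wm.excitatory_ids()[: stim_count_grid[0]])
        protocol = standard_drives(gamma_S=gamma_S, gamma_ex=0.0, gamma_in=0.0,
                               stimulated=stim)
        table, kappa = run_network(
            wm, protocol, n_steps, rng.spawn(1)[0], alpha_cal=alpha_cal
        )
        long = _melt(table, {"network_id": 0, "sparsity": sparsity,
                             "n_stimulated": stim_count_grid[0]})
        long["condition_number"] = kappa
        rows.append(long)
    for n_stim in stim_count_grid[1:]:
        wm = sparsify(base, sparsity_grid[0], rng.spawn(1)[0])
        stim = tuple(wm.excitatory_ids()[:n_stim])
        protocol = standard_drives(gamma_S=gamma_S, gamma_ex=0.0, gamma_in=0.0,
                               stimulated=stim)
        table, kappa = run_network(
            wm, protocol, n_steps, rng.spawn(1)[0], alpha_cal=alpha_cal
        )
        long = _melt(table, {"network_id": 0, "sparsity": sparsity_grid[0],
                             "n_stimulated": n_stim})
        long["condition_number"] = kappa
        rows.append(long)
    return pd.concat(rows, ignore_index=True)


def run_distance_stim(
    seed: int = 0,
    size_grid=(60, 180),
    n_networks: int = 2,
    sigma: float = 5.0,
    gamma_S: float = 8.0,
    n_steps: int = 300_000,
    alpha_cal: float = CALIBRATED_ALPHA,
) -> pd.DataFrame:
    """Distance-distributed (optics-derived) stimulus gains across sizes.

    Every neuron is illuminated with a gain set by its random distance
    from the fiber; the five best-lit neurons are scored against the rest.
    ``n_networks`` fresh weight/gain draws per size stabilize the MAE
    comparison (small networks draw occasional large weights).
    """
    rng = np.random.default_rng(seed)
    fiber, opsin = FiberSpec(), OpsinSpec()
    rows = []
    for n in size_grid:
        for net in range(n_networks):
            half = gaussian_weights(n // 2, sigma, rng.spawn(1)[0])
            wm = dale_split(half)
            gains = assign_stimulus_gains(n, fiber, opsin, rng.spawn(1)[0])
            stim = tuple(range(n))  # widefield light reaches every neuron
            pairs_from = np.argsort(-gains)[:5]
            pairs = [(int(i), j) for i in pairs_from for j in range(n)
                     if j != int(i)]
            protocol = standard_drives(gamma_S=gamma_S, stimulated=stim,
                                   gains=gains)
            table, kappa = run_network(
                wm, protocol, n_steps, rng.spawn(1)[0], pairs=pairs,
                alpha_cal=alpha_cal,
            )
            long = _melt(table, {"network_id": net, "n_neurons": n})
            long["condition_number"] = kappa
            rows.append(long)
    return pd.concat(rows, ignore_index=True)


def run_inhibitory(
    seed: int = 0,
    n_neurons: int = 60,
    sigma: float = 5.0,
    gamma_S: float = 3.0,
    n_stimulated: int = 5,
    n_steps: int = 150_000,
    alpha_cal: float = CALIBRATED_ALPHA,
) -> pd.DataFrame:
    """Stimulate inhibitory neurons; error split uses w <= 0 pairs."""
    rng = np.random.default_rng(seed)
    half = gaussian_weights(n_neurons // 2, sigma, rng.spawn(1)[0])
    wm = dale_split(half)
    stim = tuple(wm.inhibitory_ids()[:n_stimulated])
    protocol = standard_drives(gamma_S=gamma_S, stimulated=stim)
    table, kappa = run_network(
        wm, protocol, n_steps, rng.spawn(1)[0], alpha_cal=alpha_cal
    )
    long = _melt(table, {"network_id": 0})
    long["condition_number"] = kappa
    return long


def pooled_mae(long: pd.DataFrame, weight_sign: str | None = None
               ) -> pd.Series:
    """MAE per estimator, optionally restricted to w >= 0 or w <= 0 pairs."""
    d = long.dropna(subset=["estimate"])
    if weight_sign == "pos":
        d = d[d.weight >= 0]
    elif weight_sign == "neg":
        d = d[d.weight <= 0]
    return d.assign(a=d.error.abs()).groupby("estimator")["a"].mean()


def pooled_auroc(long: pd.DataFrame, mode: str = "signed") -> pd.Series:
    """AUROC per estimator with labels = (true weight != 0)."""
    out = {}
    for est, d in long.groupby("estimator"):
        ok = d.dropna(subset=["estimate"])
        labels = ok.weight != 0
        if labels.any() and not labels.all():
            out[est] = auroc(ok.estimate, labels, mode=mode)
        else:
            out[est] = np.nan
    return pd.Series(out)


def mannwhitney_comparison(long: pd.DataFrame, reference: str = "iv_did"
                           ) -> pd.DataFrame:
    """Two-sided rank-sum comparison of absolute errors against a reference."""
    from scipy.stats import mannwhitneyu

    d = long.dropna(subset=["estimate"]).assign(a=lambda x: x.error.abs())
    ref = d[d.estimator == reference].a.values
    rows = []
    for est, grp in d.groupby("estimator"):
        if est == reference:
            continue
        u, p = mannwhitneyu(ref, grp.a.values, alternative="two-sided")
        rows.append({"reference": reference, "other": est,
                     "U": u, "p_value": p})
    return pd.DataFrame(rows)


EXPERIMENTS = {
    "three_neuron": run_three_neuron,
    "drive_sweep": run_drive_sweep,
    "size_stim_weight_sweep": run_size_stim_weight_sweep,
    "sparsity_stim_fraction": run_sparsity_stim_fraction,
    "distance_stim": run_distance_stim,
    "inhibitory": run_inhibitory,
}
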