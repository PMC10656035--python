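"""Discrete-time binomial-GLM spiking-network simulator.

The generative model is a higher-order Markov chain on binary spike
indicators ``M[i, t]`` with 1-ms bins.  The conditional spike probability of
neuron *i* at time ``t + 1`` is

    p[i, t+1] = sigmoid( sum_{lag=1..H} ( M[i, t+1-lag] * r(lag)
                          + sum_j W[i, j] * M[j, t+1-lag] * c(lag) )
                         - b + U[i, t] )

where ``r`` is the refractory filter (a large negative absolute part on lags
1-3 followed by an exponentially decaying relative part), ``c`` is the
exponential cross-coupling filter supported on lags 1-5, ``b`` is a bias
setting the baseline rate and ``U`` is an external drive composed of pulsed
optogenetic stimulation plus excitatory and inhibitory confounders.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkSpec",
    "PulseSpec",
    "DriveProtocol",
    "OnsetSchedule",
    "SpikeRaster",
    "coupling_filter",
    "refractory_filter",
    "sample_onsets",
    "drive_trace",
    "simulate",
]


def sigmoid(x):
    """Logistic inverse link, numerically safe for large |x|."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class NetworkSpec:
    """Structural parameters of the binomial-GLM network.

    Defaults are the hand-tuned values used throughout: bias ``b = 5``
    (baseline rate ~6.6 Hz per neuron, ~10 Hz once confounders drive the
    population), history ``H = 10`` ms, coupling decay ``alpha = 0.2`` on
    lags 1-5, absolute refractoriness of -100 on lags 1-3 and a relative
    refractory tail ``-30 * exp(-(lag + 4) / 2)`` on lags 4-H.
    """

    n_neurons: int = 1
    bias_b: float = 5.0
    history_H: int = 10
    dt_ms: float = 1.0
    coupling_alpha: float = 0.2
    coupling_support: tuple[int, int] = (1, 5)
    coupling_lag_origin: int = 1
    refractory_abs_value: float = -100.0
    refractory_abs_span: int = 3
    refractory_rel_scale: float = -30.0
    refractory_rel_rate: float = 0.5

    def __post_init__(self):
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be a positive integer")
        if self.history_H < self.coupling_support[1]:
            raise ValueError("history_H must cover the coupling support")
        if self.dt_ms != 1.0:
            raise ValueError("the model is defined on 1-ms bins")

    def without_refractoriness(self) -> "NetworkSpec":
        """Copy of this spec with the refractory filter identically zero."""
        return replace(self, refractory_abs_value=0.0, refractory_rel_scale=0.0)


def coupling_filter(lag: int, spec: NetworkSpec) -> float:
    """Exponential cross-coupling filter on lags 1..5, zero beyond.

    ``lag`` counts 1-ms steps back from the bin being predicted; the filter
    is only defined on [1, H].  With the default ``coupling_lag_origin = 1``
    the first tap is unity, c(lag) = exp(-alpha * (lag - 1)): a presynaptic
    spike one step back contributes its full weight, which is what makes
    the closed-form causal effect sigma(W - b) - sigma(-b) exact for a
    non-refractory pair (the r = 0 model check recovers slope 1).  Setting
    ``coupling_lag_origin = 0`` gives the alternative c(lag) =
    exp(-alpha * lag) with c(1) = exp(-0.2).
    """
    lo, hi = spec.coupling_support
    if not 1 <= lag <= spec.history_H:
        raise ValueError(f"lag {lag} outside [1, {spec.history_H}]")
    if lo <= lag <= hi:
        return float(
            np.exp(-spec.coupling_alpha * (lag - spec.coupling_lag_origin))
        )
    return 0.0


def refractory_filter(lag: int, spec: NetworkSpec) -> float:
    """Refractory filter: absolute (-100) on lags 1-3, relative tail after.

    The relative part is ``-30 * exp(-(lag + 4)/2)`` for lags 4..H.
    """
    if not 1 <= lag <= spec.history_H:
        raise ValueError(f"lag {lag} outside [1, {spec.history_H}]")
    if lag <= spec.refractory_abs_span:
        return float(spec.refractory_abs_value)
    return float(
        spec.refractory_rel_scale
        * np.exp(-spec.refractory_rel_rate * (lag + 4))
    )


def _filter_vectors(spec: NetworkSpec) -> tuple[np.ndarray, np.ndarray]:
    lags = np.arange(1, spec.history_H + 1)
    c = np.array([coupling_filter(int(l), spec) for l in lags])
    r = np.array([refractory_filter(int(l), spec) for l in lags])
    return c, r


@dataclass(frozen=True)
class OnsetSchedule:
    """Strictly increasing pulse-onset times in ms."""

    onset_times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.onset_times, dtype=np.int64)
        object.__setattr__(self, "onset_times", t)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("onset times must be strictly increasing")

    def __len__(self):
        return int(self.onset_times.size)


def sample_onsets(
    mean_period: float,
    min_period: float,
    max_period: float,
    horizon: int,
    rng: np.random.Generator,
) -> OnsetSchedule:
    """Draw pulse onsets with clipped-Poisson inter-onset intervals.

    Intervals are Poisson(mean_period) draws clipped (floor/ceil replaced)
    to [min_period, max_period]; onsets are their cumulative sums truncated
    at ``horizon``.
    """
    if not (min_period <= mean_period <= max_period):
        raise ValueError("require min_period <= mean_period <= max_period")
    if horizon <= 0:
        return OnsetSchedule(np.empty(0, dtype=np.int64))
    n_guess = max(int(2 * horizon / max(min_period, 1)) + 16, 16)
    intervals = rng.poisson(mean_period, size=n_guess)
    while intervals.sum() < horizon:  # pragma: no cover - defensive top-up
        intervals = np.concatenate([intervals, rng.poisson(mean_period, size=n_guess)])
    intervals = np.clip(intervals, min_period, max_period)
    onsets = np.cumsum(intervals)
    return OnsetSchedule(onsets[onsets < horizon].astype(np.int64))


@dataclass(frozen=True)
class PulseSpec:
    """One pulsed drive: amplitude, duration and clipped-Poisson timing.

    A pulse starting at onset ``t0`` holds its amplitude on the closed bin
    interval ``[t0, t0 + duration_ms]`` (``duration_ms + 1`` active bins),
    the literal reading of the pulse definitions; the optogenetic stimulus
    has ``duration_ms = 2``.
    """

    amplitude: float = 0.0
    duration_ms: int = 2
    mean_period: float = 50.0
    min_period: float = 10.0
    max_period: float = 200.0

    def __post_init__(self):
        if self.duration_ms < 0:
            raise ValueError("duration must be >= 0 ms")

    def active_bins(self) -> int:
        return self.duration_ms + 1

    def sample(self, horizon: int, rng: np.random.Generator) -> OnsetSchedule:
        if self.amplitude == 0.0:
            return OnsetSchedule(np.empty(0, dtype=np.int64))
        return sample_onsets(
            self.mean_period, self.min_period, self.max_period, horizon, rng
        )


def _default_stimulus():
    return PulseSpec(amplitude=0.0, duration_ms=2, mean_period=50.0,
                     min_period=10.0, max_period=200.0)


def _default_excitatory():
    return PulseSpec(amplitude=0.0, duration_ms=10, mean_period=100.0,
                     min_period=30.0, max_period=400.0)


def _default_inhibitory():
    return PulseSpec(amplitude=0.0, duration_ms=10, mean_period=100.0,
                     min_period=30.0, max_period=400.0)


@dataclass
class DriveProtocol:
    """Stimulus plus excitatory/inhibitory confounder pulse trains.

    The stimulus applies only to ``stimulated_ids``, scaled per neuron by
    ``stimulus_gain`` (uniform 1.0 by default; the optics module supplies
    distance-dependent gains).  Confounders apply to every neuron.
    """

    stimulus: PulseSpec = field(default_factory=_default_stimulus)
    excitatory: PulseSpec = field(default_factory=_default_excitatory)
    inhibitory: PulseSpec = field(default_factory=_default_inhibitory)
    stimulated_ids: tuple[int, ...] = ()
    stimulus_gain: np.ndarray | None = None

    def __post_init__(self):
        if self.excitatory.amplitude < 0:
            raise ValueError("excitatory confounder amplitude must be >= 0")
        if self.inhibitory.amplitude > 0:
            raise ValueError("inhibitory confounder amplitude must be <= 0")

    def sample_schedules(
        self, horizon: int, rng: np.random.Generator
    ) -> dict[str, OnsetSchedule]:
        """Independent onset schedules for the three drives."""
        r_s, r_e, r_i = rng.spawn(3)
        return {
            "stimulus": self.stimulus.sample(horizon, r_s),
            "excitatory": self.excitatory.sample(horizon, r_e),
            "inhibitory": self.inhibitory.sample(horizon, r_i),
        }


def _pulse_trace(schedule: OnsetSchedule, amplitude: float, n_active: int,
                 horizon: int) -> np.ndarray:
    u = np.zeros(horizon)
    for t0 in schedule.onset_times:
        u[t0: min(t0 + n_active, horizon)] += amplitude
    return u


def drive_trace(
    protocol: DriveProtocol,
    schedules: dict[str, OnsetSchedule],
    horizon: int,
    n_neurons: int,
) -> np.ndarray:
    """Per-neuron, per-time drive matrix U = U_S + U_ex + U_in.

    Empty schedules yield an all-zero trace.  Overlapping pulses add.
    """
    u_common = (
        _pulse_trace(schedules["excitatory"], protocol.excitatory.amplitude,
                     protocol.excitatory.active_bins(), horizon)
        + _pulse_trace(schedules["inhibitory"], protocol.inhibitory.amplitude,
                       protocol.inhibitory.active_bins(), horizon)
    )
    U = np.tile(u_common, (n_neurons, 1))
    if protocol.stimulated_ids:
        u_s = _pulse_trace(schedules["stimulus"], protocol.stimulus.amplitude,
                           protocol.stimulus.active_bins(), horizon)
        gain = protocol.stimulus_gain
        if gain is None:
            gain = np.ones(n_neurons)
        gain = np.asarray(gain, dtype=float)
        for i in protocol.stimulated_ids:
            U[i] += gain[i] * u_s
    return U


@dataclass
class SpikeRaster:
    """Binary neuron x time spike indicator matrix at 1-ms resolution."""

    spikes: np.ndarray
    t0: int = 0

    def __post_init__(self):
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 2:
            raise ValueError("spikes must be a 2-d neuron x time matrix")
        vals = np.unique(self.spikes)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("spike raster entries must be binary")
        self.spikes = self.spikes.astype(np.uint8)

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[1]

    def spike_times(self, neuron: int) -> np.ndarray:
        """Spike times (ms, absolute) of one neuron."""
        return np.flatnonzero(self.spikes[neuron]) + self.t0

    def to_events(self):
        """Long-format events table with columns time_ms, neuron_id."""
        import pandas as pd

        nid, t = np.nonzero(self.spikes)
        order = np.argsort(t, kind="stable")
        return pd.DataFrame(
            {"time_ms": t[order] + self.t0, "neuron_id": nid[order]}
        )

    @classmethod
    def from_events(cls, events, n_neurons: int | None = None,
                    n_steps: int | None = None) -> "SpikeRaster":
        """Build a raster from a time_ms/neuron_id events table."""
        t = np.asarray(events["time_ms"], dtype=np.int64)
        nid = np.asarray(events["neuron_id"], dtype=np.int64)
        if n_neurons is None:
            n_neurons = int(nid.max()) + 1 if nid.size else 1
        if n_steps is None:
            n_steps = int(t.max()) + 1 if t.size else 0
        spikes = np.zeros((n_neurons, n_steps), dtype=np.uint8)
        spikes[nid, t] = 1
        return cls(spikes)


def simulate(
    spec: NetworkSpec,
    weights: np.ndarray,
    drive: np.ndarray | None,
    n_steps: int,
    rng: np.random.Generator,
    burn_in: int = 1000,
) -> SpikeRaster:
    """Run the binomial-GLM network forward and return its spike raster.

    ``drive`` is an ``n_neurons x n_steps`` matrix indexed on the returned
    (post-burn-in) clock; during the burn-in the drive is zero and those
    bins are discarded.  The drive at bin ``t`` enters the probability of a
    spike at ``t + 1``, matching the model definition.  History before the
    first simulated bin is all-zero.  Two calls with generators seeded
    identically produce identical rasters.
    """
    N = spec.n_neurons
    W = np.asarray(weights, dtype=float)
    if W.shape != (N, N):
        raise ValueError(f"weights must be {N}x{N}, got {W.shape}")
    if not np.isfinite(W).all():
        raise ValueError("weights must be finite")
    if drive is not None:
        drive = np.asarray(drive, dtype=float)
        if drive.shape != (N, n_steps):
            raise ValueError("drive matrix must be n_neurons x n_steps")

    H = spec.history_H
    c_vec, r_vec = _filter_vectors(spec)
    # kernels reversed so that history column k (time t-H+k) meets lag H-k
    kern = np.stack([r_vec[::-1], c_vec[::-1]], axis=1)  # (H, 2)

    total = burn_in + n_steps
    M = np.zeros((N, H + total))
    b = spec.bias_b
    chunk = 65536
    u = np.empty(N)
    n_draw = 0
    draws = None
    for t in range(total):
        if n_draw == 0:
            draws = rng.random((min(chunk, total - t), N))
            n_draw = draws.shape[0]
        hist = M[:, t: t + H] @ kern  # (N, 2): refractory, coupling inputs
        x = hist[:, 0] + W @ hist[:, 1] - b
        if drive is not None:
            # spike at bin t (post-burn-in index t-burn_in) sees U(t-1)
            rel = t - 1 - burn_in
            if rel >= 0:
                x = x + drive[:, rel]
        p = sigmoid(x)
        M[:, H + t] = draws[draws.shape[0] - n_draw] < p
        n_draw -= 1
    return SpikeRaster(M[:, H + burn_in:].astype(np.uint8))
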