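"""YAML configuration and file I/O helpers for the CLI.

The simulation YAML mirrors the drive parameter names used throughout
(gamma_S, lambda_S, lambda_S_min, lambda_S_max, tau_ex, gamma_ex, ...) plus
network fields (n_neurons, bias_b, sigma, dale, sparsity, stimulated_ids).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import (
    NetworkSpec, PulseSpec, DriveProtocol, OnsetSchedule, SpikeRaster,
    drive_trace, simulate,
)
from .connectome import gaussian_weights, dale_split, sparsify
from .trials import WindowSpec

DEFAULTS = {
    "n_neurons": 3,
    "bias_b": 5.0,
    "sigma": 0.0,
    "dale": False,
    "sparsity": 0.0,
    "stimulated_ids": [0, 1],
    "gamma_S": 5.0, "lambda_S": 50.0, "lambda_S_min": 10.0,
    "lambda_S_max": 200.0, "tau_S": 2,
    "gamma_ex": 2.0, "lambda_ex": 100.0, "lambda_ex_min": 30.0,
    "lambda_ex_max": 400.0, "tau_ex": 10,
    "gamma_in": -5.0, "lambda_in": 100.0, "lambda_in_min": 30.0,
    "lambda_in_max": 400.0, "tau_in": 10,
}


def load_simulation_config(path=None) -> dict:
    cfg = dict(DEFAULTS)
    if path is not None:
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(raw)
    return cfg


def simulate_from_config(cfg: dict, n_steps: int, seed: int):
    """Build network + drives from a config dict and run the simulator."""
    rng = np.random.default_rng(seed)
    rng_w, rng_sched, rng_sim = rng.spawn(3)
    n = int(cfg["n_neurons"])
    if cfg["sigma"] > 0:
        if cfg["dale"]:
            wm = dale_split(gaussian_weights(n // 2, cfg["sigma"], rng_w))
        else:
            wm = gaussian_weights(n, cfg["sigma"], rng_w)
        if cfg["sparsity"] > 0:
            wm = sparsify(wm, cfg["sparsity"], rng_w)
        W = wm.weights
    else:
        W = np.zeros((n, n))
    protocol = DriveProtocol(
        stimulus=PulseSpec(cfg["gamma_S"], int(cfg["tau_S"]), cfg["lambda_S"],
                           cfg["lambda_S_min"], cfg["lambda_S_max"]),
        excitatory=PulseSpec(cfg["gamma_ex"], int(cfg["tau_ex"]),
                             cfg["lambda_ex"], cfg["lambda_ex_min"],
                             cfg["lambda_ex_max"]),
        inhibitory=PulseSpec(cfg["gamma_in"], int(cfg["tau_in"]),
                             cfg["lambda_in"], cfg["lambda_in_min"],
                             cfg["lambda_in_max"]),
        stimulated_ids=tuple(int(i) for i in cfg["stimulated_ids"]),
    )
    schedules = protocol.sample_schedules(n_steps, rng_sched)
    U = drive_trace(protocol, schedules, n_steps, n)
    spec = NetworkSpec(n_neurons=n, bias_b=cfg["bias_b"])
    raster = simulate(spec, W, U, n_steps, rng_sim)
    meta = {**cfg, "n_steps": n_steps, "seed": seed}
    return raster, schedules, meta


def load_raster(path, onsets_path=None):
    """Load a raster from .npz (with stored onsets) or an events CSV."""
    path = str(path)
    onsets = None
    if path.endswith(".npz"):
        data = np.load(path)
        raster = SpikeRaster(data["spikes"])
        if "stimulus_onsets" in data:
            onsets = OnsetSchedule(data["stimulus_onsets"])
    else:
        events = pd.read_csv(path)
        raster = SpikeRaster.from_events(events)
    if onsets_path is not None:
        odf = pd.read_csv(onsets_path)
        col = "time_ms" if "time_ms" in odf.columns else odf.columns[0]
        onsets = OnsetSchedule(np.asarray(odf[col], dtype=np.int64))
    return raster, onsets


def parse_windows(text: str) -> WindowSpec:
    """Parse 'z,x,y:w' (offsets in ms, common width) into a WindowSpec."""
    offs, width = text.split(":")
    z, x, y = (int(v) for v in offs.split(","))
    return WindowSpec(z, x, y, int(width))
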