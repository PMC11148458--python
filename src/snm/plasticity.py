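"""Synaptic transmission, STDP weight updates, and homeostatic mechanisms.

Synapses between two layers are held in a dense ``SynapseMatrix`` (pre x post)
with a binary connectivity mask; absent connections carry weight exactly zero
and no operation here ever writes into them.

The pair-based STDP rule is

    dW = +A_pos * exp(-dt_pair / tau_pos)   if dt_pair > 0
         -A_neg * exp(+dt_pair / tau_neg)   if dt_pair < 0
         0                                  if dt_pair = 0

with dt_pair = t_post - t_pre, so a presynaptic spike shortly before a
postsynaptic one potentiates the synapse. Weight updates are accumulated over
spike pairs, either all pairs or nearest neighbours (each postsynaptic spike
pairs with the nearest preceding and nearest following presynaptic spike), and
scaled by the learning rate eta.

Homeostasis follows common practice for rate-stable STDP networks: incoming
weight vectors are rescaled to unit Euclidean norm per postsynaptic neuron
after each training epoch, and synaptic dropout suppresses a random fraction
of connections for the duration of a batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .neuron import SpikeTrain

WEIGHT_INIT_STD = 0.05  # Gaussian weight initialisation scale

NEAREST = "nearest"
ALL_PAIRS = "all"

def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class SynapseMatrix:
    """Weighted, masked connectivity between a pre and a post layer.

    weights[j, i] is the synaptic weight from presynaptic neuron j onto
    postsynaptic neuron i; mask[j, i] == 0 marks an absent connection and
    forces the weight to zero.
    """

    weights: np.ndarray
    mask: np.ndarray
    pre_layer: str = ""
    post_layer: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.weights.shape != self.mask.shape:
            raise ValueError(
                f"weights shape {self.weights.shape} != mask shape {self.mask.shape}"
            )
        if np.any((self.mask == 0) & (self.weights != 0)):
            raise ValueError("nonzero weight on a masked-out connection")

    @property
    def n_pre(self) -> int:
        return self.weights.shape[0]

    @property
    def n_post(self) -> int:
        return self.weights.shape[1]

    def copy(self) -> "SynapseMatrix":
        return SynapseMatrix(
            self.weights.copy(), self.mask.copy(), self.pre_layer, self.post_layer
        )


@dataclass(frozen=True)
class STDPParams:
    """Pair-based STDP parameters.

    a_pos, a_neg : potentiation / depression amplitudes (>= 0). The default
        is potentiation-dominant: under teacher forcing the forced output
        neuron fires persistently, making pre/post pairings nearly
        time-symmetric, so the net drift per co-active pathway is
        proportional to a_pos - a_neg and must be positive for the teacher
        signal to strengthen (rather than erode) the correct pathways.
    tau_pos, tau_neg : exponential decay constants in ms (> 0).
    eta : learning rate multiplying the accumulated pair sum.
    pairing : "nearest" (default) or "all".
    """

    a_pos: float = 0.1
    a_neg: float = 0.05
    tau_pos: float = 20.0
    tau_neg: float = 20.0
    eta: float = 0.01
    pairing: str = NEAREST

    def __post_init__(self) -> None:
        if self.tau_pos <= 0 or self.tau_neg <= 0:
            raise ValueError("tau_pos and tau_neg must be > 0")
        if self.a_pos < 0 or self.a_neg < 0:
            raise ValueError("a_pos and a_neg must be >= 0")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.pairing not in (NEAREST, ALL_PAIRS):
            raise ValueError(f"unknown pairing scheme {self.pairing!r}")


@dataclass
class NetworkSnapshot:
    """Per-connection weight copies taken before and after a learning episode."""

    pre: dict[str, np.ndarray]
    post: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.pre) != set(self.post):
            raise ValueError("pre and post snapshots must cover the same connections")
        for k in self.pre:
            if self.pre[k].shape != self.post[k].shape:
                raise ValueError(f"snapshot shape mismatch for connection {k!r}")


# ---------------------------------------------------------------------------
# Transmission
# ---------------------------------------------------------------------------


def synaptic_current(synapses: SynapseMatrix, presynaptic_spikes_now: np.ndarray) -> np.ndarray:
    """Instantaneous synaptic input I_syn,i = sum_j W_ji S_j for each post neuron."""
    s = np.asarray(presynaptic_spikes_now, dtype=float)
    if s.shape != (synapses.n_pre,):
        raise ValueError(
            f"spike vector length {s.shape} does not match {synapses.n_pre} presynaptic neurons"
        )
    return s @ synapses.weights


# ---------------------------------------------------------------------------
# STDP
# ---------------------------------------------------------------------------


def stdp_delta(delta_t: float, params: STDPParams) -> float:
    """Weight change for a single spike pair with dt_pair = t_post - t_pre."""
    if delta_t > 0:
        return float(params.a_pos * np.exp(-delta_t / params.tau_pos))
    if delta_t < 0:
        return float(-params.a_neg * np.exp(delta_t / params.tau_neg))
    return 0.0


def _exp_trace(binned: np.ndarray, decay: float) -> np.ndarray:
    """T[:, t] = sum_{t' < t} binned[:, t'] * decay^(t - t') via a linear filter."""
    return lfilter([0.0, decay], [1.0, -decay], binned, axis=1)


def _dw_all_pairs(
    b_pre: np.ndarray, b_post: np.ndarray, params: STDPParams, dt: float
) -> np.ndarray:
    decay_p = np.exp(-dt / params.tau_pos)
    decay_n = np.exp(-dt / params.tau_neg)
    trace_pre = _exp_trace(b_pre, decay_p)
    trace_post = _exp_trace(b_post, decay_n)
    dw_pos = params.a_pos * (trace_pre @ b_post.T)
    dw_neg = params.a_neg * (b_pre @ trace_post.T)
    return dw_pos - dw_neg


def _dw_nearest(
    b_pre: np.ndarray, b_post: np.ndarray, params: STDPParams, dt: float
) -> np.ndarray:
    n_pre, n_bins = b_pre.shape
    decay_p = np.exp(-dt / params.tau_pos)
    decay_n = np.exp(-dt / params.tau_neg)
    # P[j, t]: exp decay since the most recent pre spike strictly before bin t
    P = np.zeros_like(b_pre, dtype=float)
    prev = np.zeros(n_pre)
    for t in range(1, n_bins):
        prev = np.where(b_pre[:, t - 1] > 0, decay_p, prev * decay_p)
        P[:, t] = prev
    # N[j, t]: exp decay until the next pre spike strictly after bin t
    N = np.zeros_like(b_pre, dtype=float)
    nxt = np.zeros(n_pre)
    for t in range(n_bins - 2, -1, -1):
        nxt = np.where(b_pre[:, t + 1] > 0, decay_n, nxt * decay_n)
        N[:, t] = nxt
    return (params.a_pos * P - params.a_neg * N) @ b_post.T


def stdp_pair_sums(
    b_pre: np.ndarray, b_post: np.ndarray, params: STDPParams, dt: float
) -> np.ndarray:
    """Accumulated STDP pair sums for every (pre, post) neuron pair.

    b_pre, b_post are binned spike-count arrays of shape (n_neurons, n_bins)
    on a shared grid of width dt; the result has shape (n_pre, n_post) and is
    *not* yet scaled by eta.
    """
    b_pre = np.asarray(b_pre, dtype=float)
    b_post = np.asarray(b_post, dtype=float)
    if b_pre.shape[1] != b_post.shape[1]:
        raise ValueError("pre and post spike rasters must share the time grid")
    if params.pairing == ALL_PAIRS:
        return _dw_all_pairs(b_pre, b_post, params, dt)
    return _dw_nearest(b_pre, b_post, params, dt)


def _as_raster(trains, n_expected: int) -> tuple[np.ndarray, float]:
    """Stack a collection of SpikeTrains (or pass through a raster array)."""
    if isinstance(trains, np.ndarray):
        if trains.shape[0] != n_expected:
            raise ValueError("raster row count does not match layer size")
        return np.asarray(trains, dtype=float), np.nan
    trains = list(trains)
    if len(trains) != n_expected:
        raise ValueError(f"expected {n_expected} spike trains, got {len(trains)}")
    dt = trains[0].dt
    n_bins = trains[0].n_bins
    raster = np.zeros((len(trains), n_bins))
    for i, tr in enumerate(trains):
        if tr.dt != dt or tr.n_bins != n_bins:
            raise ValueError("all spike trains must share duration and dt")
        raster[i] = tr.binned()
    return raster, dt


def apply_stdp(
    synapses: SynapseMatrix,
    pre_trains,
    post_trains,
    params: STDPParams,
    dt: float | None = None,
) -> SynapseMatrix:
    """One STDP update W <- W + eta * pair_sum over a simulated interval.

    ``pre_trains`` / ``post_trains`` are collections of SpikeTrain (or binned
    rasters, in which case ``dt`` must be given). Masked-out connections are
    left at zero.
    """
    b_pre, dt_pre = _as_raster(pre_trains, synapses.n_pre)
    b_post, dt_post = _as_raster(post_trains, synapses.n_post)
    if dt is None:
        dt = dt_pre if np.isfinite(dt_pre) else dt_post
    if dt is None or not np.isfinite(dt):
        raise ValueError("dt must be provided when passing raw rasters")
    dw = stdp_pair_sums(b_pre, b_post, params, dt)
    new_w = synapses.weights + params.eta * dw * (synapses.mask != 0)
    return SynapseMatrix(new_w, synapses.mask.copy(), synapses.pre_layer, synapses.post_layer)


# ---------------------------------------------------------------------------
# Initialisation and homeostasis
# ---------------------------------------------------------------------------


def init_weights(shape, mask, rng_seed=None, std: float = WEIGHT_INIT_STD) -> SynapseMatrix:
    """Gaussian weight initialisation, mean 0 / std 0.05, on the masked-in entries."""
    mask = np.asarray(mask)
    if mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} does not match {tuple(shape)}")
    rng = _rng(rng_seed)
    w = rng.normal(0.0, std, size=tuple(shape)) * (mask != 0)
    return SynapseMatrix(w, mask.copy())


def normalize_weights(synapses: SynapseMatrix) -> SynapseMatrix:
    """Scale each postsynaptic neuron's incoming weight vector to L2 norm 1.

    Columns with all-zero incoming weights are left untouched. Idempotent and
    direction-preserving.
    """
    norms = np.linalg.norm(synapses.weights, axis=0)
    scale = np.where(norms > 0, norms, 1.0)
    return SynapseMatrix(
        synapses.weights / scale, synapses.mask.copy(), synapses.pre_layer, synapses.post_layer
    )


def dropout_mask(shape, rate: float, rng_seed=None) -> np.ndarray:
    """Binary mask with each entry independently dropped (0) with probability rate."""
    if not (0 <= rate < 1):
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    rng = _rng(rng_seed)
    return (rng.random(tuple(shape)) >= rate).astype(np.uint8)
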