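"""Layered feedforward spiking networks: construction, encoding, simulation,
teacher-forced STDP training, and spike-count classification readout.

Architecture follows a sparse feedforward template: an input layer of Poisson
rate-coded channels, hidden layers of spiking neurons, and one output neuron
per class. Connections between adjacent layers are Bernoulli-sampled at a
fixed connectivity probability and carry Gaussian-initialised weights.

Training is supervised STDP with teacher forcing: while a sample is
presented, a constant teacher current is injected into the output neuron of
the true class so that causal pre-before-post pairings strengthen the
pathways that should drive it. After every epoch the incoming weight vectors
are rescaled to unit norm (homeostatic normalisation); synaptic dropout is
resampled per batch.

Classification reads out the output layer's spike counts normalised to sum
one; the predicted label is the argmax (ties broken toward the lowest index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError, DynamicsError
from .neuron import (
    IZHIKEVICH,
    LIF,
    IzhikevichParams,
    LIFParams,
    SpikeTrain,
    izhikevich_step_arr,
    lif_step_arr,
)
from .plasticity import (
    STDPParams,
    dropout_mask,
    init_weights,
    normalize_weights,
    stdp_pair_sums,
)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationConfig:
    """Per-sample simulation settings.

    duration : presentation time per sample (ms).
    dt : integration step (ms).
    teacher_current : constant current injected into the true-class output
        neuron during training (push); the same amplitude is subtracted from
        every other output neuron (pull), keeping incorrect outputs silent
        while the teacher is active so that STDP cannot strengthen
        wrong-class pathways.
    max_rate_hz : Poisson input rate for a feature value of 1.0.
    """

    duration: float = 500.0
    dt: float = 1.0
    teacher_current: float = 1.0
    max_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        if not (self.duration >= self.dt > 0):
            raise ConfigurationError("require duration >= dt > 0")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class SpikeRecord:
    """Binned spike rasters for every layer of one simulated sample.

    ``layers[l]`` has shape (n_neurons_in_layer_l, n_bins); all layers share
    the same time grid.
    """

    layers: list
    dt: float
    duration: float

    def __post_init__(self) -> None:
        nb = self.n_bins
        for lay in self.layers:
            if lay.shape[1] != nb:
                raise ValueError("all layers must share the same number of bins")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def counts(self, layer: int = -1) -> np.ndarray:
        """Total spike count per neuron in a layer."""
        return self.layers[layer].sum(axis=1).astype(float)

    def trains(self, layer: int) -> list[SpikeTrain]:
        return [
            SpikeTrain(np.flatnonzero(row) * self.dt, self.duration, self.dt)
            for row in self.layers[layer]
        ]


@dataclass
class NetworkModel:
    """A layered spiking network with per-neuron adaptive thresholds.

    ``connections[k]`` links layer k to layer k+1; ``thresholds[k]`` holds the
    effective firing thresholds of layer k+1 (the input layer has none).
    """

    layer_sizes: tuple
    neuron_kind: str
    connections: list
    thresholds: list
    lif: LIFParams = field(default_factory=LIFParams)
    izh: IzhikevichParams = field(default_factory=IzhikevichParams)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int | None = None
    trained: bool = False

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_outputs(self) -> int:
        return self.layer_sizes[-1]

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)

    def baseline_theta(self) -> float:
        return self.lif.v_thresh if self.neuron_kind == LIF else self.izh.v_peak

    def reset_floor(self) -> float:
        """Lowest admissible threshold (just above the reset potential)."""
        base = self.lif.v_reset if self.neuron_kind == LIF else self.izh.c
        return base + 1e-6

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            layer_sizes=self.layer_sizes,
            neuron_kind=self.neuron_kind,
            connections=[c.copy() for c in self.connections],
            thresholds=[t.copy() for t in self.thresholds],
            lif=self.lif,
            izh=self.izh,
            sim=self.sim,
            seed=self.seed,
            trained=self.trained,
        )


def build_network(
    n_inputs: int,
    hidden_sizes,
    n_outputs: int,
    connectivity_prob: float = 0.1,
    neuron_kind: str = LIF,
    rng_seed=0,
    lif_params: LIFParams | None = None,
    izh_params: IzhikevichParams | None = None,
    sim: SimulationConfig | None = None,
    weight_std: float = 0.05,
    normalize: bool = True,
) -> NetworkModel:
    """Build a sparse feedforward network with Bernoulli connectivity masks.

    Weights are Gaussian-initialised (mean 0, std ``weight_std``) on the
    sampled connections; with ``normalize`` (default) the same homeostatic
    per-neuron unit-norm scaling used after each training epoch is also
    applied once at construction, so neurons start in a responsive regime.
    """
    sizes = (int(n_inputs), *(int(h) for h in hidden_sizes), int(n_outputs))
    if any(s <= 0 for s in sizes):
        raise ConfigurationError(f"all layer sizes must be positive, got {sizes}")
    if not (0 < connectivity_prob <= 1):
        raise ConfigurationError("connectivity_prob must lie in (0, 1]")
    if neuron_kind not in (LIF, IZHIKEVICH):
        raise ConfigurationError(f"unknown neuron kind {neuron_kind!r}")
    lif_params = lif_params or LIFParams()
    izh_params = izh_params or IzhikevichParams()
    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(2 * (len(sizes) - 1))
    connections = []
    for k in range(len(sizes) - 1):
        shape = (sizes[k], sizes[k + 1])
        mask_rng = np.random.default_rng(children[2 * k])
        mask = (mask_rng.random(shape) < connectivity_prob).astype(np.uint8)
        syn = init_weights(shape, mask, children[2 * k + 1], std=weight_std)
        if normalize:
            syn = normalize_weights(syn)
        syn.pre_layer, syn.post_layer = f"layer{k}", f"layer{k + 1}"
        connections.append(syn)
    base = lif_params.v_thresh if neuron_kind == LIF else izh_params.v_peak
    thresholds = [np.full(sizes[k + 1], base, dtype=float) for k in range(len(sizes) - 1)]
    return NetworkModel(
        layer_sizes=sizes,
        neuron_kind=neuron_kind,
        connections=connections,
        thresholds=thresholds,
        lif=lif_params,
        izh=izh_params,
        sim=sim or SimulationConfig(),
        seed=rng_seed if isinstance(rng_seed, int) else None,
    )


# ---------------------------------------------------------------------------
# Input encoding
# ---------------------------------------------------------------------------


def encode_sample(sample, config: SimulationConfig, rng_seed=None) -> SpikeRecord:
    """Poisson rate coding: channel i fires at feature_i * max_rate_hz.

    Spikes are drawn independently per time bin with probability
    rate * dt (capped at 1), which matches the Poisson counts to within the
    bin discretisation. Features must be non-negative; values are interpreted
    on a [0, 1] scale.
    """
    f = np.asarray(sample, dtype=float).ravel()
    if np.any(f < 0):
        raise DataError("features must be non-negative")
    rng = _rng(rng_seed)
    p = np.minimum(f * config.max_rate_hz * config.dt / 1000.0, 1.0)
    spikes = (rng.random((f.size, config.n_bins)) < p[:, None]).astype(np.uint8)
    return SpikeRecord([spikes], dt=config.dt, duration=config.duration)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate(
    model: NetworkModel,
    input_record: SpikeRecord,
    config: SimulationConfig | None = None,
    teacher_label: int | None = None,
    drop_masks=None,
) -> SpikeRecord:
    """Time-stepped feedforward run of the whole network for one sample.

    At each step, the previous layer's spikes drive the next layer's synaptic
    current, neurons advance one Euler step, and threshold crossings are
    recorded; a spike thus propagates one layer per operation within the same
    step. With ``teacher_label`` set, the teacher current is added to that
    output neuron at every step.
    """
    config = config or model.sim
    inp = input_record.layers[0]
    if inp.shape[0] != model.n_inputs:
        raise ValueError(
            f"input record has {inp.shape[0]} channels, model expects {model.n_inputs}"
        )
    n_bins = input_record.n_bins
    dt = input_record.dt
    kind = model.neuron_kind
    weights = [c.weights for c in model.connections]
    if drop_masks is not None:
        weights = [w * m for w, m in zip(weights, drop_masks)]

    if kind == LIF:
        vs = [np.full(s, model.lif.v_reset, dtype=float) for s in model.layer_sizes[1:]]
        us = None
    else:
        v0, u0 = model.izh.resting_state()
        vs = [np.full(s, v0, dtype=float) for s in model.layer_sizes[1:]]
        us = [np.full(s, u0, dtype=float) for s in model.layer_sizes[1:]]

    out = [inp.copy()] + [
        np.zeros((s, n_bins), dtype=np.uint8) for s in model.layer_sizes[1:]
    ]
    last = len(weights) - 1
    for t in range(n_bins):
        prev = inp[:, t].astype(float)
        for k, w in enumerate(weights):
            current = prev @ w
            if k == last and teacher_label is not None:
                current -= config.teacher_current
                current[teacher_label] += 2.0 * config.teacher_current
            if kind == LIF:
                vs[k], spiked = lif_step_arr(vs[k], model.thresholds[k], current, model.lif, dt)
            else:
                vs[k], us[k], spiked = izhikevich_step_arr(
                    vs[k], us[k], model.thresholds[k], current, model.izh, dt
                )
                if not np.all(np.isfinite(vs[k])):
                    raise DynamicsError("membrane potential diverged during simulation")
            out[k + 1][:, t] = spiked
            prev = spiked.astype(float)
    if kind == LIF and not all(np.all(np.isfinite(v)) for v in vs):
        raise DynamicsError("membrane potential diverged during simulation")
    return SpikeRecord(out, dt=dt, duration=input_record.duration)


# ---------------------------------------------------------------------------
# Readout
# ---------------------------------------------------------------------------


def classify(record: SpikeRecord) -> tuple[int, np.ndarray]:
    """Spike-count readout: normalised output counts as scores, argmax as label.

    A completely silent output layer yields uniform scores and label 0 (the
    lowest-index tie-break).
    """
    counts = record.counts(-1)
    total = counts.sum()
    if total > 0:
        scores = counts / total
    else:
        scores = np.full(counts.size, 1.0 / counts.size)
    return int(np.argmax(scores)), scores


def evaluate_dataset(
    model: NetworkModel,
    features: np.ndarray,
    config: SimulationConfig | None = None,
    rng_seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and row-normalised score matrix for a feature matrix.

    Encoding noise is drawn from per-sample seeds spawned deterministically
    from ``rng_seed``, so repeated evaluations are identical.
    """
    config = config or model.sim
    features = np.asarray(features, dtype=float)
    n = len(features)
    ss = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    children = ss.spawn(n) if n else []
    preds = np.zeros(n, dtype=int)
    scores = np.zeros((n, model.n_outputs))
    for i in range(n):
        enc = encode_sample(features[i], config, children[i])
        rec = simulate(model, enc, config)
        preds[i], scores[i] = classify(rec)
    return preds, scores


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Supervised-STDP training settings (batch size 100, learning rate via
    ``stdp.eta``, dropout 20% by default)."""

    epochs: int = 3
    batch_size: int = 100
    stdp: STDPParams = field(default_factory=STDPParams)
    dropout_rate: float = 0.2
    rng_seed: int = 0
    shuffle: bool = True
    normalize_each_epoch: bool = True
    calibrate_outputs: bool = True
    track_history: bool = True


def _calibrate_output_thresholds(
    model: NetworkModel,
    X: np.ndarray,
    sim: SimulationConfig,
    seed,
    n_cal: int = 40,
    n_iter: int = 4,
) -> None:
    """Intrinsic homeostasis of the readout: rescale each output neuron's
    firing threshold so mean output rates on (a subsample of) the training
    set are balanced. Without this, per-neuron excitability asymmetries from
    the random sparse connectivity can let one output dominate the
    spike-count readout for every input.
    """
    n_cal = min(n_cal, len(X))
    if n_cal == 0:
        return
    # evenly spaced subsample so class-blocked datasets stay balanced
    idx = np.linspace(0, len(X) - 1, n_cal).astype(int)
    children = np.random.SeedSequence(seed).spawn(n_cal)
    encs = [encode_sample(X[i], sim, children[k]) for k, i in enumerate(idx)]
    for _ in range(n_iter):
        counts = np.mean([simulate(model, e, sim).counts(-1) for e in encs], axis=0)
        scale = ((counts + 1.0) / (counts.mean() + 1.0)) ** 0.7
        model.thresholds[-1] = np.clip(model.thresholds[-1] * scale, 0.05, 10.0)


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(dataset, "features"):
        return dataset.features(), dataset.labels
    X, y = dataset
    return np.asarray(X, dtype=float).reshape(len(y), -1), np.asarray(y, dtype=int)


def train(
    model: NetworkModel,
    dataset,
    config: TrainConfig | None = None,
    validation=None,
) -> tuple[NetworkModel, dict]:
    """Teacher-forced STDP training over a labelled dataset.

    Per sample: encode, inject the teacher current into the true-class output
    neuron, simulate, and apply the STDP update on every connection (masked by
    the batch's dropout draw). Weights are re-normalised per postsynaptic
    neuron after each epoch. Returns a new model plus a history of per-epoch
    training (and optional validation) accuracy.
    """
    config = config or TrainConfig()
    X, y = _as_xy(dataset)
    model = model.copy()
    model.trained = True
    if len(y) and (y.min() < 0 or y.max() >= model.n_outputs):
        raise DataError("labels must lie in [0, n_outputs)")
    history: dict = {"train_accuracy": [], "val_accuracy": []}
    ss = np.random.SeedSequence(config.rng_seed)
    ss_shuffle, ss_drop, ss_enc, ss_eval = ss.spawn(4)
    shuffle_rng = np.random.default_rng(ss_shuffle)
    drop_rng = np.random.default_rng(ss_drop)
    enc_rng = np.random.default_rng(ss_enc)
    eval_seed = int(ss_eval.generate_state(1)[0] % (2**31))
    sim = model.sim
    n = len(y)
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(n) if config.shuffle else np.arange(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            drops = [
                dropout_mask(c.weights.shape, config.dropout_rate, drop_rng)
                for c in model.connections
            ]
            for i in batch:
                enc = encode_sample(X[i], sim, enc_rng)
                rec = simulate(model, enc, sim, teacher_label=int(y[i]), drop_masks=drops)
                for k, conn in enumerate(model.connections):
                    dw = stdp_pair_sums(
                        rec.layers[k].astype(float),
                        rec.layers[k + 1].astype(float),
                        config.stdp,
                        sim.dt,
                    )
                    conn.weights += config.stdp.eta * dw * (conn.mask != 0) * drops[k]
        if config.normalize_each_epoch:
            model.connections = [normalize_weights(c) for c in model.connections]
        # rate balancing is only meaningful when the training set spans
        # several classes; on a one-class set it would force the wrong
        # outputs to fire as often as the right one
        if config.calibrate_outputs and np.unique(y).size >= 2:
            _calibrate_output_thresholds(model, X, sim, (config.rng_seed, _epoch))
        if config.track_history:
            preds, _ = evaluate_dataset(model, X, sim, rng_seed=eval_seed)
            history["train_accuracy"].append(float(np.mean(preds == y)))
            if validation is not None:
                Xv, yv = _as_xy(validation)
                pv, _ = evaluate_dataset(model, Xv, sim, rng_seed=eval_seed + 1)
                history["val_accuracy"].append(float(np.mean(pv == yv)))
    return model, history
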