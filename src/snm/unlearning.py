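"""Hybrid machine unlearning for spiking networks.

Three phases, orchestrated iteratively until the network's response to the
forget data falls below a convergence tolerance:

1. **Selective retraining.** Neurons are scored by the correlation of their
   spike train with the target-data drive, Corr_i(d) = sum_t S_i(t) d(t) dt,
   and synapses by the weight change attributable to the forget data,
   dW_ij(d), obtained by counterfactual replay (snapshot the weights, replay
   one STDP pass over only the forget data, diff, restore). Selected synapses
   are reverted: W' = W - alpha * dW(d) * kappa, where kappa = 1 only when
   both endpoints are selected.
2. **Synaptic pruning.** Within the selection, synapses whose attributable
   change exceeds a pruning threshold theta (|dW| > theta) are zeroed and
   permanently removed from the connectivity mask.
3. **Adaptive thresholding.** Selected neurons' firing thresholds receive
   d_theta = -gamma * sum_t (S_i(t) - S_hat_i(t))
           + beta * sum_t (dS_i/dt - dS_hat_i/dt),
   where S_hat is the desired (by default silent) response to the forget
   data. Note the sign structure: with gamma > 0 this formula *lowers* the
   threshold of an over-responsive neuron; the pipeline therefore defaults to
   a negative gamma so that excess response to forget data raises the
   threshold and suppresses it. Thresholds are floored just above the reset potential.

The per-phase operators are exposed individually and composed by ``unlearn``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, StateError
from .neuron import SpikeTrain, binned_derivative
from .network import (
    NetworkModel,
    SpikeRecord,
    TrainConfig,
    classify,
    encode_sample,
    simulate,
)
from .plasticity import NetworkSnapshot, SynapseMatrix, stdp_pair_sums


# ---------------------------------------------------------------------------
# Declarations and configuration
# ---------------------------------------------------------------------------


@dataclass
class ForgetSpec:
    """What to unlearn: a whole class or an explicit sample-index subset.

    ``d_signal`` is the binned target-data drive d(t); it is filled in by the
    unlearning pipeline (mean fraction of active input channels per time bin
    over the encoded forget samples) when not supplied.
    """

    mode: str  # "class" | "sample"
    indices: np.ndarray
    target: int | None = None
    fraction: float | None = None
    d_signal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.mode not in ("class", "sample"):
            raise DataError(f"unknown forget mode {self.mode!r}")
        if self.fraction is not None and not 0 < self.fraction <= 1:
            raise DataError("fraction must lie in (0, 1]")


@dataclass
class UnlearnConfig:
    """Tunables of the three unlearning phases.

    Thresholds default to data-driven percentiles: neuron selection at the
    75th percentile of Corr_i(d), synapse selection at the 75th percentile of
    |dW(d)| over connected synapses, pruning at the 50th percentile of the
    selected |dW(d)|. Explicit ``*_threshold`` / ``prune_theta`` values
    override the percentiles. Convergence is declared when the mean true-class
    output score on the forget set drops below ``tol`` (default 1.5 x chance).
    """

    alpha: float = 1.0
    corr_threshold: float | None = None
    corr_percentile: float = 75.0
    dw_threshold: float | None = None
    dw_percentile: float = 75.0
    prune_theta: float | None = None
    prune_percentile: float = 50.0
    gamma: float = -0.002
    beta: float = 0.01
    desired_response: np.ndarray | None = None
    max_iterations: int = 10
    tol: float | None = None
    prune_scope: str = "selection"  # "selection" | "global"
    prune_criterion: str = "magnitude"  # "magnitude" | "nonpositive"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.prune_theta is not None and self.prune_theta < 0:
            raise ValueError("prune_theta must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.prune_scope not in ("selection", "global"):
            raise ValueError(f"unknown prune_scope {self.prune_scope!r}")
        if self.prune_criterion not in ("magnitude", "nonpositive"):
            raise ValueError(f"unknown prune_criterion {self.prune_criterion!r}")


@dataclass
class CorrelationProfile:
    """Per-neuron correlation values Corr_i(d), grouped per layer."""

    values: list

    def __post_init__(self) -> None:
        for v in self.values:
            if not np.all(np.isfinite(v)):
                raise ValueError("correlation scores must be finite")

    def flat(self) -> np.ndarray:
        return np.concatenate([np.ravel(v) for v in self.values]) if self.values else np.zeros(0)


@dataclass
class SelectionSet:
    """Neurons flagged for retraining/thresholding and synapse pairs with
    kappa = 1 (both endpoints selected and |dW(d)| above threshold)."""

    neurons: list  # list of bool arrays, one per layer
    synapses: list  # list of bool arrays, one per connection

    @property
    def n_neurons(self) -> int:
        return int(sum(np.sum(n) for n in self.neurons))

    @property
    def n_synapses(self) -> int:
        return int(sum(np.sum(s) for s in self.synapses))


@dataclass
class UnlearnReport:
    """Per-iteration log of the unlearning run."""

    iterations: list
    converged: bool
    forget_score_initial: float
    forget_score_final: float

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def to_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "forget_score_initial": self.forget_score_initial,
            "forget_score_final": self.forget_score_final,
        }


# ---------------------------------------------------------------------------
# Phase operators
# ---------------------------------------------------------------------------


def correlation_scores(record: SpikeRecord, d_signal: np.ndarray, dt: float) -> CorrelationProfile:
    """Discretised correlation integral Corr_i(d) = sum_t S_i(t) d(t) dt per neuron."""
    d = np.asarray(d_signal, dtype=float)
    if d.shape != (record.n_bins,):
        raise ValueError(
            f"d_signal has {d.shape} bins, record has {record.n_bins}"
        )
    return CorrelationProfile([lay.astype(float) @ d * dt for lay in record.layers])


def weight_change(snapshot: NetworkSnapshot) -> dict:
    """Elementwise dW = W_post - W_pre for every connection in the snapshot."""
    return {k: snapshot.post[k] - snapshot.pre[k] for k in snapshot.pre}


def select_targets(
    corrs: CorrelationProfile,
    dW,
    config: UnlearnConfig,
    masks=None,
) -> SelectionSet:
    """Flag neurons with Corr_i(d) above threshold and synapses with large
    attributable weight change whose endpoints are both flagged.

    ``dW`` is a list of per-connection change arrays aligned with
    ``corrs.values`` (layer k -> layer k+1). When ``masks`` is given, the
    |dW| percentile is taken over connected synapses only.
    """
    flat = corrs.flat()
    corr_thr = (
        config.corr_threshold
        if config.corr_threshold is not None
        else float(np.percentile(flat, config.corr_percentile)) if flat.size else 0.0
    )
    neurons = [np.asarray(v) > corr_thr for v in corrs.values]
    if config.dw_threshold is not None:
        dw_thr = config.dw_threshold
    else:
        pools = []
        for k, d in enumerate(dW):
            a = np.abs(d)
            pools.append(a[masks[k] != 0] if masks is not None else a.ravel())
        pool = np.concatenate(pools) if pools else np.zeros(0)
        dw_thr = float(np.percentile(pool, config.dw_percentile)) if pool.size else np.inf
    synapses = []
    for k, d in enumerate(dW):
        kappa = (np.abs(d) > dw_thr) & neurons[k][:, None] & neurons[k + 1][None, :]
        synapses.append(kappa)
    return SelectionSet(neurons=neurons, synapses=synapses)


def selective_retrain(
    synapses: SynapseMatrix, dW_d: np.ndarray, alpha: float, kappa: np.ndarray
) -> SynapseMatrix:
    """Revert the attributable weight change on selected pairs:
    W' = W - alpha * dW(d) on pairs with kappa = 1, all others untouched."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    dW_d = np.asarray(dW_d, dtype=float)
    kappa = np.asarray(kappa)
    if dW_d.shape != synapses.weights.shape or kappa.shape != synapses.weights.shape:
        raise ValueError("dW and kappa must match the weight shape")
    w = synapses.weights - alpha * dW_d * (kappa != 0) * (synapses.mask != 0)
    return SynapseMatrix(w, synapses.mask.copy(), synapses.pre_layer, synapses.post_layer)


def prune_mask(dW: np.ndarray, theta: float) -> np.ndarray:
    """Binary pruning condition: Prune_ij = 1 iff |dW_ij| > theta."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return (np.abs(np.asarray(dW, dtype=float)) > theta).astype(np.uint8)


def apply_prune(synapses: SynapseMatrix, prune: np.ndarray) -> SynapseMatrix:
    """Zero pruned weights, W' = W * (1 - Prune), and permanently remove the
    pruned connections from the connectivity mask."""
    prune = np.asarray(prune)
    if prune.shape != synapses.weights.shape:
        raise ValueError("prune mask must match the weight shape")
    keep = prune == 0
    return SynapseMatrix(
        synapses.weights * keep,
        ((synapses.mask != 0) & keep).astype(np.uint8),
        synapses.pre_layer,
        synapses.post_layer,
    )


def threshold_update(
    theta_i: float,
    S_i,
    S_hat_i,
    gamma: float,
    beta: float,
    dt: float,
) -> float:
    """Adaptive-thresholding update for one neuron.

    d_theta   = -gamma * sum_t (S_i(t) - S_hat_i(t))
    d_timing  =  beta  * sum_t (dS_i/dt - dS_hat_i/dt)

    and the new threshold is theta_i + d_theta + d_timing. ``S_i`` may be a
    SpikeTrain or an already-binned count signal; ``S_hat_i`` (the desired
    response) may be None for an all-zero target.
    """
    s = S_i.binned(dt) if isinstance(S_i, SpikeTrain) else np.asarray(S_i, dtype=float)
    if S_hat_i is None:
        s_hat = np.zeros_like(s)
    else:
        s_hat = (
            S_hat_i.binned(dt) if isinstance(S_hat_i, SpikeTrain) else np.asarray(S_hat_i, dtype=float)
        )
    if s.shape != s_hat.shape:
        raise ValueError("actual and desired responses must share the bin grid")
    d_theta = -gamma * float(np.sum(s - s_hat))
    d_timing = beta * float(np.sum(binned_derivative(s) - binned_derivative(s_hat)))
    return float(theta_i) + d_theta + d_timing


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _mean_true_score(model, encs, labels, config) -> float:
    vals = []
    for enc, lab in zip(encs, labels):
        _, scores = classify(simulate(model, enc, config))
        vals.append(scores[lab])
    return float(np.mean(vals))


def _replay_dw(model, encs, labels, stdp, sim) -> list:
    """Counterfactual replay: weight change attributable to the forget data.

    Replays one teacher-forced STDP pass over the forget data alone, applies
    the same homeostatic unit-norm rescaling used after every training epoch,
    and diffs against the current weights, so the attributed change lives on
    the scale of the trained (normalised) model and shrinks with the amount
    of data replayed. The model's weights are restored afterwards.
    """
    from .plasticity import normalize_weights

    before = [c.weights.copy() for c in model.connections]
    for enc, lab in zip(encs, labels):
        rec = simulate(model, enc, sim, teacher_label=int(lab))
        for k, conn in enumerate(model.connections):
            dw = stdp_pair_sums(
                rec.layers[k].astype(float), rec.layers[k + 1].astype(float), stdp, sim.dt
            )
            conn.weights += stdp.eta * dw * (conn.mask != 0)
    dW = [normalize_weights(c).weights - b for c, b in zip(model.connections, before)]
    for conn, b in zip(model.connections, before):
        conn.weights = b
    return dW


def unlearn(
    model: NetworkModel,
    forget: ForgetSpec,
    dataset,
    config: UnlearnConfig | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[NetworkModel, UnlearnReport]:
    """Run the full three-phase unlearning procedure on a trained model.

    Per iteration: simulate the model on the forget data; compute correlation
    scores and the replay-attributed weight change; select targets; apply
    selective retraining, then pruning (within the selection by default),
    then adaptive thresholding; stop when the mean forget-set true-class
    score falls below the tolerance or after ``max_iterations``.
    """
    if not model.trained:
        raise StateError("unlearn requires a model that has been through train()")
    if forget.indices.size == 0:
        raise DataError("forget set is empty")
    cfg = config or UnlearnConfig()
    tc = train_config or TrainConfig()
    if hasattr(dataset, "features"):
        X, y = dataset.features(), dataset.labels
    else:
        X, y = dataset
        X = np.asarray(X, dtype=float).reshape(len(y), -1)
        y = np.asarray(y, dtype=int)
    if forget.indices.max() >= len(y):
        raise DataError("forget indices outside dataset")
    Xf, yf = X[forget.indices], y[forget.indices]
    model = model.copy()
    sim = model.sim
    dt = sim.dt
    tol = cfg.tol if cfg.tol is not None else 1.5 / model.n_outputs
    ss = np.random.SeedSequence(cfg.rng_seed)
    enc_children = ss.spawn(len(yf))
    encs = [encode_sample(Xf[i], sim, enc_children[i]) for i in range(len(yf))]
    if forget.d_signal is None:
        forget.d_signal = np.mean([e.layers[0].mean(axis=0) for e in encs], axis=0)
    d = forget.d_signal

    masks = [c.mask for c in model.connections]
    iterations = []
    converged = False
    score0 = None
    for _it in range(cfg.max_iterations):
        # Forget-set response and neuron correlations
        recs = [simulate(model, e, sim) for e in encs]
        if score0 is None:
            score0 = float(
                np.mean([classify(r)[1][lab] for r, lab in zip(recs, yf)])
            )
        profiles = [correlation_scores(r, d, dt) for r in recs]
        mean_vals = [
            np.mean([p.values[l] for p in profiles], axis=0)
            for l in range(model.n_layers)
        ]
        corr = CorrelationProfile(mean_vals)
        # Attributable weight change via counterfactual replay
        dW = _replay_dw(model, encs, yf, tc.stdp, sim)
        sel = select_targets(corr, dW, cfg, masks=masks)
        # Phase 1: selective retraining
        for k, conn in enumerate(model.connections):
            model.connections[k] = selective_retrain(conn, dW[k], cfg.alpha, sel.synapses[k])
        # Phase 2: pruning
        if cfg.prune_theta is not None:
            theta_p = cfg.prune_theta
        else:
            selected_dw = np.concatenate(
                [np.abs(dW[k][sel.synapses[k]]).ravel() for k in range(len(dW))]
            )
            theta_p = (
                float(np.percentile(selected_dw, cfg.prune_percentile))
                if selected_dw.size
                else np.inf
            )
        n_pruned = 0
        for k, conn in enumerate(model.connections):
            if cfg.prune_criterion == "magnitude":
                pm = prune_mask(dW[k], theta_p)
            else:  # "nonpositive": synapses whose attributable contribution <= 0
                pm = ((dW[k] <= 0) & (conn.mask != 0)).astype(np.uint8)
            if cfg.prune_scope == "selection":
                pm = (pm != 0) & sel.synapses[k]
            pm = np.asarray(pm, dtype=np.uint8)
            n_pruned += int(pm.sum())
            model.connections[k] = apply_prune(conn, pm)
        masks = [c.mask for c in model.connections]
        # Phase 3: adaptive thresholding on selected neurons
        floor = model.reset_floor()
        theta_delta = 0.0
        for l in range(1, model.n_layers):
            selected = sel.neurons[l]
            if not np.any(selected):
                continue
            # aggregate response over all forget presentations: the threshold
            # shift scales with how much data is being forgotten
            s_mean = np.sum([r.layers[l].astype(float) for r in recs], axis=0)
            s_hat = (
                np.zeros_like(s_mean)
                if cfg.desired_response is None
                else np.broadcast_to(cfg.desired_response, s_mean.shape)
            )
            d_th = -cfg.gamma * np.sum(s_mean - s_hat, axis=1)
            ds = np.diff(s_mean, axis=1, prepend=s_mean[:, :1])
            ds_hat = np.diff(s_hat, axis=1, prepend=s_hat[:, :1])
            d_timing = cfg.beta * np.sum(ds - ds_hat, axis=1)
            th = model.thresholds[l - 1]
            new_th = np.where(selected, np.maximum(th + d_th + d_timing, floor), th)
            theta_delta += float(np.sum(np.abs(new_th - th)))
            model.thresholds[l - 1] = new_th
        # Convergence: mean true-class output score on the forget set
        score = _mean_true_score(model, encs, yf, sim)
        iterations.append(
            {
                "forget_true_score": score,
                "n_neurons_selected": sel.n_neurons,
                "n_synapses_selected": sel.n_synapses,
                "n_pruned": n_pruned,
                "threshold_delta": theta_delta,
            }
        )
        if score < tol:
            converged = True
            break
    return model, UnlearnReport(
        iterations=iterations,
        converged=converged,
        forget_score_initial=float(score0),
        forget_score_final=float(iterations[-1]["forget_true_score"]),
    )


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------


def verify_unlearning(
    model_before: NetworkModel,
    model_after: NetworkModel,
    forget_set,
    retain_set,
    rng_seed=0,
) -> dict:
    """Efficacy report: forget-set accuracy/recall and retain-set accuracy for
    both models, plus the mean true-class output score on the forget data and
    before/after deltas."""
    from .network import evaluate_dataset  # local import keeps module load light

    def _xy(ds):
        if hasattr(ds, "features"):
            return ds.features(), ds.labels
        X, y = ds
        return np.asarray(X, dtype=float).reshape(len(y), -1), np.asarray(y, dtype=int)

    Xf, yf = _xy(forget_set)
    Xr, yr = _xy(retain_set)
    if len(yf) == 0 or len(yr) == 0:
        raise DataError("forget and retain sets must be non-empty")
    out: dict = {}
    for tag, m in (("before", model_before), ("after", model_after)):
        pf, sf = evaluate_dataset(m, Xf, rng_seed=rng_seed)
        pr, _ = evaluate_dataset(m, Xr, rng_seed=rng_seed + 1)
        out[f"forget_recall_{tag}"] = float(np.mean(pf == yf))
        out[f"retain_accuracy_{tag}"] = float(np.mean(pr == yr))
        out[f"forget_true_score_{tag}"] = float(np.mean(sf[np.arange(len(yf)), yf]))
    out["forget_recall_delta"] = out["forget_recall_after"] - out["forget_recall_before"]
    out["retain_accuracy_delta"] = out["retain_accuracy_after"] - out["retain_accuracy_before"]
    out["forget_true_score_delta"] = (
        out["forget_true_score_after"] - out["forget_true_score_before"]
    )
    return out
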