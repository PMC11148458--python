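"""End-to-end reproducible experiments: generate data, train, unlearn,
optionally retrain, evaluate (baseline / post-unlearning / post-retraining),
and audit with a membership-inference attack.

All randomness fans out from the config's single run seed via per-stage
seeds, so an identical config and seed reproduces every artifact exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentConfig, stage_seed
from .data import (
    LabeledDataset,
    gen_image_dataset,
    gen_separable_dataset,
    gen_timeseries_dataset,
    make_forget_spec,
    split_dataset,
)
from .evaluation import confusion_metrics, mia_attack
from .io import save_model, save_report
from .network import SimulationConfig, TrainConfig, build_network, evaluate_dataset, train
from .neuron import LIFParams
from .plasticity import STDPParams
from .unlearning import UnlearnConfig, unlearn


def generate_data(cfg: ExperimentConfig) -> LabeledDataset:
    d = cfg.data
    seed = stage_seed(cfg.seed, "data")
    if d.kind == "image":
        return gen_image_dataset(d.n_samples, d.n_classes, d.noise_sd, seed)
    if d.kind == "timeseries":
        return gen_timeseries_dataset(
            d.n_samples, d.n_classes, d.n_channels, d.n_timesteps, d.noise_sd, seed
        )
    return gen_separable_dataset(
        d.n_samples, d.n_classes, n_channels=d.n_channels * d.n_classes,
        noise_sd=d.noise_sd, rng_seed=seed,
    )


def _sim_config(cfg: ExperimentConfig) -> SimulationConfig:
    t = cfg.training
    return SimulationConfig(
        duration=t.duration_ms,
        dt=t.dt_ms,
        teacher_current=t.teacher_current,
        max_rate_hz=t.max_rate_hz,
    )


def _train_config(cfg: ExperimentConfig, epochs: int | None = None, stage: str = "train") -> TrainConfig:
    t = cfg.training
    return TrainConfig(
        epochs=t.epochs if epochs is None else epochs,
        batch_size=t.batch_size,
        stdp=STDPParams(
            a_pos=t.a_pos,
            a_neg=t.a_neg,
            tau_pos=t.tau_pos,
            tau_neg=t.tau_neg,
            eta=t.learning_rate,
            pairing=t.pairing,
        ),
        dropout_rate=t.dropout_rate,
        rng_seed=stage_seed(cfg.seed, stage),
    )


def _metrics(model, ds: LabeledDataset, seed: int) -> dict:
    preds, scores = evaluate_dataset(model, ds.features(), rng_seed=seed)
    return confusion_metrics(ds.labels, preds, scores).to_dict()


METRIC_ROWS = ["accuracy", "precision", "recall", "f1", "sensitivity", "specificity", "roc_auc"]


def run_experiment(cfg: ExperimentConfig, out_dir) -> dict:
    """Run the full protocol and write models, JSON report and metric tables.

    Returns the report dict (also written as ``report.json``). The metric
    table mirrors the baseline / post-unlearning / post-retraining layout;
    the MIA table reports attack accuracy/precision/recall before and after
    unlearning.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = generate_data(cfg)
    train_ds, val_ds, test_ds = split_dataset(
        dataset, cfg.data.split, stage_seed(cfg.seed, "split")
    )
    sim = _sim_config(cfg)
    net = cfg.network
    model0 = build_network(
        dataset.n_features,
        net.hidden_sizes,
        dataset.n_classes,
        connectivity_prob=net.connectivity_prob,
        neuron_kind=net.neuron_kind,
        rng_seed=stage_seed(cfg.seed, "network"),
        lif_params=LIFParams(tau_m=net.tau_m, v_thresh=net.v_thresh, v_reset=net.v_reset),
        sim=sim,
        weight_std=net.weight_init_std,
    )
    model, history = train(
        model0, train_ds, _train_config(cfg), validation=val_ds if len(val_ds) else None
    )
    eval_seed = stage_seed(cfg.seed, "eval")
    baseline = _metrics(model, test_ds, eval_seed)

    ul = cfg.unlearning
    if ul.mode == "class":
        rng = np.random.default_rng(stage_seed(cfg.seed, "forget"))
        target = ul.target if ul.target is not None else int(rng.integers(dataset.n_classes))
        forget = make_forget_spec(train_ds, "class", target)
    else:
        forget = make_forget_spec(
            train_ds, "sample", ul.fraction, stage_seed(cfg.seed, "forget")
        )
    ucfg = UnlearnConfig(
        alpha=ul.alpha,
        corr_percentile=ul.corr_percentile,
        dw_percentile=ul.dw_percentile,
        prune_percentile=ul.prune_percentile,
        gamma=ul.gamma,
        beta=ul.beta,
        max_iterations=ul.max_iterations,
        prune_scope=ul.prune_scope,
        prune_criterion=ul.prune_criterion,
        rng_seed=stage_seed(cfg.seed, "unlearn"),
    )
    unlearned, ureport = unlearn(model, forget, train_ds, ucfg, _train_config(cfg))
    post_unlearning = _metrics(unlearned, test_ds, eval_seed)

    post_retraining = None
    retrained = None
    if ul.retrain_epochs > 0:
        keep = np.setdiff1d(np.arange(len(train_ds)), forget.indices)
        retained_ds = train_ds.subset(keep, note="retained")
        retrained, _ = train(
            unlearned, retained_ds, _train_config(cfg, ul.retrain_epochs, "retrain")
        )
        post_retraining = _metrics(retrained, test_ds, eval_seed)

    mia = None
    if cfg.evaluation.run_mia:
        members = train_ds.features()[forget.indices]
        nonmembers = test_ds.features()
        n = min(len(members), len(nonmembers))
        mia_seed = stage_seed(cfg.seed, "mia")
        mia = {
            "before": mia_attack(model, members[:n], nonmembers[:n], mia_seed).to_dict(),
            "after": mia_attack(unlearned, members[:n], nonmembers[:n], mia_seed).to_dict(),
        }

    report = {
        "config": json.loads(cfg.model_dump_json()),
        "package_version": __version__,
        "history": history,
        "baseline": baseline,
        "post_unlearning": post_unlearning,
        "post_retraining": post_retraining,
        "forget": {
            "mode": forget.mode,
            "target": forget.target,
            "fraction": forget.fraction,
            "n_indices": int(forget.indices.size),
        },
        "unlearning": ureport.to_dict(),
        "mia": mia,
    }
    save_report(report, out / "report.json")
    save_model(model, out / "model_baseline.h5")
    save_model(unlearned, out / "model_unlearned.h5")
    if retrained is not None:
        save_model(retrained, out / "model_retrained.h5")
    table = pd.DataFrame(
        {
            "Metric": METRIC_ROWS,
            "Baseline": [baseline[m] for m in METRIC_ROWS],
            "Post-unlearning": [post_unlearning[m] for m in METRIC_ROWS],
            "Post-retraining": [
                post_retraining[m] if post_retraining else float("nan") for m in METRIC_ROWS
            ],
        }
    )
    table.to_csv(out / "metrics_table.csv", index=False)
    if mia is not None:
        mia_table = pd.DataFrame(
            {
                "Setting": [f"Initial {forget.mode} performance",
                            f"Post-unlearning {forget.mode} performance"],
                "Accuracy": [mia["before"]["accuracy"], mia["after"]["accuracy"]],
                "Precision": [mia["before"]["precision"], mia["after"]["precision"]],
                "Recall": [mia["before"]["recall"], mia["after"]["recall"]],
            }
        )
        mia_table.to_csv(out / "mia_table.csv", index=False)
    return report


def sweep_factory(cfg: ExperimentConfig):
    """Build an ``experiment_factory(fraction, seed)`` for unlearning_sweep.

    Each call generates data, trains a fresh model, unlearns the given
    sample fraction, and returns (baseline, post-unlearning) test accuracy.
    """

    def factory(fraction: float, seed: int) -> tuple[float, float]:
        c = cfg.model_copy(deep=True)
        c.seed = int(seed)
        c.unlearning.mode = "sample"
        c.unlearning.fraction = float(fraction)
        dataset = generate_data(c)
        train_ds, _, test_ds = split_dataset(
            dataset, c.data.split, stage_seed(c.seed, "split")
        )
        net = c.network
        model0 = build_network(
            dataset.n_features,
            net.hidden_sizes,
            dataset.n_classes,
            connectivity_prob=net.connectivity_prob,
            neuron_kind=net.neuron_kind,
            rng_seed=stage_seed(c.seed, "network"),
            lif_params=LIFParams(tau_m=net.tau_m, v_thresh=net.v_thresh, v_reset=net.v_reset),
            sim=_sim_config(c),
            weight_std=net.weight_init_std,
        )
        model, _ = train(model0, train_ds, _train_config(c))
        eval_seed = stage_seed(c.seed, "eval")
        preds, _ = evaluate_dataset(model, test_ds.features(), rng_seed=eval_seed)
        base_acc = float(np.mean(preds == test_ds.labels))
        forget = make_forget_spec(train_ds, "sample", fraction, stage_seed(c.seed, "forget"))
        ucfg = UnlearnConfig(
            alpha=c.unlearning.alpha,
            gamma=c.unlearning.gamma,
            beta=c.unlearning.beta,
            max_iterations=c.unlearning.max_iterations,
            rng_seed=stage_seed(c.seed, "unlearn"),
        )
        unlearned, _ = unlearn(model, forget, train_ds, ucfg, _train_config(c))
        preds2, _ = evaluate_dataset(unlearned, test_ds.features(), rng_seed=eval_seed)
        post_acc = float(np.mean(preds2 == test_ds.labels))
        return base_acc, post_acc

    return factory
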