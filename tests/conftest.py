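"""Shared fixtures: the canonical synthetic study task and pre-trained models.

The canonical task is the 2-class linearly separable dataset (disjoint active
input-channel blocks per class) with a 20 -> 40 -> 2 LIF network, 200 ms
Poisson encoding at 1 ms resolution, and one epoch of teacher-forced STDP.
Training and unlearning runs are expensive, so models trained across the
study seeds are computed once per session and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

import snm

STUDY_SEEDS = list(range(5))

SIM = snm.SimulationConfig(duration=200.0, dt=1.0)


def make_task(seed: int, n_train: int = 100, n_test: int = 80):
    """Canonical separable task: train set, test set."""
    train = snm.gen_separable_dataset(n_train, 2, 20, rng_seed=100 + seed)
    test = snm.gen_separable_dataset(n_test, 2, 20, rng_seed=200 + seed)
    return train, test


def build_canonical(seed: int) -> snm.NetworkModel:
    return snm.build_network(
        20, [40], 2, connectivity_prob=0.5, rng_seed=seed, sim=SIM
    )


def train_canonical(
    model, dataset, seed: int, epochs: int = 1, track: bool = False, calibrate: bool = True
):
    cfg = snm.TrainConfig(
        epochs=epochs,
        batch_size=20,
        rng_seed=seed,
        track_history=track,
        calibrate_outputs=calibrate,
    )
    return snm.train(model, dataset, cfg)


@pytest.fixture(scope="session")
def trained_study():
    """Per-seed (train_ds, test_ds, trained_model) for the study seeds."""
    out = {}
    for seed in STUDY_SEEDS:
        train_ds, test_ds = make_task(seed)
        model, _ = train_canonical(build_canonical(seed), train_ds, seed)
        out[seed] = (train_ds, test_ds, model)
    return out


@pytest.fixture(scope="session")
def unlearned_study(trained_study):
    """Class-wise unlearning of class 1 for every study seed.

    Returns per-seed (train_ds, test_ds, model_before, model_after, report).
    """
    out = {}
    for seed in STUDY_SEEDS:
        train_ds, test_ds, model = trained_study[seed]
        forget = snm.make_forget_spec(train_ds, "class", 1)
        after, report = snm.unlearn(
            model,
            forget,
            train_ds,
            snm.UnlearnConfig(rng_seed=seed),
            snm.TrainConfig(rng_seed=seed),
        )
        out[seed] = (train_ds, test_ds, model, after, report)
    return out


@pytest.fixture(scope="session")
def unlearned_study_plain():
    """Class-wise unlearning on models trained without readout-rate
    homeostasis. The plain configuration keeps the trained network's
    class-conditional confidence bias, which is the signal the
    membership-inference audit exploits before unlearning.
    """
    out = {}
    for seed in STUDY_SEEDS:
        train_ds, test_ds = make_task(seed)
        model, _ = train_canonical(
            build_canonical(seed), train_ds, seed, calibrate=False
        )
        forget = snm.make_forget_spec(train_ds, "class", 1)
        after, report = snm.unlearn(
            model,
            forget,
            train_ds,
            snm.UnlearnConfig(rng_seed=seed),
            snm.TrainConfig(rng_seed=seed),
        )
        out[seed] = (train_ds, test_ds, model, after, report)
    return out


@pytest.fixture()
def tiny_trained_model():
    """A very small trained model for quick pipeline tests."""
    train_ds, _ = make_task(0, n_train=40, n_test=10)
    model, _ = train_canonical(build_canonical(0), train_ds, 0)
    return train_ds, model
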