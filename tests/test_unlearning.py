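"""Unlearning phase operators (direct-substitution oracles), locality and
composition properties, and the end-to-end pipeline contracts."""

import numpy as np
import pytest

import snm
from snm import (
    CorrelationProfile,
    SpikeTrain,
    SynapseMatrix,
    UnlearnConfig,
    apply_prune,
    correlation_scores,
    prune_mask,
    select_targets,
    selective_retrain,
    threshold_update,
    unlearn,
    verify_unlearning,
    weight_change,
)
from snm.errors import DataError, StateError
from snm.network import SpikeRecord, encode_sample, simulate
from snm.plasticity import NetworkSnapshot

from conftest import SIM, build_canonical, make_task, train_canonical


def _rec(arrays, dt=1.0):
    arrays = [np.asarray(a, dtype=np.uint8) for a in arrays]
    return SpikeRecord(arrays, dt=dt, duration=arrays[0].shape[1] * dt)


class TestCorrelationScores:
    def test_zero_drive_gives_zero_scores(self):
        rec = _rec([np.ones((2, 4))])
        prof = correlation_scores(rec, np.zeros(4), 1.0)
        assert not prof.flat().any()

    def test_direct_substitution(self):
        rec = _rec([np.array([[0, 1, 0, 1]])])
        prof = correlation_scores(rec, np.array([0.0, 1.0, 1.0, 1.0]), 1.0)
        assert prof.values[0][0] == pytest.approx(2.0)

    def test_invariant_under_joint_bin_permutation(self):
        rng = np.random.default_rng(0)
        s = rng.integers(0, 2, size=(3, 16))
        d = rng.random(16)
        perm = rng.permutation(16)
        a = correlation_scores(_rec([s]), d, 0.5).values[0]
        b = correlation_scores(_rec([s[:, perm]]), d[perm], 0.5).values[0]
        np.testing.assert_allclose(a, b)

    def test_bin_mismatch_raises(self):
        with pytest.raises(ValueError):
            correlation_scores(_rec([np.zeros((1, 4))]), np.zeros(5), 1.0)


class TestWeightChange:
    def test_identical_snapshots_give_zero(self):
        w = np.ones((2, 2))
        snap = NetworkSnapshot(pre={"c": w.copy()}, post={"c": w.copy()})
        assert not weight_change(snap)["c"].any()

    def test_single_entry_change(self):
        pre = np.zeros((2, 2))
        post = pre.copy()
        post[0, 1] = 0.3
        dW = weight_change(NetworkSnapshot(pre={"c": pre}, post={"c": post}))["c"]
        assert dW[0, 1] == pytest.approx(0.3) and np.count_nonzero(dW) == 1

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((2, 3)), rng.random((2, 3))
        d1 = weight_change(NetworkSnapshot(pre={"c": a}, post={"c": b}))["c"]
        d2 = weight_change(NetworkSnapshot(pre={"c": b}, post={"c": a}))["c"]
        np.testing.assert_allclose(d1, -d2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            NetworkSnapshot(pre={"c": np.zeros((2, 2))}, post={"c": np.zeros((3, 2))})


class TestSelectTargets:
    def test_thresholds_above_everything_select_nothing(self):
        corrs = CorrelationProfile([np.array([0.1, 0.2]), np.array([0.3])])
        dW = [np.full((2, 1), 0.05)]
        sel = select_targets(corrs, dW, UnlearnConfig(corr_threshold=1.0, dw_threshold=1.0))
        assert sel.n_neurons == 0 and sel.n_synapses == 0

    def test_zero_threshold_selects_all_positive_scores(self):
        corrs = CorrelationProfile([np.array([0.5, 0.2]), np.array([0.4])])
        dW = [np.full((2, 1), 0.3)]
        sel = select_targets(corrs, dW, UnlearnConfig(corr_threshold=0.0, dw_threshold=0.0))
        assert sel.n_neurons == 3 and sel.n_synapses == 2

    def test_explicit_corr_threshold_comparison(self):
        corrs = CorrelationProfile([np.array([0.5, 0.1])])
        sel = select_targets(corrs, [], UnlearnConfig(corr_threshold=0.3, dw_threshold=0.0))
        np.testing.assert_array_equal(sel.neurons[0], [True, False])

    def test_synapse_needs_both_endpoints_selected(self):
        corrs = CorrelationProfile([np.array([1.0, 0.0]), np.array([1.0])])
        dW = [np.array([[0.5], [0.5]])]
        sel = select_targets(corrs, dW, UnlearnConfig(corr_threshold=0.5, dw_threshold=0.1))
        np.testing.assert_array_equal(sel.synapses[0], [[True], [False]])


class TestSelectiveRetrain:
    def test_alpha_zero_is_identity(self):
        syn = SynapseMatrix(np.array([[0.8]]), np.ones((1, 1)))
        out = selective_retrain(syn, np.array([[0.3]]), 0.0, np.ones((1, 1), bool))
        assert out.weights[0, 0] == 0.8

    def test_selected_pair_reverts_attributed_change(self):
        syn = SynapseMatrix(np.array([[0.8]]), np.ones((1, 1)))
        out = selective_retrain(syn, np.array([[0.3]]), 1.0, np.ones((1, 1), bool))
        assert out.weights[0, 0] == pytest.approx(0.5)

    def test_unselected_pair_untouched(self):
        syn = SynapseMatrix(np.array([[0.8]]), np.ones((1, 1)))
        out = selective_retrain(syn, np.array([[0.3]]), 0.5, np.zeros((1, 1), bool))
        assert out.weights[0, 0] == 0.8

    def test_invalid_alpha_rejected(self):
        syn = SynapseMatrix(np.array([[0.8]]), np.ones((1, 1)))
        with pytest.raises(ValueError):
            selective_retrain(syn, np.array([[0.3]]), 1.5, np.ones((1, 1), bool))


class TestPruning:
    def test_prune_condition_direct_substitution(self):
        np.testing.assert_array_equal(
            prune_mask(np.array([0.2, -0.3, 0.05]), 0.1), [1, 1, 0]
        )

    def test_infinite_threshold_prunes_nothing(self):
        assert not prune_mask(np.array([1e6, -1e6]), np.inf).any()

    def test_zero_threshold_prunes_all_nonzero(self):
        np.testing.assert_array_equal(prune_mask(np.array([0.0, 1e-12, -2.0]), 0.0), [0, 1, 1])

    def test_apply_prune_zeroes_and_disables(self):
        syn = SynapseMatrix(np.array([[0.5, -0.4, 0.7]]), np.ones((1, 3)))
        out = apply_prune(syn, np.array([[1, 1, 0]]))
        np.testing.assert_array_equal(out.weights, [[0.0, 0.0, 0.7]])
        np.testing.assert_array_equal(out.mask, [[0, 0, 1]])

    def test_apply_prune_is_idempotent_and_only_removes(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=(4, 4))
        syn = SynapseMatrix(w, np.ones((4, 4)))
        pm = prune_mask(w, 0.5)
        once = apply_prune(syn, pm)
        twice = apply_prune(once, pm)
        np.testing.assert_array_equal(once.weights, twice.weights)
        assert np.all(np.abs(once.weights) <= np.abs(w))


class TestThresholdUpdate:
    def test_matching_desired_response_leaves_threshold_unchanged(self):
        s = SpikeTrain([2.0, 5.0], 10.0, 1.0)
        assert threshold_update(1.0, s, s, gamma=0.7, beta=0.3, dt=1.0) == pytest.approx(1.0)

    def test_excess_spikes_with_printed_sign(self):
        """5 excess spikes, desired silence, gamma=0.2, beta=0: the printed
        rule yields a threshold *decrease* of 1.0."""
        s = SpikeTrain([1.0, 3.0, 5.0, 7.0, 9.0], 20.0, 1.0)
        out = threshold_update(2.0, s, None, gamma=0.2, beta=0.0, dt=1.0)
        assert out == pytest.approx(2.0 - 1.0)

    def test_timing_term_telescopes_for_interior_spikes(self):
        """The spike-timing term sums a discrete derivative, so an extra
        interior spike contributes nothing net."""
        s = SpikeTrain([5.0], 20.0, 1.0)
        out = threshold_update(1.0, s, None, gamma=0.0, beta=0.5, dt=1.0)
        assert out == pytest.approx(1.0)

    def test_bin_mismatch_raises(self):
        with pytest.raises(ValueError):
            threshold_update(1.0, np.zeros(5), np.zeros(4), 0.1, 0.0, 1.0)


class TestUnlearnPipeline:
    def test_untrained_model_rejected(self):
        train_ds, _ = make_task(0, n_train=20, n_test=10)
        model = build_canonical(0)
        forget = snm.make_forget_spec(train_ds, "class", 1)
        with pytest.raises(StateError):
            unlearn(model, forget, train_ds)

    def test_empty_forget_set_rejected(self, tiny_trained_model):
        train_ds, model = tiny_trained_model
        forget = snm.ForgetSpec(mode="sample", indices=np.array([], dtype=int))
        with pytest.raises(DataError):
            unlearn(model, forget, train_ds)

    def test_identity_configuration_is_exact_identity(self, tiny_trained_model):
        """alpha=0, theta=inf, gamma=beta=0 disables all three phases."""
        train_ds, model = tiny_trained_model
        forget = snm.make_forget_spec(train_ds, "class", 1)
        cfg = UnlearnConfig(alpha=0.0, prune_theta=np.inf, gamma=0.0, beta=0.0,
                            max_iterations=2, rng_seed=0)
        out, _ = unlearn(model, forget, train_ds, cfg)
        for ca, cb in zip(model.connections, out.connections):
            np.testing.assert_array_equal(ca.weights, cb.weights)
            np.testing.assert_array_equal(ca.mask, cb.mask)
        for ta, tb in zip(model.thresholds, out.thresholds):
            np.testing.assert_array_equal(ta, tb)

    def test_locality_outside_selection_nothing_changes(self, tiny_trained_model):
        """With pruning disabled, weights with kappa=0 and thresholds of
        unselected neurons are bit-identical before and after."""
        train_ds, model = tiny_trained_model
        forget = snm.make_forget_spec(train_ds, "class", 1)
        cfg = UnlearnConfig(prune_theta=np.inf, max_iterations=1, rng_seed=0)
        out, rep = unlearn(model, forget, train_ds, cfg)
        # recompute the selection exactly as the pipeline did
        sel = _recompute_selection(model, forget, train_ds, cfg)
        for k, (ca, cb) in enumerate(zip(model.connections, out.connections)):
            untouched = ~sel.synapses[k]
            np.testing.assert_array_equal(ca.weights[untouched], cb.weights[untouched])
        for l in range(1, model.n_layers):
            unsel = ~sel.neurons[l]
            np.testing.assert_array_equal(
                model.thresholds[l - 1][unsel], out.thresholds[l - 1][unsel]
            )

    def test_forget_response_nonincreasing_in_alpha(self):
        """Retraining-only erasure strength grows with alpha: the mean
        forget-class output spike count never increases along
        alpha in {0, 0.25, 0.5, 0.75, 1} (fixed model, forget set and
        encoding)."""
        train_ds, _ = make_task(2)
        model, _ = train_canonical(build_canonical(2), train_ds, 2)
        forget = snm.make_forget_spec(train_ds, "class", 1)
        X = train_ds.features()[forget.indices]
        encs = [encode_sample(x, SIM, 500 + i) for i, x in enumerate(X[:20])]
        counts = []
        for alpha in (0.0, 0.25, 0.5, 0.75, 1.0):
            cfg = UnlearnConfig(alpha=alpha, prune_theta=np.inf, gamma=0.0, beta=0.0,
                                max_iterations=1, rng_seed=0)
            out, _ = unlearn(model, forget, train_ds, cfg)
            counts.append(np.mean([simulate(out, e, SIM).counts(-1)[1] for e in encs]))
        assert all(b <= a + 1e-9 for a, b in zip(counts, counts[1:]))

    def test_pipeline_matches_manual_phase_composition(self, tiny_trained_model):
        """One unlearning iteration equals manually composing the three phase
        operators on the same correlation/replay inputs."""
        train_ds, model = tiny_trained_model
        forget = snm.make_forget_spec(train_ds, "class", 1)
        cfg = UnlearnConfig(max_iterations=1, rng_seed=7)
        out, _ = unlearn(model, forget, train_ds, cfg)
        manual = _manual_one_iteration(model, forget, train_ds, cfg)
        for ca, cb in zip(manual.connections, out.connections):
            np.testing.assert_array_equal(ca.weights, cb.weights)
            np.testing.assert_array_equal(ca.mask, cb.mask)
        for ta, tb in zip(manual.thresholds, out.thresholds):
            np.testing.assert_array_equal(ta, tb)


def _forget_inputs(model, forget, dataset, cfg):
    X, y = dataset.features(), dataset.labels
    Xf, yf = X[forget.indices], y[forget.indices]
    ss = np.random.SeedSequence(cfg.rng_seed)
    enc_children = ss.spawn(len(yf))
    encs = [encode_sample(Xf[i], model.sim, enc_children[i]) for i in range(len(yf))]
    d = np.mean([e.layers[0].mean(axis=0) for e in encs], axis=0)
    return encs, yf, d


def _recompute_selection(model, forget, dataset, cfg):
    from snm.unlearning import _replay_dw

    encs, yf, d = _forget_inputs(model, forget, dataset, cfg)
    model = model.copy()
    recs = [simulate(model, e, model.sim) for e in encs]
    profs = [correlation_scores(r, d, model.sim.dt) for r in recs]
    corr = CorrelationProfile(
        [np.mean([p.values[l] for p in profs], axis=0) for l in range(model.n_layers)]
    )
    dW = _replay_dw(model, encs, yf, snm.TrainConfig().stdp, model.sim)
    return select_targets(corr, dW, cfg, masks=[c.mask for c in model.connections])


def _manual_one_iteration(model, forget, dataset, cfg):
    """Compose phases 1-3 by hand with the public operators."""
    from snm.unlearning import _replay_dw

    encs, yf, d = _forget_inputs(model, forget, dataset, cfg)
    model = model.copy()
    recs = [simulate(model, e, model.sim) for e in encs]
    profs = [correlation_scores(r, d, model.sim.dt) for r in recs]
    corr = CorrelationProfile(
        [np.mean([p.values[l] for p in profs], axis=0) for l in range(model.n_layers)]
    )
    dW = _replay_dw(model, encs, yf, snm.TrainConfig().stdp, model.sim)
    sel = select_targets(corr, dW, cfg, masks=[c.mask for c in model.connections])
    # phase 1: selective retraining
    for k, conn in enumerate(model.connections):
        model.connections[k] = selective_retrain(conn, dW[k], cfg.alpha, sel.synapses[k])
    # phase 2: pruning within the selection
    sel_dw = np.concatenate([np.abs(dW[k][sel.synapses[k]]).ravel() for k in range(len(dW))])
    theta = float(np.percentile(sel_dw, cfg.prune_percentile)) if sel_dw.size else np.inf
    for k, conn in enumerate(model.connections):
        pm = (prune_mask(dW[k], theta) != 0) & sel.synapses[k]
        model.connections[k] = apply_prune(conn, pm.astype(np.uint8))
    # phase 3: thresholds via the scalar operator on aggregate responses
    floor = model.reset_floor()
    for l in range(1, model.n_layers):
        s_total = np.sum([r.layers[l].astype(float) for r in recs], axis=0)
        th = model.thresholds[l - 1].copy()
        for i in np.flatnonzero(sel.neurons[l]):
            new = threshold_update(th[i], s_total[i], None, cfg.gamma, cfg.beta, model.sim.dt)
            th[i] = max(new, floor)
        model.thresholds[l - 1] = th
    return model


class TestVerifyUnlearning:
    def test_identical_models_give_zero_deltas(self, tiny_trained_model):
        train_ds, model = tiny_trained_model
        rep = verify_unlearning(model, model, train_ds, train_ds, rng_seed=0)
        assert rep["forget_recall_delta"] == 0.0
        assert rep["retain_accuracy_delta"] == 0.0
        assert rep["forget_true_score_delta"] == 0.0

    def test_silenced_output_yields_zero_forget_recall(self, tiny_trained_model):
        train_ds, model = tiny_trained_model
        dead = model.copy()
        for th in dead.thresholds:
            th[:] = 1e9
        forget_ds = train_ds.subset(np.flatnonzero(train_ds.labels == 1))
        retain_ds = train_ds.subset(np.flatnonzero(train_ds.labels == 0))
        rep = verify_unlearning(model, dead, forget_ds, retain_ds, rng_seed=0)
        assert rep["forget_recall_after"] == 0.0

    def test_consistent_with_confusion_metrics(self, tiny_trained_model):
        from snm.network import evaluate_dataset

        train_ds, model = tiny_trained_model
        forget_ds = train_ds.subset(np.flatnonzero(train_ds.labels == 1))
        retain_ds = train_ds.subset(np.flatnonzero(train_ds.labels == 0))
        rep = verify_unlearning(model, model, forget_ds, retain_ds, rng_seed=3)
        preds, _ = evaluate_dataset(model, forget_ds.features(), rng_seed=3)
        assert rep["forget_recall_before"] == pytest.approx(
            float(np.mean(preds == forget_ds.labels))
        )
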