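import numpy as np
import pytest

from histadapt import (DomainCase, HistAlignConfig, TrainConfig, build_network,
                       build_training_set, normalize_intensity, tiny_spec,
                       train_cascaded, train_initial)
from histadapt.training import TrainingSet, adapt_transductive


def separable_training_set(rng, n_per_class=60, size=7, k=2):
    """Two constant-intensity patch classes — linearly separable."""
    patches, priors, labels = [], [], []
    for c, level in enumerate((-1.0, 1.0)):
        p = np.full((n_per_class, 3, size, size), level, dtype=np.float32)
        p += rng.normal(0, 0.05, size=p.shape).astype(np.float32)
        patches.append(p)
        onehot = np.zeros((n_per_class, k), dtype=np.float32)
        onehot[:, c] = 1.0
        priors.append(onehot)
        labels.append(np.full(n_per_class, c, dtype=np.int64))
    return TrainingSet(patches=np.concatenate(patches),
                       priors=np.concatenate(priors),
                       labels=np.concatenate(labels))


def _tiny_config(**kw):
    defaults = dict(batch_size=32, max_epochs=20, patience=10,
                    learning_rate=1e-2, seed=0)
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestTrainInitial:
    def test_separable_classes_learned_quickly(self, rng):
        ts = separable_training_set(rng)
        net = build_network(tiny_spec(prior_units=2, out_classes=2, patch_size=7), seed=0)
        net, state = train_initial(net, ts, _tiny_config())
        assert state.best_val_accuracy >= 0.95
        assert state.epoch <= 20

    def test_early_stop_epoch_is_best_plus_patience(self, rng):
        ts = separable_training_set(rng)
        net = build_network(tiny_spec(prior_units=2, out_classes=2, patch_size=7), seed=0)
        net, state = train_initial(net, ts, _tiny_config(max_epochs=30, patience=4))
        if state.epoch < 30:  # early stopping triggered
            assert state.epoch == state.best_epoch + 4
        assert state.epochs_since_best <= 4

    def test_deterministic_history(self, rng):
        ts = separable_training_set(rng)
        spec = tiny_spec(prior_units=2, out_classes=2, patch_size=7)
        runs = []
        for _ in range(2):
            net = build_network(spec, seed=9)
            _, state = train_initial(net, ts, _tiny_config(max_epochs=5, patience=4, seed=9))
            runs.append(state.history)
        assert runs[0] == runs[1]

    def test_unlabelled_set_rejected(self, rng):
        ts = separable_training_set(rng)
        ts.labels = None
        net = build_network(tiny_spec(prior_units=2, out_classes=2, patch_size=7), seed=0)
        with pytest.raises(ValueError):
            train_initial(net, ts, _tiny_config())


class TestBuildTrainingSet:
    def test_structure_set_contains_all_positives(self, structure_phantom):
        vol, labels, atlas = structure_phantom
        ts = build_training_set(vol, labels, atlas, task="structures", patch_size=9)
        n_pos = int((labels.data > 0).sum())
        assert (ts.labels > 0).sum() == n_pos
        assert (ts.labels == 0).sum() > 0

    def test_sample_cap_preserves_positives(self, structure_phantom):
        vol, labels, atlas = structure_phantom
        n_pos = int((labels.data > 0).sum())
        ts = build_training_set(vol, labels, atlas, task="structures", patch_size=9,
                                max_samples=n_pos + 50, seed=1)
        assert len(ts) == n_pos + 50
        assert (ts.labels > 0).sum() == n_pos

    def test_lesion_set_balanced(self, lesion_phantom):
        vol, labels, atlas = lesion_phantom
        ts = build_training_set(vol, labels, atlas, task="lesions", patch_size=9)
        assert (ts.labels == 1).sum() == (ts.labels == 0).sum()

    def test_unlabelled_target_set_has_no_labels(self, structure_phantom):
        vol, _, atlas = structure_phantom
        ts = build_training_set(vol, None, atlas, task="structures", patch_size=9)
        assert ts.labels is None
        assert len(ts) > 0


class TestCascade:
    def test_two_stage_training_produces_working_segmenter(self, lesion_phantom):
        vol, labels, atlas = lesion_phantom
        spec = tiny_spec(prior_units=3, out_classes=2, patch_size=9)
        config = _tiny_config(max_epochs=8, patience=6, batch_size=32, seed=2)
        net1, net2, state2 = train_cascaded(spec, vol, labels, atlas, config,
                                            max_samples=600)
        assert net1 is not net2
        assert state2.epoch >= 1
        # the stage-2 deliverable still classifies lesion voxels on its own image
        from histadapt import segment_volume
        norm = normalize_intensity(vol)
        result = segment_volume(net2, norm, atlas, mode="lesions", threshold=0.5)
        assert result.labels.data.shape == vol.shape


class TestAdaptTransductive:
    def _cases(self, structure_phantom):
        vol, labels, atlas = structure_phantom
        source = DomainCase(volume=vol, priors=atlas, labels=labels)
        target = DomainCase(volume=vol, priors=atlas, labels=None,
                            hidden_labels=labels)
        return source, target

    def _pretrained(self, structure_phantom, seed=4):
        vol, labels, atlas = structure_phantom
        spec = tiny_spec(prior_units=atlas.n_classes, out_classes=labels.class_count,
                         patch_size=9)
        ts = build_training_set(vol, labels, atlas, task="structures", patch_size=9,
                                max_samples=400, seed=seed)
        net = build_network(spec, seed=seed)
        net, _ = train_initial(net, ts, _tiny_config(max_epochs=3, patience=2, seed=seed))
        return net

    def test_target_labels_are_rejected(self, structure_phantom):
        source, _ = self._cases(structure_phantom)
        net = self._pretrained(structure_phantom)
        config = _tiny_config(max_epochs=2, patience=1)
        with pytest.raises(ValueError):
            adapt_transductive(net, source, source, HistAlignConfig(), config)

    def test_lambda_zero_target_has_no_effect(self, structure_phantom, rng):
        # with the histogram loss disabled, two different target volumes must
        # produce bitwise-identical adapted weights (source-only fine-tuning)
        vol, labels, atlas = structure_phantom
        source = DomainCase(volume=vol, priors=atlas, labels=labels)
        from histadapt import Volume
        other = Volume(data=(vol.data * 1.7 + rng.normal(size=vol.shape)
                             ).astype(np.float32), spacing=vol.spacing)
        t1 = DomainCase(volume=vol, priors=atlas)
        t2 = DomainCase(volume=other, priors=atlas)
        align = HistAlignConfig(lambda_weight=0.0)
        config = _tiny_config(max_epochs=2, patience=1, seed=5)
        results = []
        for tgt in (t1, t2):
            net = self._pretrained(structure_phantom, seed=4)
            net, _, log = adapt_transductive(net, source, tgt, align, config,
                                             max_samples=300)
            results.append(net.state_dict())
            assert all(row.hist == 0.0 for row in log)
        for k in results[0]:
            np.testing.assert_array_equal(results[0][k], results[1][k])

    def test_adaptation_is_deterministic(self, structure_phantom):
        source, target = self._cases(structure_phantom)
        align = HistAlignConfig()
        config = _tiny_config(max_epochs=2, patience=1, seed=6)
        states = []
        for _ in range(2):
            net = self._pretrained(structure_phantom, seed=4)
            net, _, _ = adapt_transductive(net, source, target, align, config,
                                           max_samples=300)
            states.append(net.state_dict())
        for k in states[0]:
            np.testing.assert_array_equal(states[0][k], states[1][k])

    def test_loss_breakdown_identity(self, structure_phantom):
        source, target = self._cases(structure_phantom)
        net = self._pretrained(structure_phantom)
        align = HistAlignConfig(lambda_weight=0.7)
        config = _tiny_config(max_epochs=2, patience=1, seed=7)
        _, _, log = adapt_transductive(net, source, target, align, config,
                                       max_samples=300)
        assert len(log) > 0
        for row in log:
            assert row.total == pytest.approx(row.ce + 0.7 * row.hist, abs=1e-6)
            assert row.hist == pytest.approx(sum(row.per_layer_hist.values()), abs=1e-6)
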