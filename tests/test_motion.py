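"""Motion-state recognition: features, training contracts, evaluation."""

import numpy as np
import pytest

import pentacardio as pc
from pentacardio.layout import ChannelLayout
from pentacardio.recording import Segment
from pentacardio.seqmodel import (
    _summary_features,
    evaluate_classifier,
    prepare_sequence,
    preset,
    train_sequence_classifier,
)


def _segment_from(data, layout=None):
    layout = layout or ChannelLayout()
    return Segment(data=data, start_time=0.0, sampling_rate=200.0, layout=layout)


class TestPrepareSequence:
    def test_pooling_40_gives_50_timestamps(self):
        seg = _segment_from(np.random.default_rng(0).standard_normal((31, 2000)))
        X = prepare_sequence(seg, pooling_factor=40)
        assert X.shape[0] == 50

    def test_pooling_10_gives_200_timestamps(self):
        seg = _segment_from(np.zeros((31, 2000)))
        assert prepare_sequence(seg, pooling_factor=10).shape[0] == 200

    def test_all_zero_segment_gives_all_zero_features(self):
        seg = _segment_from(np.zeros((31, 2000)))
        np.testing.assert_array_equal(prepare_sequence(seg), 0.0)

    def test_feature_width_is_four_stats_per_channel(self):
        seg = _segment_from(np.zeros((31, 2000)))
        X = prepare_sequence(seg, channels=["Pad5.Acc.Z", "ECG"], pooling_factor=10)
        assert X.shape == (200, 8)

    def test_missing_channels_rejected(self):
        seg = _segment_from(np.zeros((31, 2000)))
        with pytest.raises(KeyError):
            prepare_sequence(seg, channels=["Pad9.Acc.Z"])

    def test_summary_features_translation_consistent(self):
        """Shifting a periodic artifact by one period barely moves features."""
        fs, f0 = 200.0, 2.0
        t = np.arange(2000) / fs
        period = int(fs / f0)
        x = np.sin(2 * np.pi * f0 * t) + 0.3 * np.sin(2 * np.pi * 3 * f0 * t)
        data = np.tile(x, (31, 1))
        shifted = np.tile(np.roll(x, period), (31, 1))
        a = _summary_features(prepare_sequence(_segment_from(data))[None])[0]
        b = _summary_features(prepare_sequence(_segment_from(shifted))[None])[0]
        denom = np.abs(a).max()
        assert np.abs(a - b).max() / denom < 0.01


class TestTrainingContracts:
    def test_probabilities_valid_and_argmax_state(self, tiny_motion_dataset, tiny_config):
        ds = tiny_motion_dataset
        model = pc.train_motion_classifier(
            ds.train_segments, ds.train_labels, "transformer", tiny_config, seed=1
        )
        probs = pc.classify_motion(model, ds.test_segments[0])
        assert probs.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(probs.probabilities >= 0)
        assert probs.argmax_state in pc.MOTION_STATES

    def test_training_loss_non_increasing_at_checkpoints(
        self, tiny_motion_dataset, tiny_config
    ):
        ds = tiny_motion_dataset
        model = pc.train_motion_classifier(
            ds.train_segments, ds.train_labels, "transformer", tiny_config, seed=2
        )
        losses = [l for _, l in model.training_log["checkpoints"]]
        assert losses[-1] < losses[0]

    def test_same_seed_gives_identical_predictions(self, tiny_motion_dataset, tiny_config):
        ds = tiny_motion_dataset
        runs = []
        for _ in range(2):
            m = pc.train_motion_classifier(
                ds.train_segments, ds.train_labels, "transformer", tiny_config, seed=3
            )
            runs.append(m.predict_proba(ds.test_segments))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_stateless_inference(self, tiny_motion_dataset, tiny_config):
        ds = tiny_motion_dataset
        m = pc.train_motion_classifier(
            ds.train_segments, ds.train_labels, "transformer", tiny_config, seed=4
        )
        seg = ds.test_segments[0]
        a = pc.classify_motion(m, seg).probabilities
        b = pc.classify_motion(m, seg).probabilities
        np.testing.assert_array_equal(a, b)

    def test_single_class_dataset_rejected(self, tiny_motion_dataset, tiny_config):
        ds = tiny_motion_dataset
        segs = [s for s, l in zip(ds.train_segments, ds.train_labels) if l == "sitting"]
        with pytest.raises(ValueError):
            pc.train_motion_classifier(segs, ["sitting"] * len(segs), "transformer", tiny_config)

    def test_baseline_kinds_train_and_predict(self, tiny_motion_dataset):
        ds = tiny_motion_dataset
        for kind in ("decision_tree", "random_forest"):
            m = pc.train_motion_classifier(ds.train_segments, ds.train_labels, kind, seed=5)
            res = evaluate_classifier(m, ds.test_segments, ds.test_labels)
            assert res["macro_f1"] > 0.5


class TestEvaluation:
    def _perfect_fixture(self):
        """A labeled fixture plus a mock classifier with known predictions."""
        rng = np.random.default_rng(0)
        layout = ChannelLayout()
        segs, labels = [], []
        for i, state in enumerate(pc.MOTION_STATES):
            for _ in range(5):
                data = rng.standard_normal((31, 200))
                segs.append(_segment_from(data, layout))
                labels.append(state)
        return segs, labels

    def test_perfect_predictions_give_identity_confusion_and_f1_one(self, monkeypatch):
        segs, labels = self._perfect_fixture()
        model = _mock_model(labels)
        res = evaluate_classifier(model, segs, labels)
        cm = res["confusion_matrix"]
        assert np.all(cm == np.diag([5, 5, 5, 5]))
        assert res["macro_f1"] == pytest.approx(1.0)

    def test_constant_predictor_on_balanced_data_has_quarter_accuracy(self):
        segs, labels = self._perfect_fixture()
        model = _mock_model(["sitting"] * len(labels))
        res = evaluate_classifier(model, segs, labels)
        assert res["accuracy"] == pytest.approx(0.25)

    def test_macro_f1_matches_brute_force(self):
        segs, labels = self._perfect_fixture()
        rng = np.random.default_rng(3)
        preds = [pc.MOTION_STATES[i] for i in rng.integers(0, 4, len(labels))]
        model = _mock_model(preds)
        res = evaluate_classifier(model, segs, labels)
        # brute-force per-class F1
        f1s = []
        for c in pc.MOTION_STATES:
            tp = sum(1 for t, p in zip(labels, preds) if t == c and p == c)
            fp = sum(1 for t, p in zip(labels, preds) if t != c and p == c)
            fn = sum(1 for t, p in zip(labels, preds) if t == c and p != c)
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        assert res["macro_f1"] == pytest.approx(np.mean(f1s))

    def test_confusion_rows_sum_to_support(self, tiny_motion_dataset, tiny_config):
        ds = tiny_motion_dataset
        m = pc.train_motion_classifier(
            ds.train_segments, ds.train_labels, "decision_tree", seed=6
        )
        res = evaluate_classifier(m, ds.test_segments, ds.test_labels)
        for i, c in enumerate(res["classes"]):
            assert res["confusion_matrix"][i].sum() == ds.test_labels.count(c)

    def test_empty_dataset_rejected(self, tiny_motion_dataset, tiny_config):
        model = _mock_model(["sitting"])
        with pytest.raises(ValueError):
            evaluate_classifier(model, [], [])


def _mock_model(predictions):
    """A FittedSequenceClassifier stand-in emitting fixed one-hot outputs."""

    class Mock:
        classes = list(pc.MOTION_STATES)

        def predict_proba(self, segments):
            out = np.full((len(segments), 4), 1e-9)
            for i, p in enumerate(predictions[: len(segments)]):
                out[i, self.classes.index(p)] = 1.0
            return out / out.sum(1, keepdims=True)

    return Mock()
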