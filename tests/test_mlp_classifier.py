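import numpy as np
import pytest

import sagbin as sb
from sagbin.io_formats import SeqRecord
from sagbin.mlp_classifier import (
    Hyperparameters,
    MLPModel,
    assign_reads,
    calibrate_threshold,
    loss_and_grads,
    predict,
    predict_batch,
    segments_to_xy,
    train_mlp,
)


def nearest_centroid_accuracy(X, y):
    """Independent oracle: classify by nearest class-mean vector."""
    classes = sorted(set(y))
    cents = {c: X[[i for i, l in enumerate(y) if l == c]].mean(axis=0) for c in classes}
    pred = [
        min(classes, key=lambda c: np.linalg.norm(x - cents[c])) for x in X
    ]
    return np.mean([p == t for p, t in zip(pred, y)])


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 6))
        Y = np.eye(3)[rng.integers(0, 3, 5)]
        params = {
            "W1": rng.normal(scale=0.5, size=(6, 4)),
            "b1": rng.normal(scale=0.5, size=4),
            "W2": rng.normal(scale=0.5, size=(4, 3)),
            "b2": rng.normal(scale=0.5, size=3),
        }
        _, grads = loss_and_grads(params, X, Y)
        eps = 1e-6
        for key in params:
            flat = params[key].ravel()
            for idx in range(flat.size):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = loss_and_grads(params, X, Y)
                flat[idx] = orig - eps
                lm, _ = loss_and_grads(params, X, Y)
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[key].ravel()[idx]
                denom = max(abs(numeric), abs(analytic), 1e-8)
                assert abs(numeric - analytic) / denom < 1e-5


class TestTraining:
    def test_separable_data_reaches_full_training_accuracy(self, separable_setup):
        s = separable_setup
        # oracle confirms the setup is linearly separable before asking the MLP
        assert nearest_centroid_accuracy(s["X"], s["y"]) == 1.0
        preds = predict_batch(s["model"], s["X"], [str(i) for i in range(len(s["y"]))])
        acc = np.mean([p.top_label == t for p, t in zip(preds, s["y"])])
        assert acc == 1.0
        assert s["model"].training_log[-1] <= s["model"].training_log[0]

    def test_deterministic_weights_for_fixed_seed(self, separable_setup):
        s = separable_setup
        m2 = train_mlp(s["X"], s["y"], Hyperparameters(seed=s["seed"]))
        np.testing.assert_array_equal(s["model"].W1, m2.W1)
        np.testing.assert_array_equal(s["model"].W2, m2.W2)

    def test_shuffled_labels_give_chance_holdout_accuracy(self, separable_setup):
        s = separable_setup
        rng = np.random.default_rng(13)
        y_shuf = list(rng.permutation(s["y"]))
        n = len(y_shuf)
        train_idx = rng.choice(n, size=n // 2, replace=False)
        hold_idx = np.setdiff1d(np.arange(n), train_idx)
        model = train_mlp(
            s["X"][train_idx], [y_shuf[i] for i in train_idx],
            Hyperparameters(seed=1),
        )
        preds = predict_batch(model, s["X"][hold_idx], [str(i) for i in hold_idx])
        acc = np.mean(
            [p.top_label == y_shuf[i] for p, i in zip(preds, hold_idx)]
        )
        m = len(hold_idx)
        sd = np.sqrt(0.5 * 0.5 / m)
        assert abs(acc - 0.5) < 3 * sd

    def test_single_class_refused(self):
        X = np.random.default_rng(0).random((20, 64))
        with pytest.raises(ValueError, match="2 classes"):
            train_mlp(X, ["only"] * 20)

    def test_thin_class_refused(self):
        X = np.random.default_rng(0).random((15, 64))
        with pytest.raises(ValueError, match="fewer than 10"):
            train_mlp(X, ["a"] * 10 + ["b"] * 5)

    def test_json_round_trip(self, separable_setup, tmp_path):
        model = separable_setup["model"]
        path = tmp_path / "model.json"
        model.to_json(path)
        back = MLPModel.from_json(path)
        np.testing.assert_array_equal(model.W1, back.W1)
        assert back.class_labels == model.class_labels
        x = separable_setup["X"][0]
        assert predict(back, x).confidence == pytest.approx(
            predict(model, x).confidence
        )

    def test_feature_convention_guard(self, separable_setup):
        model = separable_setup["model"]
        with pytest.raises(ValueError, match="convention"):
            model.check_convention({"k": 4, "strand_symmetric": True})


class TestPrediction:
    def test_posteriors_sum_to_one(self, separable_setup):
        rng = np.random.default_rng(3)
        X = rng.dirichlet(np.ones(64), size=20)
        P = np.stack(
            [p.posteriors for p in predict_batch(separable_setup["model"], X,
                                                 [str(i) for i in range(20)])]
        )
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((P >= 0) & (P <= 1))

    def test_class_mean_vector_predicted_as_its_class(self, separable_setup):
        s = separable_setup
        for label in s["model"].class_labels:
            mean_vec = s["X"][[i for i, l in enumerate(s["y"]) if l == label]].mean(0)
            assert predict(s["model"], mean_vec).top_label == label

    def test_confidence_bounded_below_by_uniform(self, separable_setup):
        rng = np.random.default_rng(4)
        X = rng.dirichlet(np.ones(64), size=50)
        for p in predict_batch(separable_setup["model"], X,
                               [str(i) for i in range(50)]):
            assert 1 / separable_setup["model"].n_classes <= p.confidence <= 1.0


class TestAssignReads:
    def _reads_from(self, genome, n, length, seed):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            off = int(rng.integers(0, len(genome.seq) - length))
            out.append(SeqRecord(id=f"r{i:04d}", seq=genome.seq[off : off + length]))
        return out

    def test_strict_threshold_boundary(self, separable_setup):
        # thresholding is strictly greater-than: a read at exactly the
        # threshold stays unassigned
        model = separable_setup["model"]
        reads = self._reads_from(separable_setup["genomes"][0], 50, 400, 5)
        assigned, unassigned = assign_reads(model, reads, threshold=0.9)
        confidences = {rid: p.confidence for rid, p in assigned.items()}
        assert all(c > 0.9 for c in confidences.values())
        # re-assign using one observed confidence as the threshold: that read
        # must drop out
        if confidences:
            rid, c = min(confidences.items(), key=lambda kv: kv[1])
            a2, u2 = assign_reads(model, reads, threshold=c)
            assert rid not in a2 and rid in u2

    def test_threshold_one_assigns_nothing_without_certainty(self, separable_setup):
        reads = self._reads_from(separable_setup["genomes"][0], 30, 400, 6)
        assigned, unassigned = assign_reads(
            separable_setup["model"], reads, threshold=1.0
        )
        for rid, p in assigned.items():
            assert p.confidence == 1.0

    def test_no_signal_reads_reported_unassignable(self, separable_setup):
        reads = [SeqRecord(id="nn", seq="NNNNNNNN"), SeqRecord(id="ok", seq="ACGT" * 100)]
        assigned, unassigned = assign_reads(separable_setup["model"], reads)
        assert "nn" in unassigned

    def test_recall_monotone_in_threshold(self, separable_setup):
        reads = self._reads_from(separable_setup["genomes"][0], 300, 400, 7)
        sizes = [
            len(assign_reads(separable_setup["model"], reads, threshold=t)[0])
            for t in (0.5, 0.9, 0.99)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestCalibration:
    def _holdout(self, setup, n_per=80, decoy_jsd=0.4, seed=21):
        """Separable holdout: true-class segment vectors plus decoy vectors
        drawn from a strongly divergent third population."""
        from sagbin.synthetic_community import (
            PopulationSpec, design_populations, generate_genome,
        )
        from sagbin.trimer_features import clip_segments

        X_true, y_true = setup["X"], setup["y"]
        decoy_t = design_populations(2, decoy_jsd, seed=seed)[1]
        decoy_g = generate_genome(
            PopulationSpec(label="decoy", genome_length=200_000,
                           transition=decoy_t, seed=seed)
        )
        segs = clip_segments([decoy_g], labels="decoy")[:n_per]
        Xd = np.stack([s.vector.freqs for s in segs])
        X = np.vstack([X_true, Xd])
        y = list(y_true) + ["decoy"] * len(Xd)
        return X, y

    def test_separable_holdout_reaches_perfect_j(self, separable_setup):
        X, y = self._holdout(separable_setup)
        cal = calibrate_threshold(separable_setup["model"], X, y)
        i = np.where(cal.thresholds == cal.chosen_threshold)[0][0]
        assert cal.fpr[i] == 0.0 and cal.tpr[i] == 1.0
        assert cal.youden_j[i] == 1.0

    def test_fpr_and_tpr_non_increasing_in_threshold(self, separable_setup):
        X, y = self._holdout(separable_setup)
        cal = calibrate_threshold(separable_setup["model"], X, y)
        assert np.all(np.diff(cal.fpr) <= 1e-12)
        assert np.all(np.diff(cal.tpr) <= 1e-12)

    def test_uniform_dummy_model_has_no_usable_threshold(self):
        # a model whose posteriors are uniform never clears the grid for C>=3
        labels = ["a", "b", "c"]
        dummy = MLPModel(
            class_labels=labels,
            W1=np.zeros((64, 10)), b1=np.zeros(10),
            W2=np.zeros((10, 3)), b2=np.zeros(3),
            mu=np.zeros(64), sigma=np.ones(64),
            hyper=Hyperparameters(),
        )
        rng = np.random.default_rng(0)
        X = rng.dirichlet(np.ones(64), size=60)
        y = ["a"] * 20 + ["b"] * 20 + ["decoy"] * 20
        cal = calibrate_threshold(dummy, X, y)
        np.testing.assert_allclose(cal.youden_j, 0.0, atol=1e-12)

    def test_no_decoys_refused(self, separable_setup):
        s = separable_setup
        with pytest.raises(ValueError, match="decoy"):
            calibrate_threshold(s["model"], s["X"], s["y"])
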