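"""Run normalization, block extraction, the SVM voting decoder, and LORO CV."""

import numpy as np
import pytest

import scenesim as ss
from scenesim import decoding
from scenesim.decoding import BlockSample
from conftest import make_config


def toy_run(data, onsets=(12.0,), labels=("beach",), tr=2.0, duration=16.0):
    return ss.ScanRun(
        data=data, tr=tr,
        onsets=np.asarray(onsets, dtype=float),
        durations=np.full(len(onsets), duration),
        labels=list(labels),
    )


class TestNormalizeRun:
    def test_constant_series_becomes_one(self):
        run = toy_run(np.full((40, 3), 5.0))
        normed = ss.normalize_run(run)
        assert np.allclose(normed.data, 1.0)

    def test_every_voxel_mean_is_one_afterwards(self, rng):
        run = toy_run(rng.random((40, 6)) + 1.0)
        normed = ss.normalize_run(run)
        assert np.allclose(normed.data.mean(axis=0), 1.0)

    def test_idempotent_on_normalized_input(self, rng):
        run = toy_run(rng.random((40, 6)) + 1.0)
        once = ss.normalize_run(run)
        twice = ss.normalize_run(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_zero_mean_voxel_becomes_constant_one(self, rng):
        data = rng.random((40, 3)) + 1.0
        data[:, 1] = np.tile([1.0, -1.0], 20)  # temporal mean exactly zero
        normed = ss.normalize_run(toy_run(data))
        assert np.allclose(normed.data[:, 1], 1.0)


class TestExtractBlockSamples:
    def test_shifted_window_indices(self, rng):
        """Block onset 12 s, TR 2 s, shift 4 s -> volumes 8..15."""
        data = np.arange(96)[:, None] * np.ones((1, 2))
        run = toy_run(data, onsets=(12.0,))
        (sample,) = ss.extract_block_samples(run, shift_seconds=4.0)
        assert np.array_equal(sample.volumes[:, 0], np.arange(8, 16))
        assert sample.volumes.shape == (8, 2)

    def test_zero_shift_at_run_start(self, rng):
        data = np.arange(96)[:, None] * np.ones((1, 2))
        run = toy_run(data, onsets=(0.0,))
        (sample,) = ss.extract_block_samples(run, shift_seconds=0.0)
        assert np.array_equal(sample.volumes[:, 0], np.arange(0, 8))

    def test_simulated_run_yields_six_samples_of_eight(self, block_runs_factory):
        (run,) = block_runs_factory(n_runs=1)
        samples = ss.extract_block_samples(run)
        assert len(samples) == 6
        assert all(s.volumes.shape[0] == 8 for s in samples)
        assert sorted(s.label for s in samples) == sorted(ss.CATEGORY_NAMES)

    def test_non_integer_shift_rejected(self, block_runs_factory):
        (run,) = block_runs_factory(n_runs=1)
        with pytest.raises(ValueError):
            ss.extract_block_samples(run, shift_seconds=3.0)

    def test_window_past_run_end_names_block(self):
        run = toy_run(np.zeros((10, 2)), onsets=(12.0,))
        with pytest.raises(ValueError, match="onset 12"):
            ss.extract_block_samples(run, shift_seconds=4.0)


class TestClassifierAndVoting:
    def two_cloud_problem(self, rng):
        a = rng.normal(0, 0.1, size=(40, 5)) + np.array([10, 0, 0, 0, 0])
        b = rng.normal(0, 0.1, size=(40, 5)) - np.array([10, 0, 0, 0, 0])
        X = np.vstack([a, b])
        y = ["beach"] * 40 + ["forest"] * 40
        return X, y

    def test_separable_clouds_fit_perfectly(self, rng):
        X, y = self.two_cloud_problem(rng)
        clf = ss.train_category_classifier(X, y)
        assert (clf.predict(X) == np.array(y)).all()

    def test_duplicated_training_set_same_predictions(self, rng):
        X, y = self.two_cloud_problem(rng)
        clf1 = ss.train_category_classifier(X, y)
        clf2 = ss.train_category_classifier(np.vstack([X, X]), y + y)
        assert (clf1.predict(X) == clf2.predict(X)).all()

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            ss.train_category_classifier(rng.random((10, 3)), ["beach"] * 10)

    def test_strict_majority_wins(self, rng):
        X, y = self.two_cloud_problem(rng)
        clf = ss.train_category_classifier(X, y)
        # 5 volumes deep in class beach, 3 in forest -> beach by majority
        vols = np.vstack([X[:5], X[40:43]])
        block = BlockSample(vols, label="beach", run_id=0)
        assert ss.predict_block(clf, block) == "beach"

    def test_majority_ignores_decision_values(self, rng):
        """With a strict majority the decision values must not be consulted."""
        X, y = self.two_cloud_problem(rng)
        clf = ss.train_category_classifier(X, y)

        class CorruptedMargins:
            classes_ = clf.classes_

            def predict(self, vols):
                return clf.predict(vols)

            def decision_function(self, vols):
                # enormous margins favoring classes_[1]; must never be read
                return np.full(len(vols), 1e9)

        vols = np.vstack([X[:5], X[40:43]])  # 5 beach, 3 forest volumes
        block = BlockSample(vols, label="beach", run_id=0)
        assert ss.predict_block(CorruptedMargins(), block) == "beach"

    def test_tie_resolved_by_summed_decision_values(self):
        """A 4-4 vote goes to the category with the larger summed margin."""

        class StubClassifier:
            classes_ = np.array(["beach", "forest"])

            def predict(self, X):
                return np.array(["beach"] * 4 + ["forest"] * 4)

            def decision_function(self, X):
                # positive favors classes_[1] = forest; sum strongly positive
                return np.full(len(X), 3.0)

        block = BlockSample(np.zeros((8, 2)), label="beach", run_id=0)
        assert decoding.predict_block(StubClassifier(), block) == "forest"

    def test_exact_tie_falls_back_to_class_order(self):
        class StubClassifier:
            classes_ = np.array(["beach", "forest"])

            def predict(self, X):
                return np.array(["beach"] * 4 + ["forest"] * 4)

            def decision_function(self, X):
                return np.zeros(len(X))

        block = BlockSample(np.zeros((8, 2)), label="forest", run_id=0)
        assert decoding.predict_block(StubClassifier(), block) == "beach"


class TestLoroCrossValidation:
    def test_separable_prototypes_decode_perfectly(self, block_runs_factory, separable_prototypes):
        runs = block_runs_factory(prototypes=separable_prototypes, sigma_good=0.01,
                                  sigma_noise=0.01)
        result = ss.loro_cross_validate(runs)
        assert result.accuracy == 1.0
        assert np.array_equal(result.confusion, np.eye(6, dtype=int) * 6)

    def test_confusion_bookkeeping(self, block_runs_factory):
        result = ss.loro_cross_validate(block_runs_factory(sigma_noise=1.0))
        assert result.confusion.sum() == 36
        assert np.array_equal(result.confusion.sum(axis=1), np.full(6, 6))
        assert result.accuracy == pytest.approx(
            np.trace(result.confusion) / result.confusion.sum()
        )

    def test_identical_prototypes_decode_at_chance(self):
        """No category signal -> accuracy fluctuates around 1/6."""
        null_protos = ss.generate_prototypes(30, separation=0.0, rng_seed=0)
        accs = []
        rng = np.random.default_rng(8)
        for rep in range(8):
            config = make_config(null_protos, sigma_good=1.0, sigma_noise=1.0)
            runs = []
            for r in range(6):
                order = list(rng.permutation(ss.CATEGORY_NAMES))
                runs.append(ss.simulate_block_run(ss.BlockDesign(), config, order, rng, run_id=r))
            accs.append(ss.loro_cross_validate(runs).accuracy)
        mean = np.mean(accs)
        sem = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(mean - 1 / 6) < max(3 * sem, 0.08)

    def test_voxel_reordering_leaves_accuracy_unchanged(self, block_runs_factory):
        runs = block_runs_factory(sigma_noise=0.8, seed=5)
        perm = np.random.default_rng(0).permutation(runs[0].n_voxels)
        permuted = [
            ss.ScanRun(r.data[:, perm], r.tr, r.onsets, r.durations, r.labels,
                       r.condition, r.run_id)
            for r in runs
        ]
        a = ss.loro_cross_validate(runs)
        b = ss.loro_cross_validate(permuted)
        assert a.accuracy == b.accuracy
        assert a.predicted_labels == b.predicted_labels

    def test_inconsistent_voxel_counts_rejected(self, block_runs_factory):
        runs = block_runs_factory(n_runs=3)
        runs[1] = ss.ScanRun(runs[1].data[:, :10], runs[1].tr, runs[1].onsets,
                             runs[1].durations, runs[1].labels)
        with pytest.raises(ValueError, match="voxel"):
            ss.loro_cross_validate(runs)

    def test_beta_pattern_variant_decodes_separable_runs(self, separable_prototypes, rng):
        config = make_config(separable_prototypes, sigma_good=0.01, sigma_noise=0.01)
        patterns, labels = [], []
        for r in range(4):
            order = list(rng.permutation(np.repeat(ss.CATEGORY_NAMES, 10)))
            run = ss.simulate_event_run(ss.EventDesign(), config, order, rng, run_id=r)
            b, cats = ss.event_glm_betas(run)
            patterns.append(b)
            labels.append(cats)
        result = ss.loro_cross_validate_patterns(patterns, labels)
        assert result.accuracy == 1.0


class TestCompareConditions:
    def test_identical_samples_give_t_zero_p_one(self):
        res = ss.compare_conditions([0.3, 0.4, 0.5], [0.3, 0.4, 0.5])
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0
        assert res.degenerate

    def test_constant_nonzero_difference_flagged_infinite(self):
        res = ss.compare_conditions([0.5, 0.6, 0.7, 0.8], [0.4, 0.5, 0.6, 0.7])
        assert res.degenerate
        assert np.isinf(res.t_statistic) and res.t_statistic > 0
        assert res.p_value == 0.0

    def test_hand_computed_t_statistic(self):
        """Differences (0.1, 0.2, 0.3): mean 0.2, sd 0.1 -> t = 0.2/(0.1/sqrt(3))."""
        good = np.array([0.4, 0.6, 0.8])
        bad = np.array([0.3, 0.4, 0.5])
        res = ss.compare_conditions(good, bad)
        assert res.t_statistic == pytest.approx(3.4641016, rel=1e-6)
        assert res.df == 2

    def test_chance_test_direction(self):
        res = ss.compare_conditions([0.5, 0.55, 0.6], [0.17, 0.16, 0.17])
        t_good, p_good = res.vs_chance_good
        assert t_good > 0 and p_good < 0.01
        _, p_bad = res.vs_chance_bad
        assert p_bad > 0.1  # bad hovers at chance here

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ss.compare_conditions([0.5], [0.4])
        with pytest.raises(ValueError):
            ss.compare_conditions([0.5, 0.6], [0.4])
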