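"""Splits, stratification, voting, training determinism and leakage guards."""

import numpy as np
import pytest

from eegdecoder.io import TrialSet
from eegdecoder.loso import (
    TrainConfig,
    majority_vote,
    make_inner_folds,
    make_loso_splits,
    shuffle_subject_labels,
    train_model,
)
from eegdecoder.model import ModelConfig, build_eegdecoder


class TestLosoSplits:
    def test_36_subjects_give_36_splits_of_35(self):
        subjects = [f"s{i}" for i in range(36)]
        splits = make_loso_splits(subjects)
        assert len(splits) == 36
        assert all(len(train) == 35 for train, _ in splits)

    def test_two_subjects(self):
        assert len(make_loso_splits(["a", "b"])) == 2

    def test_test_singletons_partition_subjects(self):
        subjects = [f"s{i}" for i in range(9)]
        splits = make_loso_splits(subjects)
        held = [t for _, t in splits]
        assert sorted(held) == sorted(subjects)
        for train, test in splits:
            assert test not in train
            assert sorted(train + [test]) == sorted(subjects)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_loso_splits(["a", "a", "b"])


class TestInnerFolds:
    def _labels(self, subjects):
        return {s: ("AD", "CJD", "CNTRL")[i % 3] for i, s in enumerate(subjects)}

    def test_35_subjects_into_5_equal_folds(self):
        subjects = [f"s{i}" for i in range(35)]
        folds = make_inner_folds(subjects, self._labels(subjects), k=5,
                                 rng=np.random.default_rng(0))
        assert sorted(len(f) for f in folds) == [7, 7, 7, 7, 7]

    def test_every_subject_in_exactly_one_fold(self):
        subjects = [f"s{i}" for i in range(23)]
        folds = make_inner_folds(subjects, self._labels(subjects), k=5,
                                 rng=np.random.default_rng(1))
        flat = [s for f in folds for s in f]
        assert sorted(flat) == sorted(subjects)

    def test_single_class_spread_evenly(self):
        subjects = [f"s{i}" for i in range(12)]
        labels = {s: "AD" for s in subjects}
        folds = make_inner_folds(subjects, labels, k=5, rng=np.random.default_rng(2))
        counts = [len(f) for f in folds]
        assert max(counts) - min(counts) <= 1

    def test_class_stratification_within_one(self):
        subjects = [f"s{i}" for i in range(30)]
        labels = self._labels(subjects)
        folds = make_inner_folds(subjects, labels, k=5, rng=np.random.default_rng(3))
        for cls in ("AD", "CJD", "CNTRL"):
            per_fold = [sum(labels[s] == cls for s in f) for f in folds]
            assert max(per_fold) - min(per_fold) <= 1

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_inner_folds(["a", "b"], {"a": "AD", "b": "CJD"}, k=5,
                             rng=np.random.default_rng(0))


class TestMajorityVote:
    def test_plain_majority(self):
        labels = ["AD"] * 30 + ["CJD"] * 10
        assert majority_vote(labels) == "AD"

    def test_unanimous(self):
        assert majority_vote(["CNTRL"] * 40) == "CNTRL"

    def test_tie_broken_by_summed_scores(self):
        labels = ["AD"] * 20 + ["CJD"] * 20
        scores = np.zeros((40, 3))
        scores[:20, 0] = 12.1 / 20   # AD column sums to 12.1
        scores[20:, 1] = 11.9 / 20   # CJD column sums to 11.9
        assert majority_vote(labels, scores) == "AD"
        scores[:20, 0] = 11.9 / 20
        scores[20:, 1] = 12.1 / 20
        assert majority_vote(labels, scores) == "CJD"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestTrainConfig:
    def test_defaults_mirror_protocol(self):
        tc = TrainConfig()
        assert tc.learning_rate == 1e-3
        assert tc.weight_decay == 1e-4
        assert tc.batch_size == 64
        assert tc.max_epochs == 30
        assert tc.early_stop_patience == 10
        assert tc.inner_folds == 5
        assert tc.seed_set == (42, 99, 123, 2025, 2026)

    def test_patience_cannot_exceed_epochs(self):
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=5, early_stop_patience=10)


def _toy_sets(rng, n_per=12, t=320):
    """Two-class toy with a gross amplitude difference; tiny model input."""
    def block(subject, label, scale):
        x = (rng.standard_normal((n_per, 19, t)) * scale).astype(np.float32)
        return x, [subject] * n_per, [label] * n_per

    xa, sa, la = block("a", "AD", 0.3)
    xb, sb, lb = block("b", "CJD", 2.0)
    xc, sc, lc = block("c", "AD", 0.3)
    xd, sd, ld = block("d", "CJD", 2.0)
    train = TrialSet(np.concatenate([xa, xb]), np.array(sa + sb),
                     np.array(la + lb), 64.0)
    val = TrialSet(np.concatenate([xc, xd]), np.array(sc + sd),
                   np.array(lc + ld), 64.0)
    return train, val


SMALL_CFG = ModelConfig(input_samples=320)


class TestTraining:
    def test_separable_toy_reaches_high_accuracy(self, rng):
        train, val = _toy_sets(rng)
        tc = TrainConfig(max_epochs=8, early_stop_patience=8, batch_size=8, seed=1)
        net = build_eegdecoder(SMALL_CFG, seed=1)
        net, history = train_model(net, train, val, tc)
        assert history[-1]["best_val_acc"] >= 0.95

    def test_same_seed_identical_history(self, rng):
        train, val = _toy_sets(rng)
        tc = TrainConfig(max_epochs=3, early_stop_patience=3, batch_size=8, seed=7)
        _, h1 = train_model(build_eegdecoder(SMALL_CFG, seed=7), train, val, tc)
        _, h2 = train_model(build_eegdecoder(SMALL_CFG, seed=7), train, val, tc)
        assert [e["train_loss"] for e in h1] == [e["train_loss"] for e in h2]
        assert [e["val_acc"] for e in h1] == [e["val_acc"] for e in h2]

    def test_early_stopping_contract(self, rng):
        train, val = _toy_sets(rng)
        tc = TrainConfig(max_epochs=6, early_stop_patience=2, batch_size=8, seed=3)
        _, history = train_model(build_eegdecoder(SMALL_CFG, seed=3), train, val, tc)
        e = len(history)
        assert e <= 6
        best = history[-1]["best_epoch"]
        if e < 6:  # stopped early: patience exhausted after the best epoch
            assert e - 1 - best >= 2

    def test_overlapping_subjects_rejected(self, rng):
        train, val = _toy_sets(rng)
        bad_val = TrialSet(val.trials, np.array(["a"] * val.n_trials),
                           np.array(["AD"] * val.n_trials), 64.0)
        tc = TrainConfig(max_epochs=1, early_stop_patience=1, seed=0)
        with pytest.raises(AssertionError, match="leakage"):
            train_model(build_eegdecoder(SMALL_CFG, seed=0), train, bad_val, tc)


class TestSeedRobustness:
    def _fake_results(self, acc):
        from eegdecoder.loso import LOSOResults, LOSOResult, TrainConfig
        from eegdecoder.metrics import compute_metrics

        n = 10
        truth = ["AD"] * n
        pred = ["AD"] * int(round(acc * n)) + ["CJD"] * (n - int(round(acc * n)))
        metrics = compute_metrics(truth, pred, truth, pred)
        result = LOSOResult(folds=[], classes=("AD", "CJD", "CNTRL"),
                            architecture="eegdecoder", train_config=TrainConfig())
        return LOSOResults(experiment=None, result=result, metrics=metrics,
                           wall_seconds=0.0)

    def test_mean_and_sd_over_seeds(self):
        from eegdecoder.loso import SeedRobustness

        runs = [self._fake_results(0.9), self._fake_results(0.7)]
        sr = SeedRobustness(seeds=(42, 2025), runs=runs)
        assert sr.accuracies.tolist() == [90.0, 70.0]
        text = sr.summary()
        assert "80.00" in text  # mean
        assert "42" in text and "2025" in text


class TestResultPlot:
    def test_confusion_heatmap_renders(self, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        from eegdecoder.loso import LOSOResults, LOSOResult, TrainConfig
        from eegdecoder.metrics import compute_metrics

        y = ["AD", "CJD", "CNTRL"] * 4
        metrics = compute_metrics(y, y, y, y)
        res = LOSOResults(
            experiment=None,
            result=LOSOResult(folds=[], classes=("AD", "CJD", "CNTRL"),
                              architecture="eegdecoder", train_config=TrainConfig()),
            metrics=metrics, wall_seconds=0.0)
        ax = res.plot_confusion("subject")
        ax.figure.savefig(tmp_path / "conf.png")
        assert (tmp_path / "conf.png").stat().st_size > 0


class TestLabelShuffle:
    def test_preserves_label_multiset_and_subject_consistency(self, tiny_trialset):
        shuffled = shuffle_subject_labels(tiny_trialset, np.random.default_rng(0))
        assert sorted(shuffled.labels) == sorted(tiny_trialset.labels)
        for s in shuffled.subjects():
            labels = set(shuffled.labels[shuffled.subject_ids == s])
            assert len(labels) == 1
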