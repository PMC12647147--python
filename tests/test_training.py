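"""Splits, metrics, noise injection and the training loop contracts."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from molfuse import make_variant, synthetic
from molfuse.records import DatasetTable, make_record
from molfuse.training import (
    TrainSettings,
    UndefinedMetricError,
    batch_loss,
    enumerate_fingerprint_combinations,
    evaluate,
    inject_label_noise,
    prc_auc,
    rmse,
    roc_auc,
    split_random,
    split_scaffold,
    train,
)


def _table(smiles, labels=None, task_type="classification"):
    labels = labels if labels is not None else [0.0] * len(smiles)
    return DatasetTable([make_record(s, [y]) for s, y in zip(smiles, labels)], ["y"], task_type)


def _n_table(n):
    smiles = [f"C{'C' * (i % 7)}O" for i in range(n)]  # duplicates fine for splitting
    return DatasetTable([make_record(s, [float(i % 2)]) for i, s in enumerate(smiles)], ["y"], "classification")


class TestRandomSplit:
    def test_eight_one_one_on_hundred(self):
        split = split_random(_n_table(100), seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (80, 10, 10)

    def test_deterministic(self):
        a = split_random(_n_table(50), seed=3)
        b = split_random(_n_table(50), seed=3)
        assert a.train == b.train and a.val == b.val and a.test == b.test

    def test_different_seeds_differ(self):
        a = split_random(_n_table(100), seed=0)
        b = split_random(_n_table(100), seed=1)
        assert a.train != b.train

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_random(_n_table(2))

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(3, 200), seed=st.integers(0, 2**31 - 1))
    def test_partitions_disjoint_and_exhaustive(self, n, seed):
        split = split_random(_n_table(n), seed=seed)
        assert sorted(split.train + split.val + split.test) == list(range(n))
        # floor allocation, remainder to train
        assert len(split.val) == int(np.floor(n * 0.1))
        assert len(split.test) == int(np.floor(n * 0.1))


class TestScaffoldSplit:
    def test_scaffold_groups_never_straddle(self):
        from molfuse.training import bemis_murcko_scaffold

        smiles = (
            [f"c1ccccc1CC{'C' * i}N" for i in range(8)]   # benzene scaffold
            + [f"C1CCNCC1{'C' * i}O" for i in range(8)]   # piperidine scaffold
            + ["CCO", "CCCO", "CCN", "CCCN"]              # acyclic: empty scaffold
        )
        data = _table(smiles)
        split = split_scaffold(data, seed=0)
        part = {}
        for name, idx in (("train", split.train), ("val", split.val), ("test", split.test)):
            for i in idx:
                part[i] = name
        for scaffold in set(bemis_murcko_scaffold(s) for s in smiles):
            members = [i for i, s in enumerate(smiles) if bemis_murcko_scaffold(s) == scaffold]
            assert len({part[i] for i in members}) == 1

    def test_one_group_all_in_train(self):
        data = _table([f"c1ccccc1{'C' * i}" for i in range(6)])
        # all six share the benzene scaffold -> single group -> train
        split = split_scaffold(data, seed=0)
        assert len(split.train) == 6 and not split.val and not split.test

    def test_distinct_scaffolds_match_random_sizes(self):
        smiles = ["c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCNCC1", "c1ccsc1",
                  "C1CCOC1", "c1cc[nH]c1", "C1CC1", "C1CCC1", "C1CCCC1"]
        split = split_scaffold(_table(smiles), seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (8, 1, 1)


class TestMetrics:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_known_value(self):
        # brute force over the 4 positive-negative pairs: 3 concordant
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_all_ties_is_half(self):
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5

    def test_one_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.9], [1, 1])
        with pytest.raises(UndefinedMetricError):
            prc_auc([0.1, 0.9], [0, 0])

    @settings(max_examples=60, deadline=None)
    @given(st.integers(2, 8), st.integers(0, 2**31 - 1))
    def test_matches_pairwise_concordance_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=n)
        if len(set(labels.tolist())) < 2:
            labels[0], labels[1] = 0, 1
        scores = np.round(rng.random(n), 2)  # coarse grid to exercise ties
        concordant = half = total = 0
        for i, j in itertools.product(range(n), range(n)):
            if labels[i] == 1 and labels[j] == 0:
                total += 1
                concordant += scores[i] > scores[j]
                half += scores[i] == scores[j]
        oracle = (concordant + 0.5 * half) / total
        assert roc_auc(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_rmse_cases(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))
        assert rmse([1.5, 2.5, 3.5], [1.0, 2.0, 3.0]) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestNoiseInjection:
    def _data_split(self, n=20):
        data = _n_table(n)
        return data, split_random(data, seed=0)

    def test_rate_zero_is_noop(self):
        data, split = self._data_split()
        noisy = inject_label_noise(data, 0.0, split, seed=0)
        assert np.array_equal(noisy.targets_matrix(), data.targets_matrix())

    def test_exact_flip_count(self):
        data, split = self._data_split(10)  # train+val = 10 - 1 test = 9
        n_trainval = len(split.train) + len(split.val)
        noisy = inject_label_noise(data, 0.3, split, seed=1)
        diff = (noisy.targets_matrix() != data.targets_matrix()).sum()
        assert diff == round(0.3 * n_trainval)

    def test_test_partition_untouched(self):
        data, split = self._data_split(40)
        noisy = inject_label_noise(data, 1.0, split, seed=2)
        for i in split.test:
            assert np.array_equal(noisy.records[i].targets, data.records[i].targets)
        for i in split.train + split.val:
            assert not np.array_equal(noisy.records[i].targets, data.records[i].targets)

    def test_missing_labels_never_flipped(self):
        records = [make_record("CCO", [np.nan]), make_record("CCN", [1.0]),
                   make_record("CCC", [0.0]), make_record("CCCC", [1.0])]
        data = DatasetTable(records, ["y"], "classification")
        split = split_random(data, ratio=(1.0, 0.0, 0.0), seed=0)
        noisy = inject_label_noise(data, 1.0, split, seed=0)
        assert np.isnan(noisy.records[0].targets[0])

    def test_regression_rejected(self):
        data = _table(["CCO", "CCN", "CCC"], [1.0, 2.0, 3.0], task_type="regression")
        with pytest.raises(ValueError):
            inject_label_noise(data, 0.1, split_random(data, seed=0), seed=0)


class TestCombinationCounts:
    @pytest.mark.parametrize("k,expected", [(1, 8), (2, 28), (3, 56)])
    def test_counts(self, k, expected):
        assert len(enumerate_fingerprint_combinations(k)) == expected

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            enumerate_fingerprint_combinations(4)


class TestTrainingLoop:
    def test_deterministic_history(self, motif_dataset):
        config = make_variant("FP", task_type="classification", hidden_dim=32)
        split = split_random(motif_dataset, seed=0)
        st_ = TrainSettings(max_epochs=3)
        h1 = train(config, motif_dataset, split, st_, seed=9).history
        h2 = train(config, motif_dataset, split, st_, seed=9).history
        assert h1 == h2

    def test_constant_regression_targets_drive_rmse_to_zero(self):
        spec = synthetic.FixtureSpec(n_molecules=40, seed=3, label_mode="additive_regression")
        data = synthetic.make_dataset(spec)
        for rec in data.records:
            rec.targets = np.array([2.5])
        config = make_variant("FP", task_type="regression", hidden_dim=16)
        split = split_random(data, seed=0)
        fitted = train(config, data, split, TrainSettings(max_epochs=30, patience=30), seed=0)
        report = evaluate(fitted, data, split.test)
        assert report.mean_values["rmse"] < 0.1
        preds = fitted.predict_records([data.records[i] for i in split.test])
        assert np.allclose(preds, 2.5, atol=0.2)

    def test_all_missing_labels_contribute_no_gradient(self, motif_dataset):
        from molfuse.model import MolFuseNetwork, featurize_record

        config = make_variant("FP", task_type="classification", hidden_dim=16)
        network = MolFuseNetwork(np.random.default_rng(0), config)
        feats = [featurize_record(r, config) for r in motif_dataset.records[:6]]
        y = motif_dataset.targets_matrix()[:6]

        loss_a = batch_loss(network, feats[:4], y[:4], None, None)
        loss_a.backward()
        grads_a = [p.grad.copy() if p.grad is not None else None for p in network.parameters()]

        for p in network.parameters():
            p.grad = None
        y_extended = np.vstack([y[:4], np.full((2, 1), np.nan)])
        loss_b = batch_loss(network, feats[:6], y_extended, None, None)
        loss_b.backward()
        assert float(loss_a.data) == pytest.approx(float(loss_b.data), abs=1e-12)
        for ga, p in zip(grads_a, network.parameters()):
            if ga is not None:
                assert np.allclose(ga, p.grad, atol=1e-12)

    def test_empty_train_partition_rejected(self, motif_dataset):
        from molfuse.training import Split

        config = make_variant("FP", task_type="classification", hidden_dim=16)
        split = Split(train=[], val=[], test=list(range(len(motif_dataset))), method="random", seed=0)
        with pytest.raises(ValueError, match="train"):
            train(config, motif_dataset, split, TrainSettings(max_epochs=1), seed=0)

    def test_learnable_signal_reaches_high_auc(self, motif_dataset):
        # noiseless substructure labels are perfectly learnable from
        # fingerprints: near-perfect train ranking, high validation ranking
        config = make_variant("FP", task_type="classification", hidden_dim=32)
        split = split_random(motif_dataset, seed=1)
        fitted = train(config, motif_dataset, split,
                       TrainSettings(max_epochs=20, patience=20), seed=1)
        best = max(h["val_metric"] for h in fitted.history if h["val_metric"] is not None)
        assert best >= 0.9
        assert evaluate(fitted, motif_dataset, split.train).mean_values["roc_auc"] >= 0.99

    def test_label_noise_degrades_test_auc(self):
        # heavy label reversal in train+val must hurt clean-test ranking
        # relative to the noiseless run (mean over 5 seeds)
        from molfuse.training import run_noise_benchmark

        data = synthetic.make_dataset(
            synthetic.FixtureSpec(n_molecules=300, seed=29), embed=False
        )
        config = make_variant("FP", task_type="classification", hidden_dim=32)
        df = run_noise_benchmark(
            data, rates=[0.0, 0.45], seeds=range(5), config=config,
            settings=TrainSettings(max_epochs=15, patience=15),
        )
        means = df.groupby("rate")["roc_auc"].mean()
        assert means[0.0] > means[0.45]
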