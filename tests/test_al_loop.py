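"""Active-learning loop: bookkeeping, label hygiene, aggregation."""

import numpy as np
import pytest

from ripetap.al_loop import (ALConfig, ALResults, ActiveLearningExperiment,
                             LabelHygieneError, compare_acquisitions,
                             initialise, run_iteration, run_trial)
from ripetap.preprocess import FeatureDataset


def make_dataset(n, bins=12, seed=0):
    rng = np.random.default_rng(seed)
    labels = rng.integers(1, 5, n)
    # weak class signal so stub/real models have something to chew on
    amp = rng.normal(size=(n, bins)) + labels[:, None] * 0.1
    return FeatureDataset(amp, rng.normal(size=(n, bins)),
                          rng.normal(size=(n, 6)), labels,
                          np.array([f"f{i}" for i in range(n)]))


class StubModel:
    """Deterministic posterior keyed to a hash of the amplitude row."""

    def __init__(self, seed=0):
        self.seed = seed
        self.trained = False
        self.fit_calls = 0

    def fit(self, amplitude, phase, aux, labels, **kw):
        self.fit_calls += 1
        self.trained = True

    def predict_posterior(self, amplitude, phase, aux, *, mc_dropout=False,
                          passes=1, **kw):
        # confidence decreases with the row key -> known acquisition order
        key = np.abs(amplitude).sum(axis=1)
        top = 0.25 + 0.75 / (1.0 + key / key.max())
        rest = (1 - top) / 3
        post = np.column_stack([top, rest, rest, rest])
        if mc_dropout:
            return np.stack([post] * passes)
        return post

    def embed(self, amplitude, phase, aux, **kw):
        return amplitude


def stub_factory(seed):
    return StubModel(seed)


class TestInitialise:
    def test_sizes_and_disjointness(self, rng):
        data = make_dataset(1000)
        state = initialise(data, ALConfig(initial_labelled=30), rng)
        assert len(state.labelled_indices) == 30
        assert len(state.pool_indices) == 970
        assert np.intersect1d(state.labelled_indices,
                              state.pool_indices).size == 0

    def test_deterministic_under_seed(self):
        data = make_dataset(100)
        cfg = ALConfig(initial_labelled=10)
        a = initialise(data, cfg, np.random.default_rng(3))
        b = initialise(data, cfg, np.random.default_rng(3))
        assert np.array_equal(a.labelled_indices, b.labelled_indices)

    def test_oversized_initial_set_rejected(self, rng):
        with pytest.raises(ValueError, match="smaller than the training set"):
            initialise(make_dataset(20), ALConfig(initial_labelled=20), rng)

    def test_pool_labels_hidden(self, rng):
        data = make_dataset(50)
        state = initialise(data, ALConfig(initial_labelled=5), rng)
        with pytest.raises(LabelHygieneError):
            state.labels_for(state.pool_indices[:3])
        # labelled instances are readable
        got = state.labels_for(state.labelled_indices)
        assert got.shape == (5,)


class TestIteration:
    def test_bookkeeping_one_step(self, rng):
        data = make_dataset(1000)
        cfg = ALConfig(initial_labelled=30, batch_size=50,
                       acquisition="least_confidence")
        state = initialise(data, cfg, rng)
        state.model = StubModel()
        cont = run_iteration(state, cfg, stub_factory, make_dataset(40, seed=9),
                             rng)
        assert cont
        assert (len(state.labelled_indices), len(state.pool_indices)) \
            == (80, 920)
        assert len(state.history) == 1
        assert state.history[0].n_labelled == 80

    def test_queries_follow_stub_ranking(self, rng):
        data = make_dataset(60)
        cfg = ALConfig(initial_labelled=5, batch_size=10,
                       acquisition="least_confidence")
        state = initialise(data, cfg, rng)
        state.model = StubModel()
        amp, ph, aux = state.pool_features()
        post = state.model.predict_posterior(amp, ph, aux)
        expected_local = np.argsort(-(1 - post.max(axis=1)),
                                    kind="stable")[:10]
        expected_global = set(state.pool_indices[np.sort(expected_local)])
        run_iteration(state, cfg, stub_factory, make_dataset(20, seed=9), rng)
        queried = set(state.labelled_indices[-10:])
        assert queried == expected_global

    def test_empty_pool_stop_signal(self, rng):
        data = make_dataset(12)
        cfg = ALConfig(initial_labelled=4, batch_size=8, acquisition="random")
        state = initialise(data, cfg, rng)
        test = make_dataset(10, seed=2)
        assert run_iteration(state, cfg, stub_factory, test, rng)
        assert not run_iteration(state, cfg, stub_factory, test, rng)


class TestTrial:
    def test_budget_counts_iterations(self):
        data = make_dataset(500)
        cfg = ALConfig(initial_labelled=20, batch_size=30,
                       label_budget=20 + 3 * 30, acquisition="margin")
        state = run_trial(data, make_dataset(40, seed=1), stub_factory, cfg,
                          seed=0)
        assert len(state.history) == 3
        assert len(state.labelled_indices) == 110

    def test_conservation_and_no_repeats(self):
        data = make_dataset(300)
        cfg = ALConfig(initial_labelled=10, batch_size=40,
                       acquisition="entropy")
        state = run_trial(data, make_dataset(30, seed=1), stub_factory, cfg,
                          seed=4)
        assert len(state.pool_indices) == 0
        all_idx = state.labelled_indices
        assert len(np.unique(all_idx)) == 300

    def test_fresh_model_each_iteration(self):
        data = make_dataset(200)
        cfg = ALConfig(initial_labelled=10, batch_size=50,
                       label_budget=10 + 2 * 50, acquisition="random")
        state = run_trial(data, make_dataset(30, seed=1), stub_factory, cfg,
                          seed=0)
        # retrained from scratch: the surviving model saw exactly one fit
        assert state.model.fit_calls == 1


class TestExperiment:
    def test_aggregate_has_full_provenance(self):
        data = make_dataset(300)
        cfg = ALConfig(initial_labelled=10, batch_size=40, trials=5,
                       label_budget=10 + 2 * 40, acquisition="random")
        res = ActiveLearningExperiment(data, make_dataset(40, seed=2),
                                       stub_factory, cfg, base_seed=0).run()
        frame = res.to_frame()
        assert len(frame) == 5 * 2
        agg = res.aggregate()
        assert set(agg["metric"]) == {"accuracy", "loss", "precision",
                                      "recall"}
        assert len(agg) == 2 * 4

    def test_identical_histories_zero_std(self):
        data = make_dataset(200)
        cfg = ALConfig(initial_labelled=10, batch_size=40, trials=1,
                       label_budget=90, acquisition="margin")
        test = make_dataset(30, seed=5)
        state = run_trial(data, test, stub_factory, cfg, seed=3)
        res = ALResults("margin", [state.history, state.history])
        assert np.allclose(res.aggregate()["std"], 0.0)

    def test_same_seed_reproduces_history(self):
        data = make_dataset(200)
        cfg = ALConfig(initial_labelled=10, batch_size=40, trials=1,
                       label_budget=90, acquisition="bald", mc_passes=3)
        test = make_dataset(30, seed=5)
        h1 = run_trial(data, test, stub_factory, cfg, seed=3).history
        h2 = run_trial(data, test, stub_factory, cfg, seed=3).history
        assert [r.accuracy for r in h1] == [r.accuracy for r in h2]

    def test_kdpp_acquisition_runs(self):
        data = make_dataset(120)
        cfg = ALConfig(initial_labelled=8, batch_size=20, trials=1,
                       label_budget=8 + 20, acquisition="kdpp", kdpp_k=20)
        res = ActiveLearningExperiment(data, make_dataset(30, seed=2),
                                       stub_factory, cfg, base_seed=1).run()
        assert len(res.histories[0]) == 1


class TestComparison:
    def test_identical_configs_identical_rows(self):
        data = make_dataset(200)
        test = make_dataset(40, seed=6)
        cfg = ALConfig(initial_labelled=10, batch_size=30, trials=2,
                       label_budget=70, acquisition="margin")
        table = compare_acquisitions(data, test, stub_factory, [cfg, cfg],
                                     base_seed=2)
        assert len(table) == 2
        assert np.allclose(table.iloc[0].values, table.iloc[1].values)

    def test_mismatched_budgets_rejected(self):
        data = make_dataset(100)
        a = ALConfig(initial_labelled=10, batch_size=20, label_budget=50)
        b = ALConfig(initial_labelled=10, batch_size=20, label_budget=70)
        with pytest.raises(ValueError, match="share"):
            compare_acquisitions(data, data, stub_factory, [a, b])

    def test_metric_columns_in_range(self):
        data = make_dataset(150)
        test = make_dataset(40, seed=6)
        configs = [ALConfig(initial_labelled=10, batch_size=30, trials=1,
                            label_budget=40, acquisition=name)
                   for name in ("random", "margin")]
        table = compare_acquisitions(data, test, stub_factory, configs,
                                     base_seed=0)
        for metric in ("accuracy", "precision", "recall"):
            assert table[metric].between(0, 1).all()
        assert (table["loss"] >= 0).all()
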