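"""Pool-based active-learning cycle and experiment driver.

One trial starts from a small random labelled set L0, trains the
classifier, then repeats: score the unlabelled pool U with the chosen
acquisition, move a batch of b instances from U to L (revealing their
labels — the oracle step), retrain from a fresh initialisation and record
test metrics. Trials differ only in their seed; an experiment aggregates
the per-iteration metric curves into mean +/- std across trials.

Ground-truth labels of pool instances are held privately by the trial
state and only become visible through the oracle's ``reveal`` call, so an
acquisition function cannot peek at them even by accident.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import acquisition as acq
from .classifier import MetricsRecord, evaluate_posterior
from .kdpp import kdpp_acquire
from .preprocess import FeatureDataset

__all__ = [
    "ALConfig", "ALState", "LabelHygieneError",
    "initialise", "run_iteration", "run_trial",
    "ActiveLearningExperiment", "ALResults", "compare_acquisitions",
]

logger = logging.getLogger(__name__)

_UNCERTAINTY_SCORERS = {
    "least_confidence": acq.score_least_confidence,
    "margin": acq.score_margin,
    "entropy": acq.score_entropy,
    "ratio": acq.score_ratio,
}


@dataclass(frozen=True)
class ALConfig:
    """Protocol parameters of one active-learning experiment."""

    initial_labelled: int = 30
    batch_size: int = 50
    trials: int = 5
    label_budget: int | None = None  # max |L|; None = pool exhaustion
    acquisition: str = "margin"
    kdpp_k: int = 50
    kdpp_bandwidth: float | str = "median"
    mc_passes: int = 20
    warm_start: bool = False

    def __post_init__(self) -> None:
        if self.initial_labelled < 1 or self.batch_size < 1 or self.trials < 1:
            raise ValueError("initial_labelled, batch_size, trials must be >= 1")
        if self.label_budget is not None and self.label_budget < self.initial_labelled:
            raise ValueError("label_budget must be >= initial_labelled")
        if self.acquisition not in acq.ACQUISITION_NAMES:
            raise ValueError(f"unknown acquisition {self.acquisition!r}; "
                             f"choose from {acq.ACQUISITION_NAMES}")


class LabelHygieneError(RuntimeError):
    """Raised when pool labels are requested before the oracle reveals them."""


class ALState:
    """Evolving state of one trial: L, U, the model and metric history."""

    def __init__(self, dataset: FeatureDataset, labelled: np.ndarray,
                 pool: np.ndarray) -> None:
        self._dataset = dataset
        self.labelled_indices = np.asarray(labelled, dtype=int)
        self.pool_indices = np.asarray(pool, dtype=int)
        self.iteration = 0
        self.model = None
        self.history: list[MetricsRecord] = []

    @property
    def n_total(self) -> int:
        return len(self._dataset)

    def labelled_set(self) -> FeatureDataset:
        return self._dataset.take(self.labelled_indices)

    def pool_features(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Features of the pool — labels deliberately omitted."""
        sub = self._dataset.take(self.pool_indices)
        return sub.amplitude, sub.phase, sub.aux

    def labels_for(self, indices: np.ndarray) -> np.ndarray:
        """Labels of already-labelled instances; asking for pool labels
        violates the oracle contract and raises."""
        indices = np.asarray(indices, dtype=int)
        hidden = np.setdiff1d(indices, self.labelled_indices)
        if hidden.size:
            raise LabelHygieneError(
                f"labels of pool instances {hidden.tolist()[:5]}... are "
                "hidden until the oracle reveals them")
        return self._dataset.labels[indices]

    def reveal(self, pool_positions: np.ndarray) -> np.ndarray:
        """Oracle step: move the given pool positions into L and return
        their (now visible) labels."""
        pool_positions = np.asarray(pool_positions, dtype=int)
        if np.unique(pool_positions).size != pool_positions.size:
            raise ValueError("duplicate query positions")
        chosen = self.pool_indices[pool_positions]
        self.pool_indices = np.delete(self.pool_indices, pool_positions)
        self.labelled_indices = np.concatenate(
            [self.labelled_indices, chosen])
        return self._dataset.labels[chosen]


def initialise(dataset: FeatureDataset, config: ALConfig,
               rng: np.random.Generator) -> ALState:
    """Draw the L0 initial labelled instances uniformly at random."""
    n = len(dataset)
    if config.initial_labelled >= n:
        raise ValueError(
            f"initial_labelled={config.initial_labelled} must be smaller "
            f"than the training set ({n} instances)")
    labelled = rng.choice(n, size=config.initial_labelled, replace=False)
    pool = np.setdiff1d(np.arange(n), labelled)
    return ALState(dataset, np.sort(labelled), pool)


def _train_model(state: ALState, model_factory: Callable[[int], object],
                 config: ALConfig, rng: np.random.Generator):
    if config.warm_start and state.model is not None:
        model = state.model
    else:
        model = model_factory(int(rng.integers(2**31)))
    sub = state.labelled_set()
    model.fit(sub.amplitude, sub.phase, sub.aux, sub.labels)
    state.model = model
    return model


def _select_query(state: ALState, config: ALConfig,
                  rng: np.random.Generator, b: int) -> np.ndarray:
    """Pool positions to query, according to the configured acquisition."""
    amp, phase, aux = state.pool_features()
    name = config.acquisition
    if name == "random":
        return acq.random_select(len(state.pool_indices), b, rng)
    if name == "kdpp":
        model = state.model
        if model is not None and getattr(model, "trained", False) \
                and hasattr(model, "embed"):
            emb = model.embed(amp, phase, aux)
        else:  # first iteration / featureless model: raw spectral features
            emb = amp
        return kdpp_acquire(emb, config.kdpp_k, b, rng,
                            bandwidth=config.kdpp_bandwidth)
    if state.model is None:
        raise RuntimeError(f"{name} acquisition needs a trained model")
    if name == "bald":
        stack = state.model.predict_posterior(
            amp, phase, aux, mc_dropout=True, passes=config.mc_passes)
        scores = acq.score_bald(stack)
    else:
        posterior = state.model.predict_posterior(amp, phase, aux)
        scores = _UNCERTAINTY_SCORERS[name](posterior)
    return acq.select_batch(scores, b, rng)


def run_iteration(state: ALState, config: ALConfig,
                  model_factory: Callable[[int], object],
                  test_set: FeatureDataset, rng: np.random.Generator,
                  trial: int = 0) -> bool:
    """One query/label/retrain/evaluate cycle; returns False when the
    pool is exhausted or the budget is spent (stop signal)."""
    if len(state.pool_indices) == 0:
        return False
    budget_left = (np.inf if config.label_budget is None
                   else config.label_budget - len(state.labelled_indices))
    b = int(min(config.batch_size, len(state.pool_indices), budget_left))
    if b <= 0:
        return False
    positions = _select_query(state, config, rng, b)
    state.reveal(positions)
    state.iteration += 1
    model = _train_model(state, model_factory, config, rng)
    posterior = model.predict_posterior(test_set.amplitude, test_set.phase,
                                        test_set.aux)
    record = evaluate_posterior(posterior, test_set.labels,
                                iteration=state.iteration, trial=trial)
    record.n_labelled = len(state.labelled_indices)
    state.history.append(record)
    logger.info("trial %d iter %d: |L|=%d |U|=%d acc=%.3f loss=%.3f",
                trial, state.iteration, len(state.labelled_indices),
                len(state.pool_indices), record.accuracy, record.loss)
    return True


def run_trial(train_set: FeatureDataset, test_set: FeatureDataset,
              model_factory: Callable[[int], object], config: ALConfig,
              seed: int, trial: int = 0) -> ALState:
    """Initialise, train on L0, then iterate until budget/pool exhaustion."""
    rng = np.random.default_rng(seed)
    state = initialise(train_set, config, rng)
    _train_model(state, model_factory, config, rng)  # initial model
    while run_iteration(state, config, model_factory, test_set, rng, trial):
        pass
    return state


@dataclass
class ALResults:
    """Metric histories of all trials of one acquisition."""

    acquisition: str
    histories: list[list[MetricsRecord]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"acquisition": self.acquisition, "trial": t,
             "iteration": r.iteration, "n_labelled": r.n_labelled,
             "accuracy": r.accuracy, "loss": r.loss,
             "precision": r.precision, "recall": r.recall}
            for t, hist in enumerate(self.histories) for r in hist
        ]
        return pd.DataFrame(rows)

    def aggregate(self) -> pd.DataFrame:
        """Per-iteration mean and std of each metric across trials."""
        df = self.to_frame()
        long = df.melt(id_vars=["acquisition", "trial", "iteration"],
                       value_vars=["accuracy", "loss", "precision", "recall"],
                       var_name="metric")
        out = (long.groupby(["acquisition", "iteration", "metric"])["value"]
               .agg(mean="mean", std=lambda v: v.std(ddof=0))
               .reset_index())
        return out

    def final_metrics(self) -> pd.DataFrame:
        agg = self.aggregate()
        last = agg["iteration"].max()
        return agg[agg["iteration"] == last]

    def summary(self) -> str:
        rows = self.final_metrics()
        parts = [f"{r.metric}={r['mean']:.4f} ({r['std']:.4f})"
                 for _, r in rows.iterrows()]
        return f"{self.acquisition}: " + ", ".join(parts)


class ActiveLearningExperiment:
    """Run one acquisition over several seeded trials and aggregate."""

    def __init__(self, train_set: FeatureDataset, test_set: FeatureDataset,
                 model_factory: Callable[[int], object], config: ALConfig,
                 base_seed: int = 0) -> None:
        self.train_set = train_set
        self.test_set = test_set
        self.model_factory = model_factory
        self.config = config
        self.base_seed = base_seed

    def run(self) -> ALResults:
        histories = []
        for trial in range(self.config.trials):
            state = run_trial(self.train_set, self.test_set,
                              self.model_factory, self.config,
                              seed=self.base_seed + trial, trial=trial)
            histories.append(state.history)
        return ALResults(self.config.acquisition, histories)


def compare_acquisitions(train_set: FeatureDataset, test_set: FeatureDataset,
                         model_factory: Callable[[int], object],
                         configs: Sequence[ALConfig],
                         base_seed: int = 0) -> pd.DataFrame:
    """Last-iteration mean (std) of every metric per acquisition, one row
    each — the comparison-table view of a multi-acquisition study."""
    if len(configs) < 2:
        raise ValueError("need at least two configurations to compare")
    budgets = {(c.initial_labelled, c.batch_size, c.label_budget, c.trials)
               for c in configs}
    if len(budgets) != 1:
        raise ValueError("configurations must share L0, batch size, budget "
                         "and trial count for a fair comparison")
    rows = []
    for config in configs:
        result = ActiveLearningExperiment(
            train_set, test_set, model_factory, config, base_seed).run()
        final = result.final_metrics()
        row = {"acquisition": config.acquisition}
        for _, r in final.iterrows():
            row[r["metric"]] = r["mean"]
            row[f"{r['metric']}_std"] = r["std"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("acquisition")
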