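"""Uncertainty-based acquisition scores for pool-based active learning.

Given the classifier's posterior over classes for every pool instance,
each scorer produces one real value per instance together with the
direction in which "most worth querying" lies:

- least confidence: 1 - max_c p(c)                    (higher queried)
- margin:           p(top1) - p(top2)                 (lower queried)
- maximum entropy:  -sum_c p(c) log p(c)              (higher queried)
- ratio:            p(top2) / p(top1)                 (higher queried)
- BALD:             H(mean_t p_t) - mean_t H(p_t)     (higher queried)

BALD operates on a stack of Monte-Carlo-dropout posteriors and equals the
mutual information between the prediction and the model parameters; it is
non-negative by Jensen's inequality. All logarithms are natural — the base
only rescales the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionScores",
    "score_least_confidence", "score_margin", "score_entropy",
    "score_ratio", "score_bald", "select_batch", "random_select",
    "ACQUISITION_NAMES",
]

_CLAMP = 1e-12

ACQUISITION_NAMES = ("random", "least_confidence", "margin", "entropy",
                     "ratio", "bald", "kdpp")


@dataclass(frozen=True)
class AcquisitionScores:
    """Per-instance scores plus the query direction."""

    scores: np.ndarray
    higher_is_queried: bool
    method_name: str

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.float64)
        if scores.ndim != 1:
            raise ValueError("scores must be 1-D")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores contain non-finite values")
        object.__setattr__(self, "scores", scores)


def _check_posterior(posterior: np.ndarray) -> np.ndarray:
    p = np.asarray(posterior, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError("posterior must be (instances, classes)")
    if np.any(p < -1e-9) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("posterior rows must be probability vectors")
    return p


def _entropy(p: np.ndarray) -> np.ndarray:
    q = np.clip(p, _CLAMP, 1.0)
    return -(p * np.log(q)).sum(axis=-1)


def score_least_confidence(posterior: np.ndarray) -> AcquisitionScores:
    p = _check_posterior(posterior)
    return AcquisitionScores(1.0 - p.max(axis=1), True, "least_confidence")


def score_margin(posterior: np.ndarray) -> AcquisitionScores:
    p = _check_posterior(posterior)
    if p.shape[1] < 2:
        raise ValueError("margin needs at least two classes")
    top2 = np.sort(p, axis=1)[:, -2:]
    return AcquisitionScores(top2[:, 1] - top2[:, 0], False, "margin")


def score_entropy(posterior: np.ndarray) -> AcquisitionScores:
    p = _check_posterior(posterior)
    return AcquisitionScores(_entropy(p), True, "entropy")


def score_ratio(posterior: np.ndarray) -> AcquisitionScores:
    p = _check_posterior(posterior)
    if p.shape[1] < 2:
        raise ValueError("ratio needs at least two classes")
    top2 = np.sort(p, axis=1)[:, -2:]
    if np.any(top2[:, 1] <= 0):
        raise ValueError("degenerate posterior row with zero top probability")
    return AcquisitionScores(top2[:, 0] / top2[:, 1], True, "ratio")


def score_bald(mc_posteriors: np.ndarray) -> AcquisitionScores:
    """Mutual information from a (passes, instances, classes) stack."""
    stack = np.asarray(mc_posteriors, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("mc_posteriors must be (passes, instances, classes)")
    if stack.shape[0] < 2:
        raise ValueError("BALD needs at least 2 MC passes; the mutual "
                         "information of a single pass is degenerate")
    mean_p = stack.mean(axis=0)
    info = _entropy(mean_p) - _entropy(stack).mean(axis=0)
    return AcquisitionScores(info, True, "bald")


def select_batch(scores: AcquisitionScores, b: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Indices of the b best scores; exact ties are broken uniformly at
    random with the supplied generator."""
    n = scores.scores.size
    if not 0 < b <= n:
        raise ValueError(f"batch size {b} outside 1..{n}")
    keys = scores.scores if scores.higher_is_queried else -scores.scores
    tiebreak = rng.random(n)
    order = np.lexsort((tiebreak, -keys))
    return np.sort(order[:b])


def random_select(pool_size: int, b: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform subset without replacement — the acquisition baseline."""
    if not 0 < b <= pool_size:
        raise ValueError(f"batch size {b} outside 1..{pool_size}")
    return np.sort(rng.choice(pool_size, size=b, replace=False))
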