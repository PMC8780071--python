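"""Exact k-DPP sampling for diversity-based batch selection.

A determinantal point process over a ground set of n pool instances
assigns every subset A a probability proportional to det(K_A), the
principal minor of a positive semi-definite similarity kernel K. The
k-DPP conditions on |A| = k, which removes the DPP's implicit size
model and makes the batch size an explicit dial on diversity.

Sampling follows the classical two-phase eigendecomposition scheme:

1. choose a set J of k eigenvector indices with probability
   proportional to prod_{i in J} lambda_i, realised by a backward scan
   over the elementary symmetric polynomials e_k^N of the eigenvalues,
   where the marginal of index N is lambda_N * e_{k-1}^{N-1} / e_k^N;
2. sample k items one at a time from the span of the chosen
   eigenvectors, projecting the basis orthogonally to each selected
   item's coordinate axis so no item repeats.

A brute-force enumeration of det-normalised subset probabilities is
provided as the independent oracle for small ground sets.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PSDKernel", "ESPTable", "SubsetSample",
    "build_kernel", "elementary_symmetric",
    "sample_eigenvector_set", "sample_kdpp", "sample_kdpp_many",
    "brute_force_kdpp_pmf", "kdpp_acquire",
]

EIGENVALUE_CLAMP = 1e-9


@dataclass
class PSDKernel:
    """Symmetric PSD similarity matrix with its eigendecomposition."""

    matrix: np.ndarray
    eigenvalues: np.ndarray   # ascending order is NOT assumed; clamped >= 0
    eigenvectors: np.ndarray  # columns, orthonormal

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.sum(self.eigenvalues > EIGENVALUE_CLAMP))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "PSDKernel":
        m = np.asarray(matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("kernel must be square")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("kernel must be symmetric")
        eigenvalues, eigenvectors = np.linalg.eigh((m + m.T) / 2.0)
        if np.min(eigenvalues) < -1e-6 * max(1.0, float(np.max(np.abs(eigenvalues)))):
            raise ValueError("kernel is not positive semi-definite")
        eigenvalues = np.where(eigenvalues < EIGENVALUE_CLAMP, 0.0, eigenvalues)
        return cls(m, eigenvalues, eigenvectors)


@dataclass
class ESPTable:
    """Elementary symmetric polynomials e_k^N of a set of eigenvalues.

    ``table[k, N]`` is the sum over all k-subsets of the first N
    eigenvalues of the product of their values, built with the recurrence
    e_k^N = e_k^{N-1} + lambda_N * e_{k-1}^{N-1}.
    """

    table: np.ndarray  # (kmax+1, n+1)

    def e(self, k: int, n: int) -> float:
        if k < 0 or k > n:
            return 0.0
        return float(self.table[k, n])


@dataclass(frozen=True)
class SubsetSample:
    indices: np.ndarray
    k: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size != self.k or len(set(idx.tolist())) != self.k:
            raise ValueError("sample must contain exactly k distinct indices")
        object.__setattr__(self, "indices", idx)


def elementary_symmetric(eigenvalues: np.ndarray, kmax: int) -> ESPTable:
    lam = np.asarray(eigenvalues, dtype=np.float64)
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    n = lam.size
    table = np.zeros((kmax + 1, n + 1))
    table[0, :] = 1.0
    for N in range(1, n + 1):
        kk = min(kmax, N)
        table[1:kk + 1, N] = (table[1:kk + 1, N - 1]
                              + lam[N - 1] * table[0:kk, N - 1])
    return ESPTable(table)


def _sample_eigenvector_sets(eigenvalues: np.ndarray, k: int, n_draws: int,
                             rng: np.random.Generator) -> np.ndarray:
    """(n_draws, n) boolean masks of eigenvector sets J, each drawn with
    probability proportional to prod_{i in J} lambda_i."""
    lam = np.asarray(eigenvalues, dtype=np.float64)
    n = lam.size
    if np.sum(lam > 0) < k:
        raise ValueError(
            f"cannot pick {k} eigenvectors: only {int(np.sum(lam > 0))} "
            "positive eigenvalues")
    esp = elementary_symmetric(lam, k).table
    remaining = np.full(n_draws, k, dtype=int)
    selected = np.zeros((n_draws, n), dtype=bool)
    for N in range(n, 0, -1):
        active = remaining > 0
        if not np.any(active):
            break
        denom = esp[remaining[active], N]
        numer = lam[N - 1] * esp[remaining[active] - 1, N - 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            prob = np.where(denom > 0, numer / np.maximum(denom, 1e-300), 1.0)
        take = rng.random(active.sum()) < prob
        # must take the remaining items when only as many indices are left
        take |= remaining[active] >= N
        sel_idx = np.flatnonzero(active)[take]
        selected[sel_idx, N - 1] = True
        remaining[sel_idx] -= 1
    assert np.all(remaining == 0)
    return selected


def sample_eigenvector_set(eigenvalues: np.ndarray, k: int,
                           rng: np.random.Generator) -> np.ndarray:
    """One size-k index set J with P(J) proportional to its eigenvalue
    product; marginals follow lambda_N e_{k-1}^{N-1} / e_k^N."""
    mask = _sample_eigenvector_sets(eigenvalues, k, 1, rng)[0]
    return np.flatnonzero(mask)


def _sample_items(V: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase 2, batched: given orthonormal bases V (draws, n, k), sample k
    items per draw from the elementary DPP they span."""
    R, n, k = V.shape
    V = V.copy()
    items = np.zeros((R, k), dtype=int)
    r_idx = np.arange(R)
    for j in range(k, 0, -1):
        probs = np.einsum("rnc,rnc->rn", V[:, :, :j], V[:, :, :j]) / j
        probs = np.clip(probs, 0.0, None)
        cum = np.cumsum(probs, axis=1)
        cum /= cum[:, -1:]
        u = rng.random(R)
        chosen = (cum < u[:, None]).sum(axis=1)
        chosen = np.minimum(chosen, n - 1)
        items[:, k - j] = chosen
        if j == 1:
            break
        # move the column with the largest coordinate at the chosen item
        # to position j-1, eliminate it, and re-orthonormalise the rest
        coords = V[r_idx[:, None], chosen[:, None], np.arange(j)[None, :]]
        cstar = np.abs(coords).argmax(axis=1)
        cols_star = V[r_idx, :, cstar].copy()            # (R, n)
        V[r_idx, :, cstar] = V[:, :, j - 1]
        coords_star = cols_star[r_idx, chosen]
        coords_rest = V[r_idx[:, None], chosen[:, None], np.arange(j - 1)[None, :]]
        factor = coords_rest / coords_star[:, None]
        V[:, :, :j - 1] -= cols_star[:, :, None] * factor[:, None, :]
        Q, _ = np.linalg.qr(V[:, :, :j - 1])
        V[:, :, :j - 1] = Q
    return items


def sample_kdpp(kernel: PSDKernel, k: int,
                rng: np.random.Generator) -> SubsetSample:
    """Draw one subset of cardinality exactly k with probability
    proportional to det(K_A)."""
    return SubsetSample(sample_kdpp_many(kernel, k, 1, rng)[0], k)


def sample_kdpp_many(kernel: PSDKernel, k: int, n_draws: int,
                     rng: np.random.Generator) -> np.ndarray:
    """(n_draws, k) independent k-DPP samples; the batched equivalent of
    repeated ``sample_kdpp`` calls, used for frequency studies."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > kernel.rank:
        raise ValueError(
            f"k={k} exceeds the kernel rank {kernel.rank}: every "
            f"{k}x{k} principal minor is singular")
    masks = _sample_eigenvector_sets(kernel.eigenvalues, k, n_draws, rng)
    # gather the selected eigenvector columns per draw
    order = np.argsort(~masks, axis=1, kind="stable")[:, :k]  # indices of True
    V = kernel.eigenvectors[:, order].transpose(1, 0, 2)      # (draws, n, k)
    return _sample_items(V, rng)


def brute_force_kdpp_pmf(kernel: PSDKernel, k: int, *, guard: int = 100_000
                         ) -> dict[tuple[int, ...], float]:
    """Exact det-normalised probability of every k-subset (testing oracle).

    Refuses ground sets with more than ``guard`` subsets.
    """
    n = kernel.n
    count = math.comb(n, k)
    if count > guard:
        raise ValueError(f"C({n},{k}) = {count} subsets exceeds the "
                         f"enumeration guard of {guard}")
    dets = {}
    for subset in itertools.combinations(range(n), k):
        sub = kernel.matrix[np.ix_(subset, subset)]
        dets[subset] = max(float(np.linalg.det(sub)), 0.0)
    total = sum(dets.values())
    if total <= 0:
        raise ValueError("all k-minors vanish; k exceeds the kernel rank")
    return {s: d / total for s, d in dets.items()}


def build_kernel(embeddings: np.ndarray, bandwidth: float | str = "median"
                 ) -> PSDKernel:
    """RBF similarity kernel K_ij = exp(-||e_i - e_j||^2 / (2 sigma^2))
    over standardised embeddings; ``bandwidth='median'`` uses the median
    pairwise distance heuristic for sigma."""
    emb = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    if emb.shape[0] == 1:
        return PSDKernel.from_matrix(np.ones((1, 1)))
    std = emb.std(axis=0)
    if np.all(std < 1e-12):
        warnings.warn("zero-variance embeddings: kernel degenerates to ones",
                      stacklevel=2)
        return PSDKernel.from_matrix(np.ones((emb.shape[0], emb.shape[0])))
    emb = (emb - emb.mean(axis=0)) / np.maximum(std, 1e-12)
    sq = np.sum(emb**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * emb @ emb.T, 0.0)
    if bandwidth == "median":
        upper = d2[np.triu_indices_from(d2, k=1)]
        med = float(np.sqrt(np.median(upper))) if upper.size else 1.0
        sigma = med if med > 0 else 1.0
    else:
        sigma = float(bandwidth)
        if sigma <= 0:
            raise ValueError("bandwidth must be positive")
    K = np.exp(-d2 / (2.0 * sigma**2))
    return PSDKernel.from_matrix(K)


def kdpp_acquire(embeddings: np.ndarray, k: int, b: int,
                 rng: np.random.Generator,
                 bandwidth: float | str = "median") -> np.ndarray:
    """Select b pool indices through k-DPP draws over an RBF kernel on the
    embeddings.

    If k >= b a single draw is uniformly thinned to b indices. If k < b,
    disjoint draws are accumulated, re-sampling on the shrinking pool,
    until b indices are collected.
    """
    emb = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    n = emb.shape[0]
    if not (1 <= k and 1 <= b <= n):
        raise ValueError("need 1 <= k and 1 <= b <= pool size")
    remaining = np.arange(n)
    collected: list[np.ndarray] = []
    needed = b
    while needed > 0:
        kernel = build_kernel(emb[remaining], bandwidth)
        kk = min(k, kernel.rank, remaining.size)
        if kk < 1:
            raise ValueError("kernel rank collapsed to zero during accumulation")
        draw = sample_kdpp(kernel, kk, rng).indices
        if draw.size > needed:
            draw = rng.choice(draw, size=needed, replace=False)
        collected.append(remaining[draw])
        remaining = np.delete(remaining, draw)
        needed = b - sum(len(c) for c in collected)
    return np.sort(np.concatenate(collected))
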