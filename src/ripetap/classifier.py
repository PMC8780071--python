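"""Dual-input CNN for 4-class ripeness grading.

Amplitude and phase spectra enter as two channels of a 1-D convolutional
trunk made of four modules (batch norm, two convolutions, max pooling,
dropout p=0.005) with filter counts descending towards the output. The
flattened trunk output is concatenated with the auxiliary covariates
(weight, temperature, humidity, one-hot knock zone) and passed through a
dense head to a 4-class softmax. Training uses SGD with Nesterov momentum
0.9, learning rate 0.005 with exponential decay, global-norm gradient
clipping at 1.0 and LeakyReLU activations throughout.

Monte-Carlo dropout (dropout kept active over repeated inference passes)
provides the stochastic posteriors that the BALD acquisition needs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._layers import (
    BatchNorm1d, Conv1d, Dense, Dropout, LeakyReLU, MaxPool1d,
    SGDNesterov, cross_entropy_grad, global_norm_clip, softmax,
)

__all__ = ["ModelConfig", "CnnClassifier", "MetricsRecord", "evaluate_posterior"]

N_CLASSES = 4


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimisation hyperparameters."""

    filters: tuple[int, ...] = (64, 32, 16, 8)
    kernel_size: int = 7
    pool_size: int = 2
    dropout_p: float = 0.005
    negative_slope: float = 0.01
    hidden_units: int = 32
    learning_rate: float = 0.005
    lr_decay: float = 0.95
    momentum: float = 0.9
    nesterov: bool = True
    grad_clip_norm: float = 1.0
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.grad_clip_norm <= 0:
            raise ValueError("grad_clip_norm must be positive")
        if any(b > a for a, b in zip(self.filters, self.filters[1:])):
            raise ValueError("filters must be non-increasing towards the output")
        if len(self.filters) != 4:
            raise ValueError("the trunk uses exactly four convolutional modules")


@dataclass
class MetricsRecord:
    """Test-time metrics for one model snapshot."""

    accuracy: float
    loss: float
    precision: float
    recall: float
    iteration: int = -1
    trial: int = -1
    n_labelled: int = -1

    def __post_init__(self) -> None:
        for name in ("accuracy", "precision", "recall"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.loss < 0:
            raise ValueError("loss must be non-negative")


class CnnClassifier:
    """Four-module 1-D CNN over (amplitude, phase) with auxiliary inputs."""

    def __init__(self, config: ModelConfig, spectrum_length: int,
                 aux_length: int) -> None:
        if spectrum_length <= 0 or aux_length < 0:
            raise ValueError("spectrum_length must be positive")
        min_len = config.pool_size ** len(config.filters)
        if spectrum_length < min_len:
            raise ValueError(
                f"spectrum of {spectrum_length} bins cannot survive "
                f"{len(config.filters)} pooling stages; minimum is {min_len}"
            )
        self.config = config
        self.spectrum_length = spectrum_length
        self.aux_length = aux_length
        self.rng = np.random.default_rng(config.seed)
        self.trained = False
        self._build()

    # -- architecture -----------------------------------------------------
    def _build(self) -> None:
        cfg = self.config
        rng = self.rng
        self.trunk = []
        c_in, length = 2, self.spectrum_length
        for c_out in cfg.filters:
            self.trunk += [
                BatchNorm1d(c_in),
                Conv1d(c_in, c_out, cfg.kernel_size, rng),
                LeakyReLU(cfg.negative_slope),
                Conv1d(c_out, c_out, cfg.kernel_size, rng),
                LeakyReLU(cfg.negative_slope),
                MaxPool1d(cfg.pool_size),
                Dropout(cfg.dropout_p, rng),
            ]
            c_in = c_out
            length //= cfg.pool_size
        self._flat_dim = c_in * length
        self.head = [
            Dense(self._flat_dim + self.aux_length, cfg.hidden_units, rng),
            LeakyReLU(cfg.negative_slope),
            Dropout(cfg.dropout_p, rng),
            Dense(cfg.hidden_units, N_CLASSES, rng),
        ]
        self._layers = self.trunk + self.head
        self._opt = SGDNesterov(cfg.momentum, cfg.nesterov)

    def parameters(self) -> list[np.ndarray]:
        return [layer.params[k] for layer in self._layers
                for k in sorted(layer.params)]

    def gradients(self) -> list[np.ndarray]:
        return [layer.grads[k] for layer in self._layers
                for k in sorted(layer.grads)]

    # -- forward / backward ----------------------------------------------
    def _forward(self, amplitude: np.ndarray, phase: np.ndarray,
                 aux: np.ndarray, mode: str) -> np.ndarray:
        x = np.stack([amplitude, phase], axis=1)  # (B, 2, bins)
        for layer in self.trunk:
            x = layer.forward(x, mode)
        flat = x.reshape(x.shape[0], -1)
        h = np.concatenate([flat, aux], axis=1)
        self._trunk_out_shape = x.shape
        self._embedding = None
        for i, layer in enumerate(self.head):
            h = layer.forward(h, mode)
            if i == 1:  # post-activation hidden layer = embedding
                self._embedding = h
        return h

    def _backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.head):
            d = layer.backward(d)
        d = d[:, : self._flat_dim].reshape(self._trunk_out_shape)
        for layer in reversed(self.trunk):
            d = layer.backward(d)

    # -- training ---------------------------------------------------------
    def fit(self, amplitude: np.ndarray, phase: np.ndarray, aux: np.ndarray,
            labels: np.ndarray, *, epochs: int | None = None) -> list[float]:
        """Minimise cross-entropy on (labels in 1..4); returns the
        per-epoch mean training loss."""
        if len(labels) == 0:
            raise ValueError("labelled set is empty")
        present = set(np.unique(labels).tolist())
        if present != set(range(1, N_CLASSES + 1)):
            warnings.warn(f"training labels cover only classes {sorted(present)}",
                          stacklevel=2)
        cfg = self.config
        y = np.asarray(labels, dtype=int) - 1
        n = len(y)
        history = []
        n_epochs = cfg.epochs if epochs is None else epochs
        for epoch in range(n_epochs):
            lr = cfg.learning_rate * cfg.lr_decay**epoch
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits = self._forward(amplitude[idx], phase[idx], aux[idx],
                                       mode="train")
                loss, dlogits = cross_entropy_grad(logits, y[idx])
                self._backward(dlogits)
                grads = self.gradients()
                global_norm_clip(grads, cfg.grad_clip_norm)
                self._opt.step(self.parameters(), grads, lr)
                losses.append(loss)
            history.append(float(np.mean(losses)))
        self.trained = True
        return history

    # -- inference --------------------------------------------------------
    def predict_posterior(self, amplitude: np.ndarray, phase: np.ndarray,
                          aux: np.ndarray, *, mc_dropout: bool = False,
                          passes: int = 1, batch_size: int = 256
                          ) -> np.ndarray:
        """Class probabilities; deterministic by default. With
        ``mc_dropout`` the dropout layers stay active and a stack of
        ``passes`` posterior matrices is returned."""
        if mc_dropout and passes < 1:
            raise ValueError("passes must be >= 1 for MC dropout")
        mode = "mc" if mc_dropout else "eval"
        n_passes = passes if mc_dropout else 1
        out = []
        for _ in range(n_passes):
            chunks = []
            for start in range(0, len(amplitude), batch_size):
                sl = slice(start, start + batch_size)
                logits = self._forward(amplitude[sl], phase[sl], aux[sl], mode)
                chunks.append(softmax(logits))
            out.append(np.concatenate(chunks, axis=0))
        return out[0] if not mc_dropout else np.stack(out, axis=0)

    def embed(self, amplitude: np.ndarray, phase: np.ndarray,
              aux: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Penultimate-layer activations, the feature space used for
        diversity (k-DPP) kernels."""
        chunks = []
        for start in range(0, len(amplitude), batch_size):
            sl = slice(start, start + batch_size)
            self._forward(amplitude[sl], phase[sl], aux[sl], mode="eval")
            chunks.append(self._embedding)
        return np.concatenate(chunks, axis=0)

    def evaluate(self, amplitude: np.ndarray, phase: np.ndarray,
                 aux: np.ndarray, labels: np.ndarray) -> MetricsRecord:
        if len(labels) == 0:
            raise ValueError("test set is empty")
        posterior = self.predict_posterior(amplitude, phase, aux)
        return evaluate_posterior(posterior, labels)

    # -- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        for i, layer in enumerate(self._layers):
            if isinstance(layer, BatchNorm1d):
                arrays[f"bn{i}_mean"] = layer.running_mean
                arrays[f"bn{i}_var"] = layer.running_var
        np.savez(directory / "weights.npz", **arrays)
        meta = asdict(self.config)
        meta.update(spectrum_length=self.spectrum_length,
                    aux_length=self.aux_length, trained=self.trained)
        (directory / "config.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "CnnClassifier":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        spectrum_length = meta.pop("spectrum_length")
        aux_length = meta.pop("aux_length")
        trained = meta.pop("trained")
        meta["filters"] = tuple(meta["filters"])
        model = cls(ModelConfig(**meta), spectrum_length, aux_length)
        data = np.load(directory / "weights.npz")
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
        for i, layer in enumerate(model._layers):
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = data[f"bn{i}_mean"]
                layer.running_var = data[f"bn{i}_var"]
        model.trained = trained
        return model


def evaluate_posterior(posterior: np.ndarray, labels: np.ndarray,
                       iteration: int = -1, trial: int = -1) -> MetricsRecord:
    """Accuracy, mean cross-entropy, macro precision and recall of a
    posterior matrix against labels in 1..4. Classes absent from the
    labels are excluded from the macro averages (with a warning)."""
    labels = np.asarray(labels, dtype=int)
    y = labels - 1
    pred = posterior.argmax(axis=1)
    accuracy = float(np.mean(pred == y))
    eps = 1e-12
    picked = np.clip(posterior[np.arange(len(y)), y], eps, 1.0)
    loss = float(-np.log(picked).mean())
    precisions, recalls = [], []
    absent = []
    for c in range(N_CLASSES):
        tp = np.sum((pred == c) & (y == c))
        fp = np.sum((pred == c) & (y != c))
        fn = np.sum((pred != c) & (y == c))
        if tp + fn == 0:
            absent.append(c + 1)
            continue
        recalls.append(tp / (tp + fn))
        precisions.append(tp / (tp + fp) if tp + fp > 0 else 0.0)
    if absent:
        warnings.warn(f"classes {absent} absent from the evaluation labels; "
                      "excluded from macro averages", stacklevel=2)
    return MetricsRecord(
        accuracy=accuracy,
        loss=loss,
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
        iteration=iteration,
        trial=trial,
        n_labelled=-1,
    )
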