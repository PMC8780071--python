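"""Desk-scale end-to-end benchmark: generator -> SCNR -> features -> AL.

The benchmark mirrors the study protocol at a size a single CPU handles
comfortably: 30 fruits measured weekly (days 0, 7, 14 and 21, one day per
ripeness class so the four classes are balanced and the chance level is
0.25), six knock zones, two repeats per zone, SCNR denoising, a reduced
CNN, L0 = 30 initial labels and 50 queries per iteration.
"""

from __future__ import annotations

from dataclasses import replace

from .al_loop import ALConfig, ALResults, ActiveLearningExperiment
from .classifier import CnnClassifier, ModelConfig
from .preprocess import (DatasetSplit, Standardiser, build_features,
                         split_dataset)
from .scnr import ScnrConfig, apply_scnr
from .synthetic import RipeningParams, generate_dataset

__all__ = [
    "BENCHMARK_DAYS", "REDUCED_MODEL", "make_benchmark_features",
    "model_factory_for", "run_benchmark",
]

BENCHMARK_DAYS = (0, 7, 14, 21)   # one measurement day per ripeness class
BENCHMARK_REPEATS = 2
BENCHMARK_CROP = (64, 1984)       # 2048-sample region of interest
BENCHMARK_MAX_FREQ = 2500.0       # Hz; resonances live below this
N_SAMPLES = 4096

REDUCED_MODEL = ModelConfig(filters=(16, 16, 8, 8), kernel_size=7,
                            hidden_units=32, epochs=30, batch_size=16,
                            lr_decay=0.98)


def make_benchmark_features(shift_rate: float = 0.005, n_fruits: int = 30,
                            repeats: int = BENCHMARK_REPEATS, seed: int = 0,
                            denoise: bool = True
                            ) -> tuple[DatasetSplit, Standardiser]:
    """Generate the benchmark dataset and turn it into model-ready
    features (SCNR, align, crop, spectra, standardise; grouped split)."""
    params = RipeningParams(freq_shift_rate=shift_rate)
    measurements = generate_dataset(
        n_fruits=n_fruits, measurement_days=BENCHMARK_DAYS,
        repeats=repeats, params=params, seed=seed, n_samples=N_SAMPLES)
    if denoise:
        cfg = ScnrConfig()
        measurements = [replace(m, signal=apply_scnr(m.signal, cfg))
                        for m in measurements]
    train, test, val = split_dataset(measurements, seed=seed)
    return build_features(train, test, val,
                          pre_samples=BENCHMARK_CROP[0],
                          post_samples=BENCHMARK_CROP[1],
                          max_freq=BENCHMARK_MAX_FREQ)


def model_factory_for(split: DatasetSplit,
                      config: ModelConfig = REDUCED_MODEL):
    """Classifier factory bound to the feature dimensions of a split."""
    spectrum_length = split.train.amplitude.shape[1]
    aux_length = split.train.aux.shape[1]

    def factory(seed: int) -> CnnClassifier:
        return CnnClassifier(replace(config, seed=seed),
                             spectrum_length, aux_length)

    return factory


def run_benchmark(acquisitions: tuple[str, ...] = ("random", "margin"),
                  shift_rate: float = 0.005, trials: int = 3,
                  iterations: int = 5, seed: int = 0,
                  kdpp_k: int = 50, mc_passes: int = 10,
                  split: DatasetSplit | None = None
                  ) -> dict[str, ALResults]:
    """Run the AL protocol for each acquisition on a shared dataset and
    return the per-acquisition results."""
    if split is None:
        split, _ = make_benchmark_features(shift_rate=shift_rate, seed=seed)
    factory = model_factory_for(split)
    results = {}
    for name in acquisitions:
        config = ALConfig(initial_labelled=30, batch_size=50, trials=trials,
                          label_budget=30 + 50 * iterations,
                          acquisition=name, kdpp_k=kdpp_k,
                          mc_passes=mc_passes)
        results[name] = ActiveLearningExperiment(
            split.train, split.test, factory, config,
            base_seed=seed + 1).run()
    return results
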