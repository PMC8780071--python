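# ripetap

Acoustic shelf-life grading of 'Galia' muskmelons with deep active
learning and exact k-DPP batch selection.

## The problem

Tapping a melon and listening to the ring is a classic non-destructive
ripeness test: the fruit is a resonant body, and as the flesh softens its
modal frequencies drift downward, its damping grows and the high
modes die away (the "dull thud"). A small CNN can grade the ripeness
class y ∈ {1, 2, 3, 4} (one class per week of shelf life) from the
amplitude and phase spectra of a tap recording plus auxiliary covariates
(weight, room temperature, humidity, knock zone). Labels, however, are
expensive — each one is a day of storage and a taste panel — which makes
the setting a natural fit for **pool-based active learning (AL)**: start
from a small labelled set L₀, let the learner pick which b pool
instances an oracle should label next, retrain, repeat.

`ripetap` implements the full pipeline for this problem:

- **SCNR** — single-channel noise reduction by spectral subtraction with
  a minimum-statistics noise floor. Per STFT cell,

  `G[k,n] = max( ((P[k,n] − β·PN[k,n]) / P[k,n])^α , G_min )`,

  with `PN[k,n] = min P[k, n−L..n]`, `G_min = 10^(−DBred/20)` and
  defaults α = 9, β = 45, DBred = 25 dB.
- **Preprocessing** — alignment on the waveform maximum, fixed-length
  crop of the region of interest (time and frequency axes),
  one-sided spectra, per-component standardisation fitted on the
  training split only, min-max scaling and one-hot zone encoding of the
  covariates, flip augmentation, and a grouped 0.60/0.25/0.15
  train/test/validation split (no fruit crosses splits).
- **Classifier** — a dual-channel 1-D CNN: four modules of
  (batch norm, conv, conv, max pool, dropout p = 0.005) with descending
  filter counts, flattened and concatenated with the covariates, trained
  by SGD (momentum 0.9, Nesterov) at learning rate 0.005 with
  exponential decay, global-norm gradient clipping at 1.0 and LeakyReLU
  activations. Implemented from scratch in numpy with manual
  backpropagation; Monte-Carlo dropout supplies stochastic posteriors.
- **Acquisition functions** — random baseline, least confidence
  `1 − max_c p(c)`, margin `p₁ − p₂`, maximum entropy `−Σ p log p`,
  ratio of confidence `p₂/p₁`, and BALD
  `I = H(E_t[p_t]) − E_t[H(p_t)]` over T MC-dropout passes.
- **k-DPP** — exact diversity sampling: a determinantal point process
  over a PSD similarity kernel K assigns subset A probability
  ∝ det(K_A), conditioned on |A| = k. Sampling uses the classical
  eigendecomposition scheme: eigenvector sets are drawn through the
  elementary symmetric polynomials e_k^N (marginal of index N is
  λ_N·e_{k−1}^{N−1}/e_k^N), then items are sampled from the spanned
  elementary DPP. A brute-force det-enumeration oracle is included.
- **AL loop** — initialise L₀ = 30 at random, score the pool, query
  b = 50, reveal labels, retrain from scratch, record
  accuracy/loss/precision/recall on the held-out test split; aggregate
  several seeded trials into mean ± std learning curves.
- **Synthetic generator** — the study's dataset is private, so a
  damped-resonance simulator reproduces its statistical structure:
  3–5 modes per fruit, ripening-dependent frequency shift
  (0.5 %/day by default), damping growth and high-frequency attenuation
  coupled to the same dial, broadband noise and 50 Hz mains hum,
  drifting covariates, and the factorial measurement protocol
  (30 fruits × days × 6 zones × repeats).

## Worked example

```python
import numpy as np
from ripetap import (RipeningParams, simulate_fruit, simulate_tap,
                     apply_scnr, score_margin, score_entropy,
                     PSDKernel, sample_kdpp_many, brute_force_kdpp_pmf)

rng = np.random.default_rng(0)
fruit = simulate_fruit(rng, fruit_id="demo")
print("modal frequencies (Hz):", [round(f, 1) for f in fruit.base_resonances])

fresh = simulate_tap(fruit, shelf_life_days=0, zone=3,
                     params=RipeningParams(), rng=rng)
ripe = simulate_tap(fruit, shelf_life_days=21, zone=3,
                    params=RipeningParams(), rng=rng)
for name, m in (("day 0", fresh), ("day 21", ripe)):
    spec = np.abs(np.fft.rfft(apply_scnr(m.signal).samples))
    spec[0] = 0
    peak = spec.argmax() * m.signal.sample_rate / len(m.signal)
    print(f"{name}: class {m.label}, dominant peak {peak:.0f} Hz")

posterior = np.array([[0.42, 0.38, 0.12, 0.08],
                      [0.85, 0.05, 0.05, 0.05]])
print("margin scores:", np.round(score_margin(posterior).scores, 3))
print("entropy scores:", np.round(score_entropy(posterior).scores, 3))

kernel = PSDKernel.from_matrix(np.diag([4.0, 1.0, 1.0]))
draws = sample_kdpp_many(kernel, k=1, n_draws=30_000,
                         rng=np.random.default_rng(1))
freq = np.bincount(draws.ravel(), minlength=3) / 30_000
print("k-DPP inclusion frequencies:", np.round(freq, 3))
print("exact det-normalised pmf:   ",
      [round(p, 3) for p in brute_force_kdpp_pmf(kernel, 1).values()])
```

prints

```
modal frequencies (Hz): [195.4, 381.6, 761.3, 1650.1]
day 0: class 1, dominant peak 194 Hz
day 21: class 4, dominant peak 172 Hz
margin scores: [0.04 0.8 ]
entropy scores: [1.189 0.588]
k-DPP inclusion frequencies: [0.668 0.165 0.167]
exact det-normalised pmf:    [0.667, 0.167, 0.167]
```

The simulated fruit rings at ~195 Hz when fresh and ~172 Hz after three
weeks (the 0.5 %/day shift, visible after SCNR denoising). The first
posterior row is ambiguous between its top classes, so margin ranks it
most queryable (0.04, lower = queried) and entropy agrees (1.189,
higher = queried). The k-DPP draw frequencies over a diagonal kernel
match the exact determinant-normalised probabilities (4/6, 1/6, 1/6).

## Command line

```
ripetap generate   --fruits 30 --days 0,7,14,21 --repeats 2 --seed 0 --out-dir data/
ripetap scnr       data/wav/tap00000.wav clean.wav --beta 45
ripetap preprocess --metadata data/metadata.csv --out-dir features/
ripetap run-al     --metadata data/metadata.csv --acquisition margin \
                   --trials 3 --iterations 5 --seed 1 --out-dir runs/margin/
ripetap sample-kdpp --kernel-csv kernel.csv --k 3 --draws 10000 --out freq.csv
ripetap report     runs/
```

Metadata CSV schema: `fruit_id, wav_path, shelf_life_days, zone,
weight_g, temp_c, humidity_pct, label` (UTF-8, header required). Every
run directory receives a `manifest.json` (config, seeds, input hashes)
written before any result file; run histories are CSVs with columns
`acquisition, trial, iteration, n_labelled, accuracy, loss, precision,
recall`, and `report` aggregates them into mean ± std curve tables.

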