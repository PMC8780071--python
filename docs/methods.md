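# Methods

This note records the models, numerical choices and open design
decisions behind `ripetap`, in the spirit of a package vignette. It
states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model of the synthetic generator

The real dataset (tap recordings of 30 'Galia' muskmelons measured
weekly over several weeks) is available only on request, so every stage
is exercised on a synthetic emulation. Each fruit carries a bank of
M = 4 damped modes; a tap at zone z on day s produces

    x(t) = Σ_m a_m(z, s) · exp(−d_m(s)·(t−t₀)) · sin(2π f_m(s)·(t−t₀))
           + broadband noise + mains hum,            t ≥ t₀ (random onset)

with

- `f_m(s) = f_m0 · (1 − r·s)` — ripening softens the flesh and every
  modal frequency drifts down at rate `r = freq_shift_rate`
  (default 0.005/day, i.e. 0.5 %/day);
- `d_m(s) = d_m0 · (1 + 6r·s)` — the same stiffness loss raises the
  losses, so damping growth is *coupled* to the shift dial
  (factor `DAMPING_COUPLING = 6` per unit shift rate);
- `a_m(z, s) ∝ 0.45^m · zone_gain(m, z) · exp(−5r·s·m)` — higher modes
  are progressively attenuated as the fruit ripens (the audible "dull
  thud"; `HF_COUPLING = 5`), modulated ±15 % by the knock zone;
- base frequencies on a geometric grid from 200 to 1600 Hz with
  independent ±5 % per-fruit jitter (fruit-identity nuisance), base
  damping 25–40 s⁻¹ rising with mode order;
- broadband Gaussian noise at 18 dB SNR relative to the ring RMS, plus
  a 50 Hz hum with a 100 Hz harmonic (amplitude 5 % of the tap peak) —
  the low-frequency band the SCNR stage demonstrably removes;
- weight drawn uniformly in the observed arrival range
  [837.2, 1555.3] g; temperature uniform in [18.4, 22.9] °C; humidity
  uniform in [40, 70] %; class label `min(4, ⌊s/7⌋ + 1)`.

Because *all* ripening effects are proportional to `freq_shift_rate`,
setting the dial to zero makes signals and covariates exactly
label-independent — the chance-level null used by the tests — and the
dial is a clean monotone effect-size control (verified with a fast
reference classifier at three settings).

Why damping growth and high-frequency attenuation are part of the
default model: a frequency shift alone moves spectral peaks by roughly
one DFT bin per ripeness class, which survives a fine-resolution
feature map but is erased by the classifier's four pooling stages
(16× position coarsening). The two coupled effects are the standard
acoustic correlates of softening and are exactly the kind of cue a
pooled spectral CNN can exploit — broader peaks, faster decay, energy
migrating to the low bands. They make the benchmark "clearly but
imperfectly" separable, with desk-scale final accuracies landing in the
0.6–0.9 band rather than at either extreme.

What the generator does **not** emulate: real modal physics of an
inhomogeneous fruit (mode shapes, nonlinear contact of the hammer),
microphone transfer functions, room reverberation, batch-to-batch
cross-contamination of climacteric fruit, or any biological variance
beyond the independent per-mode jitter. Passing the end-to-end tests
therefore shows the *pipeline* behaves correctly under the assumed
statistical structure; it says nothing about accuracy on real melons.

## SCNR

Spectral subtraction with a minimum-statistics floor:
`PN[k,n] = min P[k, n−L..n]` (trailing window, clipped at the first
frame; L = 20 frames by default) and
`G = max(((P − βPN)/P)^α, G_min)` with α = 9, β = 45,
`G_min = 10^(−25/20)`. Numerical choices:

- the subtraction base is clamped to [0, 1] *before* the exponent —
  α = 9 is odd, so a negative base would survive exponentiation and
  produce meaningless negative gains;
- zero-energy cells receive `G_min` directly (no 0/0);
- STFT: 1024-sample Hann window, hop 256 (unstated upstream; standard
  audio values), one-sided FFT via `scipy.signal.ShortTimeFFT`, which
  guarantees exact overlap-add inversion of unmodified coefficients.

The minimum tracker assumes a *transient* signal over stationary noise.
A continuous tone longer than the tracking window becomes its own noise
floor and is attenuated; tap recordings — milliseconds of ring inside
longer silence — are the intended regime, and the SNR-gain tests use
tap-like tone bursts for that reason.

## Preprocessing

Alignment shifts the absolute-maximum sample to a fixed index
(earliest maximum on ties; all-zero signals are rejected), cropping
takes a fixed window around it (zero-padded with a warning if the
window leaves the recording), and spectra are one-sided DFT
magnitude/phase pairs. The optional `max_freq` truncation keeps only
the band that can contain tap resonances (2.5 kHz in the benchmark);
at 44.1 kHz the untruncated spectrum is &gt;90 % resonance-free bins.

Standardisation (per-component z-score, std floored at 1e−8) is fitted
on the training split only; covariates are min-max scaled and the knock
zone one-hot encoded (6 positions). The train/test/validation split is
grouped by fruit — the classifier must generalise to unseen fruits, and
per-measurement splitting would leak fruit identity. Flip augmentation
acts on the raw waveform: amplitude negation ("vertical") and time
reversal ("horizontal"), the 1-D analogues of image flips; labels and
covariates are copied unchanged.

## Classifier

The network is written directly in numpy (no DL framework in the
dependency set): im2col convolutions, per-channel batch norm with
running statistics, inverted dropout, max pooling with argmax routing,
and a Nesterov-momentum SGD with exponential learning-rate decay and
global-norm gradient clipping. Backpropagation is manual and guarded by
a finite-difference gradient check in the test suite.

Fixed by the training recipe: lr 0.005, momentum 0.9 (Nesterov),
clip 1.0, dropout 0.005, LeakyReLU (slope 0.01), four conv modules with
non-increasing filter counts. Open choices and their defaults: filters
(64, 32, 16, 8), kernel 7, pool 2, hidden width 32, decay 0.95/epoch,
30 epochs per fit. The benchmark uses a reduced variant —
filters (16, 16, 8, 8), batch 16, decay 0.98 — sized so a full
multi-acquisition experiment runs on one CPU in minutes. Precision and
recall are macro-averaged over the four classes (classes absent from an
evaluation set are excluded with a warning). Monte-Carlo dropout keeps
the dropout masks active at inference over T passes (default 20;
10 in the benchmark) to approximate posterior sampling for BALD.

## Acquisition functions

All scores operate on softmax posteriors; natural logarithms
throughout (the base only rescales rankings), probabilities clamped to
[1e−12, 1] inside logs, and 0·log 0 := 0. Maximum entropy is
implemented as `argmax −Σ p log p`: the intended "samples instances
yielding the maximum entropy", which the negated sum realises (the
unnegated form would select one-hot rows). Batch selection takes the
top b in the score's query direction with exact ties broken uniformly
at random from the supplied generator.

## k-DPP

Exact sampling via eigendecomposition (O(n³)), the package's primary
route; rejection-sampling acceleration is deliberately out of scope.
Eigenvalues below 1e−9 are clamped to zero and the rank computed after
clamping; requesting k above the rank is an error that names the rank
(every k×k principal minor is then singular). Phase 1 selects an
eigenvector set through the ESP recurrence
`e_k^N = e_k^{N−1} + λ_N e_{k−1}^{N−1}`; phase 2 samples items from the
spanned elementary DPP with orthogonal elimination (batched QR), and a
vectorised many-draw path makes frequency studies of 10⁵–10⁶ draws
cheap. A brute-force determinant enumeration (guarded at 100,000
subsets) is the independent oracle.

The kernel over pool instances is the method's one genuinely open
ingredient: the package uses an RBF kernel on standardised embeddings —
the classifier's penultimate layer once a model exists, raw
standardised amplitude spectra before the first fit — with the median
pairwise-distance bandwidth heuristic. Reconciling the subset size k
with the label batch b is likewise open: for k ≥ b a single draw is
uniformly thinned to b; for k < b disjoint draws accumulate on the
shrinking pool until b indices are collected. Both choices are isolated
in `kdpp_acquire` for easy replacement.

## Active-learning loop

L₀ = 30 random initial labels, b = 50 queries per iteration, retraining
from a fresh initialisation each iteration (warm start available by
flag but off: fresh init avoids optimisation-path dependence on query
order). Stopping: label budget, with pool exhaustion as fallback. The
validation split plays no role during AL by default. Pool labels live
behind an oracle accessor that raises if queried before reveal, so no
acquisition can touch ground truth. Per-trial seed = base seed + trial
index; all randomness flows from per-trial generators.

## Benchmark problem sizes

The end-to-end benchmark runs 30 fruits × 4 weekly measurement days
(0, 7, 14, 21 — one day per ripeness class, balanced classes, chance
level 0.25) × 6 zones × 2 repeats = 1440 taps, SCNR-denoised, cropped
to 2048 samples and truncated at 2.5 kHz (117 spectral bins), split
0.6/0.25/0.15 by fruit. Acquisition comparisons use 3 trials × 5 AL
iterations (final |L| = 280). The generator's own defaults keep the
study protocol (days 0, 7, 10, 15, 17; 5 repeats); the benchmark's
weekly grid is chosen so that all four classes appear with equal mass,
which the chance-level null control presumes. These sizes are the
package's desk-scale defaults; all are parameters.

## Known limitations

- The numpy network is CPU-only and sized for hundreds of labelled
  instances, not thousands; it trades speed for zero framework
  dependencies.
- The eigendecomposition k-DPP is cubic in the pool size; pools beyond
  a few thousand instances need the (out-of-scope) rejection sampler.
- The generator's separability is calibrated, not measured physics;
  absolute benchmark metrics are properties of the simulation.
- BALD with dropout p = 0.005 yields small mutual-information scores
  (little posterior disagreement); it is included for protocol
  completeness rather than as a strong uncertainty signal.
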