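"""Synthetic tap-response generator with ripening-dependent acoustics.

Each fruit is a small bank of damped resonant modes. Ripening softens the
flesh, which the generator expresses as a fractional downward drift of
every modal frequency per day of shelf life; optional weight loss and
damping growth model water loss and increasing absorption. A tap excites
the modes with zone-dependent weights, and the microphone adds broadband
noise plus low-frequency mains hum — the component the SCNR stage is
meant to remove.

The model is the minimal physics consistent with acoustic resonance
testing of fruit; it makes no claim of biophysical fidelity. Its purpose
is to give every pipeline stage data with the right statistical structure:
class-informative spectral shifts, fruit-level nuisance variation, noisy
auxiliary covariates and a controllable effect size
(``freq_shift_rate = 0`` yields label-independent signals, the
chance-level benchmark).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .preprocess import Measurement, label_from_shelf_life, METADATA_COLUMNS
from .signal import TimeSignal, write_wav

__all__ = [
    "FruitSpec", "RipeningParams", "simulate_fruit", "simulate_tap",
    "generate_dataset", "write_dataset",
]

logger = logging.getLogger(__name__)

WEIGHT_RANGE_G = (837.2, 1555.3)
TEMPERATURE_RANGE_C = (18.4, 22.9)
HUMIDITY_RANGE_PCT = (40.0, 70.0)
DEFAULT_DAYS = (0, 7, 10, 15, 17)
DEFAULT_N_SAMPLES = 4096
SAMPLE_RATE = 44_100


@dataclass(frozen=True)
class FruitSpec:
    """Static acoustic identity of one melon."""

    fruit_id: str
    initial_weight: float
    base_resonances: tuple[float, ...]   # Hz, strictly increasing
    modal_decay_rates: tuple[float, ...]  # 1/s, one per mode
    origin: str = "synthetic"

    def __post_init__(self) -> None:
        freqs = np.asarray(self.base_resonances)
        if np.any(freqs <= 0) or np.any(freqs >= SAMPLE_RATE / 2):
            raise ValueError("modal frequencies must lie in (0, Nyquist)")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("modal frequencies must be strictly increasing")
        if np.any(np.asarray(self.modal_decay_rates) <= 0):
            raise ValueError("damping rates must be positive")


@dataclass(frozen=True)
class RipeningParams:
    """Effect sizes of the ripening process and the recording noise.

    freq_shift_rate
        Fractional decrease of every modal frequency per day; the main
        class-separability dial. 0.005 (0.5 %/day) separates the weekly
        classes clearly but imperfectly.
    damping_growth_rate
        Fractional increase of modal damping per day. Stiffness loss both
        lowers the resonances and raises the losses, so by default
        (``None``) the damping growth is coupled to the frequency shift as
        ``DAMPING_COUPLING * freq_shift_rate``; a shift rate of zero then
        leaves the signals completely label-independent. Pass an explicit
        value to decouple the two.
    hf_attenuation_rate
        Per-day, per-mode-order attenuation of the higher modes — the
        "dull thud" of a ripe fruit: mode m is scaled by
        ``exp(-hf_attenuation_rate * s * m)``. Also coupled to the shift
        dial by default (``HF_COUPLING * freq_shift_rate``) for the same
        reason as the damping growth.
    weight_loss_rate
        Fractional weight drift per day; defaults to 0 so the auxiliary
        covariates carry no label information unless asked for.
    noise_floor_snr
        Broadband-noise level in dB relative to the tap's RMS.
    hum_amplitude
        Peak amplitude of the 50 Hz mains hum (plus a half-amplitude
        100 Hz harmonic) relative to the tap's peak.
    """

    freq_shift_rate: float = 0.005
    weight_loss_rate: float = 0.0
    damping_growth_rate: float | None = None   # None: coupled to the shift
    hf_attenuation_rate: float | None = None   # None: coupled to the shift
    noise_floor_snr: float = 18.0
    hum_amplitude: float = 0.05
    hum_freq: float = 50.0

    DAMPING_COUPLING = 6.0  # damping growth per unit frequency-shift rate
    HF_COUPLING = 5.0       # high-frequency attenuation per unit shift rate

    def __post_init__(self) -> None:
        for name in ("freq_shift_rate", "weight_loss_rate", "hum_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("damping_growth_rate", "hf_attenuation_rate"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def effective_damping_growth_rate(self) -> float:
        if self.damping_growth_rate is None:
            return self.DAMPING_COUPLING * self.freq_shift_rate
        return self.damping_growth_rate

    @property
    def effective_hf_attenuation_rate(self) -> float:
        if self.hf_attenuation_rate is None:
            return self.HF_COUPLING * self.freq_shift_rate
        return self.hf_attenuation_rate


def simulate_fruit(rng: np.random.Generator, fruit_id: str | None = None,
                   n_modes: int = 4,
                   freq_band: tuple[float, float] = (80.0, 2000.0),
                   freq_jitter: float = 0.05,
                   weight_range: tuple[float, float] = WEIGHT_RANGE_G
                   ) -> FruitSpec:
    """Draw one fruit: weight uniform in the observed arrival range and
    modal frequencies on a geometric grid inside ``freq_band`` with
    independent per-mode jitter (fruit-to-fruit nuisance variation)."""
    weight = float(rng.uniform(*weight_range))
    lo, hi = freq_band
    centers = np.geomspace(lo * 2.5, hi * 0.8, n_modes)
    freqs = centers * rng.uniform(1 - freq_jitter, 1 + freq_jitter, n_modes)
    freqs = np.sort(np.clip(freqs, lo, hi))
    # higher modes damp faster; keeps the fundamental spectrally dominant
    damping = rng.uniform(25.0, 40.0, n_modes) * (1.0 + 0.3 * np.arange(n_modes))
    if fruit_id is None:
        fruit_id = f"fruit{int(rng.integers(1_000_000)):06d}"
    return FruitSpec(fruit_id, weight, tuple(float(f) for f in freqs),
                     tuple(float(d) for d in damping))


# zone-dependent excitation of mode m (zone 1..6): the two ends and the
# four equatorial positions couple differently into each mode
def _zone_gain(mode: int, zone: int) -> float:
    return 1.0 + 0.15 * np.cos(2.0 * np.pi * (zone - 1) * (mode + 1) / 6.0)


_BASE_AMPLITUDE_DECAY = 0.45  # mode m has base amplitude 0.45**m


def simulate_tap(fruit: FruitSpec, shelf_life_days: int, zone: int,
                 params: RipeningParams, rng: np.random.Generator,
                 n_samples: int = DEFAULT_N_SAMPLES) -> Measurement:
    """One knock: damped-sinusoid mixture with ripening-shifted modes,
    broadband noise and mains hum, plus drifted covariates."""
    if not 1 <= zone <= 6:
        raise ValueError("zone must be in 1..6")
    if shelf_life_days < 0:
        raise ValueError("shelf life must be non-negative")
    s = shelf_life_days
    shift = 1.0 - params.freq_shift_rate * s
    if shift <= 0:
        warnings.warn(f"frequency shift clips to zero at s={s} days",
                      stacklevel=2)
        shift = 1e-3
    t = np.arange(n_samples) / SAMPLE_RATE
    onset = int(rng.integers(300, 800))
    tau = np.clip(t - onset / SAMPLE_RATE, 0.0, None)
    ringing = tau > 0
    strike = float(rng.uniform(0.8, 1.2))
    clean = np.zeros(n_samples)
    for m, (f0, d0) in enumerate(zip(fruit.base_resonances,
                                     fruit.modal_decay_rates)):
        f = f0 * shift
        d = d0 * (1.0 + params.effective_damping_growth_rate * s)
        a = (strike * _BASE_AMPLITUDE_DECAY**m * _zone_gain(m, zone)
             * np.exp(-params.effective_hf_attenuation_rate * s * m))
        clean += a * np.exp(-d * tau) * np.sin(2 * np.pi * f * tau) * ringing
    rms = float(np.sqrt(np.mean(clean[ringing] ** 2))) if ringing.any() else 1.0
    noise_sigma = rms * 10.0 ** (-params.noise_floor_snr / 20.0)
    noise = rng.normal(0.0, noise_sigma, n_samples)
    hum_phase = rng.uniform(0, 2 * np.pi)
    peak = float(np.max(np.abs(clean))) or 1.0
    hum = params.hum_amplitude * peak * (
        np.sin(2 * np.pi * params.hum_freq * t + hum_phase)
        + 0.5 * np.sin(2 * np.pi * 2 * params.hum_freq * t + 2 * hum_phase))
    mix = clean + noise + hum
    mix *= 0.9 / max(float(np.max(np.abs(mix))), 1e-12)
    weight = fruit.initial_weight * (1.0 - params.weight_loss_rate * s)
    return Measurement(
        signal=TimeSignal(mix, SAMPLE_RATE),
        fruit_id=fruit.fruit_id,
        shelf_life_days=s,
        zone=zone,
        weight=weight,
        temperature=float(rng.uniform(*TEMPERATURE_RANGE_C)),
        humidity=float(rng.uniform(*HUMIDITY_RANGE_PCT)),
        label=label_from_shelf_life(s),
    )


def generate_dataset(n_fruits: int = 30,
                     measurement_days: tuple[int, ...] = DEFAULT_DAYS,
                     zones: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
                     repeats: int = 5,
                     params: RipeningParams | None = None,
                     seed: int = 0,
                     n_samples: int = DEFAULT_N_SAMPLES
                     ) -> list[Measurement]:
    """Full factorial protocol: every fruit is knocked at every zone,
    ``repeats`` times, on every measurement day."""
    if n_fruits < 1:
        raise ValueError("n_fruits must be >= 1")
    params = params or RipeningParams()
    rng = np.random.default_rng(seed)
    fruits = [simulate_fruit(rng, fruit_id=f"fruit{i:03d}")
              for i in range(n_fruits)]
    measurements = []
    for fruit in fruits:
        for day in measurement_days:
            for zone in zones:
                for _ in range(repeats):
                    measurements.append(simulate_tap(
                        fruit, day, zone, params, rng, n_samples))
    labels = np.array([m.label for m in measurements])
    fractions = {c: float(np.mean(labels == c)) for c in sorted(set(labels))}
    logger.info("generated %d measurements; class proportions %s",
                len(measurements), fractions)
    return measurements


def write_dataset(measurements: list[Measurement], out_dir: str | Path,
                  params: RipeningParams | None = None,
                  seed: int | None = None) -> Path:
    """Write WAV files, the metadata CSV and a generator manifest; returns
    the CSV path."""
    out_dir = Path(out_dir)
    (out_dir / "wav").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, m in enumerate(measurements):
        rel = f"wav/tap{i:05d}.wav"
        write_wav(out_dir / rel, m.signal)
        rows.append((m.fruit_id, rel, m.shelf_life_days, m.zone,
                     f"{m.weight:.2f}", f"{m.temperature:.2f}",
                     f"{m.humidity:.2f}", m.label))
    csv_path = out_dir / "metadata.csv"
    with open(csv_path, "w", encoding="utf-8") as fh:
        fh.write(",".join(METADATA_COLUMNS) + "\n")
        for row in rows:
            fh.write(",".join(str(v) for v in row) + "\n")
    manifest = {"n_measurements": len(measurements), "seed": seed,
                "params": asdict(params) if params else None}
    (out_dir / "generator_manifest.json").write_text(
        json.dumps(manifest, indent=2))
    return csv_path
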