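"""Training-set augmentation for the ECG branch.

Three operators, applied offline to training records only (validation and
test are never augmented, and augmented copies never cross partitions):

* additive Gaussian noise, mean 0, s.d. 0.01 mV by default;
* amplification by a gain k = 1 + x;
* attenuation by a gain k = 1 - x;

with x drawn uniformly from [0.001, 0.01] per augmented copy. Labels and
demographics are copied unchanged — the perturbations emulate sensor-level
variation, which does not alter the diagnosis.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .records import ECGRecord
from .scenarios import LabeledDataset


@dataclass(frozen=True)
class AugmentationConfig:
    noise_mean: float = 0.0
    noise_sd: float = 0.01
    gain_x_min: float = 0.001
    gain_x_max: float = 0.01
    policy: str = "triple"  # or "balance-to-majority"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.gain_x_min > self.gain_x_max:
            raise ValueError("gain_x_min must be <= gain_x_max")
        if self.policy not in ("triple", "balance-to-majority"):
            raise ValueError(f"unknown policy {self.policy!r}")


def add_gaussian_noise(
    signal: np.ndarray,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
    noise_mean: float = 0.0,
) -> np.ndarray:
    """Add i.i.d. Gaussian noise to every sample of every lead."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    signal = np.asarray(signal, dtype=np.float64)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    if noise_sd == 0 and noise_mean == 0:
        return signal.copy()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return signal + rng.normal(noise_mean, noise_sd, size=signal.shape)


def _check_gain_offset(x: float, config: AugmentationConfig | None) -> None:
    lo = config.gain_x_min if config else 0.0
    hi = config.gain_x_max if config else 1.0
    if not lo <= x <= hi:
        raise ValueError(f"gain offset x={x} outside [{lo}, {hi}]")


def amplify(
    signal: np.ndarray, x: float, config: AugmentationConfig | None = None
) -> np.ndarray:
    """Multiply the signal by the gain k = 1 + x."""
    _check_gain_offset(x, config)
    return (1.0 + x) * np.asarray(signal, dtype=np.float64)


def attenuate(
    signal: np.ndarray, x: float, config: AugmentationConfig | None = None
) -> np.ndarray:
    """Multiply the signal by the gain k = 1 - x."""
    _check_gain_offset(x, config)
    return (1.0 - x) * np.asarray(signal, dtype=np.float64)


def _augmented_copy(
    rec: ECGRecord, signal: np.ndarray, suffix: str
) -> ECGRecord:
    out = copy.copy(rec)
    out.signal = signal
    out.record_id = f"{rec.record_id}{suffix}"
    return out


def _three_copies(
    rec: ECGRecord, config: AugmentationConfig, rng: np.random.Generator
) -> list[ECGRecord]:
    noisy = add_gaussian_noise(rec.signal, config.noise_sd, rng, config.noise_mean)
    x_amp = rng.uniform(config.gain_x_min, config.gain_x_max)
    x_att = rng.uniform(config.gain_x_min, config.gain_x_max)
    return [
        _augmented_copy(rec, noisy, "_noise"),
        _augmented_copy(rec, amplify(rec.signal, x_amp, config), "_amp"),
        _augmented_copy(rec, attenuate(rec.signal, x_att, config), "_att"),
    ]


def expand_training_set(
    dataset: LabeledDataset, config: AugmentationConfig
) -> LabeledDataset:
    """Expand a training set with augmented copies.

    Policy ``triple`` adds one copy per operator, quadrupling every class
    count. Policy ``balance-to-majority`` cycles the three operators to top
    minority classes up toward the majority class count. Originals are
    always retained; calling this on validation/test partitions is an error.
    """
    if dataset.partition != "train":
        raise ValueError(
            f"augmentation is train-only; got partition {dataset.partition!r}"
        )
    rng = np.random.default_rng(config.seed)
    out: list[tuple[ECGRecord, int]] = list(dataset.records)
    if config.policy == "triple":
        for rec, y in dataset.records:
            out.extend((c, y) for c in _three_copies(rec, config, rng))
    else:  # balance-to-majority
        counts = dataset.class_counts()
        majority = max(counts.values()) if counts else 0
        by_class: dict[int, list[ECGRecord]] = {}
        for rec, y in dataset.records:
            by_class.setdefault(y, []).append(rec)
        ops = ("_noise", "_amp", "_att")
        for y, recs in by_class.items():
            deficit = majority - len(recs)
            for j in range(deficit):
                rec = recs[j % len(recs)]
                op = ops[(j // len(recs)) % 3]
                if op == "_noise":
                    sig = add_gaussian_noise(
                        rec.signal, config.noise_sd, rng, config.noise_mean
                    )
                elif op == "_amp":
                    sig = amplify(
                        rec.signal,
                        rng.uniform(config.gain_x_min, config.gain_x_max),
                        config,
                    )
                else:
                    sig = attenuate(
                        rec.signal,
                        rng.uniform(config.gain_x_min, config.gain_x_max),
                        config,
                    )
                out.append((_augmented_copy(rec, sig, f"{op}{j}"), y))
    return LabeledDataset(
        records=out, partition=dataset.partition, scenario=dataset.scenario
    )
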