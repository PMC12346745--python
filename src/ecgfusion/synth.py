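"""Synthetic PTB-XL-shaped corpora for end-to-end testing.

The generator emits 10 s, 12-lead records with class-dependent structure:
each class plants a lead-signature (12 amplitudes, millivolts) on a periodic
pulse train at a class-specific dominant frequency, plus i.i.d. Gaussian
noise. Demographics can carry class signal too (an additive age shift and a
sex log-odds per class), which lets the demographic branch of a fusion model
be tested in isolation. Waveforms are pulse trains, not morphologically
realistic P-QRS-T complexes: the point is controllable, recoverable class
structure, not physiological fidelity.

Folds are assigned uniformly at random over 1-10 (one record per synthetic
patient, so patient-level stratification is moot). Everything is a pure
function of the config, including its seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import ECGRecord
from .taxonomy import LEAD_NAMES, SUBCLASSES
from .wfdb_io import write_wfdb

# Base demographic distribution: mean age and spread loosely emulating a
# large adult clinical ECG cohort (ages clipped to 18-95), sexes near-balanced.
BASE_AGE_MEAN = 55.0
BASE_AGE_SD = 17.0
AGE_RANGE = (18.0, 95.0)
BASE_MALE_LOGIT = 0.08  # ~52% male

PULSE_WIDTH_S = 0.05  # Gaussian bump width of the pulse train


@dataclass(frozen=True)
class ClassSpec:
    """One synthetic class: SCP code, prevalence and planted structure."""

    code: str
    prevalence: float
    lead_signature: tuple[float, ...]  # 12 amplitudes, mV
    dominant_freq: float = 1.2  # Hz, heart-rate scale
    age_shift: float = 0.0  # years added to the base age draw
    sex_log_odds: float = 0.0  # added to the base male logit

    def __post_init__(self) -> None:
        if len(self.lead_signature) != 12:
            raise ValueError("lead_signature must have 12 entries")
        if any(a < 0 for a in self.lead_signature):
            raise ValueError("lead amplitudes must be >= 0")
        if self.code not in SUBCLASSES:
            raise ValueError(f"{self.code!r} is not a taxonomy subclass code")


@dataclass(frozen=True)
class SynthesisConfig:
    n_records: int
    class_spec: tuple[ClassSpec, ...]
    fs: int = 100
    noise_sd: float = 0.05  # mV, baseline wander + muscle noise scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        total = sum(c.prevalence for c in self.class_spec)
        if not self.class_spec or abs(total - 1.0) > 1e-9:
            raise ValueError("class prevalences must sum to 1")


@dataclass
class SyntheticCorpus:
    """Generated records plus the class assignment that produced them."""

    records: list[ECGRecord]
    class_codes: list[str]
    config: SynthesisConfig

    def __len__(self) -> int:
        return len(self.records)


def _pulse_train(
    n: int, fs: int, freq: float, phase: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-amplitude train of Gaussian bumps at `freq` Hz."""
    t = np.arange(n) / fs
    period = 1.0 / freq
    # distance of each sample to the nearest bump centre
    offset = (t + phase) % period
    d = np.minimum(offset, period - offset)
    return np.exp(-0.5 * (d / PULSE_WIDTH_S) ** 2)


def generate_corpus(config: SynthesisConfig) -> SyntheticCorpus:
    """Draw a corpus from the generative model; pure function of config."""
    rng = np.random.default_rng(config.seed)
    n_samples = 10 * config.fs
    prevalences = np.array([c.prevalence for c in config.class_spec])
    class_idx = rng.choice(len(config.class_spec), size=config.n_records, p=prevalences)
    folds = rng.integers(1, 11, size=config.n_records)
    records: list[ECGRecord] = []
    codes: list[str] = []
    for i in range(config.n_records):
        spec = config.class_spec[class_idx[i]]
        phase = rng.uniform(0.0, 1.0 / spec.dominant_freq)
        pulse = _pulse_train(n_samples, config.fs, spec.dominant_freq, phase, rng)
        signature = np.asarray(spec.lead_signature)
        signal = pulse[:, None] * signature[None, :]
        if config.noise_sd > 0:
            signal = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)
        age = float(
            np.clip(
                rng.normal(BASE_AGE_MEAN + spec.age_shift, BASE_AGE_SD), *AGE_RANGE
            )
        )
        p_male = 1.0 / (1.0 + np.exp(-(BASE_MALE_LOGIT + spec.sex_log_odds)))
        sex = "male" if rng.uniform() < p_male else "female"
        records.append(
            ECGRecord(
                record_id=f"synth{i:05d}",
                signal=signal,
                fs=config.fs,
                age=age,
                sex=sex,
                scp_codes={spec.code: 100.0},
                fold=int(folds[i]),
            )
        )
        codes.append(spec.code)
    return SyntheticCorpus(records=records, class_codes=codes, config=config)


def _scp_statements_table() -> pd.DataFrame:
    rows = {
        code: {
            "description": desc,
            "diagnostic": 1,
            "diagnostic_class": sup,
            "diagnostic_subclass": code,
        }
        for code, (sup, desc) in SUBCLASSES.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def metadata_tables(corpus: SyntheticCorpus) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two CSV tables (record metadata, SCP statements) for a corpus."""
    rows = {}
    for rec in corpus.records:
        rows[rec.record_id] = {
            "age": rec.age,
            "sex": 1 if rec.sex == "female" else 0,
            "scp_codes": repr({k: float(v) for k, v in rec.scp_codes.items()}),
            "strat_fold": rec.fold,
            "filename_lr": f"records100/{rec.record_id}",
            "filename_hr": f"records500/{rec.record_id}",
        }
    meta = pd.DataFrame.from_dict(rows, orient="index")
    meta.index.name = "ecg_id"
    return meta, _scp_statements_table()


def write_wfdb_fixture(corpus: SyntheticCorpus, out_dir: str) -> str:
    """Write a corpus as a PTB-XL-dialect file tree.

    Produces ``<out_dir>/records{100|500}/<id>.{hea,dat}`` plus
    ``ptbxl_database.csv`` and ``scp_statements.csv``. Round-trip through
    the corpus reader reproduces signals to the WFDB quantization bound
    (0.5 µV at the default gain) and metadata exactly.
    """
    sub = "records100" if corpus.config.fs == 100 else "records500"
    rec_dir = os.path.join(out_dir, sub)
    os.makedirs(rec_dir, exist_ok=True)
    for rec in corpus.records:
        write_wfdb(
            os.path.join(rec_dir, rec.record_id),
            rec.signal,
            rec.fs,
            list(LEAD_NAMES),
        )
    meta, scp = metadata_tables(corpus)
    meta.to_csv(os.path.join(out_dir, "ptbxl_database.csv"))
    scp.to_csv(os.path.join(out_dir, "scp_statements.csv"))
    return out_dir


def disjoint_lead_spec(
    codes: list[str],
    amplitude: float = 1.0,
    prevalences: list[float] | None = None,
) -> tuple[ClassSpec, ...]:
    """Classes with disjoint single-lead signatures and distinct rates.

    Class i plants `amplitude` mV on lead i (cycled over the 12 leads) at a
    dominant frequency stepped across the physiological heart-rate band, so
    both the spatial pattern and the rhythm separate the classes.
    """
    n = len(codes)
    prevalences = prevalences or [1.0 / n] * n
    specs = []
    for i, (code, prev) in enumerate(zip(codes, prevalences)):
        sig = [0.0] * 12
        sig[i % 12] = amplitude
        specs.append(
            ClassSpec(
                code=code,
                prevalence=prev,
                lead_signature=tuple(sig),
                dominant_freq=1.0 + 0.25 * i,
            )
        )
    return tuple(specs)


def demographic_only_spec(
    codes: list[str],
    age_step: float = 20.0,
    sex_log_odds_step: float = 1.5,
) -> tuple[ClassSpec, ...]:
    """Classes indistinguishable in the waveform, separable by demographics.

    All classes share the same lead signature and dominant frequency; class i
    shifts mean age by ``i * age_step`` years and the male log-odds by
    ``i * sex_log_odds_step``. Only a model that consumes demographics can
    beat chance on such a corpus.
    """
    n = len(codes)
    sig = tuple([0.8] * 12)
    return tuple(
        ClassSpec(
            code=code,
            prevalence=1.0 / n,
            lead_signature=sig,
            dominant_freq=1.2,
            age_shift=i * age_step,
            sex_log_odds=i * sex_log_odds_step,
        )
        for i, code in enumerate(codes)
    )
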