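"""Core record types: one 12-lead ECG with demographics, and its labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .taxonomy import SUBCLASSES, canonical_subclass, superclass_of

N_LEADS = 12
RECORD_SECONDS = 10
VALID_SAMPLING_RATES = (100, 500)


@dataclass
class ECGRecord:
    """A single 10 s, 12-lead ECG with its metadata.

    ``signal`` is (time samples, 12) in millivolts, leads in the standard
    order I, II, III, aVR, aVL, aVF, V1-V6. ``scp_codes`` maps SCP statement
    codes to likelihoods in [0, 100]. ``fold`` is the stratification fold
    (1-10) that drives the train/validation/test split. ``age`` (years) and
    ``sex`` ("male"/"female") may be missing (None).
    """

    record_id: str
    signal: np.ndarray
    fs: int
    age: float | None = None
    sex: str | None = None
    scp_codes: dict[str, float] = field(default_factory=dict)
    fold: int | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2 or self.signal.shape[1] != N_LEADS:
            raise ValueError(
                f"signal must be (samples, {N_LEADS}); got {self.signal.shape}"
            )
        if self.fs not in VALID_SAMPLING_RATES:
            raise ValueError(f"fs must be one of {VALID_SAMPLING_RATES}")
        expected = RECORD_SECONDS * self.fs
        if self.signal.shape[0] != expected:
            raise ValueError(
                f"expected {expected} samples at {self.fs} Hz, "
                f"got {self.signal.shape[0]}"
            )
        if self.fold is not None and not 1 <= self.fold <= 10:
            raise ValueError(f"fold must be in 1..10, got {self.fold}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]


@dataclass(frozen=True)
class DiagnosticLabel:
    """A resolved single diagnosis: superclass plus optional subclass."""

    superclass: str
    subclass: str | None = None

    def __post_init__(self) -> None:
        if self.subclass is not None:
            sub = canonical_subclass(self.subclass)
            if sub not in SUBCLASSES:
                raise ValueError(f"unknown subclass {self.subclass!r}")
            object.__setattr__(self, "subclass", sub)
            if superclass_of(sub) != self.superclass:
                raise ValueError(
                    f"subclass {sub} does not belong to {self.superclass}"
                )


def assign_split(fold: int) -> str:
    """Map a stratification fold to its partition.

    Folds 1-8 train, fold 9 validation, fold 10 test — the split recommended
    by the PTB-XL curators so results stay comparable across studies.
    """
    if not isinstance(fold, (int, np.integer)) or isinstance(fold, bool):
        raise ValueError(f"fold must be an integer, got {fold!r}")
    if not 1 <= fold <= 10:
        raise ValueError(f"fold must be in 1..10, got {fold}")
    if fold <= 8:
        return "train"
    return "validation" if fold == 9 else "test"
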