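"""Classification task definitions over the diagnostic taxonomy.

Every task is a :class:`Scenario`: an ordered class list plus a rule mapping
a resolved :class:`~ecgfusion.records.DiagnosticLabel` to a class index (or
exclusion). The tasks mirror the study design they come from:

* binary, case 1 — normal vs one disease superclass (CD, HYP, MI, STTC);
* binary, case 2 — normal vs one of nine disease subclasses;
* binary, case 3 — normal vs abnormal (any single disease);
* multiclass — 5 superclasses, or NORM plus the top 9/14 subclasses by
  training-set frequency (10- and 15-class tasks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import yaml

from .records import ECGRecord, DiagnosticLabel
from .taxonomy import SUBCLASS_ORDER, SUBCLASSES

logger = logging.getLogger(__name__)

#: Superclass order of the 5-class task.
FIVE_CLASS_ORDER = ("NORM", "MI", "CD", "STTC", "HYP")

#: Subclasses eligible for the binary subclass task (case 2).
BINARY_SUBCLASS_CHOICES = (
    "STTC", "AMI", "IMI", "LAFB/LPFB", "LVH", "IRBBB", "CLBBB", "ISCA", "CRBBB",
)

#: Printed class orders of the subclass tasks on the reference corpus.
TEN_CLASS_ORDER = (
    "NORM", "STTC", "AMI", "IMI", "LAFB/LPFB",
    "LVH", "IRBBB", "CLBBB", "ISCA", "CRBBB",
)
FIFTEEN_CLASS_ORDER = (
    "NORM", "STTC", "AMI", "IMI", "LAFB/LPFB", "LVH", "IRBBB", "CLBBB",
    "NST_", "ISCA", "CRBBB", "IVCD", "ISC_", "_AVB", "ISCI",
)


@dataclass(frozen=True)
class Scenario:
    """A classification task: ordered classes + label rule.

    ``granularity`` is one of ``superclass``, ``subclass`` or
    ``normal_abnormal`` and determines how a DiagnosticLabel is matched
    against ``class_names``.
    """

    name: str
    class_names: tuple[str, ...]
    granularity: str

    def __post_init__(self) -> None:
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class names must be unique")
        if self.granularity not in ("superclass", "subclass", "normal_abnormal"):
            raise ValueError(f"unknown granularity {self.granularity!r}")

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def label_index(self, label: object) -> int | None:
        """Class index for a resolved label, or None if excluded.

        The sentinels ``"unlabeled"`` / ``"ambiguous"`` are always excluded:
        single-label tasks require exactly one diagnosis per record.
        """
        if not isinstance(label, DiagnosticLabel):
            return None
        if self.granularity == "normal_abnormal":
            return 0 if label.superclass == "NORM" else 1
        if self.granularity == "superclass":
            name = label.superclass
        else:
            # NORM matches at either tier; diseases need a resolved subclass.
            if label.superclass == "NORM":
                name = "NORM"
            elif label.subclass is None:
                return None
            else:
                name = label.subclass
        try:
            return self.class_names.index(name)
        except ValueError:
            return None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "class_names": list(self.class_names),
            "granularity": self.granularity,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scenario":
        return cls(
            name=d["name"],
            class_names=tuple(d["class_names"]),
            granularity=d["granularity"],
        )

    @classmethod
    def from_yaml(cls, text: str) -> "Scenario":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class LabeledDataset:
    """Records of one partition materialized under a scenario."""

    records: list[tuple[ECGRecord, int]]
    partition: str
    scenario: Scenario

    def __post_init__(self) -> None:
        k = self.scenario.num_classes
        for _, idx in self.records:
            if not 0 <= idx < k:
                raise ValueError(f"class index {idx} out of range 0..{k - 1}")

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(self.scenario.class_names, 0)
        for _, idx in self.records:
            counts[self.scenario.class_names[idx]] += 1
        return counts


def binary_superclass(disease: str) -> Scenario:
    """Case 1: normal vs one disease superclass."""
    if disease not in ("CD", "HYP", "MI", "STTC"):
        raise ValueError(f"unknown disease superclass {disease!r}")
    return Scenario(
        name=f"binary-NORM-vs-{disease}",
        class_names=("NORM", disease),
        granularity="superclass",
    )


def binary_subclass(disease: str) -> Scenario:
    """Case 2: normal vs one disease subclass."""
    if disease not in BINARY_SUBCLASS_CHOICES:
        raise ValueError(f"unknown disease subclass {disease!r}")
    return Scenario(
        name=f"binary-NORM-vs-{disease}",
        class_names=("NORM", disease),
        granularity="subclass",
    )


def binary_normal_abnormal() -> Scenario:
    """Case 3: normal vs abnormal (any single disease)."""
    return Scenario(
        name="binary-normal-vs-abnormal",
        class_names=("NORM", "abnormal"),
        granularity="normal_abnormal",
    )


def multiclass(k: int, class_counts: Mapping[str, int] | None = None) -> Scenario:
    """The 5/10/15-class task.

    k=5 uses the five superclasses. k=10/15 keep NORM plus the k-1 most
    frequent disease subclasses of ``class_counts`` (training-set counts, so
    the held-out data cannot influence class selection); ties at the cutoff
    break by taxonomy order and are logged. If the selected set matches the
    reference corpus's printed list, that printed order is used; otherwise
    classes follow NORM-first descending-count order.
    """
    if k == 5:
        return Scenario(
            name="multiclass-5-superclass",
            class_names=FIVE_CLASS_ORDER,
            granularity="superclass",
        )
    if k not in (10, 15):
        raise ValueError(f"k must be one of 5, 10, 15; got {k}")
    if class_counts is None:
        raise ValueError("class_counts table required for subclass tasks")
    candidates = [
        c for c in class_counts
        if c in SUBCLASSES and SUBCLASSES[c][0] != "NORM"
    ]
    # sort by count desc, tie-break by taxonomy order
    ranked = sorted(
        candidates, key=lambda c: (-int(class_counts[c]), SUBCLASS_ORDER[c])
    )
    if len(ranked) < k - 1:
        raise ValueError(
            f"need at least {k - 1} disease subclasses with counts; "
            f"got {len(ranked)}"
        )
    chosen = ranked[: k - 1]
    cutoff = int(class_counts[chosen[-1]])
    tied = [c for c in ranked[k - 1 :] if int(class_counts[c]) == cutoff]
    if tied:
        logger.info(
            "top-%d cutoff at count %d broke ties by taxonomy order "
            "(excluded: %s)", k - 1, cutoff, tied,
        )
    selected = set(chosen) | {"NORM"}
    for printed in (TEN_CLASS_ORDER, FIFTEEN_CLASS_ORDER):
        if len(printed) == k and selected == set(printed):
            order = printed
            break
    else:
        order = ("NORM", *chosen)
    return Scenario(
        name=f"multiclass-{k}-subclass",
        class_names=tuple(order),
        granularity="subclass",
    )


def training_subclass_counts(
    corpus: list[tuple[ECGRecord, object]],
) -> dict[str, int]:
    """Subclass frequencies over the training folds of a labeled corpus."""
    from .records import assign_split

    counts: dict[str, int] = {}
    for rec, label in corpus:
        if not isinstance(label, DiagnosticLabel) or label.subclass is None:
            continue
        if rec.fold is None or assign_split(rec.fold) != "train":
            continue
        counts[label.subclass] = counts.get(label.subclass, 0) + 1
    return counts


def materialize(
    corpus: list[tuple[ECGRecord, object]],
    scenario: Scenario,
) -> dict[str, LabeledDataset]:
    """Split a labeled corpus into train/validation/test LabeledDatasets.

    Records failing the scenario's inclusion rule (wrong class, ambiguous,
    unlabeled) are dropped; counts of exclusions are logged.
    """
    from .records import assign_split

    buckets: dict[str, list[tuple[ECGRecord, int]]] = {
        "train": [], "validation": [], "test": [],
    }
    excluded = 0
    for rec, label in corpus:
        idx = scenario.label_index(label)
        if idx is None:
            excluded += 1
            continue
        if rec.fold is None:
            raise ValueError(f"record {rec.record_id} has no fold")
        buckets[assign_split(rec.fold)].append((rec, idx))
    if excluded:
        logger.info(
            "scenario %s: excluded %d record(s)", scenario.name, excluded
        )
    return {
        part: LabeledDataset(records=recs, partition=part, scenario=scenario)
        for part, recs in buckets.items()
    }
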