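"""Shared fixtures: synthetic corpora and (session-scoped) trained models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ecgfusion as ef
from ecgfusion.records import DiagnosticLabel
from ecgfusion.synth import (
    SynthesisConfig,
    demographic_only_spec,
    disjoint_lead_spec,
    metadata_tables,
)
from ecgfusion.taxonomy import SUBCLASSES


@pytest.fixture(scope="session")
def taxonomy_df() -> pd.DataFrame:
    """Code -> (superclass, subclass) mapping table, as a corpus would carry."""
    return pd.DataFrame.from_dict(
        {c: {"superclass": s, "subclass": c} for c, (s, _) in SUBCLASSES.items()},
        orient="index",
    )


def label_corpus(corpus, taxonomy):
    """Attach resolved labels to every record of a synthetic corpus."""
    return [
        (r, ef.map_scp_to_label(r.scp_codes, taxonomy)) for r in corpus.records
    ]


@pytest.fixture(scope="session")
def binary_corpus(taxonomy_df):
    """64 records, two classes with disjoint planted leads (NORM on lead I,
    IMI on lead II) — linearly separable by construction."""
    config = SynthesisConfig(
        n_records=64, class_spec=disjoint_lead_spec(["NORM", "IMI"]), seed=11
    )
    return label_corpus(ef.generate_corpus(config), taxonomy_df)


@pytest.fixture(scope="session")
def fiveclass_corpus(taxonomy_df):
    """400 records over five classes with distinct lead signatures."""
    config = SynthesisConfig(
        n_records=400,
        class_spec=disjoint_lead_spec(["NORM", "IMI", "CLBBB", "LVH", "ISCA"]),
        seed=12,
    )
    return label_corpus(ef.generate_corpus(config), taxonomy_df)


@pytest.fixture(scope="session")
def demographic_corpus(taxonomy_df):
    """400 records whose waveforms are class-identical; only age/sex separate
    the classes (tests the demographic branch in isolation)."""
    config = SynthesisConfig(
        n_records=400,
        class_spec=demographic_only_spec(["NORM", "IMI"]),
        seed=13,
    )
    return label_corpus(ef.generate_corpus(config), taxonomy_df)


@pytest.fixture(scope="session")
def overfit_binary_model(binary_corpus):
    """Custom CNN fitted to the full 64-record separable binary corpus
    (train == validation: a capacity/overfit check, and the fitted model
    reused by attribution tests)."""
    scenario = ef.binary_superclass("MI")
    records = [
        (r, scenario.label_index(lab))
        for r, lab in binary_corpus
        if scenario.label_index(lab) is not None
    ]
    dataset = ef.LabeledDataset(records=records, partition="train",
                                scenario=scenario)
    model = ef.build_model(
        ef.ModelConfig("custom_cnn", input_length=1000, num_classes=2, seed=0)
    )
    history = ef.train(model, dataset, dataset, ef.TrainConfig(seed=0))
    return model, dataset, history


@pytest.fixture(scope="session")
def fiveclass_run(fiveclass_corpus):
    """Custom CNN trained on the 5-class corpus under the fold split."""
    scenario = ef.multiclass(5)
    parts = ef.materialize(fiveclass_corpus, scenario)
    model = ef.build_model(
        ef.ModelConfig("custom_cnn", input_length=1000, num_classes=5, seed=0)
    )
    history = ef.train(model, parts["train"], parts["validation"],
                       ef.TrainConfig(seed=0))
    test = parts["test"]
    proba = ef.predict_proba(model, [r for r, _ in test.records])
    actual = np.array([y for _, y in test.records])
    report = ef.evaluate(actual, proba.argmax(axis=1),
                         scenario.class_names, scenario.name, "test")
    return model, parts, history, report


@pytest.fixture(scope="session")
def ablation_accuracies(demographic_corpus, taxonomy_df):
    """Accuracy with and without the demographic branch on the
    demographics-only corpus. Both models are evaluated on a 400-record
    corpus drawn independently from the same generative model, so the
    measured margin carries ~2-3 point sampling error rather than the
    ~8 points a 40-record fold would."""
    scenario = ef.binary_superclass("MI")
    parts = ef.materialize(demographic_corpus, scenario)
    eval_config = SynthesisConfig(
        n_records=400,
        class_spec=demographic_only_spec(["NORM", "IMI"]),
        seed=113,
    )
    eval_records = [
        (r, scenario.label_index(lab))
        for r, lab in label_corpus(ef.generate_corpus(eval_config), taxonomy_df)
        if scenario.label_index(lab) is not None
    ]
    actual = np.array([y for _, y in eval_records])
    accs = {}
    for use_demo in (True, False):
        model = ef.build_model(
            ef.ModelConfig("custom_cnn", input_length=1000, num_classes=2,
                           use_demographics=use_demo, seed=0)
        )
        ef.train(model, parts["train"], parts["validation"],
                 ef.TrainConfig(seed=0))
        proba = ef.predict_proba(model, [r for r, _ in eval_records])
        accs[use_demo] = float((proba.argmax(axis=1) == actual).mean())
    return accs
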