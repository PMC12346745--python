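"""Optional end-to-end reproduction on a real PTB-XL v1.0.3 download.

Requires the 100 Hz record tree plus `ptbxl_database.csv` and
`scp_statements.csv` (physionet.org/content/ptb-xl). Runs the binary and
multiclass scenarios with the custom CNN and prints test accuracies for
qualitative comparison with published results. Not part of the test
surface; expect hours of CPU time at full corpus scale (use --limit for a
subsampled dry run).

    python scripts/reproduce_ptbxl.py --data /path/to/ptb-xl --limit 2000
"""

from __future__ import annotations

import argparse

import numpy as np

import ecgfusion as ef
from ecgfusion.scenarios import training_subclass_counts


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", required=True, help="PTB-XL root directory")
    parser.add_argument("--limit", type=int, default=None,
                        help="Use only the first N records (dry runs)")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--scenarios", default="super:MI,super:STTC,5",
                        help="Comma-separated scenario names "
                             "(super:<CLS>, sub:<CLS>, normal-abnormal, 5, 10, 15)")
    args = parser.parse_args()

    print(f"loading corpus from {args.data} ...")
    corpus = ef.load_corpus(args.data, fs=100)
    if args.limit:
        corpus = corpus[: args.limit]
    print(f"{len(corpus)} records loaded")

    for name in args.scenarios.split(","):
        name = name.strip()
        if name.startswith("super:"):
            scenario = ef.binary_superclass(name.split(":")[1])
        elif name.startswith("sub:"):
            scenario = ef.binary_subclass(name.split(":")[1])
        elif name == "normal-abnormal":
            scenario = ef.binary_normal_abnormal()
        else:
            counts = training_subclass_counts(corpus)
            scenario = ef.multiclass(int(name), counts if name != "5" else None)
        parts = ef.materialize(corpus, scenario)
        print(f"\n=== {scenario.name}: "
              f"{ {p: len(d) for p, d in parts.items()} }")
        model = ef.build_model(
            ef.ModelConfig("custom_cnn", 1000, scenario.num_classes,
                           seed=args.seed)
        )
        ef.train(model, parts["train"], parts["validation"],
                 ef.TrainConfig(seed=args.seed),
                 impute_missing_demographics=True)
        test = parts["test"]
        proba = ef.predict_proba(model, [r for r, _ in test.records])
        actual = np.array([y for _, y in test.records])
        report = ef.evaluate(actual, proba.argmax(axis=1),
                             scenario.class_names, scenario.name, "test")
        print(report.summary())
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
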