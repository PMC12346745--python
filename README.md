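# ecgfusion

Dual-branch neural networks for 12-lead ECG arrhythmia classification with
demographic fusion and per-lead Shapley attribution.

## The problem

Automatic classification of resting 12-lead ECGs is a standard benchmark
problem on PTB-XL-style corpora: 10-second recordings annotated with SCP
diagnostic statements that roll up into five superclasses (NORM, MI, CD,
STTC, HYP) and 23 subclasses (IMI, CLBBB, LVH, ...). `ecgfusion` is for
researchers who want a complete, inspectable, CPU-runnable implementation
of this pipeline: corpus I/O, single-label task construction (binary,
5/10/15-class), waveform augmentation, two fusion architectures combining
the raw signal with patient age and sex, explicit micro/macro metrics, and
game-theoretic per-lead attribution — plus a synthetic corpus generator so
the whole pipeline is testable without any download.

## The models

Both architectures process the raw (time × 12) signal in a convolutional
branch (kernels 3×1, max-pooling 2×1) and the encoded (age, sex) pair in a
dense branch [100, 64, 32, 16]; branch features are concatenated into a
dense head [10, 10, K] with K-way softmax:

* **custom CNN** — conv filters [32, 64, 128, 256, 512] with batch norm
  after each pool; dense [100, 32], dropout 0.4;
* **VGG-style** — conv filters [64, 64, 128, 128, 256, 256, 512, 512];
  global average pooling; dense [512, 512], dropout 0.5.

Training: Adam (lr 0.001), cross-entropy, batch 16, ≤60 epochs, early
stopping, LR reduction on plateau, best-validation-loss checkpointing.

Lead attribution treats the 12 leads as players in a cooperative game whose
value is the predicted class probability under lead masking. The exact
Shapley value φ_l is enumerated over all 2¹² coalitions (the oracle); a
permutation-sampling estimator scales to many records. Per-class lead
importance is I_l = (1/N) Σᵢ |φ_{il}|.

## Worked example

Generate a 2-class synthetic corpus in which normal records carry their
signal on lead I and inferior-MI records on lead II, train the custom CNN,
evaluate, and attribute:

```python
import numpy as np
import ecgfusion as ef
from ecgfusion.synth import SynthesisConfig, disjoint_lead_spec

# 200 records, two classes with disjoint planted leads
config = SynthesisConfig(
    n_records=200, class_spec=disjoint_lead_spec(["NORM", "IMI"]), seed=7,
)
corpus = ef.generate_corpus(config)
ef.write_wfdb_fixture(corpus, "scratch/demo_corpus")

pairs = ef.load_corpus("scratch/demo_corpus")      # [(ECGRecord, label), ...]
scenario = ef.binary_superclass("MI")              # classes (NORM, MI)
parts = ef.materialize(pairs, scenario)            # fold split 1-8/9/10

model = ef.build_model(ef.ModelConfig("custom_cnn", 1000, 2, seed=0))
ef.train(model, parts["train"], parts["validation"], ef.TrainConfig(seed=0))

test = parts["test"]
proba = ef.predict_proba(model, [r for r, _ in test.records])
report = ef.evaluate([y for _, y in test.records], proba.argmax(axis=1),
                     scenario.class_names, scenario.name, "test")
print(report.summary())

for li in ef.per_class_importance(model, test, n_permutations=16, seed=0,
                                  normalization="sum-to-one"):
    top = max(li.as_dict().items(), key=lambda kv: kv[1])
    print(f"{li.class_label}: top lead {top[0]} ({top[1]:.2f})")
```

Output:

```
scenario: binary-NORM-vs-MI [test] (n=10)
accuracy=1.0000  precision(micro)=1.0000  recall(micro)=1.0000  F1(macro)=1.0000
  NORM         precision=1.0000 recall=1.0000 f1=1.0000
  MI           precision=1.0000 recall=1.0000 f1=1.0000
NORM: top lead I (0.43)
MI: top lead II (1.00)
```

The confusion matrix is perfectly diagonal because the two classes are
separable by construction, and the attribution recovers the planted
structure: the model's NORM probability is driven mainly by lead I and its
MI probability by lead II — exactly where the generator put the class
signal.

The same pipeline is scriptable from the shell:

```bash
ecgfusion synth --out scratch/demo --n-records 200 --classes NORM,IMI --seed 7
ecgfusion train --corpus scratch/demo --scenario super:MI --arch cnn
ecgfusion explain --corpus scratch/demo --scenario super:MI \
    --out scratch/importance.json --heatmap scratch/importance.png
```

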