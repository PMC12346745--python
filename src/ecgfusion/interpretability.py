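"""Per-lead Shapley attribution for 12-lead ECG classifiers.

Each of the 12 leads is a player in a cooperative game whose value v(S) is
the model's predicted probability of a target class when the leads outside
the coalition S are replaced by a baseline (zeros, or a reference signal
such as the training mean). With only 12 players, the exact Shapley value

    phi_l = sum over S subseteq leads\\{l} of |S|! (11-|S|)! / 12! *
            [v(S u {l}) - v(S)]

is computable by full enumeration of the 4096 coalitions and serves as the
oracle for the cheaper Monte-Carlo permutation estimator. Per-class lead
importance is the mean of absolute per-record attributions,
I_l = (1/N) sum_i |phi_il| (a signed mean is available as an option), with
optional sum-to-one normalization for cross-class comparison.

Demographic inputs are never masked: attribution is over the ECG leads only.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .nn import DualBranchNet, softmax
from .scenarios import LabeledDataset
from .taxonomy import LEAD_NAMES

logger = logging.getLogger(__name__)

N_LEADS = 12
_N_COALITIONS = 1 << N_LEADS

#: Shapley coalition weight by coalition size |S| (excluding the player).
_WEIGHTS = np.array(
    [
        math.factorial(s) * math.factorial(N_LEADS - 1 - s) / math.factorial(N_LEADS)
        for s in range(N_LEADS)
    ]
)

# bitmask -> boolean lead-inclusion table and popcounts, built once
_MASK_TABLE = (
    (np.arange(_N_COALITIONS)[:, None] >> np.arange(N_LEADS)[None, :]) & 1
).astype(bool)
_POPCOUNT = _MASK_TABLE.sum(axis=1)


@dataclass(frozen=True)
class MaskingScheme:
    """How masked-out leads are replaced.

    ``baseline="zeros"`` silences a lead entirely; ``baseline="mean"``
    substitutes a reference signal (pass it via ``baseline_signal``,
    typically the per-lead training mean).
    """

    baseline: str = "zeros"
    baseline_signal: np.ndarray | None = None

    def baseline_for(self, signal: np.ndarray) -> np.ndarray:
        if self.baseline == "zeros":
            return np.zeros_like(signal)
        if self.baseline == "mean":
            if self.baseline_signal is None:
                raise ValueError("baseline='mean' needs baseline_signal")
            return np.broadcast_to(self.baseline_signal, signal.shape)
        raise ValueError(f"unknown baseline {self.baseline!r}")


@dataclass
class LeadImportance:
    """Per-class vector of 12 non-negative lead weights."""

    class_label: str
    importance: np.ndarray
    n_samples: int
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=np.float64)
        if self.importance.shape != (N_LEADS,):
            raise ValueError("importance must be a 12-vector")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(LEAD_NAMES, self.importance.tolist()))


def _model_value_fn(model: DualBranchNet, demographics, target_class: int):
    """Probability of `target_class` as a function of the (masked) signal."""
    demo = None
    if model.use_demographics:
        if demographics is None:
            raise ValueError("model expects demographics")
        demo = np.asarray(demographics, dtype=np.float32).reshape(1, 2)

    def value_fn(batch: np.ndarray) -> np.ndarray:
        xd = np.repeat(demo, batch.shape[0], axis=0) if demo is not None else None
        logits = model.forward(batch.astype(np.float32), xd, train=False)
        return softmax(logits.astype(np.float64))[:, target_class]

    return value_fn


def _resolve_value_fn(model, record, demographics, target_class):
    if callable(model) and not isinstance(model, DualBranchNet):
        return model
    if target_class is None:
        raise ValueError("target_class is required for model attribution")
    return _model_value_fn(model, demographics, target_class)


def _masked_batch(signal, baseline, include_rows):
    inc = include_rows[:, None, :]  # (m, 1, 12)
    return np.where(inc, signal[None], baseline[None])


def _evaluate_coalitions(value_fn, signal, baseline, include_rows, chunk=256):
    out = np.empty(include_rows.shape[0])
    for i in range(0, include_rows.shape[0], chunk):
        batch = _masked_batch(signal, baseline, include_rows[i:i + chunk])
        out[i:i + chunk] = np.asarray(value_fn(batch), dtype=np.float64)
    return out


def exact_lead_shapley(
    model,
    record_signal: np.ndarray,
    demographics: np.ndarray | None = None,
    scheme: MaskingScheme = MaskingScheme(),
    target_class: int | None = None,
    chunk: int = 256,
) -> np.ndarray:
    """Exact Shapley attribution of the 12 leads by full enumeration.

    ``model`` is either a fitted :class:`DualBranchNet` (then
    ``target_class`` selects the attributed probability) or any callable
    mapping a batch of signals (m, L, 12) to m scalar values. Satisfies
    efficiency: ``phi.sum() == v(all) - v(empty)`` up to float tolerance.
    """
    signal = np.asarray(record_signal, dtype=np.float64)
    if signal.ndim != 2 or signal.shape[1] != N_LEADS:
        raise ValueError(f"signal must be (samples, {N_LEADS})")
    value_fn = _resolve_value_fn(model, signal, demographics, target_class)
    baseline = scheme.baseline_for(signal)
    v = _evaluate_coalitions(value_fn, signal, baseline, _MASK_TABLE, chunk)
    phi = np.empty(N_LEADS)
    masks = np.arange(_N_COALITIONS)
    for lead in range(N_LEADS):
        bit = 1 << lead
        without = masks[(masks & bit) == 0]
        w = _WEIGHTS[_POPCOUNT[without]]
        phi[lead] = float(np.sum(w * (v[without | bit] - v[without])))
    return phi


def sampled_lead_shapley(
    model,
    record_signal: np.ndarray,
    demographics: np.ndarray | None = None,
    scheme: MaskingScheme = MaskingScheme(),
    target_class: int | None = None,
    n_permutations: int = 64,
    seed: int | np.random.Generator = 0,
    chunk: int = 256,
) -> np.ndarray:
    """Monte-Carlo permutation estimate of the per-lead Shapley values.

    Averages, over random lead orderings, the marginal gain of adding each
    lead to the leads preceding it — an unbiased estimator of the exact
    enumeration that :func:`exact_lead_shapley` computes.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    signal = np.asarray(record_signal, dtype=np.float64)
    if signal.ndim != 2 or signal.shape[1] != N_LEADS:
        raise ValueError(f"signal must be (samples, {N_LEADS})")
    value_fn = _resolve_value_fn(model, signal, demographics, target_class)
    baseline = scheme.baseline_for(signal)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    perms = np.stack([rng.permutation(N_LEADS) for _ in range(n_permutations)])
    # prefix inclusion masks: (n_perm, 13, 12); prefix j includes perm[:j]
    include = np.zeros((n_permutations, N_LEADS + 1, N_LEADS), dtype=bool)
    for j in range(1, N_LEADS + 1):
        include[:, j] = include[:, j - 1]
        include[np.arange(n_permutations), j, perms[:, j - 1]] = True
    v = _evaluate_coalitions(
        value_fn, signal, baseline,
        include.reshape(-1, N_LEADS), chunk,
    ).reshape(n_permutations, N_LEADS + 1)
    marginals = np.diff(v, axis=1)  # (n_perm, 12) in permutation order
    phi = np.zeros(N_LEADS)
    np.add.at(phi, perms.ravel(), marginals.ravel())
    return phi / n_permutations


def lead_importance(
    attributions: np.ndarray,
    normalization: str = "raw",
    class_label: str = "",
    signed: bool = False,
) -> LeadImportance:
    """Aggregate per-record attributions into a lead-importance vector.

    Default is the mean of absolute values, I_l = (1/N) sum_i |phi_il|;
    ``signed=True`` gives the plain mean instead. ``normalization``:
    ``raw`` or ``sum-to-one``.
    """
    attributions = np.atleast_2d(np.asarray(attributions, dtype=np.float64))
    if attributions.shape[0] < 1 or attributions.shape[1] != N_LEADS:
        raise ValueError("attributions must be (N, 12) with N >= 1")
    vals = attributions if signed else np.abs(attributions)
    imp = vals.mean(axis=0)
    if normalization == "sum-to-one":
        total = imp.sum()
        if total > 0:
            imp = imp / total
    elif normalization != "raw":
        raise ValueError(f"unknown normalization {normalization!r}")
    return LeadImportance(
        class_label=class_label,
        importance=imp,
        n_samples=attributions.shape[0],
        normalization=normalization,
    )


def per_class_importance(
    model: DualBranchNet,
    dataset: LabeledDataset,
    scheme: MaskingScheme = MaskingScheme(),
    estimator: str = "sampled",
    n_permutations: int = 32,
    seed: int = 0,
    normalization: str = "raw",
    max_records_per_class: int | None = None,
) -> list[LeadImportance]:
    """Lead importance per class over a (test) dataset.

    Records are grouped by their actual class; the value function is the
    model's probability of that class. Classes without records are omitted
    with a warning. ``estimator`` is ``"sampled"`` or ``"exact"``.
    """
    if estimator not in ("sampled", "exact"):
        raise ValueError(f"unknown estimator {estimator!r}")
    scaler = getattr(model, "demo_scaler", None)
    rng = np.random.default_rng(seed)
    out: list[LeadImportance] = []
    names = dataset.scenario.class_names
    for c, name in enumerate(names):
        recs = [r for r, y in dataset.records if y == c]
        if not recs:
            warnings.warn(
                f"class {name!r} has no records; omitted", RuntimeWarning,
                stacklevel=2,
            )
            continue
        if max_records_per_class is not None:
            recs = recs[:max_records_per_class]
        rows = []
        for rec in recs:
            demo = None
            if model.use_demographics:
                if scaler is None:
                    raise ValueError("model has no fitted demographic scaler")
                demo = scaler.transform([rec])[0]
            if estimator == "exact":
                phi = exact_lead_shapley(
                    model, rec.signal, demo, scheme, target_class=c
                )
            else:
                phi = sampled_lead_shapley(
                    model, rec.signal, demo, scheme, target_class=c,
                    n_permutations=n_permutations, seed=rng,
                )
            rows.append(phi)
        out.append(
            lead_importance(
                np.stack(rows), normalization=normalization, class_label=name
            )
        )
    return out


def plot_lead_importance(importances: list[LeadImportance], ax=None):
    """Classes x 12-leads heatmap of importance vectors."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 1 + 0.5 * len(importances)))
    mat = np.stack([li.importance for li in importances])
    ax.imshow(mat, cmap="viridis", aspect="auto")
    ax.set_xticks(range(N_LEADS), LEAD_NAMES)
    ax.set_yticks(range(len(importances)), [li.class_label for li in importances])
    ax.set_xlabel("lead")
    return ax
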