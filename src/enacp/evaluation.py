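"""Metrics and protocols for benchmarking peptide classifiers.

Implements the confusion-matrix metrics (sensitivity, specificity,
accuracy, Matthews correlation coefficient), rank-based AUC, repeated
stratified k-fold cross-validation with pooled-count aggregation, the
DeLong test for comparing two correlated ROC curves, and the
better/equal/worse "comparison triplet" tabulation across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm, rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive and negative counts of a binary classifier."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("all-zero confusion counts")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape:
            raise ValueError("prediction/label length mismatch")
        return cls(
            tp=int(((yt == 1) & (yp == 1)).sum()),
            fp=int(((yt == 0) & (yp == 1)).sum()),
            tn=int(((yt == 0) & (yp == 0)).sum()),
            fn=int(((yt == 1) & (yp == 0)).sum()),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    """Sn, Sp, Acc, MCC (and optionally AUC) of one evaluation."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float | None = None
    mcc_undefined: bool = False

    def as_dict(self) -> dict[str, float]:
        out = {"Sn": self.sn, "Sp": self.sp, "Acc": self.acc, "MCC": self.mcc}
        if self.auc is not None:
            out["AUC"] = self.auc
        return out


def classification_metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricSet:
    """Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total,
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

    A zero marginal makes the MCC denominator vanish; the value is then
    reported as 0 with ``mcc_undefined`` set, the standard safe convention.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sn = tp / (tp + fn) if (tp + fn) else float("nan")
    sp = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc, undefined = 0.0, True
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(float(denom))
        undefined = False
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=float(mcc), auc=auc,
                     mcc_undefined=undefined)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC via the Mann-Whitney rank identity, ties credited 1/2.

    Equals the probability that a random positive outscores a random
    negative (+ half the tie probability); requires both classes present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(s)  # midranks handle ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """ROC curve as (FPR, TPR) rows by descending-score sweep."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr])


# ---------------------------------------------------------------------------
# DeLong comparison of correlated ROC curves
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and per-instance placement values (midrank construction)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    # V10[i]: fraction of negatives each positive outranks (ties half)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    z: float
    p_value: float
    degenerate: bool = False


def delong_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> DelongResult:
    """Two-sided DeLong test for a difference between paired AUCs.

    Both score vectors must be computed on the same instances; the
    covariance of the two empirical AUCs is estimated from placement
    values and the AUC difference referred to a standard normal. A
    (near-)zero variance — e.g. identical score vectors — is flagged
    degenerate and reported as p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("scores_a, scores_b and labels must be paired")
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("DeLong test requires both classes")
    auc_a, v10_a, v01_a = _placements(a, y)
    auc_b, v10_b, v01_b = _placements(b, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 1e-16:
        return DelongResult(auc_a, auc_b, z=0.0, p_value=1.0, degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(var)
    p = float(2 * norm.sf(abs(z)))
    return DelongResult(auc_a, auc_b, z=float(z), p_value=p)


def comparison_triplets(
    results: Mapping[str, Mapping[tuple[str, str], DelongResult]],
    alpha: float = 0.05,
) -> dict[tuple[str, str], str]:
    """Tabulate better/equal/worse counts across datasets per method pair.

    ``results[dataset][(A, B)]`` holds the DeLong comparison of methods A
    and B on that dataset (either orientation may be stored). For every
    ordered pair the triplet "b/e/w" counts datasets where A is
    significantly better than B (p < alpha and AUC_A > AUC_B), tied
    (p >= alpha), or significantly worse. Missing pairs raise KeyError.
    """
    methods: set[str] = set()
    for table in results.values():
        for pair in table:
            methods.update(pair)
    triplets: dict[tuple[str, str], str] = {}
    for a in sorted(methods):
        for b in sorted(methods):
            if a == b:
                continue
            better = equal = worse = 0
            for dataset, table in results.items():
                if (a, b) in table:
                    res = table[(a, b)]
                    auc_a, auc_b = res.auc_a, res.auc_b
                elif (b, a) in table:
                    res = table[(b, a)]
                    auc_a, auc_b = res.auc_b, res.auc_a
                else:
                    raise KeyError(f"no comparison of {a!r} vs {b!r} on {dataset!r}")
                if res.p_value >= alpha:
                    equal += 1
                elif auc_a > auc_b:
                    better += 1
                else:
                    worse += 1
            triplets[(a, b)] = f"{better}/{equal}/{worse}"
    return triplets


# ---------------------------------------------------------------------------
# Repeated stratified k-fold cross-validation
# ---------------------------------------------------------------------------

@dataclass
class RepeatedCvResult:
    """Per-repeat metric sets plus their mean and population sd."""

    per_repeat: list[MetricSet]
    mean: dict[str, float] = field(init=False)
    sd: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        keys = ["Sn", "Sp", "Acc", "MCC", "AUC"]
        table = {k: np.array([m.as_dict().get(k, np.nan) for m in self.per_repeat])
                 for k in keys}
        self.mean = {k: float(np.mean(v)) for k, v in table.items()}
        # population sd; a single repeat reports 0 by convention
        self.sd = {k: float(np.std(v)) for k, v in table.items()}


def repeated_kfold_cv(
    dataset,
    model_config: Mapping | None = None,
    k: int = 5,
    repeats: int = 30,
    seed: int = 0,
    pssms: Mapping | None = None,
) -> RepeatedCvResult:
    """Repeated stratified k-fold cross-validation of the stacked model.

    Folds are re-drawn each repeat from a seed derived as seed + repeat
    index. Within one repeat, confusion counts are pooled over the k folds
    (micro aggregation) and AUC is computed on the concatenated held-out
    scores; the per-repeat metric sets are then summarized by mean and
    population sd. Feature matrices are computed once and reused across
    folds and repeats, since encoders are deterministic per peptide.
    """
    from .ensemble import build_encoder_bank, cross_val_scores, encode_bank_matrices

    dataset.require_both_classes()
    if min(dataset.n_pos, dataset.n_neg) < k:
        raise ValueError(f"each class must have at least k={k} members")
    config = dict(model_config or {})
    bank = config.pop("bank", None)
    if bank is None:
        bank = build_encoder_bank(
            config.pop("encoders", None), profiles_available=pssms is not None
        )
    matrices = encode_bank_matrices(bank, dataset.records, pssms)
    per_repeat: list[MetricSet] = []
    for r in range(repeats):
        rep_seed = int((seed + 1) * 1009 + r) % (2**31)
        scores = cross_val_scores(
            dataset, bank, matrices=matrices, k=k, seed=rep_seed, **config
        )
        preds = (scores >= 0.5).astype(int)
        counts = ConfusionCounts.from_predictions(dataset.labels, preds)
        auc = roc_auc(scores, dataset.labels)
        per_repeat.append(classification_metrics(counts, auc=auc))
    return RepeatedCvResult(per_repeat=per_repeat)
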