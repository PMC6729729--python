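"""Evaluation: ROC curves, bag-stratified cross-validation, and the
three scoring regimes of the protein application.

AUC is computed as the rank statistic (probability a random positive
outscores a random negative, ties credited ½), which is exactly the
area under the threshold-sweep ROC curve with trapezoidal handling of
tied scores.

Cross-validation is *bag-stratified*: folds partition bags, never
instances, preserving the class ratio, so no protein contributes
residues to both train and test.  Held-out scores are pooled across
folds and reported at three levels:

- ``protein``          — bag-level AUC;
- ``residue_all``      — instance-level AUC over every instance;
- ``residue_posonly``  — instance-level AUC over instances of positive
  bags only (the regime that asks: among a binding protein's residues,
  are the truly binding ones ranked first?).  This needs true instance
  labels, which are used for evaluation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bags import Bag, MILDataset
from .boosting import MILBoost, TrainConfig, sgn

__all__ = [
    "ROCCurve",
    "CVResult",
    "roc_auc",
    "sensitivity_at_specificity",
    "stratified_folds",
    "crossvalidate",
    "residue_type_pr",
    "REGIMES",
]

REGIMES = ("protein", "residue_all", "residue_posonly")


@dataclass
class ROCCurve:
    """Threshold-sweep ROC: ordered (fpr, tpr, threshold) triples.

    The sweep visits each distinct score once, from the highest down,
    so fpr and tpr are non-decreasing with endpoints (0,0) and (1,1).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def points(self):
        return list(zip(self.fpr, self.tpr, self.thresholds))


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve and rank-based AUC for ±1 labels.

    AUC equals the normalised count of concordant (positive, negative)
    score pairs with ties counted half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D vectors")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    # Mann-Whitney rank statistic: exact pairwise concordance with ties 1/2
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # threshold sweep over distinct scores, descending
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, s_sorted.size - 1]  # last index of each score block
    tp = np.cumsum(y_sorted == 1)[idx]
    fp = np.cumsum(y_sorted == -1)[idx]
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    thresholds = np.r_[np.inf, s_sorted[idx]]
    return ROCCurve(fpr, tpr, thresholds, float(auc))


def sensitivity_at_specificity(curve: ROCCurve, specificity: float) -> float:
    """Best achievable sensitivity with fpr ≤ 1 − specificity.

    Conservative: no interpolation between operating points.
    """
    if not 0.0 < specificity < 1.0:
        raise ValueError("specificity must be in (0, 1)")
    ok = curve.fpr <= (1.0 - specificity) + 1e-12
    return float(curve.tpr[ok].max()) if np.any(ok) else 0.0


def stratified_folds(dataset: MILDataset, k: int = 5, seed: int = 0) -> np.ndarray:
    """Assign each bag to one of k folds, preserving the class ratio.

    Bags — never instances — are partitioned, so all residues of a
    protein share its fold.  Deterministic given the seed.
    """
    labels = dataset.labels()
    if k < 2:
        raise ValueError("k must be >= 2")
    for cls in (-1, 1):
        if int(np.sum(labels == cls)) < k:
            raise ValueError(
                f"need at least k={k} bags of class {cls} "
                f"(have {int(np.sum(labels == cls))})"
            )
    rng = np.random.default_rng(seed)
    folds = np.empty(dataset.n, dtype=int)
    for cls in (1, -1):
        idx = np.nonzero(labels == cls)[0]
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


@dataclass
class CVResult:
    """Pooled and per-fold cross-validated AUCs.

    ``pooled`` maps regime → AUC over held-out scores pooled across
    folds; ``per_fold`` holds one row per (fold, regime).
    """

    pooled: dict
    per_fold: pd.DataFrame
    bag_scores: pd.DataFrame
    instance_scores: pd.DataFrame
    k: int
    seed: int

    def summary(self) -> str:
        lines = [
            f"{self.k}-fold bag-stratified cross-validation (seed={self.seed})",
            "-" * 48,
        ]
        for regime in REGIMES:
            if regime in self.pooled:
                lines.append(f"{regime:18s} AUC = {self.pooled[regime]:.4f}")
        return "\n".join(lines)


def _instance_rows(dataset: MILDataset, fold_of_bag) -> pd.DataFrame:
    rows = []
    for i, bag in enumerate(dataset.bags):
        for j, inst in enumerate(bag.instances):
            rows.append({
                "bag_id": bag.bag_id,
                "bag_label": bag.label,
                "fold": fold_of_bag[i],
                "instance_index": j,
                "true_label": inst.true_label,
                "aa": inst.meta.get("aa"),
            })
    return pd.DataFrame(rows)


def crossvalidate(
    dataset: MILDataset,
    config: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
    regimes=REGIMES,
) -> CVResult:
    """k-fold bag-stratified cross-validation of the boosting model.

    Trains on k−1 folds, scores the held-out bags and their instances,
    pools scores across folds and computes AUC per regime.  The
    instance-level regimes need true instance labels (negative-bag
    instances default to −1; positive-bag instances must carry truth).
    """
    config = config or TrainConfig()
    for r in regimes:
        if r not in REGIMES:
            raise ValueError(f"unknown regime {r!r}")
    folds = stratified_folds(dataset, k=k, seed=seed)
    inst_table = _instance_rows(dataset, folds)
    needs_truth = {"residue_all", "residue_posonly"} & set(regimes)
    if needs_truth:
        # raises if positive-bag instances lack true labels
        inst_truth = dataset.instance_true_labels()
        inst_table["true_label"] = inst_truth

    bag_rows = []
    inst_scores = np.full(dataset.n_instances, np.nan)
    inst_offsets = np.r_[0, np.cumsum([len(b) for b in dataset.bags])]
    for fold in range(k):
        train_bags = [b for i, b in enumerate(dataset.bags) if folds[i] != fold]
        train_ds = MILDataset(train_bags, reorganized=dataset.reorganized)
        res = MILBoost(train_ds, config).fit()
        for i, bag in enumerate(dataset.bags):
            if folds[i] != fold:
                continue
            bag_rows.append({
                "bag_id": bag.bag_id,
                "label": bag.label,
                "fold": fold,
                "score": res.score_bag(bag),
            })
            X = np.vstack([inst.features for inst in bag.instances])
            inst_scores[inst_offsets[i]:inst_offsets[i + 1]] = (
                res.score_instances(X)
            )
    bag_scores = pd.DataFrame(bag_rows)
    inst_table["score"] = inst_scores

    pooled: dict = {}
    fold_rows = []
    for regime in regimes:
        s, y, fold_col = _regime_vectors(regime, bag_scores, inst_table)
        pooled[regime] = roc_auc(s, y).auc
        for fold in range(k):
            m = fold_col == fold
            try:
                fold_auc = roc_auc(s[m], y[m]).auc
            except ValueError:
                fold_auc = np.nan  # a fold may miss a class at instance level
            fold_rows.append({"fold": fold, "regime": regime, "auc": fold_auc})
    return CVResult(
        pooled=pooled,
        per_fold=pd.DataFrame(fold_rows),
        bag_scores=bag_scores,
        instance_scores=inst_table,
        k=k,
        seed=seed,
    )


def _regime_vectors(regime, bag_scores, inst_table):
    if regime == "protein":
        return (bag_scores["score"].to_numpy(),
                bag_scores["label"].to_numpy(),
                bag_scores["fold"].to_numpy())
    if regime == "residue_all":
        t = inst_table
    elif regime == "residue_posonly":
        t = inst_table[inst_table["bag_label"] == 1]
    else:  # pragma: no cover
        raise ValueError(regime)
    if t["true_label"].isna().any():
        raise ValueError(f"regime {regime!r} requires true instance labels")
    return (t["score"].to_numpy(),
            t["true_label"].to_numpy(dtype=int),
            t["fold"].to_numpy())


def residue_type_pr(
    instance_scores: pd.DataFrame, threshold: float = 0.0
) -> pd.DataFrame:
    """Per-residue-type precision and recall among positive-bag instances.

    For each amino-acid type: precision = TP/(TP+FP) over that type's
    predicted positives (NaN when none are predicted — undefined, not
    zero) and recall = TP/(TP+FN) over that type's true positives.
    Expects the ``instance_scores`` table of :func:`crossvalidate`
    (columns aa, bag_label, true_label, score); only instances of
    positive bags are considered, mirroring the binding-protein
    analysis.
    """
    t = instance_scores[instance_scores["bag_label"] == 1]
    if t["true_label"].isna().any():
        raise ValueError("per-type precision/recall requires true instance labels")
    rows = []
    for aa, grp in t.groupby("aa", sort=True):
        pred_pos = grp["score"] > threshold
        true_pos = grp["true_label"] == 1
        tp = int((pred_pos & true_pos).sum())
        fp = int((pred_pos & ~true_pos).sum())
        fn = int((~pred_pos & true_pos).sum())
        rows.append({
            "aa": aa,
            "n": len(grp),
            "tp": tp, "fp": fp, "fn": fn,
            "precision": tp / (tp + fp) if tp + fp > 0 else np.nan,
            "recall": tp / (tp + fn) if tp + fn > 0 else 0.0,
        })
    return pd.DataFrame(rows)
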