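"""Bag-level confidence-rated boosting for multiple-instance learning.

The trainer reduces MIL to importance-weighted classification.  Every
negative bag is first split into singleton bags (a negative bag's
instances are all certainly negative); a uniform weight distribution is
then maintained over these bags.  Each round:

1.  the bag-weighted dataset is mapped to a weighted instance table
    (each instance inherits its bag's label and w_i / n_i weight);
2.  a confidence-rated tree ĥ_t is grown on the table;
3.  instance confidences are squashed through the logistic sigmoid,
    p̂ = 1 / (1 + exp(−ĥ_t)), and each bag is scored by the
    probability-weighted vote of its instances' signs,

        h_t(X_i) = Σ_j p̂(ĥ_t(x_ij)) sgn[ĥ_t(x_ij)] / Σ_j p̂(ĥ_t(x_ij)),

    a value in [−1, 1] dominated by the instances the tree is most
    confident about — exactly the "at least one strongly positive
    instance" semantics of MIL;
4.  the weighted bag error ε_t, step size α_t = ½ ln((1−ε_t)/ε_t) and
    multiplicative bag-weight update exp(−α_t sgn[h_t] sgn[y]) / Z_t
    follow AdaBoost at the bag level.

The ensemble scores instances by H(x) = Σ_t α_t ĥ_t(x) and bags by
H(X_i) = Σ_t α_t h_t(X_i).

A standard-AdaBoost baseline is included: it treats MIL as
classification with positive-class label noise (every instance simply
labeled with its bag label; discrete instance-level error and weight
update), scoring bags at prediction time by the same step-3 aggregation
so bag-level comparisons isolate the training difference.  On a dataset
of singleton bags the two algorithms coincide round for round.

``sgn(0) = −1`` throughout: a bag must show strictly positive evidence
to be called positive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bags import (
    Bag,
    BagWeights,
    MILDataset,
    WeightedInstances,
    init_bag_weights,
    reorganize_negatives,
    split_to_instance_level,
)
from .tree import ConfidenceTree, fit_tree

__all__ = [
    "TrainConfig",
    "EnsembleModel",
    "MILBoost",
    "MILBoostResults",
    "sigmoid_prob",
    "bag_hypothesis",
    "weighted_bag_error",
    "alpha_from_error",
    "update_bag_weights",
    "fit",
    "fit_adaboost_baseline",
    "sgn",
]


def sgn(x):
    """Sign with the convention sgn(0) = −1 (no evidence ⇒ negative)."""
    return np.where(np.asarray(x) > 0, 1, -1)


def sigmoid_prob(h_hat):
    """Logistic sigmoid 1 / (1 + exp(−ĥ)), stable for large |ĥ|."""
    h = np.clip(np.asarray(h_hat, dtype=float), -709.0, 709.0)
    out = np.where(h >= 0, 1.0 / (1.0 + np.exp(-h)),
                   np.exp(h) / (1.0 + np.exp(h)))
    return out if out.ndim else float(out)


def bag_hypothesis(confidences) -> float:
    """Weak bag-level hypothesis from a bag's instance confidences.

    h = Σ_j p̂(ĥ_j) sgn(ĥ_j) / Σ_j p̂(ĥ_j) ∈ [−1, 1]; the sigmoid keeps
    the denominator strictly positive.
    """
    c = np.asarray(confidences, dtype=float)
    if c.size == 0:
        raise ValueError("bag has no instances")
    p = sigmoid_prob(c)
    return float(np.sum(p * sgn(c)) / np.sum(p))


def weighted_bag_error(weights: BagWeights, bag_preds, labels) -> float:
    """ε_t: total weight of bags whose predicted sign disagrees with y."""
    h = np.asarray(bag_preds, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (len(weights.w) == len(h) == len(y)):
        raise ValueError("weights, predictions and labels must align")
    return float(weights.w[sgn(h) != y].sum())


def alpha_from_error(epsilon: float, clamp: float = 1e-10) -> float:
    """Step size α = ½ ln((1−ε′)/ε′), ε′ = max(ε, clamp); finite, > 0."""
    if not 0.0 < clamp < 0.5:
        raise ValueError("clamp must be in (0, 0.5)")
    if epsilon >= 0.5:
        raise ValueError(
            f"epsilon = {epsilon} >= 0.5: weak learner no better than chance"
        )
    eps = max(float(epsilon), clamp)
    return 0.5 * math.log((1.0 - eps) / eps)


def update_bag_weights(
    weights: BagWeights, alpha: float, bag_preds, labels
) -> BagWeights:
    """Reweight bags by exp(−α sgn(h) sgn(y)) and renormalise.

    Correctly predicted bags are down-weighted, incorrect ones
    up-weighted; the normaliser Z_t restores Σ w = 1.
    """
    h = np.asarray(bag_preds, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (len(weights.w) == len(h) == len(y)):
        raise ValueError("weights, predictions and labels must align")
    w = weights.w * np.exp(-alpha * sgn(h) * sgn(y))
    z = w.sum()
    assert z > 0.0, "normaliser must be positive for positive weights"
    return BagWeights(w / z, t=weights.t + 1)


@dataclass
class TrainConfig:
    """Training hyperparameters.

    T is the number of boosting rounds (the ensemble may be shorter if
    the weak learner degenerates first).  max_depth/smoothing/
    min_leaf_weight configure the tree weak learner; smoothing=None
    means the 1/(2N) default.  epsilon_clamp floors ε_t away from 0 so
    α_t stays finite.

    The default weak learner is deliberately strong (depth 8 with a
    1e-3 leaf-weight floor): the probability-weighted bag vote lets a
    single instance flip a bag only when leaves are confident, so very
    shallow trees make the bag-level loop degenerate (ε_t crosses 0.5
    within a round or two) on witness-structured data.
    """

    T: int = 100
    max_depth: int = 8
    smoothing: float | None = None
    min_leaf_weight: float = 1e-3
    epsilon_clamp: float = 1e-10
    seed: int = 0
    mode: str = "mil"

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not 0.0 < self.epsilon_clamp < 0.5:
            raise ValueError("epsilon_clamp must be in (0, 0.5)")
        if self.mode not in ("mil", "adaboost_baseline"):
            raise ValueError(f"unknown mode {self.mode!r}")


class EnsembleModel:
    """Fitted boosting ensemble: ordered (α_t, tree_t) pairs.

    Scores instances by H(x) = Σ α_t ĥ_t(x) and bags by
    H(X_i) = Σ α_t h_t(X_i) with h_t the probability-weighted vote.
    """

    def __init__(self, rounds, mode: str, d: int, history=None,
                 config: TrainConfig | None = None):
        self.rounds = list(rounds)
        self.mode = mode
        self.d = d
        self.history = list(history or [])  # per-round (epsilon, alpha)
        self.config = config
        # max |Σw − 1| observed after any round's weight update
        self.max_weight_drift = 0.0

    @property
    def T(self) -> int:
        return len(self.rounds)

    def score_instances(self, X) -> np.ndarray:
        """Instance-level ensemble score Σ_t α_t ĥ_t(x)."""
        if not self.rounds:
            raise ValueError("model has no rounds")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.zeros(X.shape[0])
        for alpha, tree in self.rounds:
            out += alpha * tree.predict(X)
        return out

    def score_bag(self, bag: Bag) -> float:
        """Bag-level ensemble score Σ_t α_t h_t(X_i)."""
        if not self.rounds:
            raise ValueError("model has no rounds")
        X = np.vstack([inst.features for inst in bag.instances])
        return float(
            sum(alpha * bag_hypothesis(tree.predict(X))
                for alpha, tree in self.rounds)
        )

    def score_bags(self, dataset: MILDataset) -> np.ndarray:
        return np.array([self.score_bag(b) for b in dataset.bags])

    # --- persistence ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "d": self.d,
            "config": asdict(self.config) if self.config else None,
            "history": [
                {"round": t + 1, "epsilon": e, "alpha": a}
                for t, (e, a) in enumerate(self.history)
            ],
            "rounds": [
                {"alpha": alpha, "tree": tree.to_dict()}
                for alpha, tree in self.rounds
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "EnsembleModel":
        rounds = [
            (float(r["alpha"]), ConfidenceTree.from_dict(r["tree"]))
            for r in payload["rounds"]
        ]
        history = [(h["epsilon"], h["alpha"]) for h in payload["history"]]
        cfg = payload.get("config")
        return cls(
            rounds,
            mode=payload["mode"],
            d=int(payload["d"]),
            history=history,
            config=TrainConfig(**cfg) if cfg else None,
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


class MILBoost:
    """Boosting model over a multiple-instance dataset.

    Parameters
    ----------
    dataset
        A :class:`~milboost.bags.MILDataset` with at least one positive
        and one negative bag.
    config
        A :class:`TrainConfig`; keyword arguments build one if omitted.

    Examples
    --------
    >>> model = MILBoost(dataset, T=50, max_depth=3)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> scores = res.score_bags(test_dataset)
    """

    def __init__(self, dataset: MILDataset, config: TrainConfig | None = None,
                 **kwargs):
        if config is None:
            config = TrainConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either config or keyword arguments, not both")
        labels = dataset.labels()
        if not (np.any(labels == 1) and np.any(labels == -1)):
            raise ValueError("dataset must contain both positive and negative bags")
        self.dataset = dataset
        self.config = config

    def fit(self) -> "MILBoostResults":
        if self.config.mode == "mil":
            ensemble = self._fit_mil()
        else:
            ensemble = self._fit_baseline()
        return MILBoostResults(self, ensemble)

    # --- training loops ------------------------------------------------

    def _fit_mil(self) -> EnsembleModel:
        cfg = self.config
        ds = (self.dataset if self.dataset.reorganized
              else reorganize_negatives(self.dataset))
        weights = init_bag_weights(ds)
        y_bag = ds.labels()
        sizes = np.array([len(b) for b in ds.bags])
        bag_index = np.repeat(np.arange(ds.n), sizes)
        X = ds.feature_matrix()
        y_inst = y_bag[bag_index]
        rounds, history = [], []
        zero_streak = 0
        max_drift = 0.0
        for _ in range(cfg.T):
            w_inst = (weights.w / sizes)[bag_index]
            tree = fit_tree((X, y_inst, w_inst), max_depth=cfg.max_depth,
                            smoothing=cfg.smoothing,
                            min_leaf_weight=cfg.min_leaf_weight)
            h_hat = tree.predict(X)
            h_bag = _bag_hypotheses(h_hat, bag_index, ds.n)
            eps = weighted_bag_error(weights, h_bag, y_bag)
            if eps >= 0.5:
                break  # weak learner failed; discard round, stop
            alpha = alpha_from_error(eps, cfg.epsilon_clamp)
            rounds.append((alpha, tree))
            history.append((eps, alpha))
            weights = update_bag_weights(weights, alpha, h_bag, y_bag)
            max_drift = max(max_drift, abs(float(weights.w.sum()) - 1.0))
            if eps == 0.0:
                # weights are stationary under a zero-error round; a
                # second zero means every later round repeats verbatim
                zero_streak += 1
                if zero_streak >= 2:
                    break
            else:
                zero_streak = 0
        model = EnsembleModel(rounds, mode="mil", d=ds.d, history=history,
                              config=cfg)
        model.max_weight_drift = max_drift
        return model

    def _fit_baseline(self) -> EnsembleModel:
        """Discrete AdaBoost on instances labeled with their bag label."""
        cfg = self.config
        ds = self.dataset
        sizes = np.array([len(b) for b in ds.bags])
        bag_index = np.repeat(np.arange(ds.n), sizes)
        X = ds.feature_matrix()
        y = ds.labels()[bag_index]
        w = np.full(X.shape[0], 1.0 / X.shape[0])
        rounds, history = [], []
        zero_streak = 0
        for _ in range(cfg.T):
            tree = fit_tree((X, y, w), max_depth=cfg.max_depth,
                            smoothing=cfg.smoothing,
                            min_leaf_weight=cfg.min_leaf_weight)
            pred = sgn(tree.predict(X))
            eps = float(w[pred != y].sum())
            if eps >= 0.5:
                break
            alpha = alpha_from_error(eps, cfg.epsilon_clamp)
            rounds.append((alpha, tree))
            history.append((eps, alpha))
            w = w * np.exp(-alpha * pred * y)
            w /= w.sum()
            if eps == 0.0:
                zero_streak += 1
                if zero_streak >= 2:
                    break
            else:
                zero_streak = 0
        return EnsembleModel(rounds, mode="adaboost_baseline", d=ds.d,
                             history=history, config=cfg)


def _bag_hypotheses(h_hat, bag_index, n_bags) -> np.ndarray:
    """Vectorised step-3 aggregation over all bags at once."""
    p = sigmoid_prob(h_hat)
    num = np.bincount(bag_index, weights=p * sgn(h_hat), minlength=n_bags)
    den = np.bincount(bag_index, weights=p, minlength=n_bags)
    return num / den


class MILBoostResults:
    """Fitted-model results: the ensemble plus training diagnostics.

    Attributes
    ----------
    ensemble
        The :class:`EnsembleModel` (α_t, tree_t pairs).
    history
        DataFrame of per-round weighted error ε_t and step size α_t.
    """

    def __init__(self, model: MILBoost, ensemble: EnsembleModel):
        self.model = model
        self.ensemble = ensemble
        self.history = pd.DataFrame(
            ensemble.history, columns=["epsilon", "alpha"]
        )
        self.history.index = pd.RangeIndex(1, len(ensemble.history) + 1,
                                           name="round")

    @property
    def T(self) -> int:
        return self.ensemble.T

    @property
    def alphas(self) -> np.ndarray:
        return np.array([a for a, _ in self.ensemble.rounds])

    def score_instances(self, X) -> np.ndarray:
        return self.ensemble.score_instances(X)

    def score_bag(self, bag: Bag) -> float:
        return self.ensemble.score_bag(bag)

    def score_bags(self, dataset: MILDataset) -> np.ndarray:
        return self.ensemble.score_bags(dataset)

    def training_bag_error(self) -> float:
        """Fraction of training bags misclassified by the full ensemble."""
        ds = self.model.dataset
        preds = sgn(self.score_bags(ds))
        return float(np.mean(preds != ds.labels()))

    def save(self, path) -> None:
        self.ensemble.save(path)

    def summary(self) -> str:
        ds = self.model.dataset
        cfg = self.model.config
        lines = [
            "Multiple-instance boosting results",
            "=" * 50,
            f"mode:            {self.ensemble.mode}",
            f"bags:            {ds.n}  ({int(np.sum(ds.labels() == 1))} positive,"
            f" {int(np.sum(ds.labels() == -1))} negative)",
            f"instances:       {ds.n_instances}   feature dim: {ds.d}",
            f"rounds fitted:   {self.T} / {cfg.T} requested",
            f"tree depth:      {cfg.max_depth}",
            f"train bag error: {self.training_bag_error():.4f}",
            "-" * 50,
            "round   epsilon      alpha",
        ]
        hist = self.history
        show = hist if len(hist) <= 10 else pd.concat([hist.head(5), hist.tail(5)])
        prev = 0
        for t, row in show.iterrows():
            if t > prev + 1:
                lines.append("  ...")
            lines.append(f"{t:5d}   {row.epsilon:.5f}   {row.alpha:8.4f}")
            prev = t
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<MILBoostResults mode={self.ensemble.mode} "
                f"T={self.T} d={self.ensemble.d}>")


def fit(dataset: MILDataset, config: TrainConfig | None = None,
        **kwargs) -> MILBoostResults:
    """Train the MIL boosting ensemble (convenience wrapper)."""
    if config is not None and config.mode != "mil":
        raise ValueError("use fit_adaboost_baseline for the baseline mode")
    if config is None:
        kwargs.setdefault("mode", "mil")
        config = TrainConfig(**kwargs)
    return MILBoost(dataset, config).fit()


def fit_adaboost_baseline(dataset: MILDataset,
                          config: TrainConfig | None = None,
                          **kwargs) -> MILBoostResults:
    """Train the standard-AdaBoost baseline (bag label → instance label)."""
    if config is None:
        kwargs["mode"] = "adaboost_baseline"
        config = TrainConfig(**kwargs)
    else:
        config = TrainConfig(**{**asdict(config), "mode": "adaboost_baseline"})
    return MILBoost(dataset, config).fit()
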