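"""Confidence-rated decision trees for boosting.

The weak learner is a greedy top-down binary decision tree grown on a
weighted instance table.  Splits minimise the weighted impurity
``G(q) = 2 sqrt(q (1 - q))`` (q the weighted positive fraction), the
criterion under which the resulting real-valued leaf predictions drive
the exponential-loss bound of confidence-rated boosting.  Each leaf
predicts the half log-odds of its weighted class masses,

    c = 1/2 * ln((W+ + s) / (W- + s)),

with smoothing s > 0 bounding |c| by 1/2 * ln((1 + s)/s).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .bags import WeightedInstances

__all__ = ["SplitRule", "ConfidenceTree", "fit_tree", "impurity"]


def impurity(q):
    """Top-down splitting criterion G(q) = 2 sqrt(q (1 - q)).

    Symmetric about q = 0.5 where it peaks at 1; zero for pure nodes.
    """
    q = np.asarray(q, dtype=float)
    return 2.0 * np.sqrt(np.clip(q * (1.0 - q), 0.0, None))


@dataclass(frozen=True)
class SplitRule:
    """Axis-parallel test: instances with value <= threshold go left."""

    feature_index: int
    threshold: float


@dataclass
class _Node:
    rule: SplitRule | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None
    confidence: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.rule is None


class ConfidenceTree:
    """A fitted confidence-rated tree: real-valued output, sign = class."""

    def __init__(self, root: _Node, d: int, max_depth: int, smoothing: float):
        self.root = root
        self.d = d
        self.max_depth = max_depth
        self.smoothing = smoothing

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Confidence of the leaf each row reaches."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.d:
            raise ValueError(
                f"feature dimension {X.shape[1]} != tree dimension {self.d}"
            )
        out = np.empty(X.shape[0])
        self._predict_into(self.root, X, np.arange(X.shape[0]), out)
        return out

    def predict_one(self, x: np.ndarray) -> float:
        return float(self.predict(np.atleast_2d(x))[0])

    def _predict_into(self, node, X, idx, out) -> None:
        if node.is_leaf:
            out[idx] = node.confidence
            return
        go_left = X[idx, node.rule.feature_index] <= node.rule.threshold
        self._predict_into(node.left, X, idx[go_left], out)
        self._predict_into(node.right, X, idx[~go_left], out)

    # --- persistence ---------------------------------------------------

    def to_dict(self) -> dict:
        def enc(node):
            if node.is_leaf:
                return {"confidence": node.confidence}
            return {
                "feature_index": node.rule.feature_index,
                "threshold": node.rule.threshold,
                "left": enc(node.left),
                "right": enc(node.right),
            }

        return {
            "d": self.d,
            "max_depth": self.max_depth,
            "smoothing": self.smoothing,
            "root": enc(self.root),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ConfidenceTree":
        def dec(obj):
            if "confidence" in obj:
                return _Node(confidence=float(obj["confidence"]))
            return _Node(
                rule=SplitRule(int(obj["feature_index"]), float(obj["threshold"])),
                left=dec(obj["left"]),
                right=dec(obj["right"]),
            )

        return cls(
            dec(payload["root"]),
            d=int(payload["d"]),
            max_depth=int(payload["max_depth"]),
            smoothing=float(payload["smoothing"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "ConfidenceTree":
        return cls.from_dict(json.loads(text))


def _leaf_confidence(w_pos: float, w_neg: float, s: float) -> float:
    return 0.5 * math.log((w_pos + s) / (w_neg + s))


def _best_split(X, y, w, min_leaf_weight):
    """Exhaustive threshold search minimising summed child impurity mass.

    The score of a split is 2(sqrt(Wp_L Wn_L) + sqrt(Wp_R Wn_R)), i.e.
    W_L G(q_L) + W_R G(q_R).  Candidate thresholds are midpoints between
    consecutive distinct sorted values; ties break to the lowest feature
    index, then the lowest threshold (strict improvement required), so
    training is deterministic.
    """
    n, d = X.shape
    w_pos_tot = float(w[y == 1].sum())
    w_tot = float(w.sum())
    parent = 2.0 * math.sqrt(w_pos_tot * (w_tot - w_pos_tot))
    best = (parent, None)  # (score, rule)
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        wp = np.cumsum(np.where(y[order] == 1, w[order], 0.0))
        wa = np.cumsum(w[order])
        # splittable positions: between distinct consecutive values
        cut = np.nonzero(xs[:-1] < xs[1:])[0]
        if cut.size == 0:
            continue
        wp_l, wa_l = wp[cut], wa[cut]
        wp_r = w_pos_tot - wp_l
        wa_r = w_tot - wa_l
        ok = (wa_l >= min_leaf_weight) & (wa_r >= min_leaf_weight)
        if not np.any(ok):
            continue
        score = 2.0 * (
            np.sqrt(np.clip(wp_l * (wa_l - wp_l), 0.0, None))
            + np.sqrt(np.clip(wp_r * (wa_r - wp_r), 0.0, None))
        )
        score[~ok] = np.inf
        k = int(np.argmin(score))  # argmin takes the first minimum: lowest threshold
        if score[k] < best[0] - 1e-15:
            thr = 0.5 * (xs[cut[k]] + xs[cut[k] + 1])
            best = (float(score[k]), SplitRule(j, float(thr)))
    return best[1]


def _grow(X, y, w, depth, max_depth, smoothing, min_leaf_weight):
    w_pos = float(w[y == 1].sum())
    w_neg = float(w.sum()) - w_pos
    leaf = _Node(confidence=_leaf_confidence(w_pos, w_neg, smoothing))
    if depth >= max_depth or w_pos == 0.0 or w_neg == 0.0:
        return leaf
    rule = _best_split(X, y, w, min_leaf_weight)
    if rule is None:
        return leaf
    go_left = X[:, rule.feature_index] <= rule.threshold
    return _Node(
        rule=rule,
        left=_grow(X[go_left], y[go_left], w[go_left], depth + 1,
                   max_depth, smoothing, min_leaf_weight),
        right=_grow(X[~go_left], y[~go_left], w[~go_left], depth + 1,
                    max_depth, smoothing, min_leaf_weight),
    )


def fit_tree(
    instances: Union[WeightedInstances, tuple],
    max_depth: int = 3,
    smoothing: float | None = None,
    min_leaf_weight: float = 1e-6,
) -> ConfidenceTree:
    """Grow a confidence-rated tree on a weighted instance table.

    Parameters
    ----------
    instances
        A :class:`~milboost.bags.WeightedInstances` table, or an
        ``(X, y, w)`` triple of arrays.
    max_depth
        Maximum root-to-leaf path length; 1 gives decision stumps.
    smoothing
        Leaf smoothing s; defaults to 1/(2 N) for N training instances.
    min_leaf_weight
        Minimum total weight allowed in a child node.
    """
    if isinstance(instances, WeightedInstances):
        X, y, w = instances.X, instances.y, instances.w
    else:
        X, y, w = instances
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    w = np.asarray(w, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("cannot fit a tree on zero instances")
    total = float(w.sum())
    if total <= 0.0:
        raise ValueError("total instance weight must be positive")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if smoothing is None:
        smoothing = 1.0 / (2.0 * X.shape[0])
    if smoothing <= 0:
        raise ValueError("smoothing must be positive")
    root = _grow(X, y, w, 0, max_depth, smoothing, min_leaf_weight)
    return ConfidenceTree(root, d=X.shape[1], max_depth=max_depth,
                          smoothing=smoothing)
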