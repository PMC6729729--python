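"""Multiple-instance data model.

A *bag* is a labeled, ordered collection of *instances* (feature
vectors); the class label attaches to the bag, never to the instance.
In the protein application a bag is a protein and an instance is one
residue microenvironment.  Labels are ±1 internally; readers map other
encodings ({0,1}, binding/non-binding) at the boundary.

The module also implements the dataset transformations the boosting
loop needs: splitting every negative bag into singleton bags (each
negative instance is certainly negative, so no information is lost),
uniform bag-weight initialization, and mapping a bag-weighted dataset
to a weighted instance table (each bag's weight split uniformly over
its instances).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Instance",
    "Bag",
    "MILDataset",
    "BagWeights",
    "WeightedInstances",
    "reorganize_negatives",
    "init_bag_weights",
    "split_to_instance_level",
    "read_mil_table",
    "write_mil_table",
]


@dataclass
class Instance:
    """One feature vector with optional metadata.

    ``true_label`` (±1) is ground truth used only for instance-level
    evaluation; training code never reads it.
    """

    features: np.ndarray
    meta: dict = field(default_factory=dict)
    true_label: int | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 1:
            raise ValueError("instance features must be a 1-D vector")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("instance features must be finite")
        if self.true_label is not None and self.true_label not in (-1, 1):
            raise ValueError("true_label must be -1 or +1")


@dataclass
class Bag:
    """A labeled group of instances; the unit carrying the class label."""

    bag_id: str
    label: int
    instances: list[Instance]

    def __post_init__(self) -> None:
        if self.label not in (-1, 1):
            raise ValueError(f"bag label must be -1 or +1, got {self.label!r}")
        if len(self.instances) < 1:
            raise ValueError(f"bag {self.bag_id!r} has no instances")

    def __len__(self) -> int:
        return len(self.instances)


class MILDataset:
    """An ordered collection of bags with a common feature dimension.

    Parameters
    ----------
    bags
        The bags, in a stable order.  Bag ids must be unique.
    reorganized
        True once every negative bag holds exactly one instance (the
        canonical form the boosting loop trains on).
    """

    def __init__(self, bags: Sequence[Bag], reorganized: bool = False):
        bags = list(bags)
        if not bags:
            raise ValueError("dataset needs at least one bag")
        ids = [b.bag_id for b in bags]
        if len(set(ids)) != len(ids):
            raise ValueError("bag_ids must be unique")
        d = bags[0].instances[0].features.shape[0]
        for b in bags:
            for inst in b.instances:
                if inst.features.shape[0] != d:
                    raise ValueError(
                        f"bag {b.bag_id!r}: feature dimension "
                        f"{inst.features.shape[0]} != dataset dimension {d}"
                    )
        if reorganized:
            for b in bags:
                if b.label == -1 and len(b) != 1:
                    raise ValueError(
                        "reorganized dataset must have singleton negative bags"
                    )
        self.bags = bags
        self.d = d
        self.reorganized = reorganized

    @property
    def n(self) -> int:
        return len(self.bags)

    @property
    def n_instances(self) -> int:
        return sum(len(b) for b in self.bags)

    def labels(self) -> np.ndarray:
        return np.array([b.label for b in self.bags], dtype=int)

    def __iter__(self):
        return iter(self.bags)

    def __len__(self) -> int:
        return len(self.bags)

    def feature_matrix(self) -> np.ndarray:
        """All instance feature vectors stacked in bag order."""
        return np.vstack(
            [inst.features for b in self.bags for inst in b.instances]
        )

    def instance_true_labels(self) -> np.ndarray:
        """True instance labels (±1) for evaluation; negative-bag
        instances default to −1 (every instance of a negative bag is
        negative by the MIL assumption).  Raises if a positive bag's
        instance has no recorded truth."""
        out = []
        for b in self.bags:
            for inst in b.instances:
                if inst.true_label is not None:
                    out.append(inst.true_label)
                elif b.label == -1:
                    out.append(-1)
                else:
                    raise ValueError(
                        f"instance in positive bag {b.bag_id!r} has no "
                        "true_label; instance-level evaluation impossible"
                    )
        return np.array(out, dtype=int)


@dataclass
class BagWeights:
    """Non-negative per-bag weights summing to 1, at boosting round t."""

    w: np.ndarray
    t: int = 1

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise ValueError("bag weights must be non-negative")
        if abs(self.w.sum() - 1.0) > 1e-12:
            raise ValueError(f"bag weights must sum to 1, got {self.w.sum()!r}")


@dataclass
class WeightedInstances:
    """Flat weighted instance table: one row per instance.

    ``bag_index`` maps each row back to its bag; ``y`` carries the bag
    label down to the instance (every instance of a positive bag is
    provisionally labeled positive).
    """

    X: np.ndarray
    y: np.ndarray
    w: np.ndarray
    bag_index: np.ndarray


def reorganize_negatives(dataset: MILDataset) -> MILDataset:
    """Split every negative bag into one singleton bag per instance.

    Instances of a negative bag are all certainly negative, so the split
    loses nothing; positive bags are kept intact.  Derived bag ids are
    ``<parent>#<k>`` with k the original instance index — deterministic
    and traceable.  Reorganizing twice is an error.
    """
    if dataset.reorganized:
        raise ValueError("dataset is already reorganized")
    bags: list[Bag] = []
    for b in dataset.bags:
        if b.label == 1 or len(b) == 1:
            bags.append(b)
        else:
            for k, inst in enumerate(b.instances):
                bags.append(Bag(f"{b.bag_id}#{k}", b.label, [inst]))
    return MILDataset(bags, reorganized=True)


def init_bag_weights(dataset: MILDataset) -> BagWeights:
    """Uniform 1/n weight per (reorganized) bag."""
    if not dataset.reorganized:
        raise ValueError("initialize weights on the reorganized dataset")
    n = dataset.n
    return BagWeights(np.full(n, 1.0 / n), t=1)


def split_to_instance_level(
    dataset: MILDataset, weights: BagWeights
) -> WeightedInstances:
    """Map a bag-weighted dataset to a weighted instance table.

    Each instance inherits its bag's label and a weight of w_i / n_i, so
    total instance weight equals total bag weight.
    """
    if len(weights.w) != dataset.n:
        raise ValueError(
            f"weight vector length {len(weights.w)} != bag count {dataset.n}"
        )
    sizes = np.array([len(b) for b in dataset.bags])
    bag_index = np.repeat(np.arange(dataset.n), sizes)
    y = np.repeat(dataset.labels(), sizes)
    w = np.repeat(weights.w / sizes, sizes)
    return WeightedInstances(dataset.feature_matrix(), y, w, bag_index)


def to_frame(dataset: MILDataset) -> pd.DataFrame:
    """Flatten to one row per instance with bag_id, label, features and meta."""
    rows = []
    for b in dataset.bags:
        for inst in b.instances:
            row = {"bag_id": b.bag_id, "label": b.label}
            if inst.true_label is not None:
                row["true_label"] = inst.true_label
            for key, val in inst.meta.items():
                row[f"meta_{key}"] = val
            row.update(
                {f"feature_{j}": v for j, v in enumerate(inst.features)}
            )
            rows.append(row)
    return pd.DataFrame(rows)


def from_frame(frame: pd.DataFrame, reorganized: bool = False) -> MILDataset:
    """Rebuild a dataset from the flat per-instance table."""
    feat_cols = sorted(
        (c for c in frame.columns if c.startswith("feature_")),
        key=lambda c: int(c.split("_", 1)[1]),
    )
    meta_cols = [c for c in frame.columns if c.startswith("meta_")]
    bags = []
    for bag_id, grp in frame.groupby("bag_id", sort=False):
        labels = grp["label"].unique()
        if len(labels) != 1:
            raise ValueError(f"bag {bag_id!r} has conflicting labels")
        instances = []
        for _, row in grp.iterrows():
            meta = {
                c[len("meta_"):]: row[c]
                for c in meta_cols
                if pd.notna(row[c])
            }
            tl = row.get("true_label")
            instances.append(
                Instance(
                    row[feat_cols].to_numpy(dtype=float),
                    meta=meta,
                    true_label=None if pd.isna(tl) else int(tl),
                )
            )
        bags.append(Bag(str(bag_id), int(labels[0]), instances))
    return MILDataset(bags, reorganized=reorganized)


def write_mil_table(dataset: MILDataset, path: str | Path) -> None:
    """Write the dataset as TSV plus a JSON sidecar with its dimensions."""
    path = Path(path)
    to_frame(dataset).to_csv(path, sep="\t", index=False)
    sidecar = {
        "n_bags": dataset.n,
        "n_instances": dataset.n_instances,
        "d": dataset.d,
        "reorganized": dataset.reorganized,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_mil_table(path: str | Path) -> MILDataset:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    reorganized = False
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        reorganized = bool(meta.get("reorganized", False))
    ds = from_frame(frame, reorganized=reorganized)
    if sidecar.exists() and ds.d != meta["d"]:
        raise ValueError(
            f"table dimension {ds.d} disagrees with sidecar d={meta['d']}"
        )
    return ds
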