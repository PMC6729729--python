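"""Shared fixtures: tiny hand-built MIL datasets and programmatically
written protein input files (PDB / DSSP / PSSM) for the feature tests."""

from __future__ import annotations

import numpy as np
import pytest

from milboost.bags import Bag, Instance, MILDataset


@pytest.fixture
def tiny_dataset():
    """1 positive bag of 2 instances + 2 negative bags of 3 instances."""
    mk = lambda *vals: Instance(np.array(vals, dtype=float))
    return MILDataset([
        Bag("p0", 1, [mk(1.0, 2.0), mk(3.0, 4.0)]),
        Bag("n0", -1, [mk(-1.0, 0.0), mk(-2.0, 0.5), mk(-3.0, 1.0)]),
        Bag("n1", -1, [mk(0.1, 0.2), mk(0.3, 0.4), mk(0.5, 0.6)]),
    ])


def random_dataset(seed=0, n_bags=20, d=3, with_truth=False):
    """Random bags with reproducible contents (not a witness model)."""
    rng = np.random.default_rng(seed)
    bags = []
    for i in range(n_bags):
        label = 1 if rng.random() < 0.4 else -1
        size = int(rng.integers(1, 6))
        instances = [
            Instance(
                rng.normal(size=d),
                true_label=(int(rng.choice([-1, 1])) if with_truth and label == 1
                            else (-1 if with_truth else None)),
            )
            for _ in range(size)
        ]
        if with_truth and label == 1:
            # honour the witness rule for consistency
            if not any(inst.true_label == 1 for inst in instances):
                instances[0].true_label = 1
        bags.append(Bag(f"bag{i}", label, instances))
    labels = {b.label for b in bags}
    if labels != {-1, 1}:  # ensure both classes for downstream use
        bags[0] = Bag(bags[0].bag_id, -1 if bags[0].label == 1 else 1,
                      bags[0].instances)
    return MILDataset(bags)


# protein input files are written at test time by the package's own
# synthetic writers; re-exported here for the test modules
from milboost.synthetic_protein import write_dssp, write_pdb, write_pssm  # noqa: E402,F401


@pytest.fixture
def protein_fixture(tmp_path):
    """A 3-residue single-chain protein with matching PDB/DSSP/PSSM files."""
    residues = [
        ("A", 1, "MET", (0.0, 0.0, 0.0)),
        ("A", 2, "GLY", (3.8, 0.0, 0.0)),
        ("A", 3, "LYS", (7.6, 0.0, 0.0)),
    ]
    pdb = write_pdb(tmp_path / "prot1.pdb", residues)
    dssp = write_dssp(tmp_path / "prot1.dssp", [
        ("A", 1, "M", "H", 100),
        ("A", 2, "G", "E", 50),
        ("A", 3, "K", " ", 123),
    ])
    pssm = write_pssm(tmp_path / "prot1.pssm", "MGK")
    return {"pdb": pdb, "dssp": dssp, "pssm": pssm, "sequence": "MGK"}
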