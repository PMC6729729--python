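"""Residue-microenvironment features for the protein application.

Each residue of a protein becomes one instance: a 205-dimensional
vector built from six blocks —

====================  ====  ==================================================
block                 dim   content
====================  ====  ==================================================
identity               20   one-hot residue type (alphabetical one-letter
                            order A C D E F G H I K L M N P Q R S T V W Y)
secondary_structure     3   one-hot (helix, strand, coil) collapsed from the
                            DSSP 8-state assignment
neighbors              20   count of residues of each type whose minimum
                            heavy-atom distance is < 3.0 Å
pssm                   20   evolutionary log-odds profile row (PSI-BLAST
                            ASCII PSSM), reordered to the alphabetical order
blosum_window         140   BLOSUM62 substitution rows for sequence offsets
                            −3…+3 (7 × 20; out-of-range offsets are zero)
properties              2   formal side-chain charge and relative solvent
                            accessibility (DSSP acc / max-ASA, clipped to
                            [0, 1.2])
====================  ====  ==================================================

Structure files are read with Bio.PDB, DSSP output files with
Bio.PDB.DSSP, and substitution matrices with Bio.Align; the PSI-BLAST
ASCII PSSM parser is local.  The protein becomes a labeled bag of its
residue instances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .bags import Bag, Instance

log = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_AA",
    "FEATURE_BLOCKS",
    "FEATURE_DIM",
    "ResidueRecord",
    "read_structure",
    "read_dssp",
    "read_pssm",
    "read_blosum",
    "read_label_table",
    "encode_identity",
    "encode_secondary_structure",
    "encode_neighbors",
    "encode_blosum_window",
    "encode_properties",
    "featurize_protein",
]

#: Canonical residue alphabet: one-letter codes in alphabetical order.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(CANONICAL_AA)}

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
# common non-canonical residues mapped to their closest canonical type
_NONCANONICAL = {
    "MSE": "M",  # selenomethionine
    "SEC": "C",  # selenocysteine
    "PYL": "K",  # pyrrolysine
    "SEP": "S", "TPO": "T", "PTR": "Y",  # phosphorylated S/T/Y
    "CSO": "C", "HYP": "P",
}

# formal side-chain charge at physiological pH (H partially protonated)
_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}

#: Block layout of the feature vector.
FEATURE_BLOCKS = {
    "identity": slice(0, 20),
    "secondary_structure": slice(20, 23),
    "neighbors": slice(23, 43),
    "pssm": slice(43, 63),
    "blosum_window": slice(63, 203),
    "properties": slice(203, 205),
}
FEATURE_DIM = 205

# PSI-BLAST ASCII PSSM column order
_PSSM_ORDER = "ARNDCQEGHILKMFPSTWVY"


@dataclass
class ResidueRecord:
    """One residue's raw material for a feature vector."""

    protein_id: str
    chain: str
    seq_index: int           # 1-based position within the chain sequence
    resseq: int              # author residue number (matches DSSP lines)
    icode: str
    aa: str
    heavy_atom_coords: np.ndarray  # (k, 3) Å
    ss8: str = "-"
    acc: float = float("nan")
    pssm_row: np.ndarray | None = None


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_structure(path, protein_id: str | None = None) -> list[ResidueRecord]:
    """Read a PDB file into per-residue records (first model, heavy atoms).

    Non-canonical residues with a common canonical equivalent (MSE, SEC,
    phospho-S/T/Y, ...) are mapped; others are dropped with a log line.
    Records come back ordered by (chain, position in chain).
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(protein_id, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models in structure file")
    records: list[ResidueRecord] = []
    for chain in models[0]:
        seq_index = 0
        for res in chain:
            name = res.get_resname().strip()
            aa = _THREE_TO_ONE.get(name) or _NONCANONICAL.get(name)
            if aa is None:
                if name != "HOH":
                    log.info("dropping non-protein residue %s %s%s",
                             name, chain.id, res.id[1])
                continue
            coords = np.array(
                [atom.coord for atom in res
                 if atom.element not in ("H", "D")],
                dtype=float,
            )
            if coords.size == 0:
                log.info("residue %s %s%s has no heavy atoms; dropped",
                         name, chain.id, res.id[1])
                continue
            if not np.all(np.isfinite(coords)):
                raise ValueError(f"{path}: non-finite coordinates at "
                                 f"{chain.id}{res.id[1]}")
            seq_index += 1
            records.append(ResidueRecord(
                protein_id=protein_id,
                chain=chain.id,
                seq_index=seq_index,
                resseq=int(res.id[1]),
                icode=res.id[2].strip(),
                aa=aa,
                heavy_atom_coords=coords,
            ))
    if not records:
        raise ValueError(f"{path}: no protein residues found")
    return records


def read_dssp(path) -> dict:
    """Parse a DSSP output file into (chain, author residue number) →
    (8-state code, absolute accessibility in Å²).

    Chain breaks (blank residue-number columns) are skipped by the
    underlying parser; a file from which nothing parses is rejected.
    """
    from Bio.PDB.DSSP import make_dssp_dict

    try:
        dssp_dict, keys = make_dssp_dict(str(path))
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse DSSP file: {exc}") from exc
    if not dssp_dict:
        raise ValueError(f"{path}: no residues parsed; malformed DSSP file?")
    out = {}
    for (chain, res_id), values in dssp_dict.items():
        aa, ss, acc = values[0], values[1], values[2]
        out[(chain, res_id[1])] = (ss, float(acc))
    return out


def read_pssm(path):
    """Parse a PSI-BLAST ASCII PSSM into (L × 20 log-odds, sequence).

    Columns are reordered from the file's A R N D C … layout to the
    package's alphabetical order.  Raises on truncated files or rows
    with the wrong column count.
    """
    lines = Path(path).read_text().splitlines()
    reorder = [_PSSM_ORDER.index(a) for a in CANONICAL_AA]
    rows, seq = [], []
    in_table = False
    for line in lines:
        parts = line.split()
        if not in_table:
            # header row: at least the 20 log-odds column letters
            if len(parts) >= 20 and all(p in _PSSM_ORDER for p in parts[:20]):
                in_table = True
            continue
        if not parts:
            break  # blank line ends the matrix
        if len(parts) < 22 or not parts[0].isdigit():
            break
        try:
            values = [float(v) for v in parts[2:22]]
        except ValueError as exc:
            raise ValueError(f"{path}: bad PSSM row {parts[0]}: {exc}") from exc
        rows.append(values)
        seq.append(parts[1])
    if not rows:
        raise ValueError(f"{path}: no PSSM rows parsed; truncated or "
                         "malformed file")
    matrix = np.asarray(rows, dtype=float)[:, reorder]
    return matrix, "".join(seq)


def read_blosum(path=None):
    """A substitution matrix: NCBI-format file, or BLOSUM62 by default."""
    from Bio.Align import substitution_matrices

    if path is None:
        return substitution_matrices.load("BLOSUM62")
    return substitution_matrices.read(str(path))


def read_label_table(path) -> dict[str, int]:
    """Protein label table (TSV: protein_id, label) → {id: ±1}.

    Accepts ±1, {0, 1}, or binding / non-binding text labels.
    """
    frame = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in frame.columns}
    id_col = cols.get("protein_id", frame.columns[0])
    label_col = cols.get("label", frame.columns[1])
    out = {}
    for _, row in frame.iterrows():
        raw = row[label_col]
        if isinstance(raw, str):
            label = 1 if raw.strip().lower() in ("1", "+1", "binding", "pos",
                                                 "positive") else -1
        else:
            label = 1 if float(raw) > 0 else -1
        out[str(row[id_col])] = label
    return out


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

def encode_identity(aa: str) -> np.ndarray:
    """One-hot over the alphabetical residue alphabet ('A' → e1 … 'Y' → e20)."""
    if aa not in _AA_INDEX:
        raise ValueError(f"unknown residue code {aa!r}")
    v = np.zeros(20)
    v[_AA_INDEX[aa]] = 1.0
    return v


def encode_secondary_structure(ss8: str) -> np.ndarray:
    """Collapse the 8-state DSSP code to one-hot (helix, strand, coil).

    H/G/I → helix, E/B → strand, T/S/blank → coil; anything else is
    treated as coil with a log line.
    """
    v = np.zeros(3)
    if ss8 in ("H", "G", "I"):
        v[0] = 1.0
    elif ss8 in ("E", "B"):
        v[1] = 1.0
    else:
        if ss8 not in ("T", "S", "-", " ", ""):
            log.info("unknown secondary-structure code %r -> coil", ss8)
        v[2] = 1.0
    return v


def _min_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(cdist(a, b).min())


def encode_neighbors(records, i: int, radius: float = 3.0) -> np.ndarray:
    """Residue-type histogram of residue i's structural contacts.

    A residue j ≠ i counts when its minimum heavy-atom-to-heavy-atom
    distance to residue i is strictly below ``radius`` Å.
    """
    v = np.zeros(20)
    me = records[i].heavy_atom_coords
    for j, other in enumerate(records):
        if j == i:
            continue
        if _min_distance(me, other.heavy_atom_coords) < radius:
            v[_AA_INDEX[other.aa]] += 1.0
    return v


def _neighbor_matrix(records, radius: float = 3.0) -> np.ndarray:
    """All residues' neighbor histograms at once via a KD-tree."""
    coords = np.vstack([r.heavy_atom_coords for r in records])
    owner = np.repeat(
        np.arange(len(records)),
        [len(r.heavy_atom_coords) for r in records],
    )
    tree = cKDTree(coords)
    out = np.zeros((len(records), 20))
    seen: set[tuple[int, int]] = set()
    for a, b in tree.query_pairs(radius):
        ra, rb = owner[a], owner[b]
        if ra == rb:
            continue
        # query_pairs uses distance <= r; enforce the strict < convention
        if np.linalg.norm(coords[a] - coords[b]) >= radius:
            continue
        pair = (min(ra, rb), max(ra, rb))
        if pair in seen:
            continue
        seen.add(pair)
        out[ra, _AA_INDEX[records[rb].aa]] += 1.0
        out[rb, _AA_INDEX[records[ra].aa]] += 1.0
    return out


def encode_blosum_window(sequence: str, i: int, matrix=None) -> np.ndarray:
    """Concatenated substitution-matrix rows for offsets −3…+3 around
    position i (1-based).  Out-of-range offsets contribute zero blocks,
    as do residues absent from the matrix alphabet.
    """
    if not 1 <= i <= len(sequence):
        raise ValueError(f"position {i} outside sequence of length {len(sequence)}")
    if matrix is None:
        matrix = read_blosum()
    blocks = []
    for off in range(-3, 4):
        pos = i + off
        block = np.zeros(20)
        if 1 <= pos <= len(sequence):
            aa = sequence[pos - 1]
            if aa in matrix.alphabet:
                block = np.array([matrix[aa, b] for b in CANONICAL_AA])
        blocks.append(block)
    return np.concatenate(blocks)


def _max_asa(aa: str) -> float:
    from Bio.PDB.DSSP import residue_max_acc

    three = {v: k for k, v in _THREE_TO_ONE.items()}[aa]
    return float(residue_max_acc["Sander"][three])


def encode_properties(record: ResidueRecord) -> np.ndarray:
    """(formal charge, relative accessibility clipped to [0, 1.2]).

    Residues without an accessibility value get 0 for the surface
    component (buried by default).
    """
    charge = _CHARGE.get(record.aa, 0.0)
    if np.isnan(record.acc):
        rsa = 0.0
    else:
        rsa = min(max(record.acc / _max_asa(record.aa), 0.0), 1.2)
    return np.array([charge, rsa])


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def featurize_protein(
    structure,
    dssp=None,
    pssm=None,
    label: int = 1,
    blosum=None,
    protein_id: str | None = None,
    allow_missing_profile: bool = False,
    neighbor_radius: float = 3.0,
) -> Bag:
    """Build the labeled bag of residue instances for one protein.

    Parameters
    ----------
    structure
        Path to a PDB file, or a list of :class:`ResidueRecord`.
    dssp
        Path to a DSSP output file, or the mapping from
        :func:`read_dssp`; optional (missing → coil, buried).
    pssm
        Path to a PSI-BLAST ASCII PSSM, or an ``(matrix, sequence)``
        pair.  The PSSM sequence must match the structure sequence
        exactly; mismatching positions are reported.  ``None`` is only
        accepted with ``allow_missing_profile`` (profile block zeroed).
    label
        Bag label, ±1.
    blosum
        Substitution matrix (default BLOSUM62).
    """
    if isinstance(structure, (str, Path)):
        records = read_structure(structure, protein_id=protein_id)
    else:
        records = list(structure)
    if protein_id is None:
        protein_id = records[0].protein_id
    if label not in (-1, 1):
        raise ValueError("label must be -1 or +1")

    if dssp is not None:
        dssp_map = read_dssp(dssp) if isinstance(dssp, (str, Path)) else dssp
        for rec in records:
            hit = dssp_map.get((rec.chain, rec.resseq))
            if hit is not None:
                rec.ss8, rec.acc = hit

    sequence = "".join(r.aa for r in records)
    if pssm is not None:
        matrix, pssm_seq = (read_pssm(pssm)
                            if isinstance(pssm, (str, Path)) else pssm)
        if len(pssm_seq) != len(sequence):
            raise ValueError(
                f"{protein_id}: PSSM length {len(pssm_seq)} != structure "
                f"sequence length {len(sequence)}"
            )
        bad = [i + 1 for i, (a, b) in enumerate(zip(sequence, pssm_seq))
               if a != b and b != "X"]
        if bad:
            raise ValueError(
                f"{protein_id}: PSSM sequence disagrees with structure at "
                f"positions {bad}"
            )
        for rec, row in zip(records, matrix):
            rec.pssm_row = row
    elif not allow_missing_profile:
        raise ValueError(
            f"{protein_id}: no PSSM given; pass allow_missing_profile=True "
            "to zero the profile block"
        )
    else:
        log.warning("%s: missing PSSM; profile block zeroed", protein_id)

    if blosum is None:
        blosum = read_blosum()
    neighbors = _neighbor_matrix(records, radius=neighbor_radius)

    # BLOSUM windows are chain-local: a window never spans a chain break
    chain_seq: dict[str, str] = {}
    for rec in records:
        chain_seq[rec.chain] = chain_seq.get(rec.chain, "") + rec.aa

    instances = []
    for i, rec in enumerate(records):
        vec = np.concatenate([
            encode_identity(rec.aa),
            encode_secondary_structure(rec.ss8),
            neighbors[i],
            rec.pssm_row if rec.pssm_row is not None else np.zeros(20),
            encode_blosum_window(chain_seq[rec.chain], rec.seq_index, blosum),
            encode_properties(rec),
        ])
        assert vec.shape[0] == FEATURE_DIM
        instances.append(Instance(
            vec,
            meta={"protein_id": protein_id, "chain": rec.chain,
                  "seq_index": rec.seq_index, "aa": rec.aa},
        ))
    return Bag(protein_id, label, instances)
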