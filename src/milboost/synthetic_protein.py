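"""Synthetic protein input files.

Writers for minimal-but-valid PDB, DSSP-output and PSI-BLAST ASCII PSSM
files, so the feature pipeline can be exercised end to end without any
external structure database or profile search.  The files are synthetic
stand-ins: geometrically simplistic (four backbone heavy atoms per
residue) but format-faithful, so the same readers that consume real
files consume these.
"""

from __future__ import annotations

from pathlib import Path

__all__ = ["write_pdb", "write_dssp", "write_pssm"]

_BACKBONE = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]

_PSSM_ORDER = "ARNDCQEGHILKMFPSTWVY"


def write_pdb(path, residues) -> Path:
    """Write a minimal PDB file.

    Parameters
    ----------
    residues
        List of ``(chain, resseq, resname3, center_xyz)``; each residue
        gets four backbone heavy atoms clustered around its center.
    """
    path = Path(path)
    lines = []
    serial = 1
    for chain, resseq, resname, center in residues:
        cx, cy, cz = center
        offsets = [(-0.7, 0, 0), (0, 0, 0), (0.7, 0, 0), (0.7, 0.6, 0)]
        for (name, element), (dx, dy, dz) in zip(_BACKBONE, offsets):
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {chain}"
                f"{resseq:4d}    {cx + dx:8.3f}{cy + dy:8.3f}{cz + dz:8.3f}"
                f"  1.00  0.00          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_dssp(path, entries) -> Path:
    """Write a minimal DSSP output file.

    Parameters
    ----------
    entries
        List of ``(chain, resseq, aa1, ss_char, acc_int)``; ``ss_char``
        may be ``' '`` for unassigned.
    """
    path = Path(path)
    header = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "REFERENCE ...",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N"
        "    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI"
        "    X-CA   Y-CA   Z-CA",
    ]
    body = []
    for k, (chain, resseq, aa, ss, acc) in enumerate(entries, start=1):
        line = [" "] * 136
        line[0:5] = f"{k:5d}"
        line[5:10] = f"{resseq:5d}"
        line[11] = chain
        line[13] = aa
        line[16] = ss
        line[34:38] = f"{acc:4d}"
        for start, stop, text in [(38, 45, f"{0:7d}"), (46, 50, " 0.0"),
                                  (50, 56, f"{0:6d}"), (57, 61, " 0.0"),
                                  (61, 67, f"{0:6d}"), (68, 72, " 0.0"),
                                  (72, 78, f"{0:6d}"), (79, 83, " 0.0"),
                                  (103, 109, f"{0.0:6.1f}"),
                                  (109, 115, f"{0.0:6.1f}")]:
            line[start:stop] = text
        body.append("".join(line))
    path.write_text("\n".join(header + body) + "\n")
    return path


def write_pssm(path, sequence, rows=None) -> Path:
    """Write a PSI-BLAST ASCII PSSM for ``sequence``.

    Parameters
    ----------
    rows
        Optional L × 20 integers in the file's native A R N D C … column
        order; defaults to +5 on each residue's own column.
    """
    path = Path(path)
    if rows is None:
        rows = []
        for aa in sequence:
            row = [0] * 20
            row[_PSSM_ORDER.index(aa)] = 5
            rows.append(row)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted, and rounded",
        "            " + "  ".join(_PSSM_ORDER) + "   " + "  ".join(_PSSM_ORDER),
    ]
    for i, (aa, row) in enumerate(zip(sequence, rows), start=1):
        logodds = " ".join(f"{v:3d}" for v in row)
        percents = " ".join(f"{0:3d}" for _ in range(20))
        lines.append(f"{i:5d} {aa}  {logodds}  {percents}  0.00 0.00")
    lines += ["", "                      K         Lambda",
              "Standard   0.13   0.31"]
    path.write_text("\n".join(lines) + "\n")
    return path
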