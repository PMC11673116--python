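"""File formats: XYZ geometries, NIC definition files, Hessian matrices.

Atom indices are 1-based in all files (matching the spectroscopic
literature's coordinate tables) and 0-based in memory; the conversion
happens here and nowhere else.

NIC definition file::

    # comment
    [coordinate]
    name = ring breathing
    irrep = a1
    bond 5 3  1
    bond 3 1  1

    [coordinate]
    name = in-plane linear bend
    axis = 1 0 0
    linbend 1 2 3  1

Primitive line syntax: ``kind i j [k l] coefficient`` with kinds ``bond``,
``angle``, ``torsion``, ``oop`` (out-of-plane wag γ(i,j,k,l)) and
``linbend``.  An ``axis`` key fixes the reference perpendicular for the
block's linear bends; without it, axes are resolved at the reference
geometry via :meth:`NICSet.resolve_linear_axes`.

Hessian file: a header line ``# basis=<basis> units=<units> dim=<n>``
followed by the full symmetric matrix, 15 significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .harmonic import ForceField
from .internal_coords import NICSet, PrimitiveCoordinate
from .molecule import Molecule

__all__ = [
    "read_xyz", "write_xyz",
    "read_nic_file", "write_nic_file",
    "read_hessian", "write_hessian",
]

_KIND_MAP = {"bond": ("bond", 2), "angle": ("angle", 3),
             "torsion": ("torsion", 4), "oop": ("out_of_plane", 4),
             "linbend": ("linear_bend", 3)}
_KIND_BACK = {"bond": "bond", "angle": "angle", "torsion": "torsion",
              "out_of_plane": "oop", "linear_bend": "linbend"}


def read_xyz(path) -> Molecule:
    """Read a standard XYZ file (count line, comment, element x y z in Å)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"empty XYZ file {path}")
    n = int(lines[0].split()[0])
    symbols, coords = [], []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        symbols.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    if len(symbols) != n:
        raise ValueError(f"XYZ file {path} declares {n} atoms, "
                         f"found {len(symbols)}")
    return Molecule(symbols, np.array(coords))


def write_xyz(molecule: Molecule, path, comment: str = "") -> None:
    lines = [str(molecule.n_atoms), comment.replace("\n", " ")]
    for s, xyz in zip(molecule.symbols, molecule.coords):
        lines.append(f"{s:<3s} {xyz[0]:18.12f} {xyz[1]:18.12f} "
                     f"{xyz[2]:18.12f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_nic_file(path) -> NICSet:
    """Parse a NIC definition file into a (normalized) NICSet."""
    blocks: list[dict] = []
    current: dict | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line == "[coordinate]":
            current = {"name": None, "irrep": None, "axis": None,
                       "terms": []}
            blocks.append(current)
            continue
        if current is None:
            raise ValueError(f"{path}: content before first [coordinate]")
        if "=" in line and line.split("=", 1)[0].strip() in (
            "name", "irrep", "axis"
        ):
            key, val = (s.strip() for s in line.split("=", 1))
            if key == "axis":
                current["axis"] = tuple(float(v) for v in val.split())
            else:
                current[key] = val
            continue
        parts = line.split()
        kind_file = parts[0].lower()
        if kind_file not in _KIND_MAP:
            raise ValueError(f"{path}: unknown primitive kind {parts[0]!r}")
        kind, arity = _KIND_MAP[kind_file]
        if len(parts) != arity + 2:
            raise ValueError(
                f"{path}: {kind_file} line needs {arity} atom indices and "
                f"a coefficient: {line!r}"
            )
        atoms = tuple(int(v) - 1 for v in parts[1 : 1 + arity])
        coeff = float(parts[-1])
        current["terms"].append((kind, atoms, coeff))
    if not blocks:
        raise ValueError(f"{path}: no coordinates defined")

    primitives: list[PrimitiveCoordinate] = []
    index: dict[tuple, int] = {}
    rows = []
    names, irreps = [], []
    for i, blk in enumerate(blocks):
        if not blk["terms"]:
            raise ValueError(f"{path}: coordinate block {i + 1} has no "
                             "primitive terms")
        row: dict[int, float] = {}
        for kind, atoms, coeff in blk["terms"]:
            axis = blk["axis"] if kind == "linear_bend" else None
            key = (kind, atoms, axis)
            if key not in index:
                index[key] = len(primitives)
                primitives.append(
                    PrimitiveCoordinate(kind, atoms, axis=axis)
                )
            row[index[key]] = row.get(index[key], 0.0) + coeff
        rows.append(row)
        names.append(blk["name"] or f"S{i + 1}")
        irreps.append(blk["irrep"])
    C = np.zeros((len(rows), len(primitives)))
    for i, row in enumerate(rows):
        for j, c in row.items():
            C[i, j] = c
    return NICSet(primitives, C, names=names, irreps=irreps)


def write_nic_file(nics: NICSet, path, header: str = "") -> None:
    lines = [f"# {ln}" for ln in header.splitlines() if ln]
    for i in range(nics.n):
        lines.append("")
        lines.append("[coordinate]")
        lines.append(f"name = {nics.names[i]}")
        if nics.irreps[i]:
            lines.append(f"irrep = {nics.irreps[i]}")
        axes = {p.axis for j, p in enumerate(nics.primitives)
                if nics.raw_coefficients[i, j] != 0
                and p.kind == "linear_bend" and p.axis is not None}
        if len(axes) == 1:
            ax = next(iter(axes))
            lines.append("axis = " + " ".join(f"{v:.15g}" for v in ax))
        for j, p in enumerate(nics.primitives):
            c = nics.raw_coefficients[i, j]
            if c == 0:
                continue
            idx = " ".join(str(a + 1) for a in p.atoms)
            lines.append(f"{_KIND_BACK[p.kind]} {idx}  {c:.15g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_hessian(ff: ForceField, path, units: str = "aJ-based") -> None:
    n = ff.n
    head = f"# basis={ff.basis} units={units} dim={n}"
    if ff.level:
        head += f" level={ff.level}"
    rows = [head]
    for i in range(n):
        rows.append(" ".join(f"{v:.15g}" for v in ff.matrix[i]))
    Path(path).write_text("\n".join(rows) + "\n")


def read_hessian(path) -> ForceField:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: missing Hessian header line")
    meta = dict(
        kv.split("=", 1) for kv in lines[0].lstrip("# ").split() if "=" in kv
    )
    dim = int(meta["dim"])
    data = np.array(
        [[float(v) for v in ln.split()] for ln in lines[1 : 1 + dim]]
    )
    if data.shape != (dim, dim):
        raise ValueError(f"{path}: expected a {dim}×{dim} matrix")
    return ForceField(data, meta.get("basis", "internal"),
                      meta.get("level"))
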