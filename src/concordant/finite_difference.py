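"""Displacement planning and finite-difference force-constant assembly.

Second derivatives of the energy are taken in the NIC basis (or in the
Level-B normal-mode basis when ``modes`` are supplied to the planner) with
central stencils of second- or fourth-order accuracy:

* diagonal, order 4: the 5-point stencil (−1, 16, −30, 16, −1)/12h²;
* diagonal, order 2: the 3-point stencil (1, −2, 1)/h²;
* off-diagonal, order 4: the tensor product of the 4-point first-derivative
  stencil (1, −8, 8, −1)/12h over offsets (−2, −1, +1, +2) in each of the
  two coordinates (16 energies, no axis points);
* off-diagonal, order 2: the 4-point cross formula over (±1, ±1).

All displaced geometries are generated through the curvilinear
back-transformation, so the stencils sample the energy along the true
curved coordinates.  The fourth-order stencils are exact for polynomial
potentials through degree 5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .internal_coords import NICSet, displace_internal
from .harmonic import ForceField, NormalModes
from .molecule import Molecule

__all__ = [
    "DisplacementPlan",
    "plan_displacements",
    "assemble_force_constants",
    "PartialForceField",
    "enforce_symmetry",
]

# first-derivative stencil, order 4: offset -> weight (×1/12h)
_D1_O4 = {-2: 1.0, -1: -8.0, 1: 8.0, 2: -1.0}
_D1_O2 = {-1: -1.0, 1: 1.0}  # ×1/2h
# diagonal second-derivative stencils: offset -> weight (×1/denom h²)
_D2_O4 = ({-2: -1.0, -1: 16.0, 0: -30.0, 1: 16.0, 2: -1.0}, 12.0)
_D2_O2 = ({-1: 1.0, 0: -2.0, 1: 1.0}, 1.0)


def _label(offsets: dict[int, int]) -> str:
    """Canonical job label, e.g. '2:+1;5:-2'; the reference is 'ref'."""
    items = sorted((i, m) for i, m in offsets.items() if m != 0)
    if not items:
        return "ref"
    return ";".join(f"{i}:{m:+d}" for i, m in items)


@dataclass
class DisplacementPlan:
    """Displaced geometries keyed by canonical labels.

    ``basis`` records whether displacements were taken along individual
    NICs ('internal') or along Level-B normal modes ('qb').
    """

    molecule: Molecule
    jobs: dict[str, np.ndarray]  # label -> N×3 coords
    step: float
    order: int
    elements: list[tuple[int, int]]
    basis: str = "internal"
    dim: int = 0  # full coordinate-space dimension

    @property
    def labels(self) -> list[str]:
        return list(self.jobs)

    def to_json(self) -> str:
        payload = {
            "step": self.step,
            "order": self.order,
            "basis": self.basis,
            "dim": self.dim,
            "elements": [list(e) for e in self.elements],
            "symbols": self.molecule.symbols,
            "masses": self.molecule.masses.tolist(),
            "jobs": {lab: xyz.tolist() for lab, xyz in self.jobs.items()},
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DisplacementPlan":
        d = json.loads(text)
        mol = Molecule(d["symbols"], np.asarray(d["jobs"]["ref"], float),
                       np.asarray(d["masses"], float))
        jobs = {lab: np.asarray(xyz, float) for lab, xyz in d["jobs"].items()}
        return cls(mol, jobs, d["step"], d["order"],
                   [tuple(e) for e in d["elements"]], d["basis"],
                   d.get("dim", 0))


def _offsets_for_element(i: int, j: int, order: int):
    """Yield {coord: multiple} dicts for one requested element."""
    if i == j:
        stencil = _D2_O4[0] if order == 4 else _D2_O2[0]
        for m in sorted(stencil):
            yield {i: m}
    else:
        d1 = _D1_O4 if order == 4 else _D1_O2
        for mi in sorted(d1):
            for mj in sorted(d1):
                yield {i: mi, j: mj}


def plan_displacements(
    nics: NICSet,
    molecule: Molecule,
    elements: list[tuple[int, int]],
    step: float = 0.01,
    order: int = 4,
    modes: NormalModes | None = None,
) -> DisplacementPlan:
    """Build the deduplicated set of displaced geometries for ``elements``.

    ``elements`` is a list of (i, j) index pairs with i ≤ j into the NIC
    list (or into the mode list when ``modes`` is given).  The undisplaced
    geometry is always included under the label 'ref'.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if order not in (2, 4):
        raise ValueError("stencil order must be 2 or 4")
    dim = modes.n if modes is not None else nics.n
    norm_elems: list[tuple[int, int]] = []
    for i, j in elements:
        if not (0 <= i <= j < dim):
            raise ValueError(f"element ({i},{j}) out of range for dim {dim}")
        norm_elems.append((i, j))
    norm_elems = sorted(set(norm_elems))

    jobs: dict[str, np.ndarray] = {"ref": molecule.coords.copy()}
    for i, j in norm_elems:
        for offs in _offsets_for_element(i, j, order):
            lab = _label(offs)
            if lab in jobs:
                continue
            dq = np.zeros(dim)
            for k, m in offs.items():
                dq[k] = m * step
            ds = modes.L @ dq if modes is not None else dq
            try:
                displaced = displace_internal(molecule, nics, ds)
            except Exception as exc:
                raise RuntimeError(
                    f"back-transformation failed for job {lab!r}: {exc}"
                ) from exc
            jobs[lab] = displaced.coords
    return DisplacementPlan(
        molecule, jobs, step, order, norm_elems,
        "qb" if modes is not None else "internal", dim,
    )


@dataclass
class PartialForceField:
    """Force constants for a requested subset of elements.

    ``present`` marks which elements were actually assembled; everything
    else is *absent*, not zero.
    """

    matrix: np.ndarray
    present: np.ndarray  # boolean mask, symmetric
    basis: str

    def to_force_field(self, fill: float = 0.0,
                       level: str | None = None) -> ForceField:
        m = np.where(self.present, self.matrix, fill)
        return ForceField(0.5 * (m + m.T), self.basis, level)

    def diagonal(self) -> np.ndarray:
        if not np.all(np.diag(self.present)):
            missing = np.nonzero(~np.diag(self.present))[0]
            raise ValueError(f"diagonal elements {missing.tolist()} absent")
        return np.diag(self.matrix).copy()

    def offdiagonal_items(self) -> list[tuple[tuple[int, int], float]]:
        out = []
        n = self.matrix.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                if self.present[i, j]:
                    out.append(((i, j), float(self.matrix[i, j])))
        return out


def assemble_force_constants(
    plan: DisplacementPlan, energies: dict[str, float]
) -> PartialForceField:
    """Second derivatives from planned energies (aJ per NIC-unit²)."""
    missing = [lab for lab in plan.labels if lab not in energies]
    if missing:
        raise KeyError(f"energies missing for labels: {missing}")
    h = plan.step
    dim = plan.dim
    if dim == 0 and plan.elements:
        dim = 1 + max(max(e) for e in plan.elements)
    F = np.zeros((dim, dim))
    present = np.zeros((dim, dim), dtype=bool)
    for i, j in plan.elements:
        if i == j:
            stencil, denom = _D2_O4 if plan.order == 4 else _D2_O2
            val = sum(
                w * energies[_label({i: m})] for m, w in stencil.items()
            ) / (denom * h * h)
        else:
            d1 = _D1_O4 if plan.order == 4 else _D1_O2
            denom = 12.0 if plan.order == 4 else 2.0
            val = sum(
                wi * wj * energies[_label({i: mi, j: mj})]
                for mi, wi in d1.items()
                for mj, wj in d1.items()
            ) / (denom * denom * h * h)
        F[i, j] = F[j, i] = val
        present[i, j] = present[j, i] = True
    return PartialForceField(F, present, plan.basis)


def enforce_symmetry(F: ForceField,
                     irreps: list[str | None] | None) -> ForceField:
    """Zero every element coupling coordinates/modes of different irreps.

    With no (or incomplete) labels this is a no-op with a warning — point
    group symmetry cannot be guessed.
    """
    if irreps is None or any(r is None for r in irreps):
        warnings.warn(
            "irrep labels missing; symmetry not enforced", stacklevel=2
        )
        return F
    if len(irreps) != F.n:
        raise ValueError("one irrep label required per index")
    lab = np.asarray(irreps, dtype=object)
    same = lab[:, None] == lab[None, :]
    return ForceField(np.where(same, F.matrix, 0.0), F.basis, F.level,
                      F.geometry_id)
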