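"""Synthetic molecules, NIC sets, quadratic potentials and correlated
Level A/B/C force-field triples.

The generator targets the statistical structure the CMA-2 selection
exploits, not electronic-structure physics: Level B differs from the
target Level A by small couplings Δ in the internal basis, and the cheap
auxiliary Level C differs from B such that its couplings track Δ with a
tunable fidelity ρ (ρ = 1: C's coupling pattern is an exact — sign-flipped
— copy of the A−B difference, the ideal "photographic negative"; ρ = 0:
uncorrelated noise).  Coupling magnitudes scale with √(F_ii·F_jj) so that
the ξ diagnostics land in the operating range of real multi-level force
fields (roughly 0.005–0.2).

All randomness flows through a single ``numpy.random.Generator`` seeded
per call; identical (parameters, seed) give bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .harmonic import ForceField
from .internal_coords import NICSet, PrimitiveCoordinate, build_b_matrix, \
    build_g_matrix
from .molecule import Molecule

__all__ = [
    "make_toy_molecule",
    "LevelTriple",
    "make_level_triple",
    "model_energy",
    "energies_for_plan",
    "make_ensemble",
]

log = logging.getLogger(__name__)

_KINDS = ("bent_triatomic", "linear_triatomic", "planar_ring", "chain")


def _bent_triatomic(rng: np.random.Generator):
    central = rng.choice(["O", "S", "N", "C"])
    term = rng.choice(["H", "H", "F", "Cl"], size=2)
    r1, r2 = rng.uniform(0.95, 1.45, size=2)
    theta = np.deg2rad(rng.uniform(95.0, 115.0))
    coords = np.array([
        [0.0, 0.0, 0.0],
        [r1, 0.0, 0.0],
        [r2 * np.cos(theta), r2 * np.sin(theta), 0.0],
    ])
    mol = Molecule([str(central), str(term[0]), str(term[1])], coords)
    prims = [
        PrimitiveCoordinate("bond", (0, 1)),
        PrimitiveCoordinate("bond", (0, 2)),
        PrimitiveCoordinate("angle", (1, 0, 2)),
    ]
    nics = NICSet(prims, np.eye(3),
                  names=["r1", "r2", "bend"],
                  irreps=["a1", "a1", "a1"])
    return mol, nics


def _linear_triatomic(rng: np.random.Generator):
    symbols = [["N", "N", "O"], ["O", "C", "O"], ["H", "C", "N"]][
        int(rng.integers(3))
    ]
    r1, r2 = rng.uniform(1.05, 1.25, size=2)
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r1], [0.0, 0.0, r1 + r2]])
    mol = Molecule(symbols, coords)
    prims = [
        PrimitiveCoordinate("bond", (0, 1)),
        PrimitiveCoordinate("bond", (1, 2)),
        PrimitiveCoordinate("linear_bend", (0, 1, 2)),
        PrimitiveCoordinate("linear_bend", (0, 1, 2)),
    ]
    nics = NICSet(prims, np.eye(4),
                  names=["r1", "r2", "linbend_a", "linbend_b"],
                  irreps=["sg", "sg", "pi", "pi"])
    nics = nics.resolve_linear_axes(coords)
    return mol, nics


# classic symmetry-adapted six-ring combinations: 6 stretch + 3 in-plane
# bend + 3 out-of-plane torsion rows span exactly the 12 ring DOF
_HEX_BONDS = [
    ("ring breathing", "a1", [1, 1, 1, 1, 1, 1]),
    ("ring str. def. 1", "b2", [1, -1, 1, -1, 1, -1]),
    ("ring str. def. 2", "a1", [2, -1, -1, 2, -1, -1]),
    ("ring str. def. 3", "b2", [2, 1, -1, -2, -1, 1]),
    ("ring str. def. 4", "a1", [0, 1, 1, 0, -1, -1]),
    ("ring str. def. 5", "b2", [0, 1, -1, 0, 1, -1]),
]
_HEX_ANGLES = [
    ("ring stellation", "a1", [1, -1, 1, -1, 1, -1]),
    ("ring rectangulation", "a1", [2, -1, -1, 2, -1, -1]),
    ("ring shearing", "b2", [0, 1, -1, 0, 1, -1]),
]
_HEX_TORSIONS = [
    ("chair pucker", "b1", [1, -1, 1, -1, 1, -1]),
    ("boat pucker", "b1", [0, 1, -1, 0, 1, -1]),
    ("ring twist", "a2", [2, -1, -1, 2, -1, -1]),
]


def _planar_ring(rng: np.random.Generator, n: int = 6):
    if n != 6:
        raise ValueError("planar_ring supports n = 6")
    radius = rng.uniform(1.35, 1.45)
    sym = rng.choice(["C", "N"], size=6, p=[0.85, 0.15]).tolist()
    ang = np.deg2rad(90.0 - 60.0 * np.arange(6))
    coords = np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)]
    )
    mol = Molecule(sym, coords)
    bonds = [PrimitiveCoordinate("bond", (i, (i + 1) % 6)) for i in range(6)]
    angles = [
        PrimitiveCoordinate("angle", ((i - 1) % 6, i, (i + 1) % 6))
        for i in range(6)
    ]
    torsions = [
        PrimitiveCoordinate(
            "torsion", ((i - 1) % 6, i, (i + 1) % 6, (i + 2) % 6)
        )
        for i in range(6)
    ]
    prims = bonds + angles + torsions
    rows, names, irreps = [], [], []
    for block, offset in ((_HEX_BONDS, 0), (_HEX_ANGLES, 6),
                          (_HEX_TORSIONS, 12)):
        for name, irr, coef in block:
            row = np.zeros(18)
            row[offset : offset + 6] = coef
            rows.append(row)
            names.append(name)
            irreps.append(irr)
    nics = NICSet(prims, np.array(rows), names=names, irreps=irreps)
    return mol, nics


def _chain(rng: np.random.Generator, n: int = 4):
    if n < 4:
        raise ValueError("chain needs at least 4 atoms")
    r = rng.uniform(1.45, 1.6)
    theta = np.deg2rad(rng.uniform(108.0, 114.0))
    tau = np.deg2rad(rng.choice([60.0, 180.0, -60.0], size=max(n - 3, 1)))
    coords = np.zeros((n, 3))
    coords[1] = [r, 0.0, 0.0]
    coords[2] = coords[1] + r * np.array(
        [-np.cos(theta), np.sin(theta), 0.0]
    )
    for i in range(3, n):
        # place atom i at bond r, angle theta, torsion tau[i-3]
        b1 = coords[i - 2] - coords[i - 3]
        b2 = coords[i - 1] - coords[i - 2]
        e2 = b2 / np.linalg.norm(b2)
        nvec = np.cross(b1, b2)
        nvec /= np.linalg.norm(nvec)
        m = np.cross(nvec, e2)
        t = tau[i - 3]
        d = (-e2 * np.cos(theta)
             + m * np.sin(theta) * np.cos(t)
             + nvec * np.sin(theta) * np.sin(t))
        coords[i] = coords[i - 1] + r * d
    mol = Molecule(["C"] * n, coords)
    prims = (
        [PrimitiveCoordinate("bond", (i, i + 1)) for i in range(n - 1)]
        + [PrimitiveCoordinate("angle", (i, i + 1, i + 2))
           for i in range(n - 2)]
        + [PrimitiveCoordinate("torsion", (i, i + 1, i + 2, i + 3))
           for i in range(n - 3)]
    )
    nics = NICSet(prims, np.eye(len(prims)))
    return mol, nics


def _random_field(nics: NICSet, rng: np.random.Generator) -> ForceField:
    """A positive-definite quadratic potential in the NIC basis with
    chemically plausible diagonal magnitudes per coordinate type."""
    diag_range = {"bond": (4.0, 8.0), "angle": (0.4, 1.2),
                  "linear_bend": (0.3, 0.9), "out_of_plane": (0.2, 0.7),
                  "torsion": (0.05, 0.35)}
    n = nics.n
    diag = np.empty(n)
    for i in range(n):
        dom = int(np.argmax(np.abs(nics.coefficients[i])))
        lo, hi = diag_range[nics.primitives[dom].kind]
        diag[i] = rng.uniform(lo, hi)
    c = rng.uniform(-0.08, 0.08, size=(n, n))
    c = np.triu(c, 1)
    F = np.diag(diag) + (c + c.T) * np.sqrt(np.outer(diag, diag))
    # enforce positive definiteness with an eigenvalue floor
    w, V = np.linalg.eigh(F)
    floor = 1e-2 * np.max(w)
    if w[0] < floor:
        F = (V * np.maximum(w, floor)) @ V.T
    return ForceField(0.5 * (F + F.T), "internal", "A")


def make_toy_molecule(kind: str, seed: int, n: int | None = None):
    """Generate (Molecule, NICSet, ForceField) for a supported kind.

    Kinds: ``bent_triatomic``, ``linear_triatomic``, ``planar_ring`` (six
    atoms) and ``chain`` (n ≥ 4 heavy atoms).  The NIC set is complete and
    nonredundant; the potential is positive definite and exactly quadratic
    in the NICs.
    """
    if kind not in _KINDS:
        raise ValueError(f"unsupported kind {kind!r}; choose from {_KINDS}")
    rng = np.random.default_rng(seed)
    if kind == "bent_triatomic":
        mol, nics = _bent_triatomic(rng)
    elif kind == "linear_triatomic":
        mol, nics = _linear_triatomic(rng)
    elif kind == "planar_ring":
        mol, nics = _planar_ring(rng, n or 6)
    else:
        mol, nics = _chain(rng, n or 4)
    return mol, nics, _random_field(nics, rng)


@dataclass
class LevelTriple:
    """Correlated Level A/B/C force fields in the internal basis."""

    F_A: ForceField
    F_B: ForceField
    F_C: ForceField
    params: dict = field(default_factory=dict)


def _sparse_symmetric(n: int, sparsity: float, scale: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    mask = rng.random((n, n)) < sparsity
    mag = rng.normal(size=(n, n))
    M = np.triu(mask * mag, 1) * scale
    return M + M.T


def make_level_triple(
    F_A: ForceField | np.ndarray,
    alpha: float = 0.03,
    beta: float = 0.03,
    rho: float = 0.9,
    sparsity: float = 0.5,
    seed: int = 0,
) -> LevelTriple:
    """Derive Level B and C fields from a target Level A field.

    F_B = F_A + α·Δ with Δ a sparse symmetric coupling perturbation whose
    elements scale with √(F_ii·F_jj); F_C = F_B + β·(ρ·Δ′ + (1−ρ)·noise)
    with Δ′ = −Δ, so that for ρ near 1 the ξ diagnostic computed from F_C
    ranks the A−B coupling differences faithfully.  If F_B comes out
    non-positive-definite, α is halved (logged) and Δ reapplied.
    """
    if isinstance(F_A, np.ndarray):
        F_A = ForceField(F_A, "internal", "A")
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [0, 1]")
    A = F_A.matrix
    if np.any(np.linalg.eigvalsh(A) <= 0):
        raise ValueError("F_A must be positive definite")
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    scale = np.sqrt(np.outer(np.diag(A), np.diag(A)))
    delta = _sparse_symmetric(n, sparsity, scale, rng)
    noise = _sparse_symmetric(n, sparsity, scale, rng)

    a = alpha
    for _ in range(20):
        B = A + a * delta
        if np.all(np.linalg.eigvalsh(B) > 0):
            break
        a *= 0.5
        log.info("damping alpha to %.3g to keep F_B positive definite", a)
    else:  # pragma: no cover - pathological inputs
        raise RuntimeError("could not keep F_B positive definite")

    b = beta
    for _ in range(20):
        C = B + b * (rho * (-delta) + (1.0 - rho) * noise)
        if np.all(np.diag(C) > 0):
            break
        b *= 0.5
        log.info("damping beta to %.3g to keep F_C diagonals positive", b)

    params = {"alpha": a, "beta": b, "rho": rho, "sparsity": sparsity,
              "seed": seed, "delta": delta}
    return LevelTriple(
        ForceField(A, "internal", "A"),
        ForceField(B, "internal", "B"),
        ForceField(C, "internal", "C"),
        params,
    )


def model_energy(geometry: np.ndarray, molecule: Molecule, nics: NICSet,
                 potential: ForceField) -> float:
    """E = ½ ΔSᵀ F ΔS (aJ) through the true curvilinear coordinates.

    ΔS is measured from the molecule's reference geometry; torsions are
    unwrapped toward their reference values so displaced geometries across
    the ±π cut are handled continuously.  Fulfills the energy-backend
    contract of the finite-difference module.
    """
    if potential.basis != "internal":
        raise ValueError("potential must be in the internal (NIC) basis")
    ref_prims = nics.primitive_values(molecule.coords)
    s0 = nics.evaluate(molecule.coords, ref_prims)
    s = nics.evaluate(np.asarray(geometry, float), ref_prims)
    ds = s - s0
    return float(0.5 * ds @ potential.matrix @ ds)


def energies_for_plan(plan, nics: NICSet,
                      potential: ForceField) -> dict[str, float]:
    """Evaluate the synthetic potential on every job of a plan."""
    mol = plan.molecule
    return {
        lab: model_energy(xyz, mol, nics, potential)
        for lab, xyz in plan.jobs.items()
    }


def make_ensemble(n_molecules: int, seed: int, alpha: float = 0.03,
                  beta: float = 0.03, rho: float = 0.9,
                  sparsity: float = 0.5):
    """Seeded ensemble of (molecule, nics, LevelTriple, G) study systems.

    Molecule kinds cycle through bent triatomics and 4–6 atom chains,
    giving vibrational dimensions between 3 and 12.
    """
    rng = np.random.default_rng(seed)
    out = []
    kinds = ["bent_triatomic", "chain", "chain", "chain"]
    sizes = [None, 4, 5, 6]
    for k in range(n_molecules):
        pick = k % len(kinds)
        sub = int(rng.integers(0, 2**31 - 1))
        mol, nics, F_A = make_toy_molecule(kinds[pick], sub, n=sizes[pick])
        triple = make_level_triple(
            F_A, alpha=alpha, beta=beta, rho=rho, sparsity=sparsity,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        B = build_b_matrix(nics, mol.coords)
        G = build_g_matrix(B, mol.masses)
        out.append((mol, nics, triple, G))
    return out
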