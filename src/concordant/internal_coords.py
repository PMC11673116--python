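"""Primitive internal coordinates, natural internal coordinates (NICs),
Wilson B and G matrices, and the iterative back-transformation.

Primitives are bonds r(i,j), angles θ(i,j,k) (vertex j), torsions
τ(i,j,k,l) (IUPAC sign, range (−π, π]), signed out-of-plane wags
γ(i,j,k,l) — the angle of the i–j bond out of the k–j–l plane, positive on
the side of (j→k)×(j→l) — and linear bends for quasilinear fragments.

A linear bend i–j–k measures the deviation from linearity projected on a
fixed reference unit vector ŵ perpendicular to the i···k axis:
q = −ŵ·(ê_ji + ê_jk), which equals π − θ(i,j,k) to first order.  Two bends
with perpendicular ŵ span the degenerate pair.  ŵ must be frozen at the
reference geometry (see :meth:`NICSet.resolve_linear_axes`) so that
displaced geometries are measured against the same axis.

Atom indices are 0-based throughout this module; the file format (and the
tables the packaged fixtures come from) is 1-based, converted at the I/O
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "PrimitiveCoordinate",
    "NICSet",
    "evaluate_primitive",
    "primitive_b_row",
    "build_b_matrix",
    "build_g_matrix",
    "check_nonredundancy",
    "RankReport",
    "displace_internal",
    "back_transform",
]

_ARITY = {"bond": 2, "angle": 3, "torsion": 4, "out_of_plane": 4,
          "linear_bend": 3}

#: singular values below RANK_TOL × (largest) count as zero
RANK_TOL = 1e-8


class DegenerateGeometryError(ValueError):
    """A geometry at which an internal coordinate is undefined."""


@dataclass(frozen=True)
class PrimitiveCoordinate:
    """One primitive internal coordinate.

    ``atoms`` are 0-based indices; ``axis`` is the reference perpendicular
    for linear bends (ignored otherwise).
    """

    kind: str
    atoms: tuple[int, ...]
    axis: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _ARITY:
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if len(self.atoms) != _ARITY[self.kind]:
            raise ValueError(
                f"{self.kind} takes {_ARITY[self.kind]} atoms, "
                f"got {len(self.atoms)}"
            )
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError(f"atom indices must be distinct: {self.atoms}")
        if any(a < 0 for a in self.atoms):
            raise ValueError("atom indices must be non-negative")

    def label(self) -> str:
        idx = ",".join(str(a + 1) for a in self.atoms)
        return f"{self.kind}({idx})"


def _unit(v: np.ndarray, what: str) -> tuple[np.ndarray, float]:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise DegenerateGeometryError(f"coincident atoms in {what}")
    return v / n, n


def evaluate_primitive(coord: PrimitiveCoordinate, geometry: np.ndarray) -> float:
    """Value of a primitive coordinate (Å for bonds, rad otherwise)."""
    x = np.asarray(geometry, dtype=float)
    if max(coord.atoms) >= x.shape[0]:
        raise IndexError(f"{coord.label()} references atoms beyond geometry")
    a = [x[i] for i in coord.atoms]
    if coord.kind == "bond":
        return float(np.linalg.norm(a[0] - a[1]))
    if coord.kind == "angle":
        u, _ = _unit(a[0] - a[1], coord.label())
        v, _ = _unit(a[2] - a[1], coord.label())
        return float(np.arccos(np.clip(u @ v, -1.0, 1.0)))
    if coord.kind == "torsion":
        b1, b2, b3 = a[1] - a[0], a[2] - a[1], a[3] - a[2]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
            raise DegenerateGeometryError(
                f"collinear atoms in a bounding plane of {coord.label()}"
            )
        b2h, _ = _unit(b2, coord.label())
        val = float(np.arctan2(np.cross(n1, n2) @ b2h, n1 @ n2))
        if abs(val + np.pi) < 1e-10:  # branch cut: report +π, not −π
            val = np.pi
        return val
    if coord.kind == "out_of_plane":
        # γ(i,j,k,l): i–j bond against the k–j–l plane
        u = a[0] - a[1]
        p = a[2] - a[1]
        q = a[3] - a[1]
        n = np.cross(p, q)
        nh, _ = _unit(n, f"{coord.label()} (collinear plane atoms)")
        uh, _ = _unit(u, coord.label())
        return float(np.arcsin(np.clip(nh @ uh, -1.0, 1.0)))
    # linear_bend
    if coord.axis is None:
        raise ValueError(
            f"linear bend {coord.label()} has no reference axis; call "
            "NICSet.resolve_linear_axes on the reference geometry first"
        )
    w = np.asarray(coord.axis, dtype=float)
    w, _ = _unit(w, coord.label())
    e1, _ = _unit(a[0] - a[1], coord.label())
    e2, _ = _unit(a[2] - a[1], coord.label())
    return float(-w @ (e1 + e2))


def primitive_b_row(coord: PrimitiveCoordinate, geometry: np.ndarray) -> np.ndarray:
    """Analytic gradient of a primitive coordinate w.r.t. Cartesians.

    Returns a length-3N row; entries of atoms not in the coordinate are
    exactly zero, and each Cartesian axis sums to zero (translational sum
    rule).
    """
    x = np.asarray(geometry, dtype=float)
    n_atoms = x.shape[0]
    row = np.zeros(3 * n_atoms)
    a = [x[i] for i in coord.atoms]

    def put(atom: int, g: np.ndarray) -> None:
        row[3 * atom : 3 * atom + 3] = g

    if coord.kind == "bond":
        e, _ = _unit(a[0] - a[1], coord.label())
        put(coord.atoms[0], e)
        put(coord.atoms[1], -e)
    elif coord.kind == "angle":
        u, ru = _unit(a[0] - a[1], coord.label())
        v, rv = _unit(a[2] - a[1], coord.label())
        c = np.clip(u @ v, -1.0, 1.0)
        s = np.sqrt(max(1.0 - c * c, 0.0))
        if s < 1e-10:
            raise DegenerateGeometryError(
                f"collinear atoms in {coord.label()}; use a linear bend"
            )
        gi = (c * u - v) / (ru * s)
        gk = (c * v - u) / (rv * s)
        put(coord.atoms[0], gi)
        put(coord.atoms[2], gk)
        put(coord.atoms[1], -(gi + gk))
    elif coord.kind == "torsion":
        b1, b2, b3 = a[1] - a[0], a[2] - a[1], a[3] - a[2]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        n1sq = float(n1 @ n1)
        n2sq = float(n2 @ n2)
        if n1sq < 1e-20 or n2sq < 1e-20:
            raise DegenerateGeometryError(
                f"collinear atoms in a bounding plane of {coord.label()}"
            )
        nb2 = float(np.linalg.norm(b2))
        gi = -(nb2 / n1sq) * n1
        gl = (nb2 / n2sq) * n2
        p = float(b1 @ b2) / nb2**2
        q = float(b3 @ b2) / nb2**2
        gj = -(1.0 + p) * gi + q * gl
        gk = p * gi - (1.0 + q) * gl
        put(coord.atoms[0], gi)
        put(coord.atoms[1], gj)
        put(coord.atoms[2], gk)
        put(coord.atoms[3], gl)
    elif coord.kind == "out_of_plane":
        u = a[0] - a[1]
        p = a[2] - a[1]
        q = a[3] - a[1]
        nvec = np.cross(p, q)
        nh, nn = _unit(nvec, f"{coord.label()} (collinear plane atoms)")
        uh, ru = _unit(u, coord.label())
        s = float(np.clip(nh @ uh, -1.0, 1.0))
        denom = np.sqrt(max(1.0 - s * s, 0.0))
        if denom < 1e-10:
            raise DegenerateGeometryError(
                f"{coord.label()} at ±π/2; gradient undefined"
            )
        ds_du = (nh - s * uh) / ru
        ds_dn = (uh - s * nh) / nn
        # δn = δp×q + p×δq  ⇒  δn·g = δp·(q×g) + δq·(g×p)
        ds_dp = np.cross(q, ds_dn)
        ds_dq = np.cross(ds_dn, p)
        gi = ds_du / denom
        gk = ds_dp / denom
        gl = ds_dq / denom
        put(coord.atoms[0], gi)
        put(coord.atoms[2], gk)
        put(coord.atoms[3], gl)
        put(coord.atoms[1], -(gi + gk + gl))
    else:  # linear_bend
        if coord.axis is None:
            raise ValueError(
                f"linear bend {coord.label()} has no reference axis"
            )
        w = np.asarray(coord.axis, dtype=float)
        w, _ = _unit(w, coord.label())
        e1, r1 = _unit(a[0] - a[1], coord.label())
        e2, r2 = _unit(a[2] - a[1], coord.label())
        gi = -(w - (w @ e1) * e1) / r1
        gk = -(w - (w @ e2) * e2) / r2
        put(coord.atoms[0], gi)
        put(coord.atoms[2], gk)
        put(coord.atoms[1], -(gi + gk))
    return row


@dataclass
class NICSet:
    """Natural internal coordinates: linear combinations of primitives.

    ``coefficients`` is the raw (n_NIC × n_primitive) combination matrix as
    defined (e.g. in a coordinate file); rows are normalized to unit
    Euclidean norm on construction so that a "displacement of 0.01 in NIC
    units" is well-defined.  The raw coefficients are retained for
    provenance in ``raw_coefficients``.
    """

    primitives: list[PrimitiveCoordinate]
    raw_coefficients: np.ndarray
    names: list[str] = field(default_factory=list)
    irreps: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.raw_coefficients = np.atleast_2d(
            np.asarray(self.raw_coefficients, dtype=float)
        )
        n_nic, n_prim = self.raw_coefficients.shape
        if n_prim != len(self.primitives):
            raise ValueError("coefficient columns must match primitives")
        norms = np.linalg.norm(self.raw_coefficients, axis=1)
        if np.any(norms < 1e-12):
            bad = int(np.argmin(norms))
            raise ValueError(f"NIC row {bad} has (near-)zero coefficients")
        self.coefficients = self.raw_coefficients / norms[:, None]
        if not self.names:
            self.names = [f"S{i + 1}" for i in range(n_nic)]
        if not self.irreps:
            self.irreps = [None] * n_nic
        if len(self.names) != n_nic or len(self.irreps) != n_nic:
            raise ValueError("names/irreps must have one entry per NIC")

    @property
    def n(self) -> int:
        return self.raw_coefficients.shape[0]

    def resolve_linear_axes(self, geometry: np.ndarray) -> "NICSet":
        """Freeze reference perpendiculars for linear bends at ``geometry``.

        Bends sharing the same atom triple get mutually perpendicular axes
        (an in-plane / out-of-plane degenerate pair), chosen
        deterministically from the i···k axis at the reference geometry.
        """
        x = np.asarray(geometry, dtype=float)
        new_prims: list[PrimitiveCoordinate] = []
        seen: dict[tuple[int, ...], int] = {}
        for p in self.primitives:
            if p.kind != "linear_bend" or p.axis is not None:
                new_prims.append(p)
                continue
            axis, _ = _unit(x[p.atoms[2]] - x[p.atoms[0]], p.label())
            trial = np.array([0.0, 0.0, 1.0])
            if abs(trial @ axis) > 0.9:
                trial = np.array([1.0, 0.0, 0.0])
            w1 = np.cross(trial, axis)
            w1 /= np.linalg.norm(w1)
            w2 = np.cross(axis, w1)
            k = seen.get(p.atoms, 0)
            seen[p.atoms] = k + 1
            w = (w1, w2)[k % 2]
            new_prims.append(replace(p, axis=tuple(float(v) for v in w)))
        return NICSet(new_prims, self.raw_coefficients.copy(),
                      list(self.names), list(self.irreps))

    def evaluate(self, geometry: np.ndarray,
                 reference_primitive_values: np.ndarray | None = None
                 ) -> np.ndarray:
        """NIC values; periodic primitives are unwrapped toward a reference.

        When ``reference_primitive_values`` is given, each torsion value is
        shifted by multiples of 2π to the branch nearest its reference, so
        finite displacements across the ±π cut stay continuous.
        """
        vals = np.array(
            [evaluate_primitive(p, geometry) for p in self.primitives]
        )
        if reference_primitive_values is not None:
            for i, p in enumerate(self.primitives):
                if p.kind == "torsion":
                    d = vals[i] - reference_primitive_values[i]
                    vals[i] -= 2.0 * np.pi * np.round(d / (2.0 * np.pi))
        return self.coefficients @ vals

    def primitive_values(self, geometry: np.ndarray) -> np.ndarray:
        return np.array(
            [evaluate_primitive(p, geometry) for p in self.primitives]
        )


def build_b_matrix(nics: NICSet, geometry: np.ndarray) -> np.ndarray:
    """Wilson B matrix for the NIC set: rows are ∂S_i/∂x (n_NIC × 3N)."""
    prim_rows = np.array(
        [primitive_b_row(p, geometry) for p in nics.primitives]
    )
    B = nics.coefficients @ prim_rows
    norms = np.linalg.norm(B, axis=1)
    if np.any(norms < 1e-10):
        bad = [nics.names[i] for i in np.nonzero(norms < 1e-10)[0]]
        raise ValueError(
            f"NIC combination(s) {bad} cancel to a zero B row at this "
            "geometry"
        )
    return B


def build_g_matrix(B: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Wilson G = B u Bᵀ with u the reciprocal-mass diagonal."""
    B = np.asarray(B, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    u = np.repeat(1.0 / masses, 3)
    G = (B * u) @ B.T
    return 0.5 * (G + G.T)


@dataclass
class RankReport:
    rank: int
    n_expected: int
    singular_values: np.ndarray
    tolerance: float

    @property
    def ok(self) -> bool:
        return self.rank == self.n_expected


def check_nonredundancy(B: np.ndarray, n_expected: int,
                        tol: float = RANK_TOL) -> RankReport:
    """Numerical-rank diagnostic for a candidate complete coordinate set."""
    s = np.linalg.svd(np.atleast_2d(B), compute_uv=False)
    cutoff = tol * (s[0] if s.size else 1.0)
    rank = int(np.sum(s > cutoff))
    return RankReport(rank, n_expected, s, cutoff)


def displace_internal(
    molecule,
    nics: NICSet,
    delta_s: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-12,
):
    """Find Cartesians realizing S(x) = S(x₀) + δS (δS in NIC units).

    Iterates the linearized relation δx = u Bᵀ G⁻¹ ΔS with B and G
    refreshed at every step; converges quadratically for small δS on a
    nonredundant set.
    """
    delta_s = np.asarray(delta_s, dtype=float)
    if delta_s.shape != (nics.n,):
        raise ValueError("delta_s must have one entry per NIC")
    x0 = molecule.coords
    ref_prims = nics.primitive_values(x0)
    s_target = nics.evaluate(x0, ref_prims) + delta_s
    u = molecule.reciprocal_mass_diagonal()
    x = x0.copy()
    for _ in range(max_iter):
        resid = s_target - nics.evaluate(x, ref_prims)
        if np.max(np.abs(resid)) < tol:
            return molecule.with_coords(x)
        B = build_b_matrix(nics, x)
        G = build_g_matrix(B, molecule.masses)
        dx = (u[:, None] * B.T) @ np.linalg.solve(G, resid)
        x = x + dx.reshape(-1, 3)
    resid = s_target - nics.evaluate(x, ref_prims)
    raise RuntimeError(
        "back-transformation did not converge after "
        f"{max_iter} iterations (residual norm "
        f"{float(np.linalg.norm(resid)):.3e})"
    )


def back_transform(molecule, delta_q: np.ndarray, modes, nics: NICSet,
                   max_iter: int = 50, tol: float = 1e-12):
    """Map a normal-mode displacement δQ to displaced Cartesians.

    Uses δS = L δQ and the same curvilinear iteration as
    :func:`displace_internal`.
    """
    delta_q = np.asarray(delta_q, dtype=float)
    delta_s = modes.L @ delta_q
    return displace_internal(molecule, nics, delta_s,
                             max_iter=max_iter, tol=tol)
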