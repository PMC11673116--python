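"""Wilson GF eigenproblem and Hessian basis transformations.

Force constants live in one of three bases:

* ``cartesian`` — the raw 3N×3N Hessian (aJ·Å⁻², mass-unweighted);
* ``internal`` — the NIC basis S (aJ·Å⁻² / aJ·Å⁻¹·rad⁻¹ / aJ·rad⁻²
  depending on the block);
* ``qb`` — the normal-mode basis Q_B of a lower-level (Level B) field,
  related by S = L_B Q_B.

The GF eigenproblem G F L = L Λ is solved through the symmetric square
root W of G: with G = W², the symmetric matrix W F W is diagonalized by an
orthonormal C, and L = W C.  This normalization gives LᵀF L = Λ and
L⁻¹ G L⁻ᵀ = I simultaneously (equivalently Lᵀ G⁻¹ L = I); any other
convention consistent with S = L Q yields identical frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .constants import eigenvalue_to_wavenumber

__all__ = [
    "ForceField",
    "NormalModes",
    "solve_gf",
    "cartesian_hessian_to_internal",
    "internal_to_qb",
    "qb_to_internal",
    "zpve",
    "cartesian_frequencies",
]

_BASES = ("cartesian", "internal", "qb")


@dataclass
class ForceField:
    """A symmetric force-constant matrix with basis and level provenance."""

    matrix: np.ndarray
    basis: str
    level: str | None = None
    geometry_id: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.basis not in _BASES:
            raise ValueError(f"basis must be one of {_BASES}")
        m = self.matrix
        if m.shape[0] != m.shape[1]:
            raise ValueError("force-constant matrix must be square")
        scale = max(float(np.max(np.abs(m))), 1e-300)
        if float(np.max(np.abs(m - m.T))) > 1e-12 * scale:
            raise ValueError("force-constant matrix is not symmetric")
        self.matrix = 0.5 * (m + m.T)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class NormalModes:
    """GF eigenvectors (columns of L, S-basis amplitude per unit Q),
    eigenvalues λ and harmonic wavenumbers ω (negative = imaginary)."""

    L: np.ndarray
    eigenvalues: np.ndarray
    frequencies: np.ndarray
    irreps: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.L = np.atleast_2d(np.asarray(self.L, dtype=float))
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if not self.irreps:
            self.irreps = [None] * self.n

    @property
    def n(self) -> int:
        return self.L.shape[1]


def _fix_column_signs(C: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """First component of each column larger than tol in magnitude made
    positive (stable tie-break for degenerate eigenvalues)."""
    C = C.copy()
    for k in range(C.shape[1]):
        col = C[:, k]
        nz = np.nonzero(np.abs(col) > tol * max(np.max(np.abs(col)), 1e-300))[0]
        if nz.size and col[nz[0]] < 0:
            C[:, k] = -col
    return C


def solve_gf(F: ForceField, G: np.ndarray,
             coordinate_irreps: list[str | None] | None = None
             ) -> NormalModes:
    """Solve the GF eigenproblem for an internal-basis force field.

    Modes are sorted by descending frequency (a stable sort, so degenerate
    pairs keep the eigenvector sign convention's order).  If per-coordinate
    irrep labels are supplied, each mode inherits the label of its dominant
    symmetry-adapted component.
    """
    if F.basis != "internal":
        raise ValueError("solve_gf expects an internal-basis force field")
    G = np.asarray(G, dtype=float)
    if float(np.max(np.abs(G - G.T))) > 1e-10 * max(float(np.max(np.abs(G))), 1e-300):
        raise ValueError("G matrix is not symmetric")
    gvals, gvecs = scipy.linalg.eigh(G)
    if gvals[0] <= 1e-10 * max(gvals[-1], 1e-300):
        raise ValueError(
            "G matrix is not positive definite (redundant or incomplete "
            "coordinate set)"
        )
    W = (gvecs * np.sqrt(gvals)) @ gvecs.T  # symmetric square root
    lam, C = scipy.linalg.eigh(W @ F.matrix @ W)
    C = _fix_column_signs(C)
    L = W @ C
    freqs = np.array([eigenvalue_to_wavenumber(v) for v in lam])
    order = np.argsort(-freqs, kind="stable")
    L = L[:, order]
    lam = lam[order]
    freqs = freqs[order]
    irreps: list[str | None] = [None] * len(lam)
    if coordinate_irreps is not None:
        C_sorted = C[:, order]
        for k in range(len(lam)):
            irreps[k] = coordinate_irreps[int(np.argmax(np.abs(C_sorted[:, k])))]
    return NormalModes(L, lam, freqs, irreps)


def cartesian_hessian_to_internal(
    F_x: ForceField,
    B: np.ndarray,
    G: np.ndarray,
    masses: np.ndarray,
    gradient: np.ndarray | None = None,
) -> ForceField:
    """Transform a Cartesian Hessian to the internal (NIC) basis.

    F_S = A F_x Aᵀ with A = G⁻¹ B u, the generalized-inverse coordinate
    transform.  The gradient-dependent curvature term is omitted: the
    transform is meant for optimized reference geometries.  If a gradient
    is supplied and its norm exceeds 1e−6 aJ/Å a warning is issued.
    """
    if F_x.basis != "cartesian":
        raise ValueError("expected a cartesian-basis force field")
    if gradient is not None:
        gnorm = float(np.linalg.norm(np.asarray(gradient, float)))
        if gnorm > 1e-6:
            warnings.warn(
                f"gradient norm {gnorm:.2e} aJ/Å exceeds 1e-06: geometry is "
                "not a stationary point; the internal-basis Hessian omits "
                "the gradient term",
                stacklevel=2,
            )
    u = np.repeat(1.0 / np.asarray(masses, float), 3)
    A = np.linalg.solve(np.asarray(G, float), np.asarray(B, float) * u)
    F_S = A @ F_x.matrix @ A.T
    return ForceField(0.5 * (F_S + F_S.T), "internal", F_x.level,
                      F_x.geometry_id)


def internal_to_qb(F_S: ForceField, modes: NormalModes) -> ForceField:
    """Congruence into the Level-B normal-mode basis: F_Q = LᵀF_S L."""
    if F_S.basis != "internal":
        raise ValueError("expected an internal-basis force field")
    if F_S.n != modes.n:
        raise ValueError("dimension mismatch between field and modes")
    F_Q = modes.L.T @ F_S.matrix @ modes.L
    return ForceField(0.5 * (F_Q + F_Q.T), "qb", F_S.level, F_S.geometry_id)


def qb_to_internal(F_Q: ForceField, modes: NormalModes) -> ForceField:
    """Inverse congruence: F_S = (L⁻¹)ᵀ F_Q L⁻¹ (the CMA ansatz)."""
    if F_Q.basis != "qb":
        raise ValueError("expected a qb-basis force field")
    cond = np.linalg.cond(modes.L)
    if cond > 1e10:
        warnings.warn(
            f"L matrix condition number {cond:.2e} > 1e10; the "
            "back-transformed force field may be inaccurate",
            stacklevel=2,
        )
    Linv = np.linalg.inv(modes.L)
    F_S = Linv.T @ F_Q.matrix @ Linv
    return ForceField(0.5 * (F_S + F_S.T), "internal", F_Q.level,
                      F_Q.geometry_id)


def zpve(frequencies) -> float:
    """Harmonic zero-point vibrational energy ½Σω (cm⁻¹).

    Imaginary modes (encoded as negative wavenumbers) are excluded with a
    warning.
    """
    w = np.asarray(frequencies, dtype=float)
    if w.size == 0:
        return 0.0
    if np.any(w < 0):
        warnings.warn(
            f"excluding {int(np.sum(w < 0))} imaginary mode(s) from the ZPVE",
            stacklevel=2,
        )
        w = w[w >= 0]
    return float(0.5 * np.sum(w))


def cartesian_frequencies(F_x: ForceField, masses: np.ndarray,
                          n_vib: int | None = None) -> np.ndarray:
    """Frequencies from the mass-weighted Cartesian Hessian (cm⁻¹).

    Diagonalizes M^{-1/2} F_x M^{-1/2} directly — the route independent of
    any internal-coordinate machinery.  Returns all 3N values sorted
    descending, or only the ``n_vib`` largest-magnitude vibrations if
    requested (rigid-motion eigenvalues cluster at zero).
    """
    if F_x.basis != "cartesian":
        raise ValueError("expected a cartesian-basis force field")
    m = np.repeat(np.asarray(masses, float), 3)
    H = F_x.matrix / np.sqrt(np.outer(m, m))
    vals = scipy.linalg.eigh(H, eigvals_only=True)
    freqs = np.array([eigenvalue_to_wavenumber(v) for v in vals])
    freqs = np.sort(freqs)[::-1]
    if n_vib is not None:
        keep = np.argsort(-np.abs(freqs), kind="stable")[:n_vib]
        freqs = np.sort(freqs[keep])[::-1]
    return freqs
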