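"""The Concordant Mode Approach: CMA-0, CMA-1 and the convergent CMA-2.

The idea: expensive (Level A) harmonic frequencies are computed in the
normal-mode basis Q_B of a cheap Level B field.  In that basis the Level-A
force-constant matrix F_CMA(A) is strongly diagonally dominant, so the
diagonal alone (CMA-0) already recovers the Level-A spectrum to a fraction
of a cm⁻¹ in typical cases.  CMA-1 adds n hand-picked couplings; CMA-2
selects couplings automatically from a still cheaper Level C field via the
dimensionless ξ diagnostic: couplings that move when going C → B are the
ones expected to move again going B → A (the "photographic negative").

ξ normalization is a pluggable strategy because the precise algebraic form
is an interpretive choice; the default divides each |F^C_ij| by the
geometric mean of the corresponding diagonal magnitudes.  The strategy used
is always recorded in the XiMatrix provenance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .harmonic import (ForceField, NormalModes, internal_to_qb,
                       qb_to_internal, solve_gf, zpve)

__all__ = [
    "XiMatrix",
    "xi_matrix",
    "select_offdiagonals",
    "eta",
    "assemble_cma_field",
    "cma_frequencies",
    "match_modes",
    "CMAResult",
    "run_cma",
    "OUTLIER_THRESHOLD",
]

#: |ϵ| above this (cm⁻¹) counts as a CMA outlier
OUTLIER_THRESHOLD = 1.5


@dataclass
class XiMatrix:
    """Dimensionless coupling-importance diagnostics (zero diagonal)."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(v < 0):
            raise ValueError("ξ entries must be non-negative")
        if float(np.max(np.abs(v - v.T))) > 1e-12 * max(float(v.max()), 1e-300):
            raise ValueError("ξ matrix must be symmetric")
        if float(np.max(np.abs(np.diag(v)))) > 0:
            raise ValueError("ξ diagonal must be zero")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def xi_matrix(F_C_qb: ForceField, normalization: str = "geometric_diag",
              lambda_b: np.ndarray | None = None) -> XiMatrix:
    """Build ξ from a Level-C field expressed in the Q_B basis.

    Strategies:

    * ``geometric_diag`` (default): ξ_ij = |F^C_ij| / √(|F^C_ii|·|F^C_jj|);
    * ``lambda_b``: ξ_ij = |F^C_ij| / √(λ_i λ_j), normalizing by the
      Level-B eigenvalues instead (requires ``lambda_b``).

    Both are invariant under overall positive scaling of F^C.
    """
    if F_C_qb.basis != "qb":
        raise ValueError("ξ requires the Level-C field in the Q_B basis")
    F = F_C_qb.matrix
    if normalization == "geometric_diag":
        d = np.abs(np.diag(F))
    elif normalization == "lambda_b":
        if lambda_b is None:
            raise ValueError("lambda_b normalization needs the Level-B "
                             "eigenvalues")
        d = np.abs(np.asarray(lambda_b, dtype=float))
    else:
        raise ValueError(f"unknown ξ normalization {normalization!r}")
    if np.any(d <= 0):
        raise ValueError(
            "zero diagonal/eigenvalue encountered; ξ normalization undefined"
        )
    xi = np.abs(F) / np.sqrt(np.outer(d, d))
    np.fill_diagonal(xi, 0.0)
    return XiMatrix(
        0.5 * (xi + xi.T),
        {"normalization": normalization, "level": F_C_qb.level},
    )


def select_offdiagonals(xi: XiMatrix, cutoff: float) -> set[tuple[int, int]]:
    """Pairs (i, j), i < j, with ξ_ij strictly greater than ``cutoff``.

    ``cutoff = inf`` selects nothing (CMA-0); selections are nested:
    a smaller cutoff always yields a superset.
    """
    if not (cutoff > 0):
        raise ValueError("cutoff must be positive (inf allowed)")
    if math.isinf(cutoff):
        return set()
    iu, ju = np.triu_indices(xi.n, k=1)
    keep = xi.values[iu, ju] > cutoff
    return {(int(i), int(j)) for i, j in zip(iu[keep], ju[keep])}


def eta(selection: set[tuple[int, int]], dof: int) -> float:
    """Included off-diagonals as a percentage of vibrational DOF.

    Full precision is returned; reports round to the nearest integer, the
    convention of the benchmark tables.
    """
    if dof <= 0:
        raise ValueError("dof must be positive")
    return 100.0 * len(selection) / dof


def assemble_cma_field(
    diagonal: np.ndarray,
    offdiagonals: list[tuple[tuple[int, int], float]],
    dimension: int | None = None,
    level: str | None = None,
) -> ForceField:
    """Build F_CMA from a complete diagonal plus selected couplings.

    Unselected off-diagonals are exactly zero (they are *omitted*, not
    merely small).
    """
    diagonal = np.asarray(diagonal, dtype=float)
    if dimension is None:
        dimension = diagonal.size
    if diagonal.size != dimension:
        raise ValueError(
            f"need all {dimension} diagonal values, got {diagonal.size}"
        )
    F = np.diag(diagonal.astype(float))
    for (i, j), v in offdiagonals:
        if i == j or not (0 <= i < dimension and 0 <= j < dimension):
            raise ValueError(f"invalid off-diagonal index pair ({i},{j})")
        F[i, j] = F[j, i] = v
    return ForceField(F, "qb", level)


def cma_frequencies(F_CMA: ForceField, modes_B: NormalModes,
                    G: np.ndarray) -> NormalModes:
    """Transform F_CMA(A) back to the S basis and solve GF_A."""
    F_A = qb_to_internal(F_CMA, modes_B)
    return solve_gf(F_A, G)


def match_modes(
    modes_ref: NormalModes,
    modes_cma: NormalModes,
    G: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair CMA modes with reference modes; return (permutation, ϵ).

    Columns of L are orthonormal under the G⁻¹ metric, so
    O = L_refᵀ G⁻¹ L_cma is an (near-)orthogonal overlap matrix.  Matching
    is greedy on |O| within equal-irrep pairs (all pairs when either side
    lacks labels), with a frequency-order fallback on ambiguous overlaps.
    ``permutation[k]`` is the CMA mode paired with reference mode k, and
    ϵ_k = ω_CMA,perm[k] − ω_ref,k.
    """
    if modes_ref.n != modes_cma.n:
        raise ValueError("mode sets must have equal dimension")
    n = modes_ref.n
    O = modes_ref.L.T @ np.linalg.solve(np.asarray(G, float), modes_cma.L)
    absO = np.abs(O)
    labelled = all(r is not None for r in modes_ref.irreps) and all(
        r is not None for r in modes_cma.irreps
    )
    allowed = np.ones((n, n), dtype=bool)
    if labelled:
        ref_lab = np.asarray(modes_ref.irreps, dtype=object)
        cma_lab = np.asarray(modes_cma.irreps, dtype=object)
        allowed = ref_lab[:, None] == cma_lab[None, :]
        if not np.all(allowed.sum(axis=1) > 0):
            allowed = np.ones((n, n), dtype=bool)  # inconsistent labels
    perm = -np.ones(n, dtype=int)
    score = np.where(allowed, absO, -1.0)
    order = np.argsort(-score, axis=None, kind="stable")
    taken_ref = np.zeros(n, dtype=bool)
    taken_cma = np.zeros(n, dtype=bool)
    flat = score.ravel()
    for idx in order:
        k, m = divmod(int(idx), n)
        if flat[idx] < 0 or taken_ref[k] or taken_cma[m]:
            continue
        # ambiguity check: another free candidate within 1e-6
        rivals = score[k, ~taken_cma]
        rivals = rivals[rivals >= 0]
        if rivals.size > 1:
            top2 = np.sort(rivals)[-2:]
            if abs(top2[1] - top2[0]) < 1e-6 and top2[0] >= 0:
                warnings.warn(
                    f"ambiguous mode overlap for reference mode {k}; "
                    "falling back to frequency ordering for this mode",
                    stacklevel=2,
                )
                free = np.nonzero(~taken_cma & allowed[k])[0]
                m = int(free[np.argmin(np.abs(
                    modes_cma.frequencies[free] - modes_ref.frequencies[k]
                ))])
        perm[k] = m
        taken_ref[k] = True
        taken_cma[m] = True
    if np.any(perm < 0):  # leftover (fully blocked rows): frequency order
        free_ref = np.nonzero(perm < 0)[0]
        free_cma = np.setdiff1d(np.arange(n), perm[perm >= 0])
        for k, m in zip(free_ref, free_cma):
            perm[k] = m
    eps = modes_cma.frequencies[perm] - modes_ref.frequencies
    return perm, eps


@dataclass
class CMAResult:
    """Everything one CMA run produces."""

    protocol: str
    selection: set[tuple[int, int]]
    F_CMA: ForceField
    modes: NormalModes
    frequencies: np.ndarray
    reference_frequencies: np.ndarray
    residuals: np.ndarray
    permutation: np.ndarray
    eta: float
    zpve_residual: float
    xi: XiMatrix | None = None

    @property
    def mae(self) -> float:
        return float(np.mean(np.abs(self.residuals)))

    @property
    def max_abs_residual(self) -> float:
        return float(np.max(np.abs(self.residuals)))

    def outliers(self, threshold: float = OUTLIER_THRESHOLD) -> list[int]:
        return np.nonzero(np.abs(self.residuals) > threshold)[0].tolist()


def run_cma(
    F_A: ForceField,
    F_B: ForceField,
    G: np.ndarray,
    F_C: ForceField | None = None,
    protocol: str = "cma0",
    cutoff: float = math.inf,
    pairs: list[tuple[int, int]] | None = None,
    xi_normalization: str = "geometric_diag",
    coordinate_irreps: list[str | None] | None = None,
) -> CMAResult:
    """Execute a full CMA protocol from internal-basis force fields.

    This is the zero-numerical-error benchmark route: F_CMA(A) is obtained
    by congruence of the exact Level-A field into the Q_B basis and then
    masked according to the protocol, exactly as done for reference
    statistics.  (In production the retained elements would instead come
    from finite differences of Level-A energies; see
    :mod:`concordant.finite_difference`.)
    """
    for ff, nm in ((F_A, "F_A"), (F_B, "F_B")):
        if ff.basis != "internal":
            raise ValueError(f"{nm} must be in the internal basis")
    modes_B = solve_gf(F_B, G, coordinate_irreps)
    F_CMA_full = internal_to_qb(F_A, modes_B)

    xi: XiMatrix | None = None
    if protocol == "cma0":
        selection: set[tuple[int, int]] = set()
    elif protocol == "cma1":
        if not pairs:
            raise ValueError("cma1 needs explicit pairs")
        selection = {(min(i, j), max(i, j)) for i, j in pairs}
    elif protocol == "cma2":
        if F_C is None:
            raise ValueError("cma2 needs a Level-C field")
        F_C_qb = internal_to_qb(F_C, modes_B) if F_C.basis == "internal" \
            else F_C
        xi = xi_matrix(F_C_qb, xi_normalization,
                       lambda_b=modes_B.eigenvalues)
        selection = select_offdiagonals(xi, cutoff)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    offd = [((i, j), float(F_CMA_full.matrix[i, j])) for i, j in selection]
    F_CMA = assemble_cma_field(np.diag(F_CMA_full.matrix), offd,
                               F_CMA_full.n, F_A.level)
    modes_cma = solve_gf(qb_to_internal(F_CMA, modes_B), G,
                         coordinate_irreps)
    modes_ref = solve_gf(F_A, G, coordinate_irreps)
    perm, eps = match_modes(modes_ref, modes_cma, G)
    dz = zpve(modes_cma.frequencies) - zpve(modes_ref.frequencies)
    return CMAResult(
        protocol=protocol,
        selection=selection,
        F_CMA=F_CMA,
        modes=modes_cma,
        frequencies=modes_cma.frequencies[perm],
        reference_frequencies=modes_ref.frequencies,
        residuals=eps,
        permutation=perm,
        eta=eta(selection, modes_B.n),
        zpve_residual=dz,
        xi=xi,
    )
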