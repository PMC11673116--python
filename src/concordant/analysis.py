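"""Total energy distributions and benchmark residual statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cma import run_cma
from .harmonic import ForceField, NormalModes

__all__ = ["ted", "TEDTable", "summary_stats", "SummaryStats",
           "convergence_curve"]


@dataclass
class TEDTable:
    """Per-mode signed percentage contributions of each coordinate.

    Entry (k, i) is the share of mode k's vibrational energy attributable
    to internal coordinate i; the sign records the relative phase in the
    eigenvector.  Rows sum to 100.  ``entries`` filters by a display
    threshold in the style of spectroscopic tables.
    """

    percentages: np.ndarray  # n_modes × n_coords, signed
    coordinate_names: list[str]

    def entries(self, mode: int, threshold: float = 5.0
                ) -> list[tuple[str, float]]:
        row = self.percentages[mode]
        keep = np.nonzero(np.abs(row) >= threshold)[0]
        keep = keep[np.argsort(-np.abs(row[keep]), kind="stable")]
        return [(self.coordinate_names[i], float(row[i])) for i in keep]

    def format_mode(self, mode: int, threshold: float = 5.0) -> str:
        parts = []
        for name, val in self.entries(mode, threshold):
            sign = "-" if val < 0 else ("+" if parts else "")
            parts.append(f"{sign} {name}({abs(val):.0f})".strip())
        return " ".join(parts)


def ted(modes: NormalModes, F_S: ForceField,
        coordinate_names: list[str] | None = None) -> TEDTable:
    """Total energy distribution: TED_ki = 100·L_ik·(F_S L)_ik / λ_k.

    Decomposes the potential energy of each normal mode over the internal
    coordinates (the standard eigenvector-weighted force-constant
    decomposition).  Modes with λ = 0 are skipped with a warning.
    """
    if F_S.basis != "internal":
        raise ValueError("TED needs the internal-basis force field")
    L = modes.L
    FL = F_S.matrix @ L
    out = np.full((modes.n, L.shape[0]), np.nan)
    for k in range(modes.n):
        lam = modes.eigenvalues[k]
        if abs(lam) < 1e-14:
            warnings.warn(f"mode {k} has zero eigenvalue; TED undefined",
                          stacklevel=2)
            continue
        out[k] = 100.0 * L[:, k] * FL[:, k] / lam
    if coordinate_names is None:
        coordinate_names = [f"S{i + 1}" for i in range(L.shape[0])]
    return TEDTable(out, coordinate_names)


@dataclass
class SummaryStats:
    """Benchmark residual statistics (all cm⁻¹).

    ``eps_max`` is the *average* per-molecule maximum absolute residual;
    ``eps_MAX`` is the global maximum over the whole set.  σ uses the
    sample (n−1) denominator.
    """

    mae: float
    mean: float
    sigma: float
    eps_max: float
    eps_MAX: float
    mae_zpve: float | None = None
    mean_zpve: float | None = None
    sigma_zpve: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _sample_std(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def summary_stats(residuals_by_molecule: list[np.ndarray],
                  zpve_residuals: np.ndarray | None = None) -> SummaryStats:
    """Pooled statistics over per-molecule residual sets."""
    groups = [np.asarray(r, dtype=float) for r in residuals_by_molecule
              if np.asarray(r).size]
    if not groups:
        raise ValueError("at least one residual is required")
    pooled = np.concatenate(groups)
    per_mol_max = np.array([np.max(np.abs(g)) for g in groups])
    stats = SummaryStats(
        mae=float(np.mean(np.abs(pooled))),
        mean=float(np.mean(pooled)),
        sigma=_sample_std(pooled),
        eps_max=float(np.mean(per_mol_max)),
        eps_MAX=float(np.max(per_mol_max)),
    )
    if zpve_residuals is not None:
        z = np.asarray(zpve_residuals, dtype=float)
        stats.mae_zpve = float(np.mean(np.abs(z)))
        stats.mean_zpve = float(np.mean(z))
        stats.sigma_zpve = _sample_std(z)
    return stats


def convergence_curve(
    triples: list[tuple[ForceField, ForceField, ForceField, np.ndarray]],
    cutoffs: list[float],
    xi_normalization: str = "geometric_diag",
) -> pd.DataFrame:
    """MAE/ϵ_MAX vs ξ-cutoff over an ensemble of (F_A, F_B, F_C, G).

    One row per cutoff with the mean η, the mean percentage of nonzero
    off-diagonals included, the MAE, ϵ_max and ϵ_MAX pooled over the
    ensemble — the data behind a cost/accuracy convergence plot.
    """
    rows = []
    for cutoff in cutoffs:
        residuals = []
        etas = []
        pct_incl = []
        zs = []
        for F_A, F_B, F_C, G in triples:
            res = run_cma(F_A, F_B, G, F_C=F_C, protocol="cma2",
                          cutoff=cutoff, xi_normalization=xi_normalization)
            residuals.append(res.residuals)
            etas.append(res.eta)
            zs.append(res.zpve_residual)
            n = res.F_CMA.n
            n_off = n * (n - 1) // 2
            pct_incl.append(100.0 * len(res.selection) / max(n_off, 1))
        stats = summary_stats(residuals, np.asarray(zs))
        rows.append({
            "cutoff": cutoff,
            "eta": float(np.mean(etas)),
            "pct_offdiag": float(np.mean(pct_incl)),
            "mae": stats.mae,
            "eps_max": stats.eps_max,
            "eps_MAX": stats.eps_MAX,
        })
    return pd.DataFrame(rows)
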