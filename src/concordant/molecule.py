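"""Molecular geometry container and the standard-atomic-weight table."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Standard atomic weights (amu), CIAAW 2021 abridged values, H through Kr.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "He": 4.0026,
    "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95,
    "K": 39.098, "Ca": 40.078, "Sc": 44.956, "Ti": 47.867, "V": 50.942,
    "Cr": 51.996, "Mn": 54.938, "Fe": 55.845, "Co": 58.933, "Ni": 58.693,
    "Cu": 63.546, "Zn": 65.38, "Ga": 69.723, "Ge": 72.630, "As": 74.922,
    "Se": 78.971, "Br": 79.904, "Kr": 83.798,
}


@dataclass
class Molecule:
    """Atoms, masses and Cartesian geometry (Å).

    ``masses`` may be omitted, in which case standard atomic weights are
    looked up from the element symbols.
    """

    symbols: list[str]
    coords: np.ndarray
    masses: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an N×3 array")
        n = len(self.symbols)
        if self.coords.shape[0] != n:
            raise ValueError("symbols and coords disagree on atom count")
        if n < 2:
            raise ValueError("a molecule needs at least 2 atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.masses is None:
            try:
                self.masses = np.array(
                    [ATOMIC_MASSES[s] for s in self.symbols], dtype=float
                )
            except KeyError as exc:  # pragma: no cover - data table gap
                raise KeyError(f"no mass tabulated for element {exc}") from exc
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (n,):
                raise ValueError("masses must have one entry per atom")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def n_vib(self) -> int:
        """Vibrational degrees of freedom: 3N−6, or 3N−5 if linear."""
        return 3 * self.n_atoms - (5 if self.is_linear() else 6)

    def is_linear(self, tol: float = 1e-6) -> bool:
        x = self.coords - self.coords.mean(axis=0)
        # all atoms on one line <=> second singular value ~ 0
        s = np.linalg.svd(x, compute_uv=False)
        return bool(s[1] < tol * max(s[0], 1.0))

    def reciprocal_mass_diagonal(self) -> np.ndarray:
        """The 3N-vector of reciprocal masses (the diagonal of u)."""
        return np.repeat(1.0 / self.masses, 3)

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        return Molecule(list(self.symbols), np.asarray(coords, float),
                        self.masses.copy())
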