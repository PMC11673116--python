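"""Packaged example systems.

The geometries shipped here are clearly-labeled idealized placeholders
(planar hexagon for pyridine, a force-field-relaxed conformer for
1-(1H-pyrrol-3-yl)ethanol) — adequate for exercising the coordinate,
transformation and selection machinery, not reference ab initio
structures.  The NIC definitions are the standard chemically intuitive
sets for these molecules.
"""

from __future__ import annotations

from importlib import resources

from .io import read_nic_file, read_xyz

__all__ = ["available_fixtures", "load_fixture"]

_FIXTURES = ("pyridine", "pyrrolylethanol")


def available_fixtures() -> tuple[str, ...]:
    return _FIXTURES


def load_fixture(name: str):
    """Return (Molecule, NICSet) for a packaged fixture.

    Linear-bend axes, if any, are resolved at the fixture geometry.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; have {_FIXTURES}")
    base = resources.files(__package__) / "data"
    with resources.as_file(base / f"{name}.xyz") as p:
        mol = read_xyz(p)
    with resources.as_file(base / f"{name}.nic") as p:
        nics = read_nic_file(p)
    return mol, nics.resolve_linear_axes(mol.coords)
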