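import numpy as np
import pytest

from concordant import (build_b_matrix, build_g_matrix, load_fixture,
                        make_toy_molecule)

TOY_KINDS = [("bent_triatomic", None), ("linear_triatomic", None),
             ("planar_ring", 6), ("chain", 5)]


@pytest.fixture(params=TOY_KINDS, ids=[k for k, _ in TOY_KINDS])
def toy_system(request):
    """(molecule, nics, potential) for each supported toy kind."""
    kind, n = request.param
    return make_toy_molecule(kind, seed=42, n=n)


@pytest.fixture(params=["pyridine", "pyrrolylethanol"])
def packaged_system(request):
    mol, nics = load_fixture(request.param)
    return mol, nics


def bg_matrices(mol, nics):
    B = build_b_matrix(nics, mol.coords)
    G = build_g_matrix(B, mol.masses)
    return B, G


def numerical_b_row(coord, geometry, h=1e-5):
    """Independent 5-point finite-difference gradient of a primitive."""
    from concordant import evaluate_primitive

    x = np.asarray(geometry, float).reshape(-1)
    g = np.zeros(x.size)
    for k in range(x.size):
        vals = []
        for m in (-2, -1, 1, 2):
            xx = x.copy()
            xx[k] += m * h
            vals.append(evaluate_primitive(coord, xx.reshape(-1, 3)))
        g[k] = (vals[0] - 8 * vals[1] + 8 * vals[2] - vals[3]) / (12 * h)
    return g
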