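"""Primitive coordinates, B/G matrices, and the back-transformation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from concordant import (DegenerateGeometryError, Molecule, NICSet,
                        PrimitiveCoordinate, back_transform, build_b_matrix,
                        build_g_matrix, check_nonredundancy,
                        displace_internal, evaluate_primitive,
                        make_toy_molecule, primitive_b_row, solve_gf)
from conftest import bg_matrices, numerical_b_row


def _random_geometry(seed, n=5, spread=1.5):
    return np.random.default_rng(seed).normal(size=(n, 3)) * spread


def _all_kinds_at(x):
    """One primitive of every kind, with a frozen linear-bend axis."""
    axis = x[2] - x[0]
    axis = axis / np.linalg.norm(axis)
    trial = np.array([0.0, 0.0, 1.0])
    if abs(trial @ axis) > 0.9:
        trial = np.array([1.0, 0.0, 0.0])
    w = np.cross(trial, axis)
    w /= np.linalg.norm(w)
    return [
        PrimitiveCoordinate("bond", (0, 1)),
        PrimitiveCoordinate("angle", (0, 1, 2)),
        PrimitiveCoordinate("torsion", (0, 1, 2, 3)),
        PrimitiveCoordinate("out_of_plane", (0, 1, 2, 3)),
        PrimitiveCoordinate("linear_bend", (0, 1, 2), axis=tuple(w)),
    ]


class TestEvaluate:
    def test_bond_distance(self):
        c = PrimitiveCoordinate("bond", (0, 1))
        x = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.5]])
        assert evaluate_primitive(c, x) == pytest.approx(1.5)

    def test_right_angle(self):
        c = PrimitiveCoordinate("angle", (0, 1, 2))
        x = np.array([[1.0, 0, 0], [0.0, 0, 0], [0.0, 1, 0]])
        assert evaluate_primitive(c, x) == pytest.approx(np.pi / 2)

    def test_coplanar_wag_is_zero(self):
        c = PrimitiveCoordinate("out_of_plane", (0, 1, 2, 3))
        x = np.array([[1.0, 1, 0], [0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]])
        assert evaluate_primitive(c, x) == pytest.approx(0.0, abs=1e-14)

    def test_wag_sign_convention(self):
        # i on the (j->k)x(j->l) side of the plane => positive
        x = np.array([[0.3, 0.3, 0.5], [0.0, 0, 0], [1.0, 0, 0],
                      [0.0, 1, 0]])
        c = PrimitiveCoordinate("out_of_plane", (0, 1, 2, 3))
        assert evaluate_primitive(c, x) > 0
        x[0, 2] = -0.5
        assert evaluate_primitive(c, x) < 0

    def test_torsion_range_and_branch(self):
        # trans arrangement sits exactly on the branch cut: report +pi
        x = np.array([[1.0, 0, 0], [0.0, 0, 0], [0.0, 0, 1.0],
                      [-1.0, 0, 1.0]])
        c = PrimitiveCoordinate("torsion", (0, 1, 2, 3))
        assert evaluate_primitive(c, x) == pytest.approx(np.pi)

    def test_degenerate_torsion_raises(self):
        x = np.array([[0.0, 0, 0], [0.0, 0, 1], [0.0, 0, 2],
                      [1.0, 0, 3]])
        c = PrimitiveCoordinate("torsion", (0, 1, 2, 3))
        with pytest.raises(DegenerateGeometryError, match="torsion"):
            evaluate_primitive(c, x)

    def test_bad_arity_rejected(self):
        with pytest.raises(ValueError):
            PrimitiveCoordinate("angle", (0, 1))
        with pytest.raises(ValueError):
            PrimitiveCoordinate("bond", (1, 1))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(4, 3)) * 1.5
        t = rng.normal(size=3)
        c = PrimitiveCoordinate("torsion", (0, 1, 2, 3))
        try:
            v0 = evaluate_primitive(c, x)
        except DegenerateGeometryError:
            return
        assert evaluate_primitive(c, x + t) == pytest.approx(v0, abs=1e-10)


class TestBRows:
    @pytest.mark.parametrize("seed", range(5))
    def test_rows_match_numerical_differentiation(self, seed):
        x = _random_geometry(seed)
        for c in _all_kinds_at(x):
            an = primitive_b_row(c, x)
            nu = numerical_b_row(c, x)
            assert np.max(np.abs(an - nu)) < 1e-8, c.kind

    def test_diatomic_unit_bond_vector(self):
        x = np.array([[0.0, 0, 0], [0.0, 0, 1.1]])
        row = primitive_b_row(PrimitiveCoordinate("bond", (0, 1)), x)
        assert row[2] == pytest.approx(-1.0)
        assert row[5] == pytest.approx(1.0)

    def test_uninvolved_atoms_exactly_zero(self):
        x = _random_geometry(1, n=6)
        row = primitive_b_row(PrimitiveCoordinate("angle", (0, 1, 2)), x)
        assert np.all(row[9:] == 0.0)

    def test_translational_sum_rule(self):
        x = _random_geometry(2)
        for c in _all_kinds_at(x):
            row = primitive_b_row(c, x).reshape(-1, 3)
            np.testing.assert_allclose(row.sum(axis=0), 0.0, atol=1e-10)

    def test_rotational_orthogonality(self):
        # a rigid infinitesimal rotation changes no internal coordinate
        x = _random_geometry(3)
        for c in _all_kinds_at(x):
            if c.kind == "linear_bend":
                continue  # its frozen axis is space-fixed by design
            row = primitive_b_row(c, x).reshape(-1, 3)
            for k in range(3):
                e = np.zeros(3)
                e[k] = 1.0
                rot = np.cross(e, x)  # displacement field of rotation
                assert abs(np.sum(row * rot)) < 1e-8


class TestBMatrix:
    def test_single_primitive_identity_combination(self):
        x = _random_geometry(4, n=3)
        prims = [PrimitiveCoordinate("bond", (0, 1))]
        nics = NICSet(prims, np.array([[1.0]]))
        B = build_b_matrix(nics, x)
        np.testing.assert_allclose(B[0], primitive_b_row(prims[0], x))

    def test_cancelling_combination_flagged(self):
        x = _random_geometry(5, n=3)
        p = PrimitiveCoordinate("bond", (0, 1))
        nics = NICSet([p, p], np.array([[1.0, -1.0]]))
        with pytest.raises(ValueError, match="zero B row"):
            build_b_matrix(nics, x)

    def test_hexagon_breathing_row_rotation_symmetry(self):
        # on a regular hexagon, the ring-breathing row maps onto itself
        # under 60-degree rotation of the atom labels
        mol, nics, _ = make_toy_molecule("planar_ring", seed=0, n=6)
        B = build_b_matrix(nics, mol.coords)
        breathing = B[0].reshape(-1, 3)
        th = np.deg2rad(-60.0)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        rotated = breathing @ R.T
        np.testing.assert_allclose(rotated, np.roll(breathing, -1, axis=0),
                                   atol=1e-10)


class TestGMatrix:
    def test_diatomic_closed_form(self):
        x = np.array([[0.0, 0, 0], [0.0, 0, 1.2]])
        masses = np.array([12.0, 16.0])
        nics = NICSet([PrimitiveCoordinate("bond", (0, 1))],
                      np.array([[1.0]]))
        G = build_g_matrix(build_b_matrix(nics, x), masses)
        assert G[0, 0] == pytest.approx(1 / 12.0 + 1 / 16.0)

    def test_infinite_mass_limit(self):
        x = np.array([[0.0, 0, 0], [0.0, 0, 1.2]])
        nics = NICSet([PrimitiveCoordinate("bond", (0, 1))],
                      np.array([[1.0]]))
        B = build_b_matrix(nics, x)
        G = build_g_matrix(B, np.array([1e12, 1e12]))
        assert abs(G[0, 0]) < 1e-11

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_triple_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        x = rng.normal(size=(n, 3)) * 1.5
        masses = rng.uniform(1.0, 30.0, size=n)
        prims = [PrimitiveCoordinate("bond", (i, (i + 1) % n))
                 for i in range(n)]
        nics = NICSet(prims, np.eye(n))
        B = build_b_matrix(nics, x)
        G = build_g_matrix(B, masses)
        brute = np.zeros_like(G)
        for i in range(n):
            for j in range(n):
                for a in range(n):
                    brute[i, j] += (1 / masses[a]) * (
                        B[i, 3 * a : 3 * a + 3] @ B[j, 3 * a : 3 * a + 3]
                    )
        assert np.max(np.abs(G - brute)) < 1e-12


class TestNonredundancy:
    def test_complete_set_passes(self, toy_system):
        mol, nics, _ = toy_system
        B = build_b_matrix(nics, mol.coords)
        rep = check_nonredundancy(B, mol.n_vib)
        assert rep.ok and rep.rank == mol.n_vib

    def test_duplicated_row_fails(self):
        mol, nics, _ = make_toy_molecule("bent_triatomic", seed=0)
        B = build_b_matrix(nics, mol.coords)
        B2 = np.vstack([B, B[0]])
        rep = check_nonredundancy(B2, B2.shape[0])
        assert not rep.ok
        assert rep.rank == B.shape[0]


class TestBackTransform:
    def test_zero_displacement_is_identity(self, toy_system):
        mol, nics, F = toy_system
        _, G = bg_matrices(mol, nics)
        modes = solve_gf(F, G)
        out = back_transform(mol, np.zeros(nics.n), modes, nics)
        np.testing.assert_allclose(out.coords, mol.coords, atol=1e-14)

    def test_homonuclear_diatomic_splits_evenly(self):
        mol = Molecule(["N", "N"], np.array([[0.0, 0, 0], [0.0, 0, 1.1]]))
        nics = NICSet([PrimitiveCoordinate("bond", (0, 1))],
                      np.array([[1.0]]))
        out = displace_internal(mol, nics, np.array([0.02]))
        assert out.coords[0, 2] == pytest.approx(-0.01, abs=1e-12)
        assert out.coords[1, 2] == pytest.approx(1.11, abs=1e-12)

    def test_heteronuclear_diatomic_mass_weighted_split(self):
        mol = Molecule(["H", "F"], np.array([[0.0, 0, 0], [0.0, 0, 0.92]]))
        nics = NICSet([PrimitiveCoordinate("bond", (0, 1))],
                      np.array([[1.0]]))
        delta = 0.015
        out = displace_internal(mol, nics, np.array([delta]))
        new_r = np.linalg.norm(out.coords[1] - out.coords[0])
        assert new_r == pytest.approx(0.92 + delta, abs=1e-12)
        # displacement split inversely proportional to the masses
        d0 = np.linalg.norm(out.coords[0] - mol.coords[0])
        d1 = np.linalg.norm(out.coords[1] - mol.coords[1])
        assert d0 / d1 == pytest.approx(mol.masses[1] / mol.masses[0],
                                        rel=1e-9)

    def test_target_internal_displacement_reached(self, toy_system):
        mol, nics, F = toy_system
        _, G = bg_matrices(mol, nics)
        modes = solve_gf(F, G)
        rng = np.random.default_rng(11)
        dq = rng.uniform(-0.05, 0.05, size=nics.n)
        out = back_transform(mol, dq, modes, nics)
        ref = nics.primitive_values(mol.coords)
        s_new = nics.evaluate(out.coords, ref)
        s_tgt = nics.evaluate(mol.coords, ref) + modes.L @ dq
        assert np.max(np.abs(s_new - s_tgt)) < 1e-10

    def test_nonconvergence_reports_residual(self):
        mol = Molecule(["H", "F"], np.array([[0.0, 0, 0], [0.0, 0, 0.92]]))
        nics = NICSet([PrimitiveCoordinate("bond", (0, 1))],
                      np.array([[1.0]]))
        with pytest.raises(RuntimeError, match="residual"):
            displace_internal(mol, nics, np.array([0.5]), max_iter=1)
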