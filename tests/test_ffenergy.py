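import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cleavescan.structio import Structure
from cleavescan.ffenergy import (
    EnergyModel,
    MinimizerConfig,
    ParameterError,
    default_forcefield,
    energy_filter,
    intra_energy,
    load_forcefield,
    nonbonded_energy,
    steepest_descent,
)
from cleavescan.fixtures import make_peptide


def two_atoms(r, nb, charges=(0.0, 0.0), bond=False):
    return Structure(
        ["X1", "X2"], [1, 2], ["UNK", "UNK"], ["A", "A"],
        np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]),
        elements=["C", "C"], charges=list(charges), nb_types=list(nb),
        bonds=[(0, 1)] if bond else [],
    )


def custom_params(text):
    return load_forcefield(io.StringIO(text))


class TestNonbonded:
    def test_zero_lj_zero_charge_is_zero(self):
        p = custom_params("[LJ]\nX 0 0\n")
        s = two_atoms(0.7, ("X", "X"))
        assert nonbonded_energy(s, [0], [1], p) == 0.0

    def test_coulomb_prefactor_against_physical_constants(self):
        # independent oracle: e^2 / (4 pi eps0 * 1 nm) in kJ/mol
        e = 1.602176634e-19
        eps0 = 8.8541878128e-12
        na = 6.02214076e23
        expected = e * e / (4 * math.pi * eps0 * 1e-9) * na / 1000.0
        p = custom_params("[LJ]\nX 0 0\n")
        s = two_atoms(1.0, ("X", "X"), charges=(1.0, 1.0))
        assert nonbonded_energy(s, [0], [1], p) == pytest.approx(
            expected, rel=1e-5
        )
        assert nonbonded_energy(s, [0], [1], p) == pytest.approx(138.935, abs=5e-3)

    def test_lj_minimum_closed_form(self):
        c12, c6 = 2.5e-5, 9.0e-3
        rstar = (2 * c12 / c6) ** (1 / 6)
        p = custom_params(f"[LJ]\nX {c12} {c6}\n")
        s = two_atoms(rstar, ("X", "X"))
        assert nonbonded_energy(s, [0], [1], p) == pytest.approx(
            -(c6**2) / (4 * c12), rel=1e-12
        )

    def test_symmetry(self, params, peptide):
        a = list(range(5))
        b = list(range(10, 20))
        assert nonbonded_energy(peptide, a, b, params) == nonbonded_energy(
            peptide, b, a, params
        )

    def test_rigid_motion_invariance(self, params, peptide):
        from scipy.spatial.transform import Rotation

        a, b = list(range(8)), list(range(12, 30))
        e0 = nonbonded_energy(peptide, a, b, params)
        rot = Rotation.from_rotvec([0.3, -1.2, 0.7])
        moved = peptide.with_coords(rot.apply(peptide.coords) + [1.0, -2.0, 0.5])
        e1 = nonbonded_energy(moved, a, b, params)
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_overlapping_groups_error(self, params, peptide):
        with pytest.raises(ValueError):
            nonbonded_energy(peptide, [0, 1], [1, 2], params)

    def test_zero_distance_error(self):
        p = custom_params("[LJ]\nX 1e-5 1e-3\n")
        s = two_atoms(0.0, ("X", "X"))
        with pytest.raises(FloatingPointError):
            nonbonded_energy(s, [0], [1], p)

    def test_bonded_neighbours_are_excluded(self, params, peptide):
        # atoms 0-1 are covalently linked: no nonbonded contribution
        i, j = sorted(next(iter(peptide.bonds)))
        assert nonbonded_energy(peptide, [i], [j], params) == 0.0


class TestIntra:
    def test_bond_at_rest_length_zero_energy(self):
        p = custom_params("[LJ]\nX 0 0\n[BONDS]\nX X 1e5 0.15\n")
        s = two_atoms(0.15, ("X", "X"), bond=True)
        e, g = intra_energy(s, [0, 1], p)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_stretched_bond_quadratic(self):
        k, b0, d = 1.0e5, 0.15, 0.013
        p = custom_params(f"[LJ]\nX 0 0\n[BONDS]\nX X {k} {b0}\n")
        s = two_atoms(b0 + d, ("X", "X"), bond=True)
        e, _ = intra_energy(s, [0, 1], p)
        assert e == pytest.approx(k * d * d, rel=1e-12)

    def test_gradient_matches_finite_differences(self, params):
        pep = make_peptide("AVS", "extended")
        model = EnergyModel(pep, params)
        x = pep.coords.copy()
        _, g = model.energy_grad(x)
        rng = np.random.default_rng(5)
        for _ in range(25):
            i = int(rng.integers(pep.n_atoms))
            k = int(rng.integers(3))
            h = 1e-6
            xp, xm = x.copy(), x.copy()
            xp[i, k] += h
            xm[i, k] -= h
            num = (model.energy(xp) - model.energy(xm)) / (2 * h)
            assert g[i, k] == pytest.approx(num, rel=1e-5, abs=1e-4)

    def test_missing_parameter_names_the_type(self):
        p = custom_params("[LJ]\nX 0 0\n")
        s = two_atoms(0.15, ("X", "X"), bond=True)
        with pytest.raises(ParameterError, match="X"):
            intra_energy(s, [0, 1], p)

    def test_mobile_subtotal_gradient_matches_full(self, params, peptide):
        mobile = list(range(10))
        _, g_sub = intra_energy(peptide, mobile, params)
        _, g_full = intra_energy(peptide, range(peptide.n_atoms), params)
        assert np.allclose(g_sub, g_full[:10], rtol=1e-12)


class TestSteepestDescent:
    def test_already_minimal_converges_immediately(self):
        p = custom_params("[LJ]\nX 0 0\n[BONDS]\nX X 1e5 0.15\n")
        s = two_atoms(0.15, ("X", "X"), bond=True)
        _, n, conv = steepest_descent(s, [0, 1], p)
        assert conv and n <= 1

    def test_stretched_bond_relaxes_to_rest_length(self):
        p = custom_params("[LJ]\nX 0 0\n[BONDS]\nX X 1e5 0.15\n")
        s = two_atoms(0.24, ("X", "X"), bond=True)
        out, _, _ = steepest_descent(
            s, [1], p, MinimizerConfig(max_steps=100, energy_tol=1e-6)
        )
        b = np.linalg.norm(out.coords[1] - out.coords[0])
        assert b == pytest.approx(0.15, abs=1e-3)

    def test_clashed_lj_pair_separates(self):
        c12, c6 = 2.5e-5, 9.0e-3
        rstar = (2 * c12 / c6) ** (1 / 6)
        p = custom_params(f"[LJ]\nX {c12} {c6}\n")
        s = two_atoms(0.15, ("X", "X"))
        out, _, _ = steepest_descent(
            s, [1], p, MinimizerConfig(max_steps=200, energy_tol=1e-9,
                                       initial_step=0.01)
        )
        e, _ = intra_energy(out, [0, 1], p)
        r = np.linalg.norm(out.coords[1] - out.coords[0])
        assert e < 0
        assert r >= rstar - 1e-2

    def test_only_mobile_atoms_move(self, params, poi):
        body, pep, plan = poi
        mobile = list(range(10))
        out, _, _ = steepest_descent(pep, mobile, params)
        assert np.array_equal(out.coords[10:], pep.coords[10:])
        assert not np.array_equal(out.coords[:10], pep.coords[:10])

    def test_max_steps_honoured(self):
        p = custom_params("[LJ]\nX 0 0\n[BONDS]\nX X 1e5 0.15\n")
        s = two_atoms(0.5, ("X", "X"), bond=True)
        _, n, _ = steepest_descent(
            s, [1], p, MinimizerConfig(max_steps=3, energy_tol=1e-12,
                                       initial_step=1e-4, step_grow=1.0)
        )
        assert n == 3

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_energy_never_increases(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        coords = rng.normal(0.0, 0.15, (n, 3))
        s = Structure(
            [f"X{i}" for i in range(n)], list(range(1, n + 1)), ["UNK"] * n,
            ["A"] * n, coords, elements=["C"] * n, nb_types=["X"] * n,
        )
        p = custom_params("[LJ]\nX 2.5e-5 9e-3\n")
        model = EnergyModel(s, p)
        e0 = model.energy(s.coords)
        out, _, _ = steepest_descent(s, range(n), p)
        e1 = model.energy(out.coords)
        assert e1 <= e0 + 1e-9


class TestEnergyFilter:
    def test_zero_is_not_negative(self):
        assert energy_filter([("a", -5.0), ("b", 0.0), ("c", 3.0)]) == ["a"]

    def test_all_positive_empty(self):
        assert energy_filter([(i, float(i + 1)) for i in range(5)]) == []

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        energies = rng.normal(0.0, 10.0, 200)
        items = list(enumerate(energies))
        expected = [i for i, e in items if e < 0.0]
        assert energy_filter(items) == expected


class TestTableParser:
    def test_bundled_table_loads(self):
        p = default_forcefield()
        assert p.lj_pair("CH3", "CH3")[0] > 0
        assert p.charges["O"] == -0.45

    def test_cross_pair_geometric_combination(self):
        p = custom_params("[LJ]\nA 4e-6 4e-3\nB 1e-6 1e-3\n")
        c12, c6 = p.lj_pair("A", "B")
        assert c12 == pytest.approx(2e-6)
        assert c6 == pytest.approx(2e-3)

    def test_explicit_pair_overrides_combination(self):
        p = custom_params("[LJ]\nA 4e-6 4e-3\nB 1e-6 1e-3\nA B 9e-6 9e-3\n")
        assert p.lj_pair("B", "A") == (9e-6, 9e-3)

    def test_malformed_line_errors_with_line_number(self):
        with pytest.raises(ValueError, match="line 2"):
            custom_params("[LJ]\nA oops 0\n")
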