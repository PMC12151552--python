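"""Structure factors, energy/force assembly and the full pipeline."""

import numpy as np
import pytest
from scipy.special import erf

import glst
from glst.core import (
    GLSTConfig,
    compute_basis,
    compute_cell_structure_factors,
    compute_total,
    long_range_energy_forces,
    remove_net_force,
    short_range_energy_forces,
    sum_remote_structure_factors,
)
from glst.cubature import calibrate_cubature
from glst.geometry import (
    assign_atoms_to_cells,
    build_alpha_groups,
    build_cell_grid,
    build_cell_neighbor_list,
)
from glst.oracle import direct_coulomb
from glst.system import ParticleSystem

KE = glst.COULOMB_CONSTANT


def _system(positions, charges, box):
    positions = np.asarray(positions, float)
    return ParticleSystem(
        positions=positions,
        charges=np.asarray(charges, float),
        labels=["X"] * len(positions),
        box=box,
    )


@pytest.fixture(scope="module")
def small_cubature():
    return calibrate_cubature(6.4, 33.3, 0.4, 1e-3, seed=0).cubature


class TestBasis:
    def test_zero_charge(self, small_cubature):
        C, S = compute_basis(np.array([1.0, 2.0, 3.0]), 0.0, small_cubature)
        assert not C.any() and not S.any()

    def test_origin(self, small_cubature):
        C, S = compute_basis(np.zeros(3), 0.7, small_cubature)
        assert np.allclose(C, 0.7)
        assert np.allclose(S, 0.0)

    def test_pythagorean_identity(self, small_cubature, rng):
        r = rng.random(3) * 10
        C, S = compute_basis(r, -0.42, small_cubature)
        assert np.allclose(C**2 + S**2, 0.42**2, atol=1e-13)


class TestStructureFactors:
    def _grid_group(self, system, eps=1e-3):
        grid0 = build_cell_grid(system.box, 6.4)
        grid, ss = assign_atoms_to_cells(system, grid0)
        groups = build_alpha_groups(grid, eps)
        for g in groups:
            cal = calibrate_cubature(g.d_min, g.d_max, g.alpha, eps, seed=0)
            g.zeta, g.cubature = cal.zeta, cal.cubature
        return grid, ss, groups

    def test_single_atom_cell_equals_basis(self):
        s = _system([[3.0, 3.0, 3.0]], [0.5], box=(32, 32, 32))
        grid, ss, groups = self._grid_group(s)
        sf = compute_cell_structure_factors(ss, grid, groups[0])
        C, S = compute_basis(ss.positions[0], 0.5, groups[0].cubature)
        assert np.allclose(sf.C[0], C, atol=1e-14)
        assert np.allclose(sf.S[0], S, atol=1e-14)

    def test_opposite_charges_cancel(self):
        s = _system([[3.0, 3.0, 3.0], [3.0, 3.0, 3.0]], [0.8, -0.8],
                    box=(32, 32, 32))
        grid, ss, groups = self._grid_group(s)
        sf = compute_cell_structure_factors(ss, grid, groups[0])
        assert np.allclose(sf.C, 0.0, atol=1e-14)
        assert np.allclose(sf.S, 0.0, atol=1e-14)

    def test_naive_loop_oracle_50_atoms(self, rng):
        """Vectorized per-cell sums match a per-atom python loop to 1e-12."""
        pos = rng.random((50, 3)) * 6.4
        q = rng.normal(size=50)
        s = _system(pos, q, box=(32, 32, 32))
        grid, ss, groups = self._grid_group(s)
        group = groups[0]
        sf = compute_cell_structure_factors(ss, grid, group)
        C_loop = np.zeros(group.cubature.n_nodes)
        S_loop = np.zeros(group.cubature.n_nodes)
        for i in range(50):
            Ci, Si = compute_basis(ss.positions[i], ss.charges[i],
                                   group.cubature)
            C_loop += Ci
            S_loop += Si
        scale = np.abs(C_loop).max()
        assert np.allclose(sf.C[0], C_loop, atol=1e-12 * scale)
        assert np.allclose(sf.S[0], S_loop, atol=1e-12 * scale)
        # linearity: cell sums add up to the whole-system sum
        assert np.allclose(sf.C.sum(axis=0), C_loop, atol=1e-12 * scale)

    def test_remote_sum_excludes_self_and_neighbors(self, rng):
        pos = rng.random((40, 3)) * 32
        s = _system(pos, rng.normal(size=40), box=(32, 32, 32))
        grid, ss, groups = self._grid_group(s)
        nbr = build_cell_neighbor_list(grid, groups)
        sf = compute_cell_structure_factors(ss, grid, groups[0])
        for cell in (0, 62):
            remote = nbr.long_range[0][cell]
            assert cell not in remote
            assert not np.intersect1d(remote, nbr.short_range[cell]).size
            Csum, Ssum = sum_remote_structure_factors(cell, nbr, sf)
            assert np.allclose(Csum, sf.C[remote].sum(axis=0), atol=1e-13)
            assert np.allclose(Ssum, sf.S[remote].sum(axis=0), atol=1e-13)

    def test_remote_sums_reproduce_cell_pair_sums(self, rng):
        """4^3-grid check: summed remote factors equal explicit pair sums."""
        pos = rng.random((60, 3)) * 25.6
        s = _system(pos, rng.normal(size=60), box=(25.6, 25.6, 25.6))
        grid0 = build_cell_grid(s.box, 6.4)
        grid, ss = assign_atoms_to_cells(s, grid0)
        groups = build_alpha_groups(grid, 1e-2)
        for g in groups:
            cal = calibrate_cubature(g.d_min, g.d_max, g.alpha, 1e-2, seed=0)
            g.zeta, g.cubature = cal.zeta, cal.cubature
        nbr = build_cell_neighbor_list(grid, groups)
        sf = compute_cell_structure_factors(ss, grid, groups[0])
        for cell in range(grid.n_cells):
            Csum, _ = sum_remote_structure_factors(cell, nbr, sf)
            explicit = sum(
                (sf.C[c2] for c2 in nbr.long_range[0][cell]),
                start=np.zeros(groups[0].cubature.n_nodes),
            )
            assert np.allclose(Csum, explicit, atol=1e-13)


class TestPairOracle:
    def test_two_atom_erf_pair(self):
        """Atoms in cells at separation 2 reproduce k_e q1 q2 erf(ar)/r."""
        eps = 1e-4
        q1, q2 = 0.9, -0.6
        s = _system([[3.2, 3.2, 3.2], [16.3, 4.1, 5.0]], [q1, q2],
                    box=(32, 32, 32))
        grid0 = build_cell_grid(s.box, 6.4)
        grid, ss = assign_atoms_to_cells(s, grid0)
        groups = build_alpha_groups(grid, eps)
        for g in groups:
            cal = calibrate_cubature(g.d_min, g.d_max, g.alpha, eps, seed=0)
            g.zeta, g.cubature = cal.zeta, cal.cubature
        nbr = build_cell_neighbor_list(grid, groups)
        e_l, f_l, _ = long_range_energy_forces(ss, grid, groups, nbr)
        r_vec = s.positions[0] - s.positions[1]
        r = np.linalg.norm(r_vec)
        a = groups[0].alpha
        expected = q1 * q2 * erf(a * r) / r
        tol = eps * abs(q1 * q2) * 2
        assert e_l[0] == pytest.approx(expected, abs=tol)
        assert e_l[1] == pytest.approx(expected, abs=tol)
        # force: -d/dr of the pair kernel, along the separation axis
        dkernel = (
            2 * a / np.sqrt(np.pi) * np.exp(-(a * r) ** 2) / r
            - erf(a * r) / r**2
        )
        f_expected = -q1 * q2 * dkernel * (r_vec / r)
        assert np.allclose(f_l[0], f_expected, atol=tol)
        assert np.allclose(f_l[1], -f_expected, atol=tol)

    def test_translation_invariance(self):
        eps = 1e-3
        s = _system([[3.2, 3.2, 3.2], [16.3, 4.1, 5.0]], [1.0, 1.0],
                    box=(32, 32, 32))
        shifted = ParticleSystem(
            positions=s.positions + np.array([1.7, 0.9, 1.1]),
            charges=s.charges, labels=["X", "X"], box=s.box,
        )
        res = []
        for sys_ in (s, shifted):
            grid0 = build_cell_grid(sys_.box, 6.4)
            grid, ss = assign_atoms_to_cells(sys_, grid0)
            groups = build_alpha_groups(grid, eps)
            for g in groups:
                cal = calibrate_cubature(g.d_min, g.d_max, g.alpha, eps,
                                         seed=0)
                g.zeta, g.cubature = cal.zeta, cal.cubature
            nbr = build_cell_neighbor_list(grid, groups)
            e_l, _, _ = long_range_energy_forces(ss, grid, groups, nbr)
            res.append(e_l[0])
        # kernel depends on pair separation only; the finite-cubature
        # residual bounds the translation sensitivity
        assert res[0] == pytest.approx(res[1], abs=2 * eps)


class TestShortRange:
    def _setup(self, positions, charges, box, cutoff):
        s = _system(positions, charges, box)
        grid0 = build_cell_grid(s.box, cutoff)
        grid, ss = assign_atoms_to_cells(s, grid0)
        groups = build_alpha_groups(grid, 1e-3)
        nbr = build_cell_neighbor_list(grid, groups)
        return ss, grid, nbr

    def test_unit_charges_one_angstrom(self):
        ss, grid, nbr = self._setup(
            [[1.0, 1.0, 1.0], [2.0, 1.0, 1.0]], [1.0, 1.0], (3, 3, 3), 3.0
        )
        e, f, total = short_range_energy_forces(ss, grid, nbr)
        assert KE * total == pytest.approx(332.0637141)
        assert KE * f[0][0] == pytest.approx(-332.0637141)
        assert KE * f[1][0] == pytest.approx(332.0637141)

    def test_far_pairs_not_included(self):
        # atoms in cells at Chebyshev separation 3 contribute nothing here
        ss, grid, nbr = self._setup(
            [[1.0, 1.0, 1.0], [23.0, 1.0, 1.0]], [1.0, 1.0], (32, 32, 32), 6.4
        )
        e, f, total = short_range_energy_forces(ss, grid, nbr)
        assert total == 0.0
        assert np.allclose(f, 0.0)

    def test_naive_loop_oracle(self, rng):
        """Two-cell system matches an all-pairs loop restricted to
        short-range pairs to 1e-12 relative."""
        pos = np.concatenate([
            rng.random((50, 3)) * 6.4,
            rng.random((50, 3)) * 6.4 + np.array([6.4, 0, 0]),
        ])
        q = rng.normal(size=100)
        ss, grid, nbr = self._setup(pos, q, (32, 32, 32), 6.4)
        e, f, total = short_range_energy_forces(ss, grid, nbr)
        e_loop = np.zeros(100)
        f_loop = np.zeros((100, 3))
        p, qs = ss.positions, ss.charges
        for i in range(100):
            for j in range(i + 1, 100):
                rv = p[i] - p[j]
                r = np.linalg.norm(rv)
                pair = qs[i] * qs[j] / r
                e_loop[i] += 0.5 * pair
                e_loop[j] += 0.5 * pair
                f_loop[i] += pair / r**2 * rv
                f_loop[j] -= pair / r**2 * rv
        assert np.allclose(e, e_loop, rtol=1e-12, atol=1e-12)
        assert np.allclose(f, f_loop, rtol=1e-12, atol=1e-12)

    def test_coincident_charged_atoms_raise(self):
        ss, grid, nbr = self._setup(
            [[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]], [1.0, -1.0], (3, 3, 3), 3.0
        )
        with pytest.raises(ZeroDivisionError, match="coincident"):
            short_range_energy_forces(ss, grid, nbr)


class TestComputeTotal:
    def test_small_grid_equals_direct(self, rng):
        """<= 3 cells per axis: no long-range part, exact Coulomb."""
        pos = rng.random((30, 3)) * 9.0
        s = _system(pos, rng.normal(size=30), box=(9, 9, 9))
        res = compute_total(s, cutoff=3.0, epsilon=1e-4)
        ref = direct_coulomb(s)
        assert res.total_energy == pytest.approx(ref.total_energy, rel=1e-12)
        assert np.allclose(res.forces, ref.forces, rtol=1e-12, atol=1e-12)
        assert res.metadata["groups"] == []

    def test_38_atom_single_cell_box(self):
        """The smallest benchmark box in one cell reduces to direct Coulomb."""
        rec = glst.table1_recipes(seed=5)[0]
        assert (rec.n_water, rec.n_nacl, rec.n_atoms) == (12, 1, 38)
        s = glst.build_salt_water_box(rec)
        res = compute_total(s, cutoff=8.0, epsilon=1e-4)
        ref = direct_coulomb(s)
        assert res.total_energy == pytest.approx(ref.total_energy, rel=1e-12)

    def test_charge_scaling_quadratic(self, rng):
        pos = rng.random((25, 3)) * 9.0
        q = rng.normal(size=25)
        s1 = _system(pos, q, box=(9, 9, 9))
        s2 = _system(pos, 3.0 * q, box=(9, 9, 9))
        r1 = compute_total(s1, 3.0, 1e-3)
        r2 = compute_total(s2, 3.0, 1e-3)
        assert r2.total_energy == pytest.approx(9 * r1.total_energy,
                                                rel=1e-12)
        assert np.allclose(r2.forces, 9 * r1.forces, rtol=1e-12, atol=1e-10)

    def test_total_is_sum_of_per_atom_and_breakdown(self, box349, config):
        res = compute_total(box349, 3.2, 1e-2, config)
        assert res.total_energy == pytest.approx(res.per_atom_energy.sum(),
                                                 rel=1e-10)
        assert res.total_energy == pytest.approx(
            sum(res.breakdown.values()), rel=1e-10
        )

    def test_input_order_restored(self, rng):
        pos = rng.random((40, 3)) * 32
        q = rng.normal(size=40)
        s = _system(pos, q, box=(32, 32, 32))
        res = compute_total(s, 6.4, 1e-2)
        # permute atoms; energies must permute identically
        perm = rng.permutation(40)
        s2 = _system(pos[perm], q[perm], box=(32, 32, 32))
        res2 = compute_total(s2, 6.4, 1e-2)
        assert np.allclose(res2.per_atom_energy, res.per_atom_energy[perm],
                           rtol=1e-10, atol=1e-10)


class TestRemoveNetForce:
    def test_balanced_forces_unchanged(self, rng):
        f = rng.normal(size=(30, 3))
        f -= f.mean(axis=0)
        assert np.allclose(remove_net_force(f), f, atol=1e-15)

    def test_uniform_forces_vanish(self):
        f = np.tile([1.0, -2.0, 0.5], (10, 1))
        assert np.allclose(remove_net_force(f), 0.0)

    def test_net_force_removed_and_change_is_mean(self, rng):
        f = rng.normal(size=(50, 3))
        out = remove_net_force(f)
        assert np.allclose(out.sum(axis=0), 0.0, atol=1e-13)
        assert np.allclose(f - out, f.mean(axis=0), atol=1e-15)
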