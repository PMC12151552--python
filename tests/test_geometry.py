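"""Cell grid, atom binning, alpha-group shells and neighbour classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfc

from glst.geometry import (
    assign_atoms_to_cells,
    build_alpha_groups,
    build_cell_grid,
    build_cell_neighbor_list,
    choose_alpha,
)
from glst.system import ParticleSystem


def _system(positions, box):
    positions = np.asarray(positions, float)
    n = positions.shape[0]
    return ParticleSystem(
        positions=positions,
        charges=np.ones(n),
        labels=["X"] * n,
        box=box,
    )


class TestBuildCellGrid:
    @pytest.mark.parametrize(
        "box, cutoff, n_expected, edge_expected",
        [
            ((64, 64, 64), 12.8, 5, 12.8),
            ((32, 32, 32), 9.0, 3, 32 / 3),
            ((256, 256, 256), 20.0, 12, 256 / 12),
        ],
    )
    def test_cell_counts_and_stretching(self, box, cutoff, n_expected,
                                        edge_expected):
        grid = build_cell_grid(box, cutoff)
        assert np.all(grid.n_cells_per_axis == n_expected)
        assert np.allclose(grid.cell_edge, edge_expected)
        assert np.all(grid.cell_edge >= cutoff - 1e-12)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            build_cell_grid((10, 10, 10), 11.0)
        with pytest.raises(ValueError):
            build_cell_grid((10, 10, 10), 0.0)


class TestAssignAtoms:
    def test_single_atom_first_cell(self):
        s = _system([[0.1, 0.1, 0.1]], box=(2, 2, 2))
        grid = build_cell_grid(s.box, 1.0)
        filled, _ = assign_atoms_to_cells(s, grid)
        assert filled.cell_of_atom[0] == 0
        assert filled.cell_count[0] == 1
        assert filled.cell_count.sum() == 1

    def test_stability_within_cell(self):
        pos = np.column_stack([
            np.linspace(0.1, 0.9, 20),
            np.full(20, 0.5),
            np.full(20, 0.5),
        ])
        s = _system(pos, box=(4, 4, 4))
        grid = build_cell_grid(s.box, 1.0)
        filled, sorted_sys = assign_atoms_to_cells(s, grid)
        # all in cell 0; stable sort keeps input order
        assert np.all(filled.sorted_order == np.arange(20))
        assert np.allclose(sorted_sys.positions, pos)

    def test_counts_match_histogram(self, rng):
        pos = rng.random((1000, 3)) * 8.0
        s = _system(pos, box=(8, 8, 8))
        grid = build_cell_grid(s.box, 2.0)
        filled, _ = assign_atoms_to_cells(s, grid)
        assert filled.cell_count.sum() == 1000
        # independent recount
        coords = np.floor(pos / filled.cell_edge).astype(int)
        lin = np.ravel_multi_index(coords.T, tuple(filled.n_cells_per_axis))
        expected = np.bincount(lin, minlength=filled.n_cells)
        assert np.array_equal(filled.cell_count, expected)

    def test_sort_round_trip(self, rng):
        pos = rng.random((200, 3)) * 6.0
        s = _system(pos, box=(6, 6, 6))
        grid = build_cell_grid(s.box, 2.0)
        filled, sorted_sys = assign_atoms_to_cells(s, grid)
        inv = np.empty(200, int)
        inv[np.arange(200)] = np.argsort(filled.sorted_order, kind="stable")
        # applying the inverse permutation recovers the input bit-exactly
        restored = sorted_sys.positions[np.argsort(filled.sorted_order,
                                                   kind="stable")]
        assert np.array_equal(restored, pos)

    def test_atom_outside_box_rejected(self):
        s = _system([[5.0, 1.0, 1.0]], box=(4, 4, 4))
        grid = build_cell_grid(s.box, 1.0)
        with pytest.raises(ValueError, match="outside the box"):
            assign_atoms_to_cells(s, grid)

    def test_atoms_inside_assigned_cells(self, rng):
        pos = rng.random((300, 3)) * 9.0
        s = _system(pos, box=(9, 9, 9))
        grid = build_cell_grid(s.box, 2.0)
        filled, sorted_sys = assign_atoms_to_cells(s, grid)
        coords = np.array(
            np.unravel_index(filled.cell_of_atom,
                             tuple(filled.n_cells_per_axis))
        ).T
        lo = coords * filled.cell_edge
        hi = (coords + 1) * filled.cell_edge
        assert np.all(sorted_sys.positions >= lo - 1e-12)
        assert np.all(sorted_sys.positions <= hi + 1e-12)


class TestAlphaGroups:
    def test_5cube_shells(self):
        grid = build_cell_grid((32, 32, 32), 6.4)
        groups = build_alpha_groups(grid, 1e-4)
        assert [(g.shell_min, g.shell_max) for g in groups] == [(2, 2), (3, 4)]
        assert [g.thickness for g in groups] == [1, 2]

    def test_3cube_empty(self):
        grid = build_cell_grid((9, 9, 9), 3.0)
        assert build_alpha_groups(grid, 1e-4) == []

    def test_12cube_shells_cover_exactly_once(self):
        grid = build_cell_grid((96, 96, 96), 8.0)
        groups = build_alpha_groups(grid, 1e-4)
        assert [(g.shell_min, g.shell_max) for g in groups] == [
            (2, 2), (3, 4), (5, 8), (9, 11)
        ]
        # exhaustive: every separation >= 2 covered by exactly one group
        for sep in range(2, 12):
            covering = [
                g.index for g in groups if g.shell_min <= sep <= g.shell_max
            ]
            assert len(covering) == 1

    def test_thickness_law(self):
        grid = build_cell_grid((96, 96, 96), 8.0)
        groups = build_alpha_groups(grid, 1e-4)
        remaining = 10  # separations 2..11
        for g, expected in zip(groups, [1, 2, 4, 8]):
            assert g.thickness == min(expected, remaining)
            remaining -= g.thickness

    def test_d_min_lower_bounds_pairs(self, rng):
        grid = build_cell_grid((40, 40, 40), 5.0)
        groups = build_alpha_groups(grid, 1e-4)
        for g in groups:
            # random atoms in cells at separation shell_min along x
            a = rng.random((200, 3)) * grid.cell_edge
            b = rng.random((200, 3)) * grid.cell_edge
            b[:, 0] += g.shell_min * grid.cell_edge[0]
            d = np.linalg.norm(a - b, axis=1)
            assert np.all(d >= g.d_min - 1e-12)

    def test_epsilon_validation(self):
        grid = build_cell_grid((32, 32, 32), 6.4)
        for bad in (0.0, -1.0, 1.0, 2.0):
            with pytest.raises(ValueError):
                build_alpha_groups(grid, bad)


class TestChooseAlpha:
    KE = 332.0637141

    def test_defining_property(self):
        """The remainder bound holds at the returned alpha, not at 0.99x."""
        for d_min, eps in [(6.4, 1e-4), (10.0, 1e-4), (3.0, 1e-2)]:
            a = choose_alpha(d_min, eps)
            bound = eps / self.KE
            assert erfc(a * d_min) / d_min <= bound * (1 + 1e-9)
            assert erfc(0.99 * a * d_min) / d_min > bound

    def test_internal_unit_scale(self):
        a = choose_alpha(10.0, 1e-4, pair_energy_scale=1.0)
        assert erfc(a * 10.0) / 10.0 <= 1e-4 * (1 + 1e-9)
        assert erfc(0.99 * a * 10.0) / 10.0 > 1e-4

    def test_grid_scan_oracle(self):
        d_min, eps = 10.0, 1e-4
        a = choose_alpha(d_min, eps)
        scan = np.linspace(0.5 * a, 1.5 * a, 20001)
        ok = erfc(scan * d_min) / d_min <= eps / self.KE
        a_scan = scan[np.argmax(ok)]
        assert a == pytest.approx(a_scan, rel=1e-3)

    @given(st.floats(min_value=1.0, max_value=30.0),
           st.sampled_from([1e-2, 1e-4, 1e-6]))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_distance(self, d_min, eps):
        assert choose_alpha(2 * d_min, eps) < choose_alpha(d_min, eps)


@pytest.fixture(scope="module")
def grid5():
    return build_cell_grid((32, 32, 32), 6.4)


class TestNeighborList:

    def test_interior_cell_26_neighbors(self, grid5):
        groups = build_alpha_groups(grid5, 1e-4)
        nbr = build_cell_neighbor_list(grid5, groups)
        center = grid5.linear_index(np.array([[2, 2, 2]]))[0]
        assert len(nbr.short_range[center]) == 26

    def test_corner_cell_7_neighbors(self, grid5):
        groups = build_alpha_groups(grid5, 1e-4)
        nbr = build_cell_neighbor_list(grid5, groups)
        assert len(nbr.short_range[0]) == 7

    def test_7cube_group1_count(self):
        grid = build_cell_grid((56, 56, 56), 8.0)
        groups = build_alpha_groups(grid, 1e-4)
        nbr = build_cell_neighbor_list(grid, groups)
        center = grid.linear_index(np.array([[3, 3, 3]]))[0]
        assert len(nbr.long_range[0][center]) == 5**3 - 3**3

    @pytest.mark.parametrize("n_cells", [3, 4, 5, 7, 12])
    def test_partition_property(self, n_cells):
        grid = build_cell_grid((8.0 * n_cells,) * 3, 8.0)
        groups = build_alpha_groups(grid, 1e-4)
        nbr = build_cell_neighbor_list(grid, groups)
        for c in range(grid.n_cells):
            total = 1 + len(nbr.short_range[c]) + sum(
                len(lr[c]) for lr in nbr.long_range
            )
            assert total == grid.n_cells
            # no overlap between classifications
            all_listed = np.concatenate(
                [nbr.short_range[c]] + [lr[c] for lr in nbr.long_range]
            )
            assert len(np.unique(all_listed)) == len(all_listed)
            assert c not in all_listed
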