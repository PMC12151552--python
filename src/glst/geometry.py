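"""Spatial decomposition for the erf/erfc-split Coulomb solver.

The box is tiled by congruent cells of edge >= the direct-space cutoff.  Each
cell interacts directly (full 1/r Coulomb) with itself and its 26 nearest
neighbours; everything further away is handled in reciprocal form through one
of several *alpha groups*: concentric shells of cells, of thickness doubling
outward (1, 2, 4, ...), each carrying its own Ewald parameter alpha, radial
truncation zeta and cubature certified for that shell's distance range.

Cell separations are measured in the Chebyshev (max) norm, so shells are cubic
rings.  There are no periodic images anywhere: boundary cells simply have
fewer neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from .system import ParticleSystem

__all__ = [
    "CellGrid",
    "AlphaGroup",
    "CellNeighborList",
    "build_cell_grid",
    "assign_atoms_to_cells",
    "build_alpha_groups",
    "choose_alpha",
    "build_cell_neighbor_list",
]


@dataclass
class CellGrid:
    """Cubic spatial decomposition, optionally with atoms binned into cells.

    ``cell_of_atom``, ``cell_start``, ``cell_count`` and ``sorted_order`` are
    filled by :func:`assign_atoms_to_cells`; a freshly built grid is geometry
    only.  ``sorted_order[k]`` is the original index of the atom stored at
    sorted position ``k``.
    """

    n_cells_per_axis: np.ndarray  # (3,) int
    cell_edge: np.ndarray  # (3,) float, Å
    cell_of_atom: np.ndarray | None = None
    cell_start: np.ndarray | None = None
    cell_count: np.ndarray | None = None
    sorted_order: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.n_cells_per_axis))

    @property
    def max_separation(self) -> int:
        """Largest possible Chebyshev separation between two cells."""
        return int(self.n_cells_per_axis.max()) - 1

    def cell_coords(self) -> np.ndarray:
        """(n_cells, 3) integer coordinates of every cell, in linear order."""
        nx, ny, nz = (int(v) for v in self.n_cells_per_axis)
        ii = np.indices((nx, ny, nz)).reshape(3, -1).T
        return ii

    def linear_index(self, coords: np.ndarray) -> np.ndarray:
        return np.ravel_multi_index(
            tuple(np.asarray(coords).T), tuple(self.n_cells_per_axis)
        )


@dataclass
class AlphaGroup:
    """One doubling shell of cells with its Ewald parameter and cubature.

    ``shell_min``/``shell_max`` bound the Chebyshev cell separations the group
    covers; ``d_min``/``d_max`` bound the atom-atom distances any pair of
    atoms in cells of this shell can realise (conservative corner-to-corner
    bounds).  ``alpha`` makes the neglected erfc remainder at ``d_min`` fall
    below the target error; ``zeta`` and ``cubature`` are attached by the
    calibration stage.
    """

    index: int
    shell_min: int
    shell_max: int
    d_min: float
    d_max: float
    alpha: float
    zeta: float | None = None
    cubature: object | None = None

    @property
    def thickness(self) -> int:
        return self.shell_max - self.shell_min + 1


@dataclass
class CellNeighborList:
    """Per-cell classification of all other cells.

    ``short_range[c]`` holds the linear indices of the <=26 cells at Chebyshev
    separation 1 from cell ``c``; ``long_range[g][c]`` holds the cells whose
    separation falls in alpha group ``g``'s shell.  Together with ``{c}``
    itself these partition the grid for every cell.
    """

    short_range: list
    long_range: list  # long_range[group][cell] -> int array


def build_cell_grid(box, cutoff: float) -> CellGrid:
    """Tile ``box`` with the coarsest grid of congruent cells of edge >= cutoff.

    ``n_cells[i] = floor(box[i]/cutoff)`` and cells are stretched to
    ``box[i]/n_cells[i]`` so they tile the box exactly; every edge is then at
    least the cutoff, so direct interactions never reach past the 26
    neighbours.
    """
    box = np.asarray(box, dtype=np.float64).reshape(3)
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    if np.any(box < cutoff):
        raise ValueError(
            f"cutoff {cutoff} exceeds a box edge {box.tolist()}; invalid geometry"
        )
    n = np.floor(box / cutoff + 1e-9).astype(int)  # tolerate exact division
    n = np.maximum(n, 1)
    return CellGrid(n_cells_per_axis=n, cell_edge=box / n)


def assign_atoms_to_cells(
    system: ParticleSystem, grid: CellGrid
) -> tuple[CellGrid, ParticleSystem]:
    """Bin atoms into cells and sort them cell-contiguously (stable).

    Returns a filled copy of ``grid`` and the cell-sorted system.  The sort is
    a stable counting sort: within a cell, atoms keep their original relative
    order, and ``sorted_order`` maps sorted slots back to input indices so
    downstream energies/forces can be returned in input order.
    """
    system.validate_in_box()
    coords = np.floor(system.positions / grid.cell_edge[None, :]).astype(int)
    coords = np.minimum(coords, grid.n_cells_per_axis[None, :] - 1)
    cell_idx = grid.linear_index(coords)
    order = np.argsort(cell_idx, kind="stable")
    counts = np.bincount(cell_idx, minlength=grid.n_cells).astype(np.int64)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    filled = CellGrid(
        n_cells_per_axis=grid.n_cells_per_axis.copy(),
        cell_edge=grid.cell_edge.copy(),
        cell_of_atom=cell_idx[order],
        cell_start=starts,
        cell_count=counts,
        sorted_order=order,
    )
    return filled, system.take(order)


def choose_alpha(
    d_min: float, epsilon: float, pair_energy_scale: float = 332.0637141
) -> float:
    """Smallest Ewald parameter whose neglected erfc remainder is < epsilon.

    The direct stage uses the full 1/r potential, so the long-range stage's
    erf(alpha*r)/r kernel under-counts each remote pair by erfc(alpha*r)/r.
    This rule caps that remainder at the shell's closest approach:
    erfc(alpha*d_min)/d_min <= epsilon / pair_energy_scale.  The default
    scale is the Coulomb constant, i.e. epsilon bounds the missing pair
    energy for unit charges in kcal/mol -- the unit in which the method's
    accuracy is stated (per-atom RMS errors track the threshold on that
    scale).  Pass ``pair_energy_scale=1`` for a bound in internal (e^2/Å)
    units.  Bisection to 1e-12 relative.
    """
    if not d_min > 0:
        raise ValueError("d_min must be positive")
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    target = epsilon / pair_energy_scale * d_min  # erfc(alpha*d_min) <= target

    def ok(a: float) -> bool:
        return erfc(a * d_min) <= target

    hi = 1.0 / d_min
    while not ok(hi):
        hi *= 2.0
    lo = 0.0
    while hi - lo > 1e-12 * hi:
        mid = 0.5 * (lo + hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return hi


def build_alpha_groups(grid: CellGrid, epsilon: float) -> list[AlphaGroup]:
    """Construct the doubling shells covering all separations >= 2.

    Shells are ``[2,2], [3,4], [5,8], [9,16], ...`` clipped at the grid's
    maximum Chebyshev separation; each group's distance bounds are the
    conservative corner bounds ``d_min = (shell_min-1)*min(edge)`` and
    ``d_max = sqrt(3)*(shell_max+1)*max(edge)``.  ``alpha`` is filled by
    :func:`choose_alpha`; ``zeta`` and the cubature are attached later by the
    calibration stage.  Returns an empty list when no cell pair is further
    than Chebyshev separation 1 (grids up to 3 cells per axis).
    """
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    smax = grid.max_separation
    if int(grid.n_cells_per_axis.max()) < 4:
        # grids up to 3 cells per axis are summed entirely in the direct
        # stage (the neighbour list falls back to all-pairs classification)
        return []
    groups: list[AlphaGroup] = []
    lo, width = 2, 1
    g = 1
    emin = float(grid.cell_edge.min())
    emax = float(grid.cell_edge.max())
    while lo <= smax:
        hi = min(lo + width - 1, smax)
        d_min = (lo - 1) * emin
        d_max = np.sqrt(3.0) * (hi + 1) * emax
        groups.append(
            AlphaGroup(
                index=g,
                shell_min=lo,
                shell_max=hi,
                d_min=d_min,
                d_max=d_max,
                alpha=choose_alpha(d_min, epsilon),
            )
        )
        lo = hi + 1
        width *= 2
        g += 1
    return groups


def build_cell_neighbor_list(
    grid: CellGrid, groups: list[AlphaGroup]
) -> CellNeighborList:
    """Classify every ordered cell pair by Chebyshev separation.

    Separation 0 is the cell itself (direct, in-cell), 1 a short-range
    neighbour (direct, pairwise), >= 2 a long-range neighbour under the unique
    covering alpha group.  Lists are truncated at the box boundary (no wrap).
    """
    coords = grid.cell_coords()
    n_cells = coords.shape[0]
    # separation matrix: fine up to a few thousand cells
    sep = np.max(
        np.abs(coords[:, None, :] - coords[None, :, :]), axis=2
    )
    if not groups and grid.max_separation >= 2:
        # grids with < 4 cells per axis carry no alpha groups: every cell
        # pair is summed directly, which is exact (and cheap at this size)
        short = [np.where(sep[c] >= 1)[0] for c in range(n_cells)]
        return CellNeighborList(short_range=short, long_range=[])
    short = [np.where(sep[c] == 1)[0] for c in range(n_cells)]
    long_range = []
    covered = sep <= 1
    for grp in groups:
        mask = (sep >= grp.shell_min) & (sep <= grp.shell_max)
        covered |= mask
        long_range.append([np.where(mask[c])[0] for c in range(n_cells)])
    if not np.all(covered):
        bad = np.argwhere(~covered)[0]
        raise RuntimeError(
            f"cell pair {bad.tolist()} at separation {sep[tuple(bad)]} "
            "not covered by any alpha group"
        )
    return CellNeighborList(short_range=short, long_range=long_range)
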