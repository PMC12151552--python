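"""Energy and force evaluation: direct near field + cubature far field.

The total electrostatic energy is split per cell pair.  Pairs inside a cell
or between 26-neighbour cells get the full Coulomb 1/r directly (each alpha
group carries its own alpha, so there is no single erfc complement; using the
full potential near and erf(alpha_g r)/r far, with erfc(alpha_g d_min)
capped below the target error, keeps the decomposition exact to the
threshold).  All farther pairs are mediated by structure factors: each cell
accumulates, at every cubature node k_j, the sums C_j = sum q cos(k_j.r) and
S_j = sum q sin(k_j.r) over its atoms (the real-trig convention: the
imaginary unit of the complex basis is dropped and the energy combination
becomes C.C + S.S, algebraically identical to the complex form), and an atom
interacts with the summed structure factor of all its remote cells at once.

Per-atom bookkeeping: the atom-cell energies count every ordered pair once
in each direction, so the long-range total halves their sum; forces are
direction-resolved and are not halved.  Reported per-atom energies use the
half-share convention throughout (each pair contributes half its energy to
each partner), which makes them directly comparable with the brute-force
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _fast
from .cubature import Cubature, calibrate_cubature
from .geometry import (
    AlphaGroup,
    CellGrid,
    CellNeighborList,
    assign_atoms_to_cells,
    build_alpha_groups,
    build_cell_grid,
    build_cell_neighbor_list,
)
from .system import ParticleSystem
from .units import COULOMB_CONSTANT

__all__ = [
    "GLSTConfig",
    "EnergyForceResult",
    "StructureFactorSet",
    "compute_basis",
    "compute_cell_structure_factors",
    "sum_remote_structure_factors",
    "short_range_energy_forces",
    "long_range_energy_forces",
    "compute_total",
    "remove_net_force",
]


@dataclass
class GLSTConfig:
    """Tunables that are not part of the minimum input.

    ``coulomb_constant`` converts internal (e^2/Å) energies to kcal/mol and
    is applied once at the end; ``single_precision_trig`` mimics the GPU
    optimization of evaluating the trigonometric basis in float32 (off by
    default; it broadens the error distribution).  ``node_chunk`` bounds the
    atoms-x-nodes work arrays of the streaming far-field passes.
    """

    coulomb_constant: float = COULOMB_CONSTANT
    seed: int = 0
    design_seed: int = 0
    design_cache_dir: str | None = None
    node_chunk: int = 6_000_000
    single_precision_trig: bool = False


@dataclass
class EnergyForceResult:
    """Energies (kcal/mol), forces (kcal/mol/Å) and their decomposition.

    ``per_atom_energy`` uses half-share pair accounting and sums exactly to
    ``total_energy``; ``breakdown`` maps stage names (``short_range``,
    ``long_range_g1``, ...) to their energy totals.
    """

    total_energy: float
    per_atom_energy: np.ndarray
    forces: np.ndarray
    breakdown: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


@dataclass
class StructureFactorSet:
    """Per-cell cosine/sine node sums for one alpha group (real convention)."""

    group: int
    C: np.ndarray  # (n_cells, n_nodes)
    S: np.ndarray


def _trig(phase: np.ndarray, single_precision: bool):
    if single_precision:
        p32 = phase.astype(np.float32)
        return np.cos(p32).astype(np.float64), np.sin(p32).astype(np.float64)
    return np.cos(phase), np.sin(phase)


def compute_basis(
    position: np.ndarray, charge: float, cubature: Cubature
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node basis (C_j, S_j) = q (cos, sin)(k_j . r) for one atom."""
    phase = cubature.k_vectors @ np.asarray(position, float)
    return charge * np.cos(phase), charge * np.sin(phase)


def _segment_sums(values: np.ndarray, grid: CellGrid) -> np.ndarray:
    """Sum rows of ``values`` (atoms x nodes, cell-sorted) per cell."""
    # reduce over non-empty cells only: their starts are strictly increasing
    # and in range, so consecutive starts delimit exactly one cell's atoms
    out = np.zeros((grid.n_cells, values.shape[1]))
    nz = np.flatnonzero(grid.cell_count > 0)
    if nz.size:
        out[nz] = np.add.reduceat(values, grid.cell_start[nz], axis=0)
    return out


def compute_cell_structure_factors(
    sorted_system: ParticleSystem, grid: CellGrid, group: AlphaGroup
) -> StructureFactorSet:
    """Eq.-style per-cell node sums over the cell's (contiguous) atoms."""
    cub: Cubature = group.cubature
    if cub is None:
        raise ValueError(f"alpha group {group.index} has no cubature attached")
    phase = sorted_system.positions @ cub.k_vectors.T
    c = np.cos(phase) * sorted_system.charges[:, None]
    s = np.sin(phase) * sorted_system.charges[:, None]
    return StructureFactorSet(
        group=group.index, C=_segment_sums(c, grid), S=_segment_sums(s, grid)
    )


def sum_remote_structure_factors(
    cell: int,
    neighbor_list: CellNeighborList,
    sf: StructureFactorSet,
    group_index: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Node-wise sums of the structure factors of a cell's remote cells.

    The summed remote factor lets the energy pass touch each atom's basis
    functions once per group instead of once per remote cell.
    """
    g = (group_index if group_index is not None else sf.group) - 1
    remote = neighbor_list.long_range[g][cell]
    if remote.size == 0:
        n = sf.C.shape[1]
        return np.zeros(n), np.zeros(n)
    return sf.C[remote].sum(axis=0), sf.S[remote].sum(axis=0)


def _remote_matrix(n_cells: int, cells_lists) -> np.ndarray:
    """0/1 aggregation matrix A with A[c, c'] = 1 iff c' is remote to c."""
    A = np.zeros((n_cells, n_cells))
    for c, remote in enumerate(cells_lists):
        A[c, remote] = 1.0
    return A


def long_range_energy_forces(
    sorted_system: ParticleSystem,
    grid: CellGrid,
    groups: list[AlphaGroup],
    neighbor_list: CellNeighborList,
    config: GLSTConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Far-field energies/forces for the cell-sorted system (internal units).

    Returns (per-atom atom-cell energy sums E_a, per-atom forces, per-group
    energy totals).  E_a counts each pair once per direction; the caller
    halves the sum for the total.  Forces are complete as returned.  The
    Coulomb constant is *not* applied here.

    Streaming layout: nodes are processed in chunks; within a chunk each
    atom's basis functions are computed once and reused by both the
    structure-factor accumulation and the energy pass, with the per-cell
    sums and the remote-cell aggregation done by dense linear algebra in
    between.  Whole-cubature basis arrays are never materialized.
    """
    cfg = config or GLSTConfig()
    n = sorted_system.n_atoms
    pos = sorted_system.positions
    q = sorted_system.charges
    cell_of_atom = grid.cell_of_atom
    energies = np.zeros(n)
    forces = np.zeros((n, 3))
    group_totals: dict[str, float] = {}
    for gi, group in enumerate(groups):
        cub: Cubature = group.cubature
        if cub is None:
            raise ValueError(f"alpha group {group.index} has no cubature attached")
        A = _remote_matrix(grid.n_cells, neighbor_list.long_range[gi])
        e_before = energies.sum()
        step = max(64, int(cfg.node_chunk // max(1, n)))
        fused = _fast.HAVE_NUMBA and not cfg.single_precision_trig
        for j0 in range(0, cub.n_nodes, step):
            K = np.ascontiguousarray(cub.k_vectors[j0 : j0 + step])
            W = cub.node_weights[j0 : j0 + step]
            if fused:
                Ca, Sa = _fast.basis_block(pos, q, K)
            else:
                phase = pos @ K.T
                cth, sth = _trig(phase, cfg.single_precision_trig)
                Ca = cth * q[:, None]
                Sa = sth * q[:, None]
            Rc = A @ _segment_sums(Ca, grid)
            Rs = A @ _segment_sums(Sa, grid)
            if fused:
                _fast.energy_force_accum(Ca, Sa, Rc, Rs, cell_of_atom,
                                         W, K, energies, forces)
            else:
                Rca = Rc[cell_of_atom]
                Rsa = Rs[cell_of_atom]
                energies += (Ca * Rca + Sa * Rsa) @ W
                forces += (Sa * Rca - Ca * Rsa) @ (W[:, None] * K)
        group_totals[f"long_range_g{group.index}"] = 0.5 * float(
            energies.sum() - e_before
        )
    return energies, forces, group_totals


def short_range_energy_forces(
    sorted_system: ParticleSystem,
    grid: CellGrid,
    neighbor_list: CellNeighborList,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Direct 1/r sums for in-cell and short-range-neighbour pairs.

    Internal units (no Coulomb constant).  Every pair is counted once; the
    per-atom energies are half shares.  There is no distance cutoff inside
    the short-range region.  Coincident charged atoms raise a singularity
    error naming the pair.
    """
    pos = sorted_system.positions
    q = sorted_system.charges
    n = sorted_system.n_atoms
    energies = np.zeros(n)
    forces = np.zeros((n, 3))
    starts, counts = grid.cell_start, grid.cell_count
    for c in range(grid.n_cells):
        if counts[c] == 0:
            continue
        i0, i1 = starts[c], starts[c] + counts[c]
        pi, qi = pos[i0:i1], q[i0:i1]
        # in-cell pairs: full matrix with zeroed diagonal (each pair appears
        # twice, so energies take half shares directly and forces are exact)
        if counts[c] > 1:
            d = pi[:, None, :] - pi[None, :, :]
            r = np.sqrt((d * d).sum(axis=2))
            iu = np.triu_indices(int(counts[c]), k=1)
            _check_singular(r[iu], qi[:, None] * qi[None, :], iu, i0, i0)
            r_safe = np.where(r > 0, r, 1.0)
            e = np.where(r > 0, (qi[:, None] * qi[None, :]) / r_safe, 0.0)
            fvec = (e / (r_safe * r_safe))[:, :, None] * d
            energies[i0:i1] += 0.5 * e.sum(axis=1)
            forces[i0:i1] += fvec.sum(axis=1)
        # cross pairs with higher-index neighbour cells (each cell pair once)
        nbrs = neighbor_list.short_range[c]
        nbrs = nbrs[(nbrs > c) & (counts[nbrs] > 0)]
        for dcell in nbrs:
            j0, j1 = starts[dcell], starts[dcell] + counts[dcell]
            pj, qj = pos[j0:j1], q[j0:j1]
            d = pi[:, None, :] - pj[None, :, :]
            r = np.sqrt((d * d).sum(axis=2))
            qq = qi[:, None] * qj[None, :]
            if np.any(r == 0):
                bad = np.argwhere(r == 0)
                if np.any(qq[r == 0] != 0):
                    a, b = bad[0]
                    raise ZeroDivisionError(
                        f"coincident charged atoms {i0 + a} and {j0 + b}"
                    )
            with np.errstate(divide="ignore", invalid="ignore"):
                e = np.where(r > 0, qq / np.where(r > 0, r, 1.0), 0.0)
                fvec = (e / np.where(r > 0, r * r, 1.0))[:, :, None] * d
                fvec = np.where((r > 0)[:, :, None], fvec, 0.0)
            energies[i0:i1] += 0.5 * e.sum(axis=1)
            energies[j0:j1] += 0.5 * e.sum(axis=0)
            forces[i0:i1] += fvec.sum(axis=1)
            forces[j0:j1] -= fvec.sum(axis=0)
    return energies, forces, float(energies.sum())


def _check_singular(r_flat, qq, iu, off_i, off_j):
    if np.any(r_flat == 0):
        qq_flat = qq[iu]
        mask = (r_flat == 0) & (qq_flat != 0)
        if np.any(mask):
            k = int(np.argmax(mask))
            raise ZeroDivisionError(
                f"coincident charged atoms {off_i + iu[0][k]} and "
                f"{off_j + iu[1][k]}"
            )


def compute_total(
    system: ParticleSystem,
    cutoff: float,
    epsilon: float,
    config: GLSTConfig | None = None,
) -> EnergyForceResult:
    """Full pipeline: grid -> sort -> groups -> cubatures -> energies/forces.

    The result is mapped back to the input atom order.  Systems whose grid
    has no long-range cells (fewer than 4 cells per axis) fall back to direct
    summation over all cell pairs and are exact.
    """
    cfg = config or GLSTConfig()
    grid0 = build_cell_grid(system.box, cutoff)
    grid, sorted_sys = assign_atoms_to_cells(system, grid0)
    groups = build_alpha_groups(grid, epsilon)
    meta_groups = []
    for g in groups:
        cal = calibrate_cubature(
            g.d_min,
            g.d_max,
            g.alpha,
            epsilon,
            seed=cfg.seed,
            design_seed=cfg.design_seed,
            cache_dir=cfg.design_cache_dir,
        )
        g.zeta = cal.zeta
        g.cubature = cal.cubature
        meta_groups.append(
            {
                "group": g.index,
                "shell": (g.shell_min, g.shell_max),
                "d_range": (g.d_min, g.d_max),
                "alpha": g.alpha,
                "zeta": cal.zeta,
                "n_radial": cal.rule.n_positive,
                "design_strength": cal.design.strength,
                "m_hemisphere": cal.design.m_hemisphere,
                "n_nodes": cal.cubature.n_nodes,
                "certified_error": cal.certified_error,
            }
        )
    nbr = build_cell_neighbor_list(grid, groups)
    e_short, f_short, e_short_total = short_range_energy_forces(
        sorted_sys, grid, nbr
    )
    ke = cfg.coulomb_constant
    per_atom = e_short.copy()
    forces = f_short.copy()
    breakdown = {"short_range": ke * e_short_total}
    if groups:
        e_long, f_long, group_totals = long_range_energy_forces(
            sorted_sys, grid, groups, nbr, cfg
        )
        per_atom += 0.5 * e_long
        forces += f_long
        for k, v in group_totals.items():
            breakdown[k] = ke * v
    per_atom *= ke
    forces *= ke
    # back to input order
    inv = np.empty_like(grid.sorted_order)
    inv[grid.sorted_order] = np.arange(system.n_atoms)
    per_atom = per_atom[inv]
    forces = forces[inv]
    return EnergyForceResult(
        total_energy=float(per_atom.sum()),
        per_atom_energy=per_atom,
        forces=forces,
        breakdown=breakdown,
        metadata={
            "n_atoms": system.n_atoms,
            "cutoff": cutoff,
            "epsilon": epsilon,
            "n_cells_per_axis": grid.n_cells_per_axis.tolist(),
            "groups": meta_groups,
            "coulomb_constant": ke,
        },
    )


def remove_net_force(forces: np.ndarray) -> np.ndarray:
    """Project forces onto the zero-net-force subspace (subtract the mean).

    Orthogonal projection along the three uniform-translation directions;
    this is the Gram-Schmidt removal of the spurious net force left by
    roundoff and finite cubature error.
    """
    forces = np.asarray(forces, float)
    return forces - forces.mean(axis=0, keepdims=True)
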