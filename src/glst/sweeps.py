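"""Desk-scale benchmark sweeps: system size, error threshold, cutoff.

Performance is reported as hardware-independent operation counts, not wall
clock.  The long-range count is the number of atom x node basis evaluations,
``2 * N * sum_g nodes_g`` (each atom's basis functions are computed twice per
group: once into its cell's structure factor, once in the energy pass); the
short-range count is the number of direct pairs.  Sweeping the cutoff at
fixed accuracy exposes the characteristic U-shaped total cost: small cells
push work into the cubatures (more nodes for tighter distance ranges), large
cells push it into near-quadratic direct summation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GLSTConfig, compute_total
from .cubature import calibrate_cubature
from .geometry import (
    assign_atoms_to_cells,
    build_alpha_groups,
    build_cell_grid,
    build_cell_neighbor_list,
)
from .oracle import direct_coulomb, error_report
from .synthetic import BoxRecipe, build_salt_water_box
from .system import ParticleSystem

__all__ = [
    "SweepResult",
    "sweep_size",
    "sweep_threshold",
    "sweep_cutoff",
    "long_range_operation_count",
    "short_range_pair_count",
]


@dataclass
class SweepResult:
    """Rows of per-point records for one swept variable.

    ``axis`` names the swept quantity (``n_atoms`` | ``epsilon`` |
    ``cutoff``); rows are dicts sorted by it.  ``summary`` carries
    axis-specific aggregates (e.g. the linear-fit slope and R^2 of the size
    sweep).
    """

    axis: str
    rows: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def to_tsv(self, stream) -> None:
        if not self.rows:
            stream.write("# empty sweep\n")
            return
        keys = list(self.rows[0].keys())
        stream.write("\t".join(keys) + "\n")
        for row in self.rows:
            stream.write(
                "\t".join(_fmt(row.get(k)) for k in keys) + "\n"
            )
        for k in sorted(self.summary):
            stream.write(f"# {k}\t{_fmt(self.summary[k])}\n")


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.10e}"
    return str(v)


def _calibrated_groups(grid, epsilon: float, cfg: GLSTConfig):
    groups = build_alpha_groups(grid, epsilon)
    for g in groups:
        cal = calibrate_cubature(
            g.d_min, g.d_max, g.alpha, epsilon,
            seed=cfg.seed, design_seed=cfg.design_seed,
            cache_dir=cfg.design_cache_dir,
        )
        g.zeta = cal.zeta
        g.cubature = cal.cubature
    return groups


def long_range_operation_count(n_atoms: int, groups) -> int:
    """Atom x node basis evaluations: two passes over every group's nodes."""
    return int(2 * n_atoms * sum(g.cubature.n_nodes for g in groups))


def short_range_pair_count(grid, neighbor_list) -> int:
    """Exact number of direct pairs given the cell occupancy."""
    counts = grid.cell_count
    total = int(np.sum(counts * (counts - 1) // 2))
    for c in range(grid.n_cells):
        nbrs = neighbor_list.short_range[c]
        nbrs = nbrs[nbrs > c]
        total += int(counts[c] * counts[nbrs].sum())
    return total


def _count_point(system: ParticleSystem, cutoff: float, epsilon: float,
                 cfg: GLSTConfig):
    grid0 = build_cell_grid(system.box, cutoff)
    grid, _ = assign_atoms_to_cells(system, grid0)
    groups = _calibrated_groups(grid, epsilon, cfg)
    nbr = build_cell_neighbor_list(grid, groups)
    return grid, groups, nbr


def sweep_size(
    recipes: list[BoxRecipe],
    epsilon: float,
    cutoff,
    oracle_max: int = 30_000,
    config: GLSTConfig | None = None,
    compute_energies: bool = True,
) -> SweepResult:
    """Operation counts (and oracle errors where affordable) vs atom count.

    ``cutoff`` is a number or a callable mapping a recipe to one.  Systems
    above ``oracle_max`` atoms skip the O(N^2) comparison (recorded as a
    logged note in the row).  The summary holds a linear fit of the
    long-range operation count against N with its R^2; a single-point sweep
    is flagged degenerate rather than fitted.
    """
    cfg = config or GLSTConfig()
    rows = []
    for rec in recipes:
        cut = cutoff(rec) if callable(cutoff) else float(cutoff)
        system = build_salt_water_box(rec)
        grid, groups, nbr = _count_point(system, cut, epsilon, cfg)
        row = {
            "n_atoms": system.n_atoms,
            "cutoff": cut,
            "n_groups": len(groups),
            "nodes_per_group": ",".join(
                str(g.cubature.n_nodes) for g in groups
            ),
            "long_range_ops": long_range_operation_count(
                system.n_atoms, groups
            ),
            "short_range_pairs": short_range_pair_count(grid, nbr),
            "rmse_energy": None,
            "rmse_force_max": None,
            "note": "",
        }
        if compute_energies and system.n_atoms <= oracle_max:
            res = compute_total(system, cut, epsilon, cfg)
            rep = error_report(res, direct_coulomb(system))
            row["rmse_energy"] = rep.rmse_energy
            row["rmse_force_max"] = rep.rmse_force_max
        else:
            row["note"] = "oracle-skipped"
        rows.append(row)
    rows.sort(key=lambda r: r["n_atoms"])
    result = SweepResult(axis="n_atoms", rows=rows)
    n = np.array([r["n_atoms"] for r in rows], float)
    ops = np.array([r["long_range_ops"] for r in rows], float)
    if n.size >= 2 and np.ptp(n) > 0:
        slope, intercept = np.polyfit(n, ops, 1)
        pred = slope * n + intercept
        ss_res = float(np.sum((ops - pred) ** 2))
        ss_tot = float(np.sum((ops - ops.mean()) ** 2))
        result.summary = {
            "fit_slope": float(slope),
            "fit_intercept": float(intercept),
            "fit_r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        }
    else:
        result.summary = {"fit_r2": None, "note": "degenerate-fit"}
    return result


def sweep_threshold(
    system: ParticleSystem,
    cutoff: float,
    epsilons,
    config: GLSTConfig | None = None,
) -> SweepResult:
    """Node counts and oracle errors vs target error threshold.

    The reference is computed once; calibration failures at extreme
    thresholds are recorded per point and the sweep continues.
    """
    cfg = config or GLSTConfig()
    ref = direct_coulomb(system)
    rows = []
    for eps in sorted(epsilons, reverse=True):
        row = {"epsilon": eps, "n_nodes_total": None,
               "rmse_energy": None, "rmse_force_max": None, "note": ""}
        try:
            res = compute_total(system, cutoff, eps, cfg)
        except RuntimeError as exc:
            row["note"] = f"calibration-failed: {exc}"
            rows.append(row)
            continue
        row["n_nodes_total"] = sum(
            g["n_nodes"] for g in res.metadata["groups"]
        )
        rep = error_report(res, ref)
        row["rmse_energy"] = rep.rmse_energy
        row["rmse_force_max"] = rep.rmse_force_max
        rows.append(row)
    rows.sort(key=lambda r: r["epsilon"])
    return SweepResult(axis="epsilon", rows=rows)


def sweep_cutoff(
    system: ParticleSystem,
    epsilon: float,
    cutoffs,
    config: GLSTConfig | None = None,
    compute_energies: bool = False,
) -> SweepResult:
    """Short/long operation-count split (and optional errors) vs cutoff.

    Cutoffs exceeding a box edge are recorded as invalid points.  With
    ``compute_energies`` the oracle comparison verifies that accuracy is only
    weakly affected by the cutoff choice.
    """
    cfg = config or GLSTConfig()
    ref = direct_coulomb(system) if compute_energies else None
    rows = []
    for cut in sorted(cutoffs):
        row = {"cutoff": float(cut), "short_range_pairs": None,
               "long_range_ops": None, "total_ops": None,
               "rmse_energy": None, "note": ""}
        try:
            grid, groups, nbr = _count_point(system, cut, epsilon, cfg)
        except ValueError as exc:
            row["note"] = f"invalid: {exc}"
            rows.append(row)
            continue
        sr = short_range_pair_count(grid, nbr)
        lr = long_range_operation_count(system.n_atoms, groups)
        row["short_range_pairs"] = sr
        row["long_range_ops"] = lr
        row["total_ops"] = sr + lr
        if compute_energies:
            rep = error_report(compute_total(system, cut, epsilon, cfg), ref)
            row["rmse_energy"] = rep.rmse_energy
        rows.append(row)
    return SweepResult(axis="cutoff", rows=rows)
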