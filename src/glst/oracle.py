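"""Brute-force references and error metrics.

``direct_coulomb`` is the O(N^2) all-pairs ground truth the fast solver is
judged against; ``direct_erf_energy`` is the literal atom-cell erf sum used
to unit-test the cubature machinery in isolation; ``error_report`` computes
the RMSE-style statistics (per-atom energies and force components, their
normalized variants, and signed-deviation histograms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .core import EnergyForceResult
from .system import ParticleSystem
from .units import COULOMB_CONSTANT

__all__ = ["ErrorReport", "direct_coulomb", "direct_erf_energy", "error_report"]


def direct_coulomb(
    system: ParticleSystem,
    coulomb_constant: float = COULOMB_CONSTANT,
    chunk: int = 512,
) -> EnergyForceResult:
    """All-pairs k_e q_a q_b / r energies and forces, O(N^2), chunked.

    Per-atom energies are half shares of each pair.  Raises on coincident
    charged atoms.
    """
    pos, q, n = system.positions, system.charges, system.n_atoms
    energies = np.zeros(n)
    forces = np.zeros((n, 3))
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        d = pos[i0:i1, None, :] - pos[None, :, :]  # (b, n, 3)
        r = np.sqrt((d * d).sum(axis=2))
        qq = q[i0:i1, None] * q[None, :]
        # mask the diagonal block's self terms
        sub = np.arange(i0, i1)
        r[sub - i0, sub] = np.inf
        if np.any(r == 0):
            bad = np.argwhere(r == 0)
            if np.any(qq[r == 0] != 0):
                a, b = bad[0]
                raise ZeroDivisionError(
                    f"coincident charged atoms {i0 + a} and {b}"
                )
            r[r == 0] = np.inf
        e = qq / r
        energies[i0:i1] += 0.5 * e.sum(axis=1)
        forces[i0:i1] += ((e / (r * r))[:, :, None] * d).sum(axis=1)
    energies *= coulomb_constant
    forces *= coulomb_constant
    return EnergyForceResult(
        total_energy=float(energies.sum()),
        per_atom_energy=energies,
        forces=forces,
        breakdown={"direct_coulomb": float(energies.sum())},
        metadata={"n_atoms": n, "method": "direct_coulomb"},
    )


def direct_erf_energy(
    atom_position: np.ndarray,
    atom_charge: float,
    cell_positions: np.ndarray,
    cell_charges: np.ndarray,
    alpha: float,
    coulomb_constant: float = 1.0,
) -> float:
    """Literal atom-cell sum q_a sum_b q_b erf(alpha r_ab)/r_ab.

    Internal units by default (``coulomb_constant=1``); the atom must not be
    a member of the cell.
    """
    d = np.asarray(cell_positions, float) - np.asarray(atom_position, float)
    r = np.linalg.norm(d, axis=1)
    if np.any(r == 0):
        raise ValueError("atom coincides with a cell member")
    return coulomb_constant * float(
        atom_charge * np.sum(np.asarray(cell_charges) * erf(alpha * r) / r)
    )


@dataclass
class ErrorReport:
    """RMSE-style comparison of two energy/force results.

    ``rmse_energy`` is over per-atom energies (half-share convention on both
    sides); ``rmse_force`` has one entry per Cartesian component.  Normalized
    variants divide by the root-mean-square of the reference quantity.
    ``histogram`` holds (bin_edges, counts) of the signed per-atom energy
    deviations.
    """

    rmse_energy: float
    rmse_force: np.ndarray  # (3,)
    normalized_rmse_energy: float
    normalized_rmse_force: np.ndarray
    rmse_total_energy: float
    per_atom_energy_errors: np.ndarray
    per_atom_force_errors: np.ndarray
    histogram: tuple = field(default=())

    @property
    def rmse_force_max(self) -> float:
        return float(self.rmse_force.max())


def _fd_edges(x: np.ndarray, fallback_bins: int = 20) -> np.ndarray:
    """Freedman-Diaconis bin edges with a fixed-count fallback."""
    if x.size > 1 and np.ptp(x) > 0:
        edges = np.histogram_bin_edges(x, bins="fd")
        if edges.size > 2:
            return edges
    lo = float(x.min()) if x.size else 0.0
    hi = float(x.max()) if x.size else 1.0
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, fallback_bins + 1)


def error_report(
    test: EnergyForceResult, reference: EnergyForceResult
) -> ErrorReport:
    """Per-atom RMSE of energies and force components, plus histograms."""
    if test.per_atom_energy.shape != reference.per_atom_energy.shape:
        raise ValueError("results compare different numbers of atoms")
    de = test.per_atom_energy - reference.per_atom_energy
    df = test.forces - reference.forces
    rmse_e = float(np.sqrt(np.mean(de * de)))
    rmse_f = np.sqrt(np.mean(df * df, axis=0))
    ref_e_rms = float(np.sqrt(np.mean(reference.per_atom_energy**2)))
    ref_f_rms = np.sqrt(np.mean(reference.forces**2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        norm_e = rmse_e / ref_e_rms if ref_e_rms > 0 else np.nan
        norm_f = np.where(ref_f_rms > 0, rmse_f / ref_f_rms, np.nan)
    edges = _fd_edges(de)
    counts, _ = np.histogram(de, bins=edges)
    return ErrorReport(
        rmse_energy=rmse_e,
        rmse_force=rmse_f,
        normalized_rmse_energy=norm_e,
        normalized_rmse_force=norm_f,
        rmse_total_energy=abs(test.total_energy - reference.total_energy),
        per_atom_energy_errors=de,
        per_atom_force_errors=df,
        histogram=(edges, counts),
    )


def report_to_text(report: ErrorReport) -> str:
    """Key-value text serialization (tab-separated histogram appended)."""
    lines = [
        f"rmse_energy\t{report.rmse_energy:.10e}",
        f"rmse_force_x\t{report.rmse_force[0]:.10e}",
        f"rmse_force_y\t{report.rmse_force[1]:.10e}",
        f"rmse_force_z\t{report.rmse_force[2]:.10e}",
        f"normalized_rmse_energy\t{report.normalized_rmse_energy:.10e}",
        f"normalized_rmse_force_x\t{report.normalized_rmse_force[0]:.10e}",
        f"normalized_rmse_force_y\t{report.normalized_rmse_force[1]:.10e}",
        f"normalized_rmse_force_z\t{report.normalized_rmse_force[2]:.10e}",
        f"abs_total_energy_error\t{report.rmse_total_energy:.10e}",
        "histogram_bin_edges\t"
        + " ".join(f"{v:.6e}" for v in report.histogram[0]),
        "histogram_counts\t" + " ".join(str(int(v)) for v in report.histogram[1]),
    ]
    return "\n".join(lines) + "\n"
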