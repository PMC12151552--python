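"""Particle containers and extended-XYZ input/output.

A :class:`ParticleSystem` is the object whose electrostatic energy and forces
the package computes: atom positions (Å), partial charges (elementary charge
units) and an orthorhombic, non-periodic box.  Systems are read and written in
a small extended-XYZ dialect whose comment line carries the box as
``Lattice="Lx 0 0 0 Ly 0 0 0 Lz"`` and whose per-atom columns are
``element x y z charge`` (the charge column is mandatory for this tool).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParticleSystem", "read_xyz", "write_xyz"]


@dataclass
class ParticleSystem:
    """Positions, charges and element labels of the atoms in a box.

    Parameters
    ----------
    positions : (n_atoms, 3) float array, Å.  All coordinates must lie in
        ``[0, box[i])`` along each axis; the solver has no periodic images.
    charges : (n_atoms,) float array, elementary charge units.
    labels : sequence of element symbols, one per atom.
    box : length-3 edge lengths of the orthorhombic box, Å.
    """

    positions: np.ndarray
    charges: np.ndarray
    labels: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.charges = np.ascontiguousarray(self.charges, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        n = self.positions.shape[0]
        if n < 1:
            raise ValueError("a ParticleSystem needs at least one atom")
        if self.charges.shape != (n,) or self.labels.shape != (n,):
            raise ValueError("charges/labels length must match positions")
        if not np.all(self.box > 0):
            raise ValueError("box edges must be positive")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def validate_in_box(self) -> None:
        """Raise if any atom lies outside ``[0, box)`` on some axis."""
        p = self.positions
        if np.any(p < 0.0) or np.any(p >= self.box[None, :]):
            bad = np.where(np.any((p < 0.0) | (p >= self.box[None, :]), axis=1))[0]
            raise ValueError(
                f"atom(s) {bad[:5].tolist()} outside the box; "
                "periodic wrapping is not supported"
            )

    def take(self, order: np.ndarray) -> "ParticleSystem":
        """Return a copy with atoms permuted by ``order``."""
        return ParticleSystem(
            positions=self.positions[order],
            charges=self.charges[order],
            labels=self.labels[order],
            box=self.box.copy(),
        )


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')


def read_xyz(source) -> ParticleSystem:
    """Read a ParticleSystem from an extended-XYZ file path or text stream.

    Line 1: atom count.  Line 2: comment containing
    ``Lattice="Lx 0 0 0 Ly 0 0 0 Lz"``.  Then one
    ``element x y z charge`` record per atom (whitespace-delimited).
    """
    if isinstance(source, (str, bytes)):
        with open(source, "r") as fh:
            return read_xyz(fh)
    lines = source.read().splitlines()
    if len(lines) < 2:
        raise ValueError("truncated XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError("first XYZ line must be the atom count") from exc
    m = _LATTICE_RE.search(lines[1])
    if not m:
        raise ValueError('XYZ comment line must carry Lattice="Lx 0 0 0 Ly 0 0 0 Lz"')
    lat = np.fromstring(m.group(1), sep=" ")
    if lat.size != 9:
        raise ValueError("Lattice must contain 9 numbers")
    lat = lat.reshape(3, 3)
    if np.any(lat != np.diag(np.diag(lat))):
        raise ValueError("only orthorhombic (diagonal) lattices are supported")
    box = np.diag(lat)
    if len(lines) < 2 + n:
        raise ValueError(f"expected {n} atom records, found {len(lines) - 2}")
    labels, pos, chg = [], [], []
    for i, line in enumerate(lines[2 : 2 + n]):
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(
                f"atom line {i + 1}: need 'element x y z charge' (charge column "
                "is mandatory)"
            )
        labels.append(parts[0])
        pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
        chg.append(float(parts[4]))
    return ParticleSystem(
        positions=np.array(pos), charges=np.array(chg), labels=labels, box=box
    )


def write_xyz(system: ParticleSystem, target) -> None:
    """Write ``system`` to a file path or text stream in the dialect above.

    Output is deterministic (fixed float format) so identical systems produce
    byte-identical files.
    """
    if isinstance(target, (str, bytes)):
        with open(target, "w") as fh:
            write_xyz(system, fh)
            return
    b = system.box
    target.write(f"{system.n_atoms}\n")
    target.write(
        f'Lattice="{b[0]:.10g} 0 0 0 {b[1]:.10g} 0 0 0 {b[2]:.10g}" '
        'Properties=species:S:1:pos:R:3:charge:R:1\n'
    )
    for lab, p, q in zip(system.labels, system.positions, system.charges):
        target.write(
            f"{lab} {p[0]:.12f} {p[1]:.12f} {p[2]:.12f} {q:.6f}\n"
        )


def to_string(system: ParticleSystem) -> str:
    buf = io.StringIO()
    write_xyz(system, buf)
    return buf.getvalue()
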