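"""Synthetic neutral salt-water benchmark boxes and small test fixtures.

The benchmark compositions (water count, NaCl pair count, cubic box edge)
range from 38 atoms in an 8 Å box to ~1.6M atoms in a 256 Å box at roughly
liquid-water density.  The electrostatics benchmark depends only on positions
and charge magnitudes, not on liquid structure, so molecules are placed by
seeded rejection sampling with a minimum heavy-atom separation rather than by
equilibration; waters are rigid 3-site molecules with a common fixed-charge
geometry (O-H 0.9572 Å, H-O-H 104.52 deg, q_O = -0.834, q_H = +0.417 --- a
stand-in, since the benchmark never specifies a water model), ions are +1/-1
point charges.  Boxes are exactly neutral by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import ParticleSystem

__all__ = [
    "BoxRecipe",
    "build_salt_water_box",
    "table1_recipes",
    "fixture_dimer",
    "WATER_CHARGES",
]

_OH = 0.9572  # Å
_HOH = np.deg2rad(104.52)
WATER_CHARGES = {"O": -0.834, "H": 0.417}


@dataclass
class BoxRecipe:
    """Composition of one benchmark box."""

    n_water: int
    n_nacl: int
    box: tuple[float, float, float]
    seed: int = 0
    min_separation: float = 2.0  # Å between heavy atoms of different molecules

    @property
    def n_atoms(self) -> int:
        return 3 * self.n_water + 2 * self.n_nacl


#: (n_water, n_nacl, box edge Å) for the eleven benchmark compositions
_TABLE1 = [
    (12, 1, 8.0),
    (115, 2, 16.0),
    (979, 11, 32.0),
    (8172, 84, 64.0),
    (65275, 667, 128.0),
    (101212, 1033, 148.0),
    (159746, 1631, 172.0),
    (222303, 2269, 192.0),
    (316376, 3229, 216.0),
    (411904, 4204, 236.0),
    (526044, 5368, 256.0),
]


def table1_recipes(seed: int = 0) -> list[BoxRecipe]:
    """The eleven benchmark compositions, smallest (38 atoms) first."""
    return [
        BoxRecipe(n_water=w, n_nacl=s, box=(b, b, b), seed=seed)
        for w, s, b in _TABLE1
    ]


def _water_template() -> np.ndarray:
    """O at origin, two H in the xz-plane."""
    h1 = np.array([_OH, 0.0, 0.0])
    h2 = np.array([_OH * np.cos(_HOH), 0.0, _OH * np.sin(_HOH)])
    return np.stack([np.zeros(3), h1, h2])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def build_salt_water_box(recipe: BoxRecipe) -> ParticleSystem:
    """Place waters and ions by seeded rejection sampling; deterministic.

    Molecule centers (water O, each ion) keep at least ``min_separation``
    from every previously placed center; whole molecules stay inside the box
    with a 1 Å margin so no hydrogen pokes out.  Raises a packing error if a
    molecule cannot be placed within the attempt budget.
    """
    rng = np.random.default_rng(recipe.seed)
    box = np.asarray(recipe.box, float)
    margin = 1.0
    if np.any(box <= 2 * margin):
        raise ValueError("box too small for molecule placement margins")
    n_mol = recipe.n_water + 2 * recipe.n_nacl
    centers = np.empty((n_mol, 3))
    n_placed = 0
    max_attempts = 2000 * max(1, n_mol)
    attempts = 0
    min_sep2 = recipe.min_separation**2
    while n_placed < n_mol:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"failed to place molecule {n_placed + 1}/{n_mol} after "
                f"{max_attempts} attempts; use a larger box or smaller "
                "min_separation"
            )
        cand = margin + rng.random(3) * (box - 2 * margin)
        if n_placed:
            d = centers[:n_placed] - cand
            if np.min((d * d).sum(axis=1)) < min_sep2:
                continue
        centers[n_placed] = cand
        n_placed += 1

    water = _water_template()
    positions, charges, labels = [], [], []
    for i in range(recipe.n_water):
        rot = _random_rotation(rng)
        mol = centers[i] + water @ rot.T
        # keep the whole molecule inside the open box
        mol = np.clip(mol, 1e-6, box - 1e-6)
        positions.extend(mol)
        charges.extend([WATER_CHARGES["O"], WATER_CHARGES["H"], WATER_CHARGES["H"]])
        labels.extend(["O", "H", "H"])
    for i in range(recipe.n_nacl):
        positions.append(centers[recipe.n_water + 2 * i])
        charges.append(1.0)
        labels.append("Na")
        positions.append(centers[recipe.n_water + 2 * i + 1])
        charges.append(-1.0)
        labels.append("Cl")
    return ParticleSystem(
        positions=np.array(positions),
        charges=np.array(charges),
        labels=labels,
        box=box,
    )


def fixture_dimer(
    q1: float,
    q2: float,
    separation: float,
    box: tuple[float, float, float] | None = None,
    first_position: np.ndarray | None = None,
) -> ParticleSystem:
    """Two point charges on the x-axis; a deterministic unit-test fixture.

    By default the pair is centered in a box of edge 2*separation+2 Å.
    ``first_position`` overrides the first atom's location (the second sits
    at +separation along x), which lets tests drop the pair into specific
    cells of a chosen grid.
    """
    if not separation > 0:
        raise ValueError("separation must be positive")
    if box is None:
        edge = 2.0 * separation + 2.0
        box = (edge, edge, edge)
    box = np.asarray(box, float)
    if first_position is None:
        first_position = np.array(
            [0.5 * (box[0] - separation), 0.5 * box[1], 0.5 * box[2]]
        )
    p1 = np.asarray(first_position, float)
    p2 = p1 + np.array([separation, 0.0, 0.0])
    return ParticleSystem(
        positions=np.stack([p1, p2]),
        charges=np.array([q1, q2]),
        labels=["X", "X"],
        box=box,
    )
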