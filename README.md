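# glst — accuracy-controlled O(N) electrostatics for non-periodic systems

Computing Coulomb energies and forces is the standing bottleneck of
molecular simulation: the bare sum

$$E = k_e \sum_{a<b} \frac{q_a q_b}{r_{ab}}$$

is O(N²) and decays too slowly to truncate.  `glst` implements the
Gauss–Legendre–spherical-*t* (GLST) approach for open (non-periodic)
systems: the Ewald identity `1/r = erfc(αr)/r + erf(αr)/r` splits each
interaction; the short-range part is summed directly over a cell
decomposition (each cell and its 26 neighbours); and the smooth long-range
part is written as a finite plane-wave cubature

$$\frac{\mathrm{erf}(\alpha r)}{r} \approx \sum_j W_j \cos(\vec k_j\cdot\vec r),
\qquad \vec k_{nm} = 2\alpha\zeta\, s_n \hat t_m,$$

with Gauss–Legendre radial nodes $s_n$ and spherical *t*-design directions
$\hat t_m$.  Sums of the per-atom basis functions
$C^a_j = q_a\cos(\vec k_j\cdot\vec r_a)$, $S^a_j = q_a\sin(\vec k_j\cdot\vec r_a)$
over a cell form its *structure factor*, and one atom interacts with the
summed structure factor of all its remote cells at once — linear cost in N.
Distant cells are organised into shells of doubling thickness ("α groups"),
each with its own Ewald parameter α, radial truncation ζ and cubature
*calibrated* so the kernel error over that shell's distance range is below a
user-chosen threshold ε.  Accuracy is therefore a dial: per-atom RMS errors
track ε from 10⁻² down to 10⁻⁸ kcal/mol.

Who it is for: method developers and simulators who need fast, tunably
accurate electrostatics for droplets/clusters (no periodic images), and a
transparent reference implementation of structure-factor cubature
electrostatics with brute-force oracles and benchmark harnesses built in.

## Worked example

```python
import glst

# two unit charges 1 Å apart: plain Coulomb
dimer = glst.fixture_dimer(1.0, -1.0, 1.0)
print(glst.direct_coulomb(dimer).total_energy)   # -332.0637141 kcal/mol

# a 349-atom neutral salt-water box (16 Å edge), cutoff 3.2 Å, eps = 1e-3
rec = glst.BoxRecipe(n_water=115, n_nacl=2, box=(16.0, 16.0, 16.0), seed=7)
system = glst.build_salt_water_box(rec)
result = glst.compute_total(system, cutoff=3.2, epsilon=1e-3)
report = glst.error_report(result, glst.direct_coulomb(system))
print(result.total_energy)       # -23270.0869 kcal/mol (direct: -23270.1052)
print(result.breakdown)          # short_range -22925.0916,
                                 # long_range_g1 -578.3886, long_range_g2 +233.3933
print(report.rmse_energy)        # 7.3e-04 kcal/mol per-atom RMSE
print(report.rmse_force.max())   # 3.8e-03 kcal/mol/Å worst force component
```

The 16 Å box tiles into 5³ cells of edge 3.2 Å; cells beyond the 26
short-range neighbours form two shells ([2,2] and [3,4] in Chebyshev cell
separation) whose calibrated cubatures here use 59,160 and 30,240 nodes
with certified kernel errors 2.6e-4 and 4.6e-4 — and the measured per-atom
errors land below the 1e-3 threshold.  `result.metadata["groups"]` carries
these calibration records.

A CLI wraps the same pipeline:

```
glst generate --waters 115 --nacl 2 --box 16 --seed 7 --out box.xyz
glst compute box.xyz --cutoff 3.2 --epsilon 1e-3 --validate --out-prefix run
glst sweep-threshold box.xyz --cutoff 3.2 --epsilons 1e-2,1e-4 --out sweep.tsv
```

Input/output is an extended-XYZ dialect (`element x y z charge` with a
`Lattice` comment line); results are tab-separated per-atom tables plus
key-value metadata, byte-reproducible for a fixed `--seed`.

## What `scripts/acceptance.py` does

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

builds a synthetic benchmark box from the given seed, runs the full pipeline
(cell grid → α groups → calibrated cubatures → structure-factor energies and
forces), verifies it against the O(N²) direct-Coulomb oracle on stderr, and
writes the acceptance-target JSON to `--out`.

## Layout

- `glst.system` — particle container and extended-XYZ I/O
- `glst.geometry` — cell grid, atom binning, α-group shells, neighbour lists
- `glst.designs` — antipodal spherical t-designs: generation, certification
- `glst.cubature` — radial rules, node fusion, kernel-error calibration
- `glst.core` — structure factors, energies/forces, the full pipeline
- `glst.oracle` — brute-force references and RMSE/error reports
- `glst.synthetic` — benchmark salt-water boxes and fixtures
- `glst.sweeps`, `glst.cli` — benchmark sweeps and the command line

`docs/methods.md` documents the model, the calibration procedure, the
design-generation algorithm, and known limitations.
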