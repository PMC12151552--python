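# Methods

## The problem

Non-periodic particle systems (droplets, clusters, implicit-boundary
biomolecular setups) need all-pairs Coulomb energies and forces

    E = k_e * sum_{a<b} q_a q_b / r_ab,

which is O(N^2) when summed directly.  This package implements a
linear-scaling alternative: the Ewald identity

    1/r = erfc(alpha r)/r + erf(alpha r)/r

splits the interaction into a short-range part that decays like a Gaussian
and a smooth long-range part, and the smooth part is evaluated collectively
through per-cell *structure factors* instead of per-pair.

## Decomposition

The box is tiled by cubic cells with edge >= the direct-space cutoff
(`n_cells = floor(box/cutoff)` per axis; cells are stretched to tile the box
exactly).  A cell interacts directly — full 1/r, no distance cutoff inside
the region — with itself and its 26 Chebyshev-distance-1 neighbours.  All
farther cells are partitioned into concentric cubic shells of thickness
1, 2, 4, ... ("alpha groups").  Each group g covers Chebyshev separations
[s_min, s_max] and hence pair distances in

    d_min = (s_min - 1) * min(cell_edge),
    d_max = sqrt(3) * (s_max + 1) * max(cell_edge)

(conservative corner-to-corner bounds; center-to-center bounds are
looser and could under-cover).  Boundaries are open: no periodic images
anywhere, boundary cells simply have fewer neighbours.  Grids with fewer
than 4 cells per axis have no far field at all and are summed directly —
for them the method *is* the direct sum.

### Choosing alpha

Because the near field keeps the full 1/r (each group has its own alpha, so
no single erfc complement exists), the far field's erf(alpha_g r)/r kernel
under-counts every remote pair by erfc(alpha_g r)/r.  `choose_alpha` picks
the smallest alpha with

    erfc(alpha * d_min) / d_min <= epsilon / k_e,

i.e. the neglected remainder for unit charges is below the threshold *in
kcal/mol*.  The kcal/mol scale is deliberate: the method's accuracy is
reported as per-atom RMS errors in kcal/mol, and error decomposition on the
2959-atom benchmark shows the remainder dominates the observed RMSE, so the
remainder budget must live on the reporting scale.  (An internal-unit bound,
`pair_energy_scale=1`, is ~330x looser and raises the energy RMSE at
epsilon=1e-4 from ~2e-4 to ~2.4e-3 kcal/mol.)  Smaller alpha is always
cheaper (fewer cubature nodes), so "smallest alpha passing the bound" is the
right extreme; bisection to 1e-12 relative makes it reproducible.

## The far-field cubature

The smooth kernel has the truncated integral form

    erf(alpha r)/r = (4 alpha zeta / pi) * int_0^1 exp(-zeta^2 s^2)
                     sinc(2 alpha zeta s r) ds + O(exp(-zeta^2)),

and sinc(kr) is the exact average of the plane wave cos(k.r) over the sphere
|k| = 2 alpha zeta s.  Three approximations follow:

1. **Radial truncation.** zeta = sqrt(ln(10/epsilon)), so the dropped tail
   exp(-zeta^2) <= epsilon/10 — a tenth of the budget, leaving the rest for
   quadrature error.
2. **Radial quadrature.** The positive half of a 2*N_l-point Gauss-Legendre
   rule (the integrand is even in s; the factor 2 is folded into the
   prefactor).  N_l is grown (x1.25) until the kernel with *exact* angular
   integration matches erf(alpha r)/r within epsilon/3 on 512 log-spaced
   radii — this isolates radial from angular error and converges
   spectrally.
3. **Angular quadrature.** An antipodally symmetric spherical t-design:
   M_t upper-hemisphere points whose unweighted average integrates all
   spherical harmonics through degree t exactly (each point stands for an
   antipodal pair; the kernel is even).

Fused nodes and weights:

    k_(n,m) = 2 alpha zeta s_n t_m,
    W_(n,m) = (4 alpha zeta / (pi M_t)) w_n exp(-zeta^2 s_n^2),

flattened to a single list so the energy pass is one sum.  The leading
4/pi is (2/pi) from the sine-transform representation of erf times 2 from
the half-rule folding; the r->0 limit sum_j W_j = 2 alpha/sqrt(pi) pins the
constant and is asserted in tests.

### Calibration, not theory

No closed-form node-selection rule is used.  For each group the design
strength is selected by screening a Gauss x equispaced-phi *product* rule of
equal polynomial exactness (cheap: no design needs to be solved to predict
what degree t is required), then the actual design is certified on a probe
grid of 64 log-spaced radii times (50 seeded random directions + up to 50 of
the design's own points under a fixed rotation — the directions where
angular error cancels least).  The certificate is the worst probe residual;
the strength steps up a ~1.22x ladder until it is <= epsilon.  Tests
re-verify every certificate on an independently seeded probe set at 2x
tolerance.  Required strengths scale with the largest plane-wave phase
2 alpha zeta d_max and are essentially geometry-independent per threshold:
t ~ 60-70 at 1e-4, ~130 at 1e-6, ~190 at 1e-8.  Node counts per cubature
(N_l x M_t) range from a few thousand (1e-2) to ~1.3M (1e-8), under a 4e6
hard cap.

### Generating the designs

Designs are solved numerically as unions of orbits: of the icosahedral
rotation group x inversion (120 points per generic orbit) for t >= 12, of
plain antipodal pairs below.  Orbit unions annihilate every non-invariant
harmonic identically, so the design conditions reduce to the group averages
of a few generic zonal harmonics per degree (the invariant dimension comes
from the character sum; one spare axis per degree conditions the system).
Levenberg-Marquardt with an analytic Jacobian on those residuals solves
t = 200 systems in seconds.  Certification is always independent: explicit
orthonormal-harmonic sums (stable column-wise recurrences) must stay below
1e-9 through degree t, and odd degrees are asserted to vanish by symmetry.
Solved representative angles for the ladder strengths 12-230 ship with the
package as small text tables (~100 kB total) and are certified again at
load; absent a table, the solver runs at import-free runtime and caches to
disk keyed by (t, M, seed).  Minimality is not claimed: shipped designs run
~1.9x the conjectured minimal point counts.

## Energy and force assembly

Per atom and node, the basis is C_j = q cos(k_j.r), S_j = q sin(k_j.r) (the
complex basis's imaginary unit is dropped; the energy combination C C - S S
with imaginary S becomes C C + S S — algebraically identical, asserted
against the literal erf pair sum in tests).  Cells sum their atoms' bases
into structure factors; each cell then sums the structure factors of all its
remote cells per group, so an atom's basis is evaluated once per group for
the structure-factor pass and once for the energy pass:

    E_a = k_e sum_g sum_j W_j (C_j^a C_j^rem + S_j^a S_j^rem)
    F_a = k_e sum_g sum_j W_j k_j (S_j^a C_j^rem - C_j^a S_j^rem)

E_a counts each ordered pair once in each direction, so the total halves
sum_a E_a; forces are not halved.  Reported per-atom energies use half-share
pair accounting in both stages (and in the brute-force reference), making
per-atom comparisons convention-free.  Atoms are cell-sorted by a stable
counting sort; results map back to input order through the recorded
permutation.

All arithmetic is double precision.  The node streams are chunked (default
~6M atom-node entries) and the hot loops (phase + sincos + accumulate) run
through numba-compiled kernels with a polynomial sincos (octant range
reduction, pointwise error ~1e-14); a pure-numpy path is kept as the
reference implementation, agrees to 1e-12 in tests, and is used
automatically if numba is missing.  An opt-in `single_precision_trig` flag
rounds the trigonometric basis through float32, reproducing qualitatively
the error broadening of GPU single-precision trig; it is never on by
default and caps accuracy near 1e-7.

Finite cubature error leaves a small net force; `remove_net_force` projects
it out (subtracting the mean force is the orthogonal projection onto the
zero-net-force subspace).

## Error metrics

`direct_coulomb` is the O(N^2) reference.  RMSE is computed over per-atom
energies (primary; a total-energy deviation is also reported — an RMSE over
the single total would be degenerate) and per force component; normalized
variants divide by the RMS of the reference quantity.  Signed per-atom
deviations are binned by Freedman-Diaconis edges with a fixed-count
fallback.

## The synthetic benchmark boxes

Neutral salt-water boxes emulate the published benchmark compositions
(38 to 1,588,868 atoms in 8-256 Å cubic boxes, ~0.7-1.0x liquid water
density).  Water is a rigid 3-site model (O-H 0.9572 Å, H-O-H 104.52 deg,
q_O = -0.834, q_H = +0.417) — a stand-in, since the benchmark's force field
is unspecified and the electrostatics depend only on positions and charges.
Placement is seeded rejection sampling with a 2.0 Å heavy-atom minimum
separation and a 1 Å wall margin, not an equilibrated liquid: error
statistics depend on charge magnitudes and spatial density, not liquid
ordering, so a green test establishes error control for disordered
charge-neutral media, not for any specific liquid structure.  Boxes are
byte-reproducible for a fixed seed.  Rejection packing is practical to
~30k atoms; the million-atom compositions are used for operation-count
accounting, where only cell occupancy matters.

## Cost accounting

Performance is reported as hardware-independent operation counts: direct
pairs for the near field, 2 x N x (nodes per group summed) basis
evaluations for the far field (two passes per group).  These counts grow
linearly in N at fixed cutoff and threshold, and sweeping the cutoff at
fixed accuracy exposes the U-shaped total cost.  In raw counts the interior
cost minimum only appears for systems above ~1M atoms — below that,
all-pairs direct summation has fewer operations than any split (published
wall-clock U-shapes at ~200k atoms reflect hardware constant factors, which
this accounting deliberately excludes).

## Numerical choices and edge cases

- Coincident charged atoms raise a singularity error naming the pair;
  coincident neutral ghosts are tolerated.
- Atoms outside [0, box) are an error — there is no wrapping.
- Equatorial design points use the deterministic tie rule z > 0, else y > 0,
  else x > 0.
- Cubature node order is radial-major; weights are strictly positive.
- `epsilon` must lie in (0, 1); cutoffs must be positive and no larger than
  any box edge.
- Degenerate sweeps (single point) are flagged, not fitted.

## Known limitations

- Open boundaries only; no periodic images, no minimum-image convention,
  no triclinic boxes.
- No virial/pressure tensor and no bonded-exclusion lists.
- The error *certificate* is empirical (probe-grid maximum), not a proof;
  independent resampling bounds the generalization gap at 2x in practice.
- Designs are not minimal-point; node counts could drop ~2x with stronger
  design optimization.
- Rejection packing does not produce liquid structure and becomes slow
  beyond ~10^4 molecules.
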