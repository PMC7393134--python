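# Methods

## Model

A closed, single-cell-thick epithelial shell encloses an incompressible
fluid lumen.  Each of the `N_c` cells is a prism-like polyhedron with a
polygonal apical side facing the lumen, a basal side of identical topology
facing outward, and one lateral quadrilateral per cell–cell junction; the
apical and basal vertex networks share one set of cyclic cell loops, every
vertex is 3-valent, and on the closed surface `V − E + N_c = 2` (so
`E = 3(N_c − 2)` junctions and `V = 2(N_c − 2)` vertices per surface).

Lengths are measured in units of the cell-volume scale `V_cell^(1/3)`,
energies in units of the lateral tension times `V_cell^(2/3)`, and time in
units of the intrinsic relaxation time `tau_0 = 1/(Gamma_l mu)` (`mu` is
the vertex mobility; it only sets the clock and never appears separately).
The dimensionless energy is

    w = sum_cells [ alpha a_a + beta a_b + (1/2) a_l ]
      + (K_cell/2) sum_cells (V_i − 1)^2
      + (K_lumen/2) (V_lumen − v_lumen)^2
      + sum_junctions gamma_i (l_a,i + l_b,i)

with `alpha`, `beta` the apical/basal tensions in lateral-tension units.
Incompressibility of cells and lumen is enforced by stiff harmonic terms;
we write them with a `K/2` prefactor and modulus `K = 100` (the prefactor
convention is ours; at modulus 100 the factor-of-two ambiguity is
irrelevant to the shapes).  The `gamma_i` are fluctuating junctional line
tensions, zero except in the fluctuating-tension activity scheme.

A stiff harmonic constraint is not exact: at equilibrium each cell volume
sits below its target by `(∂w_surface/∂V)/K`, about 2–3 % at `K = 100`
(the lumen, with much larger geometric leverage, stays within ~0.1–1 %).
This offset is physical to the method, not an integration error.

Faces are generally non-planar; every area and volume is defined through
the centroid-fan triangulation (fan from the vertex-mean of the face),
which is orientation-consistent and smooth in the vertex positions, so
the energy gradient exists everywhere.  Cell and lumen volumes use the
divergence theorem over the fan triangles; the identity
`sum of cell volumes + lumen volume = basal-envelope volume` holds to
1e-9 and is asserted in tests.

## Dynamics

Vertices move by overdamped gradient descent `dr/dt = −grad w`,
integrated with forward Euler at `dt = 1e-4`.  Forces are the exact
analytic gradient of the triangulated-geometry energy, evaluated in a
jit-compiled kernel; a central-finite-difference oracle in the test suite
verifies the gradient to 1e-6 relative per component.  Between Euler
steps the driver processes discrete events (T1 initiations, rosette
resolutions, growth entries, divisions).  All stochastic channels use
counter-based RNG streams split per purpose (T1 selection, tension noise,
growth), so a run is bit-reproducible given seed and parameters, and a
saved snapshot resumes the trajectory bit-exactly.

Stochastic active-T1 attempts occur at per-junction rate `k_T1/E`
(`E` junctions), i.e. total rate `k_T1`.  Rather than testing every
junction every step, the driver samples exact geometric waiting times at
the current rate and thins by `k(t')/k(t_sample)`; because every
supported schedule (linear decay, step, constant) is non-increasing, the
thinning is exact.  Activity schedules: linear `k(t) = k0 (t_max − t)/t_max`,
step (`k0` until `t_max/2`, then 0), constant.

## T1 transitions

Both activity schemes share one mechanical move.  The junction is viewed
as its projection onto the midplane, with mid-length `(l_a + l_b)/2`.

* Threshold scheme: junctions with mid-length below `delta_l = 0.15` flip
  with probability one (these are the passive, mechanically driven T1s,
  active also at `k_T1 = 0`); longer junctions flip at the active rate.
* Fluctuating-tension scheme: each `gamma_i` follows an Ornstein–Uhlenbeck
  process `d gamma/dt = −gamma/tau + xi(t)` with `tau = 1` and long-time
  variance `sigma^2`, integrated by Euler–Maruyama
  (`gamma <- gamma (1 − dt/tau) + N(0,1) sqrt(2 sigma^2 dt/tau)`); a flip
  is initiated only when a junction is squeezed below the 0.01 trigger
  length.  We apply the trigger to the mid-length, consistent with the
  threshold scheme (the alternative, the apical length alone, differs
  negligibly at the trigger scale).

The move itself: both vertex pairs of the junction (apical and basal)
collapse to their midpoints; the four-cell rosette dwells for 2e-3 time
units (20 steps), during which the coincident vertices move jointly by
their mean force and the four involved cells are barred from further
T1s; then the four cells swap neighbours (losing cells drop a vertex,
gaining cells insert one; side counts change by −1, −1, +1, +1) and the
new vertex pair separates by 5e-4, perpendicular to the collapsed edge,
each vertex displaced toward the losing cell it remains part of.  The
basal network and the lateral faces are updated identically (shared
topology).  A flip is refused (and the junction temporarily exempted) if
a losing cell is a triangle, if the gaining cells are already neighbours
or identical, or if any involved cell is in a rosette dwell.

A junction created by a flip starts at length 5e-4, far below every
trigger, and a literal reading of the probability-one rule would flip it
straight back forever.  We therefore make fresh junctions refractory to
threshold-triggered flips until their mid-length first exceeds the
trigger; the stochastic `k_T1` channel still applies to them.  The
tension of a flipped junction restarts at zero (fresh motor population).

## Seeding

Initial shells are the dual of the convex hull of a local minimum of the
Thomson problem (`sum 1/r_ij` on the unit sphere; L-BFGS from seeded
random starts, best of three restarts).  Each hull triangle becomes an
apical vertex at the outward-normalized triangle centroid (the dual is
3-valent by construction; centroid versus circumcenter placement is our
choice and is washed out by relaxation and activity).  The apical
polyhedron is scaled to enclose `v_lumen`; basal vertices sit radially
outward by `[3(v_lumen+N_c)/(4 pi)]^(1/3) − [3 v_lumen/(4 pi)]^(1/3)`, so
the construction encloses the correct total volume.  The shell is then
relaxed passively for t = 1 (a "short time"; construction errors in the
cell volumes, up to ~25 % for pentagons, fall into the constraint band
well within this).  Any local Thomson minimum with a 3-valent dual is
acceptable: junctional activity randomizes the packing anyway.

## Growth

Quiescent cells enter a growth phase at rate `1/tau_d` (`tau_d = 2000`);
a growing cell's target volume rises linearly at `1/tau_g` (`tau_g = 1`)
and the cell divides on doubling, across a pair of opposing lateral
sides: a vertex is inserted at the midpoint of side `i` (chosen
uniformly) and of side `i + n//2` (the near-opposite side for odd `n`),
and a new junction joins them; the basal trace mirrors the apical one.
This preserves 3-valence and changes counts by `N_c + 1`, `E + 3`,
`V + 2`.  (Connecting existing vertices instead would create 4-valent
vertices, which the structure forbids — so an n-gon parent yields
daughters with `n//2 + 2` and `n − n//2 + 2` sides, two pentagons for a
hexagon.)  Triangular cells postpone division until a rearrangement
frees them.  The preferred lumen volume tracks the total tissue target
volume `x` through the size-matching rule

    (v + x)^(1/3) − v^(1/3) = 400^(1/3) − 100^(1/3),

anchored at `v(300) = 100`.  The rule equates the geometric thickness of
the spherical shell across sizes, keeping the tissue-tension threshold
for sphericity size-independent; it has no nonnegative solution below
`x ≈ 20.3`, so growth runs start at 21 cells or more.  When comparing
shells of different sizes, the active T1 rate is rescaled as
`k_T1 -> k_T1 E_{N_c} / E_300` (`E_300 = 894`) so the per-junction rate
is size-independent.

## Morphometrics

* Reduced volume `v = 6 sqrt(pi) V / A^(3/2)` of the midplane surface
  (vertices at apical/basal midpoints, fan-triangulated); 1 for a sphere.
* Per-cell thickness `h` = distance between the area centroids of the
  apical and basal side; mean curvature from the truncated cone with the
  same apical area, basal area and height:
  `c = (2/h)(sqrt(a_b) − sqrt(a_a))/(sqrt(a_b) + sqrt(a_a))`, positive
  when the outer side is larger.
* Thickness modulation `delta = p * Dh / mean(h)` with `Dh` half the full
  range of `h` (a percentile-based variant is available by flag for noisy
  ensembles) and `p` the sign of the Pearson correlation of `(c, h)`.
* `h(c)` scatter fitted by least squares; the rescaling
  `h -> h − (2^(1/3)/3^(1/6))(alpha+beta)^(2/3)`,
  `c -> [lambda_1 + (alpha−beta) lambda_2] c` with `lambda_1 = −0.059`,
  `lambda_2 = 0.45` collapses shells below the spherical onset onto the
  identity line.
* Topological pair correlation `g_gamma(d)`: mean number of
  gamma-sided cells at graph distance `d` from a gamma-sided cell
  (breadth-first distances on the cell adjacency graph), averaged
  unweighted over the shells of an ensemble; per shell
  `sum_d g_gamma(d) = n_gamma − 1`.
* Face anisometry `kappa = (g1 − g2)/(g1 + g2)` from the unweighted
  vertex gyration tensor.
* Self-overlap screening (final snapshots only; transient overlaps during
  dynamics are allowed and unchecked): triangle–triangle intersection of
  non-adjacent fan triangles of the apical+basal surfaces, KD-tree
  prefiltered; coplanar grazing contacts do not count.  Overlapping
  shapes are labelled nonphysical and excluded from ensemble statistics.

### Morphology classifier

The reference work classifies shapes by eye; our operationalization:
nonphysical if self-overlapping; spherical if `v > 0.94`; otherwise
per-cell curvatures are compared with the curvature `1/R` of the
equal-midplane-volume sphere — cells with `c < −0.5/R` mark invaginations,
connected regions with `c > 1.7/R` mark protrusion lobes.  Shapes with an invagination and anticorrelated thickness are
stomatocytes; two or more lobes with mean elongation (gyration aspect of
the lobe's cell centroids) above 1.45 are branched (scaled shells
support about two branches, versus ~5 at full size); other lobed shapes
are budded; the remainder hybrid.  The
thresholds are fixed calibration constants chosen once against the four
reference parameter sets (spherical 1.2/1.2, stomatocyte 0.7/0.5 passive,
budded 1.5/0.3, branched 0.7/0.5 active) on ~100-cell shells and are all
exposed in `ClassifierConfig`.

## Study conditions and scaled problem sizes

The reference conditions are `N_c = 300`, `v_lumen = 100`, `t = 1000` for
active runs (`k_T1` decaying linearly from 200) and `t = 2000` for
passive runs, with ensembles of 100–300 instances.  A single such run is
~10^7 Euler steps over ~7000 triangles — hours of CPU.  The shipped
tests and the acceptance script therefore work at the package's own
scaled sizes: shells of 32–100 cells with the lumen volume from the
size-matching rule, the active rate rescaled by junction count, and run
times of 25–500 time units chosen by observing convergence of the shape
statistics (reduced volume and curvature distributions stop moving well
before these horizons at those sizes).  The scaled shells reproduce the
reference morphologies with caveats established empirically here:

* spherical shells and the reduced-volume law behave quantitatively down
  to 64 cells;
* stomatocyte invagination and budding need the packing disorder of
  ~100 cells to nucleate — at 64 cells the passive low-tension shell
  arrests in a metastable discocyte and the high-differential-tension
  shell stays spherical;
* branched morphologies require the active T1 schedule at every size, as
  in the reference study.

What passing scaled tests show is that the mechanics, rearrangement
machinery and statistics are implemented faithfully; they do not probe
300-cell ensemble distributions, whose means enter only the acceptance
report.

## Numerical choices and degenerate inputs

* Fixed `dt = 1e-4` (no adaptivity); energy decrease along passive
  trajectories is asserted in tests at this step.
* The jit kernels compile with relaxed floating-point (`fastmath`);
  round-off differs from strict IEEE ordering by ~1e-12 relative, far
  below every physical tolerance.  Determinism (identical seed and
  configuration give byte-identical trajectories) holds within a given
  build of the kernels.
* Degenerate fan triangles (area below 1e-14) contribute no area
  gradient; degenerate faces return zero area.
* Separation direction fallback: if the losing-cell centroids project
  onto the collapsed edge (degenerate), a fixed perpendicular is used.
* `flat_equilibrium` is the closed form; the test oracle is a numeric
  root of the differentiated hexagonal-prism energy (agreement 1e-8).
* The lumen rule is solved by Brent bisection (scalar) or warm-started
  Newton (vectorized, used every step in growth runs).
* Geometry I/O is plain-text OFF plus a JSON sidecar; positions are
  serialized via shortest round-trip decimal `repr`, making snapshot
  round-trips bit-exact.

## Known limitations

* No steric repulsion: interpenetrating shapes are possible and are only
  screened, not prevented.
* No apical perimeter elasticity / acto-myosin cable, no T2 extrusions,
  no rosettes beyond the transient four-fold one, no curved-face
  geometry, no substrate or hydrodynamics.
* The classifier is a heuristic on top of visual categories; near domain
  boundaries (hybrid shapes) its labels are as ambiguous as the eye's.
* Scaled-size caveats above; 300-cell ensemble statistics (e.g. pentagon
  pair-correlation peak positions of branched shells) are reproduced in
  structure but not re-measured at full scale here.
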