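# Methods

This note records the models behind each module, the conventions and
parameter defaults, what the synthetic generator does and does not emulate,
and the numerical choices a user should know before trusting a number.

## Surface representation and conventions

A tube surface is an oriented triangle mesh of a topological cylinder with a
per-vertex chart `(s, phi)`: `s` a longitudinal coordinate in µm from the
anterior end, `phi` a circumferential angle with period 2π.  Units are µm
and minutes everywhere except calcium frames (seconds).

Sign conventions are fixed once: face windings make normals point **inward**
(toward the lumen), so the mean curvature is positive on a cylinder
(`H = 1/2R`) and negative in sharp necks whose axial curvature exceeds the
circumferential one, and the normal velocity `v_n` is positive for inward
(constricting) motion.  With these signs, local area conservation reads
`2*H*v_n = div(v_par)` with both sides positive in a deepening constriction.

## Synthetic generator

The generator defines the study conditions; its defaults are chosen to
resemble a stage-15 midgut at desk scale and are not tuned per analysis.

**Constricting tube.**  A surface of revolution with radius profile
`r(z,t) = R0 - Σ d_j(t) exp(-(z-c_j)²/2w_j²)`; defaults `R0 = 30 µm`,
`L0 = 200 µm`, one constriction of width 15 µm whose depth ramps linearly to
`0.6*R0` over the sequence (the waveform of a real constriction is not
constrained by the data this emulates, so the ramp is configuration).
Material markers are labelled by their rest axial coordinate `u`; their
positions solve the 1D conservation law "area per marker is constant",
first by quadrature of the continuum area element
`r*sqrt(1+r_z²)` on an 8192-point grid, then refined by a fixed-point sweep
until the *discrete* band areas of the actual mesh match their initial
values to 1e-12.  Conservation is therefore exact on material cells (the
quad of two triangles per lattice cell); individual triangles of a tilting
band exchange area across their shared diagonal, which is a triangulation
artifact, not a property of the flow.  The generator also returns exact
per-vertex `H`, `v_n` and `div(v_par)` from the parametric form, and an
optional uniform area-growth rate (exponential in time) for growth-recovery
tests.  Axisymmetry is a deliberate restriction: it makes the
incompressible flow solvable by quadrature and exactly checkable.
Lagrangian correspondence is by construction (same vertex = same material
point), so no velocimetry from images is needed or modelled.

**Cell tessellations.**  Jittered hexagonal-lattice Voronoi cells built in
an auxiliary isotropic space and mapped into the chart by an anisotropic
stretch (Voronoi diagrams do not commute with anisotropic scaling, so
polygons are mapped, not seeds).  With circumferential orientation the map
warps only the longitudinal axis and the tessellation is exactly periodic
across the seam; with a rotated orientation the stretch is a global linear
map and seam periodicity is approximate.  Target aspect profiles are
realized to within a few percent; cell areas vary inversely with the local
aspect when the profile varies along `s`.  Jitter (default 0.1 of the
lattice spacing) emulates segmentation irregularity; at 0.1 an isotropic
lattice measures ⟨a/b⟩ ≈ 1.13, so isotropy *controls* use jitter 0.02.

**Nuclei pairs, calcium movies, fold outcomes.**  Pairs ride the tube flow
(so integrated path length dwarfs relative motion) and separate at a
configured rate along a fixed random direction from an initial distance
drawn below the 5 µm pairing threshold; tracking noise is isotropic
Gaussian (default 0.3 µm SD).  Calcium movies are background + i.i.d.
Gaussian noise + Gaussian pulse blobs (Poisson event times, default
duration one frame) in triplets 9 s apart, one triplet per 90 s composite
period.  Fold outcomes are Bernoulli three-fold successes; failures form
0–2 folds uniformly.

**What the generator does not emulate:** image formation and optics,
segmentation errors other than polygon jitter and adjacency flicker,
out-of-plane cell geometry, active mechanics (the flow is kinematic), cell
divisions, and non-axisymmetric organ shapes.  Passing tests demonstrate
that the *measurement* pipeline is correct and well-conditioned on data
with the assumed structure; they do not validate surface extraction or
segmentation on real images, which are inputs here.

## Numerical choices

- **Curvature** uses the cotangent Laplace–Beltrami operator applied to the
  embedding, projected on inward vertex normals, with Meyer mixed
  (Voronoi-safe) vertex areas — barycentric areas bias the estimate by
  >10 % at low-valence vertices such as the twelve icosahedral points of a
  subdivided sphere.  Boundary values are one-sided and excluded from all
  patch statistics.
- **Velocities** are forward differences of vertex positions; geometric
  operators are evaluated on the midpoint surface, which makes the forward
  difference a centered (second-order) estimate.  The first/last timepoints
  use one-sided differences.
- **Covariant divergence** is the P1 finite-element weak form with lumped
  areas.  It satisfies a discrete divergence theorem exactly: the
  area-weighted sum over any vertex set equals the flux defined through the
  same weak form (`patch_flux`), which the tests check to machine
  precision.
- **Patch averaging** (default 20×16 bins in `(s, phi)`, echoing ~320
  patches) averages the *pointwise product* `2*H*v_n`, not the product of
  patch means: `H` and `v_n` co-vary strongly within a neck patch and the
  covariance term does not vanish under mesh refinement.
- **Pooled correlation** is a single area-weighted Pearson correlation over
  all (patch, timepoint) samples; an unweighted option exists.  Per-group
  alternatives (per-embryo then average) are a caller-side loop.
- **Material charts** take the surface's own chart (or a harmonic one) and
  rescale the longitudinal coordinate by one global factor minimizing the
  area-weighted mean reference |µ|.  A harmonic map on the cut cylinder —
  Dirichlet 0/1 on the boundary loops for `s`, Dirichlet 0/2π across a
  shortest boundary-to-boundary cut for `phi` — replaces full conformal
  uniformization; for tubes this leaves reference anisotropy below |µ| ≈
  1e-8 on a cylinder and is required to stay below 0.05 (reported as
  `residual_mu`).  Faces straddling the seam use locally unwrapped
  coordinates.
- **Kymograph averaging** of µ is complex and area-weighted, preserving
  orientation cancellation; a magnitude-averaging option is exposed (it
  bounds the complex average from above).
- **Cell orientation averaging** ships in two forms: the weighted vector
  sum of `(cos θ, sin θ)` (default) and an axial variant that doubles
  angles before averaging, appropriate for undirected axes (±θ near ±90°
  average to ~0 in the vector form but to ±90° axially).
- **Bootstrap SE** draws 1000 subsamples with replacement at 50 sizes in
  (N/4, N), fits `var(n) = a/n + c` by least squares in 1/n, and evaluates
  at n = N; the intercept absorbs variance that does not shrink with n.
  It agrees with the plain N-out-of-N bootstrap within ~10 % on i.i.d.
  data and requires N ≥ 8.
- **T1 detection** takes adjacency time series, drops pairs adjacent at all
  timepoints, debounces state runs that revert within one timepoint
  (configurable) as segmentation flicker, and stamps each change with the
  first timepoint of the new state.  The event axis is the
  centroid–centroid segment of the pair in a locally conformal patch whose
  first axis is AP; events within 45° of AP count as AP-oriented and the
  bias test is an exact two-sided binomial test against 1/2.
- **Calcium filtering** defaults: Gaussian blur σ = 2 px, white top-hat
  radius 15 px (bright features on dark background).  A top-hat radius
  below the blur support triggers a warning.  Blobs closer than the radius
  merge into one feature — documented behavior, not a defect.  The
  background window for per-embryo normalization is 45–50 µm from the
  constriction site.  Constriction-onset times are inputs; onset detection
  from bright-field is out of scope.
- **Statistics**: sample SDs use the n−1 denominator; a zero pooled
  variance with unequal means reports a signed infinity rather than
  failing; the sustained-difference p across timepoints combines
  per-timepoint z-scores with Stouffer's rule `Z = Σ Z_t / √T` (the choice
  of combination rule is a documented interpretation).
- **Degenerate inputs** fail loudly with context: zero-area triangles name
  face indices, self-intersecting polygons name the cell id, empty patches
  or hoop bins name the bin, wrong topology reports the Euler
  characteristic, and a closing neck names the offending timestep.

## Problem sizes

Tests run the full pipeline at meshes from 32×16 to 128×64 vertices and
5–30 timepoints; the headline incompressibility figure uses a 128×64 mesh,
30 one-minute steps, and 20×16 patches (≈9 300 patch samples), where the
pooled correlation is 0.9998 and the patch residual is below
2×10⁻³ min⁻¹ against a deformation scale of ~2×10⁻² min⁻¹.  Residuals
decrease monotonically under mesh doubling (tested over two doublings).
Cell statistics use ~600 cells of ~60 µm², matching segmentation yields of
600–1300 cells per timepoint.

## Known limitations

- The discrete divergence and curvature lose an order of accuracy at mesh
  boundaries; all quantitative outputs exclude boundary vertices, so the
  two terminal s-bins of a patch grid summarize slightly shrunken patches.
- `metric_rate_check` (the full metric-rate identity
  `∂t g_ij = ∇_i v_j + ∇_j v_i − 2 v_n b_ij`) is a validation operation on
  parametric axisymmetric flows, where the second fundamental form is
  analytic; no general discrete shape operator is implemented, and the
  production pipeline uses only the trace relation through `2*H*v_n`.
- The quantitative contracts (e.g. the 5 % residual-vs-area-growth
  cross-check) hold on smooth flows at adequate resolution; a 0.6-depth
  neck of width ≲12 µm needs ≳96 rings before pointwise errors at the neck
  fall below that level.
- The tessellation generator's aspect control is exact for constant
  profiles and first-order for profiles varying on scales comparable to a
  cell diameter.
- Calcium analysis assumes motion between the frames of one triplet is
  negligible; no motion correction is performed.
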