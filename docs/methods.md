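# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `blebkit`, and what the synthetic-data tests do and
do not establish about real microscopy data.

## Image pipeline

**Calibration and background.** A `Movie` carries named T×H×W channels with
pixel size (μm) and frame interval (s). When a camera dark frame is
provided it is subtracted (clipped at zero) before any quantification.
Coordinates are 0-based (row, col) pixel indices; physical coordinates are
index × pixel size with no half-pixel offset.

**Segmentation.** Otsu's threshold is computed *per frame* (photobleaching
drifts the histogram over a movie, so a pooled threshold would bias late
frames). A frame whose histogram is degenerate (single value) segments to
empty rather than inventing a threshold. Components are 4-connected. The
~1 μm inward erosion of cell bodies is realized as
`floor(erosion_um / pixel_size)` pixels via distance-transform
thresholding, which is exactly erosion by the discrete Euclidean disk.

**Seeded propagation.** Biosensor regions are grown from the cell-body
seeds by competitive geodesic propagation: per-pixel step cost
`λ + |∇I|` on unit-normalized intensity (default λ = 0.05), with contested
pixels assigned to the seed of smallest cumulative cost. The candidate
region is thresholded with Otsu computed on log1p intensities. The
log-domain choice matters: a strongly polarized cell has a *trimodal*
histogram (dark exterior, dim cytosol, bright rim focus), and linear Otsu
then separates cytosol from rim instead of cell from exterior; in the log
domain the exterior/cytosol split dominates. A fixed numeric threshold can
be passed instead.

**Tracking and QC.** Linking is greedy nearest-centroid per frame pair,
gated at a configurable step distance (default 10 μm per frame — the gate
is not dictated by the science, only by plausible cell speeds). Two labeled
regions that are 8-adjacent in a frame set a `collision` flag on every
involved track. QC removes tracks that touch the field border, stay within
5 μm of their start over the observation window (dead cells/debris), or
carry collision flags. MSD is time-averaged over all start times within a
cell and then averaged across cells with a 95% t-interval; instantaneous
velocity is step length over the frame interval (μm/min); persistence is
net displacement over path length.

**Polarity scores.** The normalized-distance score is
`d/(0.5 L)` where `d` is the distance between the intensity-weighted
centroid and the centroid of the binary footprint, and `L` is the
major-axis length of the ellipse with the footprint's normalized second
central moments. `L` uses the *binary* moments by default so the
normalization is independent of the signal being scored;
intensity-weighted moments are available via `weighted_L=True`. Scores are
reported raw (no clamping above 1). The angular score weights each
footprint pixel's cosine (relative to the center → weighted-centroid
direction) by its intensity; when the weighted centroid coincides with the
geometric center there is no reference direction and the score is defined
as 0; pixels exactly at the center have no angle and are excluded. Only
dark-frame subtraction is applied before weighting — no cytosolic
background subtraction — so a cytosolic pool compresses scores toward 0,
as it does for real biosensors.

## Edge dynamics

**Boundaries.** The half-level contour of the (single-region) mask is fit
with a periodic cubic smoothing spline and resampled to P = 1000 points
equally spaced in arc length, oriented to positive signed area. The
default smoothing budget (0.3 px RMS) absorbs the rasterization staircase;
`smoothing=0` interpolates the raw contour. Frame-to-frame index alignment
searches all P circular shifts (via FFT cross-correlation, exact up to
floating point) for the minimum summed squared distance; ties break toward
the smaller |shift|, then the negative one, making alignment deterministic.

**Edge velocity.** v(p,t) = [SDT(t+1) − SDT(t−1)] / (2Δt) evaluated at the
aligned boundary points of frame t, positive outward. The signed distance
is measured *to the sub-pixel contours* of the neighboring frames
(nearest-neighbor query against their dense spline points, sign from the
mask) rather than by interpolating a pixel-grid distance transform: the
grid transform carries a direction-dependent half-pixel bias that does not
cancel in the difference and systematically underestimates front speeds by
~10%. On rasterized test disks the contour-based estimator is unbiased to
<1% with a per-point spread of ~±20% of the front speed (the half-pixel
contour jitter); smoother real outlines sit between these bounds. A
centered difference is used because a literal average of the two distance
transforms has no velocity units; the division by 2Δt yields the μm/s
quantity that the 0.15 μm/s protrusion threshold presupposes.

**Cross-correlation.** r(k) pools all valid (position, time) pairs of
vel(·, t+k) against fluo(·, t) over k ∈ [−max_offset, max_offset], all
timepoints (no sliding window). Under this convention a fluorescence map
that *lags* the velocity map peaks at negative k — "the fluorescence must
be shifted back in time to match the motion". Per-cell curves are averaged
unweighted with a 95% t-interval; the argmax offset is reported in seconds.

## Bleb reversals

The velocity map is Gaussian-smoothed (default σ = 5 position indices × 2
frames; the smoothing scale is a free parameter of the analysis, exposed in
the API) with periodic boundary handling in the position axis, thresholded
at 0.15 μm/s, and labeled with 8-connectivity that wraps across the seam,
so a band crossing position 0 is one component. Component centers are
circular means of member positions (unit-circle embedding), unwrapped in
time; reversals are sign changes of consecutive displacements, with zero
displacement inheriting the previous direction to avoid chattering on
plateaus. Only components with ≥ 3 reversals contribute events. The
Rac-activity zone is the smoothed fluorescence map binarized with a single
Otsu threshold over the whole map (one map, one threshold), with per-frame
edges at state changes along the periodic axis. Event–edge distances are
circular, reported as % of perimeter (≤ 50%), summarized as median with
both SD and MAD (the field reports spreads either way). The null rotates
the zone by integer offsets uniform over the P positions, 20 rotations,
pooling all recomputed distances.

## Membrane Monte-Carlo

**Model.** A closed genus-0 triangulated vesicle of V vertices (E = 3V−6
bonds, F = 2V−4 triangles); each vertex is bare membrane or a protein
(actin-nucleator complex). Energy, in kT₀ with lengths in l_min:

- stretching `W_A = (k_A/2) Σ_t (a_t/a₀ − 1)²`, a₀ the area of an
  equilateral triangle of side l₀ = (l_min + l_max)/2, l_max = 1.7 l_min;
- bending `W_b = (κ/2) Σ_i A_i (2H_i − C₀,i)²`, C₀,i = c₀ on protein
  vertices, else 0;
- contacts `W_d = −w Σ_{i<j} Θ(r₀ − r_ij)` over protein pairs, r₀ = l_max;
- active force `W_F = −F Σ_i n̂_i·x_i` over protein vertices, treated as a
  state function with normals recomputed for each proposed state.

**Bending discretization.** H_i comes from the cotangent Laplace–Beltrami
operator with Meyer *mixed* (Voronoi with obtuse fallback) dual areas and
the area-weighted outward vertex normal fixing the sign. On vertices lying
exactly on a sphere this discretization is pointwise exact (H = 1/R), and
the closed-sphere bending energy reproduces the continuum 8πκ within 0.5%
on relaxed production meshes, independent of mesh density. The raw
unweighted vertex sum is not used because its continuum limit depends on
the triangulation.

**Moves and sampling.** One sweep makes V vertex-move attempts
(displacement uniform in a cube of half-width δ = 0.1 l_min, tuned for
~45% acceptance at the reference parameters), E bond-flip attempts and
n_protein hop attempts, drawn in random order. Hard constraints are
checked before any energetics: bonds must stay strictly inside
(l_min, l_max), non-bonded vertex pairs at least l_min apart (checked by
brute force against all vertices — at desk scales this is faster and
simpler than maintaining a spatial hash), plate walls when active, and
flip validity (no duplicate edge, no vertex dropping below degree 3).
Accepted with probability min[1, exp(−ΔE/k_BT)], T/T₀ = 0.7 by default.
Protein diffusion is an occupancy swap across a *uniformly random edge*
with exactly one occupied endpoint: picking a random neighbor of a random
protein would make proposal probabilities depend on vertex degree and
break detailed balance; the edge-based proposal is symmetric, and a frozen
five-vertex two-level system reproduces its Boltzmann occupancy ratio in
the test suite. The spontaneous-curvature default c₀ = 1/l_min is a
representative nucleator curvature within the range the model explores;
κ = 20 kT₀, k_A = 1 kT₀, w = 1 kT₀, F = 1 kT₀/l_min, ρ = 0.11 are the
reference condition.

**Energy bookkeeping.** Each accepted move updates a running four-term
breakdown from locally recomputed energies; after every `run_sweeps` call
the breakdown is recomputed from scratch by an independent vectorized path
(numpy/cKDTree, not the numba kernels) and the relative drift recorded
(machine precision in practice, asserted < 10⁻⁶).

**Confinement.** Hard walls at z = ±d/2. Because a hard wall only
rectifies fluctuations, a stiff vesicle cannot follow a wall that simply
teleports inward; the initialization protocol instead ramps the half-gap
linearly over the first 80% of thermalization and *pushes* any vertex the
wall has overtaken onto it whenever the bond window and self-avoidance
permit, booking the energy change. Stragglers keep the effective wall at
their own |z| until they can follow, so the wall never cuts the membrane.
If the target gap is not reached by the end of thermalization the run
aborts with a diagnostic (infeasible gap or too few sweeps). Reaching
d = 2.6 l_min from an unconfined V = 600 vesicle takes ~8,000 sweeps.

**Meshes.** Vesicle meshes place exactly n vertices by Fibonacci spiral on
the sphere, triangulate by convex hull (genus 0 by convexity, so the Euler
counts hold automatically for any n — including n = 3127 → 6250 faces),
then relax with equal-rest-length spring smoothing, reprojection and
periodic re-hulling until the edge-length ratio fits the bond window; the
final scale centers the edge spectrum geometrically inside
(l_min, 1.7 l_min). An icosphere-plus-decimation construction was
considered and rejected: edge collapse to an arbitrary exact vertex count
needs link-condition bookkeeping that the hull construction gets for free.

**Observables and problem sizes.** Tension is σ = ⟨W_A/A⟩ over sampled
microstates; the gyration tensor of unweighted vertex positions gives
λ₁ ≥ λ₂ ≥ λ₃ and asphericity A = [(λ₁−λ₂)² + (λ₂−λ₃)² + (λ₃−λ₁)²] /
[2(λ₁+λ₂+λ₃)²]. Production ensembles use 200 independently seeded
replicates; the test suite runs desk-scale versions (V = 162–600,
hundreds to a few thousand sweeps, 2–3 replicates) chosen so that every
qualitative claim it checks (equilibration, aggregation, tension ordering,
confinement trend) is resolved several standard errors beyond sampling
noise at those sizes.

## Synthetic data: what it does and does not emulate

The movie generator renders an anti-aliased disk cell (channel 1) and a
biosensor channel built from a cytosolic background plus a von-Mises rim
focus masked by the cell body. The focus amplitude is solved *on the
actual pixel grid* each frame so the noise-free normalized-distance
polarity of the rendered image equals the requested target — ground truth
is exact by construction, not nominal. Motion models: stationary, straight
(along +x), isotropic Gaussian random walk; specs whose cell would leave
the frame are rejected. The kymograph generator moves a Gaussian velocity
band (default amplitude 0.3 μm/s, width P/20) at constant speed with
direction flips at planned frames; the fluorescence map is the smoothed
velocity delayed by the planted lag, so the cross-correlation convention
is testable end to end; zone ground truth uses the band's half-max
interval. All generators are bit-deterministic given a seed.

Not emulated: point-spread functions and shot noise (noise is additive
Gaussian), 3-D cell bodies, cell-shape irregularity beyond transient rim
bumps, photobleaching, or multi-cell crowding. Passing the round-trip
tests therefore demonstrates correctness of the *measurement machinery*
(segmentation geometry, index bookkeeping, sign conventions, statistics),
not robustness to every pathology of real microscopy.

## Known limitations

- Track linking is greedy nearest-neighbor without gap closing or
  merge/split handling; heavy crowding should rely on the collision QC.
- Edge velocity per-point noise is bounded by contour rasterization
  (~±0.03 μm/s at 0.2 μm pixels); band-level statistics average it out.
- The simulator has no volume constraint, hydrodynamics, or explicit
  contractility; the active force is a state-function approximation of a
  non-conservative push.
- Triangle–triangle intersection is not tested explicitly; hard-core
  vertex self-avoidance at the δ = 0.1 l_min move scale is the standard
  surrogate.
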