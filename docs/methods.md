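# Methods

This note documents the models, conventions and numerical choices behind
`wormtda`, in the order of the pipeline.

## Posture representation

A midline of 101 evenly spaced planar points is reduced to the 100 absolute
tangent angles of its segments, mean-centered per frame. Centering removes
rigid rotation; position is discarded by construction. Two conventions exist
in the field (absolute tangent angles vs adjacent-segment turning angles);
`wormtda` defaults to centered absolute angles, and `angles_to_midline`
inverts the map with the centroid gauge-fixed at the origin (any rigid
placement is equivalent downstream). Posture PCA (`fit_posture_pca`) keeps
the full orthonormal basis by default: projection is then an isometry, so
every Vietoris–Rips quantity is unchanged; truncation (e.g. to the first
five components) is an explicit, separate step. Self-occluded frames are
filled by carrying the most recent valid frame forward; the fill is
idempotent and fails loudly if the first frame is invalid.

## Sliding windows, patches, null model

The sliding-window embedding uses delay 1 and no subsampling; window length
`l` concatenates `l` consecutive frames, so an `N`-frame series yields
`N − l + 1` points of dimension `l·d`. Patches are contiguous blocks
(default 300 frames) with stride `P/2`; a trailing partial patch is dropped
(count = `floor((N − P)/stride) + 1`). The moving-average filter is exactly
the image of the sliding-window embedding under block averaging, a fact the
tests assert bitwise. The null model permutes frame order uniformly before
any patching or windowing, destroying temporal structure while preserving
the pose multiset.

## Vietoris–Rips persistence

Simplices enter at their diameter (edge `{x_i, x_j}` at `|x_i − x_j|`).
Degree 0 uses Kruskal union-find (all vertices born at 0; one infinite
bar). Degree 1 reduces the triangle boundary matrix over GF(2) in
filtration order, columns stored as arbitrary-precision integer bitsets;
reduction never mixes dimensions, so the (pivot edge, triangle) pairs equal
those of the full reduction. All degree-1 bars of a finite cloud are
finite. Coefficients are GF(2); ties among equal-diameter simplices are
broken by edge rank, which does not affect the diagram. On clouds of ≤ 8
points the implementation is tested against an independent full
boundary-matrix reduction written from scratch in the test suite.

Complexity is O(n³) triangles, so embedded patch clouds are optionally
capped by farthest-point (maxmin) subsampling, the standard landmarking
device in topological data analysis: it covers the cloud at its k-th
packing radius and preserves large-scale loops while bounding cost. The cap
is the single desk-scale knob (see "Problem sizes" below).

**Significant features.** The source analysis counts "significant"
topological features without defining the rule; `wormtda` declares one:
persistence ≥ ρ · (maximal persistence in the diagram), ρ = 0.3 by default
and configurable. All feature counts reported by the package are counts
under this declared rule.

**Representative cycles.** The class born at a positive edge e = {u, v} is
witnessed by e plus the shortest u–v path (Dijkstra, Euclidean edge
lengths) through strictly earlier edges — an approximate-shortest
representative whose edges all fit inside the birth scale. Tests verify
homological validity: the cycle's GF(2) chain becomes a triangle boundary
exactly at the death scale and not before. `order_cycle` orients the loop
so consecutive time indices majority-increase (ties toward increasing),
recovering trajectory order; the behavioral forward/backward label is a
separate inference (below).

## Persistence landscapes

Tent functions are evaluated exactly at the grid knots; the depth-k
landscape is the k-th largest tent value (vectorized sort). Landscapes are
nested, nonnegative and 1-Lipschitz in the scale axis, so a grid of step h
(default 0.1 scale units) bounds the discretization error by h; the grid is
fixed per experiment as [0, max death + h] over all diagrams being
compared, which the constructor enforces ("covers every bar"). Averages
zero-pad depths to the common maximum (landscape space is a vector space).
Distances are plain Euclidean distances between the concatenated
discretized vectors, unweighted by step size; with a fixed grid per
experiment this is a consistent metric (it differs from the L² function
norm by the constant factor √h). The class-distance table includes the zero
landscape as an origin and is normalized so the mean class-to-origin
distance is exactly 1.

## Statistics

- **MDS** is classical (Torgerson) scaling: double-centering and an
  eigendecomposition — exact for Euclidean-realizable distances.
- **Permutation tests** use the Euclidean distance between group mean
  vectors, 10,000 uniform label permutations by default, and the plain
  proportion of permuted statistics ≥ the observed one (no +1 correction;
  resolution floor 1/n_perm, so p = 0 means "below the floor").
- **SVM/SVR** use scikit-learn's RBF implementations. The original
  analysis relied on an R implementation's automatic kernel bandwidth; for
  reproducibility `wormtda` fixes the median heuristic
  (γ = 1/(2·median²) over pairwise feature distances), cost 10, one-vs-one
  multiclass, stratified folds (10 samples per class make unstratified
  folds degenerate), 10-fold CV repeated 20× (SVM) / 10× (SVR), all fold
  assignments seeded. SVR predictions are unconstrained in sign; with the
  ε-insensitive loss (ε = 0.1), out-of-fold errors on noiseless targets
  plateau at the tube scale rather than machine precision.
- **Baselines**: mean 2-norm of consecutive-frame differences (speed
  proxy, one scalar per sample) and per-coordinate posture standard
  deviation (100-vector per sample).

## Synthetic data generator

The generator emulates posture recordings, not biomechanics: no forces,
viscosity physics, or self-occlusion geometry.

**Gait model.** angleᵢ(t) = A·sin(p(t) − 2π sᵢ/λ) + turn(t)·bump(sᵢ) + ε,
with phase p advancing by σ·2πf/fps per frame, σ ∈ {+1, 0, −1} for
forward/turn, pause, backward. Pauses hold the last pre-pause posture
(plus observation noise ε ~ N(0, σ_noise²) i.i.d. per angle). Turns add a
smooth rise-and-fall static-curvature pulse (Gaussian bump centered at
s = 0.35, width 0.12). Behavior switching is a continuous-time Markov
chain sampled at the frame rate — the simplest process giving
class-controllable behavioral variety.

**Class presets.** Four presets labeled by nominal methylcellulose content
(0.5/1/2/3% w/v): amplitude 0.55/0.45/0.33/0.24 rad, frequency
1.8/1.5/1.2/1.0 Hz, wavelength 0.90/0.80/0.65/0.55 body lengths, switching
rate 0.05–0.35 s⁻¹, noise 0.04 rad, 30 fps, 10,665 frames. The trend —
larger, simpler, faster undulation at low viscosity; smaller, tighter,
more varied behavior at high viscosity — mirrors the qualitative contrast
reported for real viscosity gradients; the numbers are this package's
model, not measured worm physiology. Cohorts add per-sample lognormal
jitter (12% amplitude, 8% frequency) to emulate individual variability;
without it, class amplitude alone would classify even the frame-permuted
null cohort perfectly, which no real dataset does.

**Case study.** The 400-frame forward/backward/pause/backward series is
engineered so that the noiseless raw angle cloud contains exactly three
loops: the forward bout switches gait halfway (amplitude 0.55 → 0.45,
spatial mode 1.0 → 1.65), giving two loops in near-orthogonal mode planes,
and both backward bouts share one gait (amplitude 0.50, mode 2.4), giving
the third. The pause freezes the posture (an exactly revisited point of
the backward loop, plus noise), so it encloses no hole in the raw cloud;
under windowing, entry windows (gait frames then frozen frames) and exit
windows (frozen frames then gait frames) occupy different regions of
ℝ^{2000}, and together with the one-period-long window (gait period = 20
frames = l) they close a fourth loop. Loop radii in angle space are
A·√(d/2), VR deaths ≈ √3·radius, which is how the amplitudes were chosen
to keep all features above the ρ = 0.3 rule. This construction realizes
the documented qualitative phenomenon (windowing resolves the pause); it
is not a claim about which three features a real recording exhibits.

**What the generator does not emulate.** Real midline-tracking noise is
structured (segmentation jitter, occlusion artifacts), behavior is not
Markovian, gaits drift continuously, and posture space is nonlinearly
constrained. Passing tests therefore demonstrate the pipeline's
correctness and its sensitivity to the emulated regimes — not performance
figures transferable to real video.

## Direction inference for synthesized clips

Any undirected cycle can be traversed two ways; index-majority always
prefers trajectory order, so it cannot distinguish a forward recording
from a reversed one. The behavioral label instead comes from the poses:
each pose is projected onto its dominant spatial Fourier mode, and the
sign of the phase velocity along the clip decides forward (wave phase
advancing) vs backward. This is exactly the arrow-of-time information that
sliding-window embeddings preserve and moving averages destroy. The
de-embedding combiner defaults to the mean of the l poses (alternatives:
middle or first block); when the window length equals the gait period the
mean attenuates amplitude, so synthesis fixtures use periods ≠ l.

## Problem sizes and determinism

Default structural parameters follow the reference analysis (patch 300,
stride 150, l = 20, grid step 0.1, ρ = 0.3, 10,000 permutations, SVM
10-fold/cost 10/20 repeats). `PipelineConfig.desk_scale()` is the
laptop-scale profile used by the tests and examples: embedded patch clouds
capped at 60 farthest-point landmarks, 2,000 permutations, and cohorts
simulated at 900 frames per recording (30 s) instead of the full ~5.9 min;
these sizes keep a full 40-recording experiment (plus its permuted null)
around two minutes while leaving every qualitative result intact. Feature
counting demonstrations subsample clouds to ~90–110 landmarks. Every
stochastic step (generator, jitter, subsampling, permutations, CV folds)
is seeded; identical seeds reproduce results exactly.

## Known limitations

- Degree ≥ 2 homology, non-Euclidean metrics and alpha/Čech filtrations
  are out of scope.
- The O(n³) reduction limits uncapped clouds to a few hundred points;
  beyond that, use the landmark cap.
- The significance rule is a declared convention; feature counts change
  under other rules.
- Landscape distances scale with grid resolution (unweighted vectors);
  only compare landscapes sharing a grid.
- The CLI's `synthesize` subcommand maps cycles through subsampled
  clouds; vertex time indices then refer to landmark positions.
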