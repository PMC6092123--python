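# Methods

This note documents the models, defaults, and design decisions behind
`conngrad`, and what the synthetic validation does and does not establish.

## Diffusion map embedding

The embedding operates on an affinity matrix `W` built from a connectivity
matrix: each row is sparsified to its top `keep_pct` (default 10 %) of
entries — ties at the percentile cut are retained (closed threshold), so the
selection is deterministic and exactly reproducible by a sort — and pairwise
cosine similarity between sparsified rows gives `W`, with negative cosines
clamped to 0 so the Markov construction below has a nonnegative kernel.
Sparsified connectivity rows are predominantly nonnegative, so the clamp
discards almost nothing.

With degrees `D = diag(W·1)`, the anisotropic normalization
`W' = D^-α W D^-α` with `α = 0.5` discounts sampling-density effects (the
Fokker–Planck convention), and `M = D'^-1 W'` is the diffusion operator. We
eigendecompose the symmetric conjugate `S = D'^-1/2 W' D'^-1/2` with dense
`scipy.linalg.eigh`, which is fully deterministic — no iterative solver,
start vector, or seed. Matrices in this package's scope (≤ ~5,000 voxels)
make the dense route both simpler and safer than a Lanczos solver; its
correctness is pinned, in the tests, against the *generalized* eigenproblem
`W' u = λ D' u` solved independently.

The trivial constant eigenvector (λ = 1) is dropped; the remaining right
eigenvectors are divided by the stationary one and scaled `λ/(1−λ)`
(diffusion time 0) or `λ^t` (t > 0). Eight components are computed by
default. Variance explained is reported as `λ_i²/Σλ_j²` over the computed
spectrum; the convention is recorded in the output so alternatives can be
compared. A repeated unit eigenvalue means the affinity graph is
disconnected; the embedding refuses to proceed and points at the
sparsification settings, rather than silently returning component scores
that mix disconnected blocks.

Gradient sign is arbitrary, so two alignment tools are provided:
`orient_gradients` (flip so an anchor region sits at the low end, or so a
reference vector correlates positively) and `match_gradients` (optimal
one-to-one assignment plus sign flips against a reference gradient set,
solved with the Hungarian algorithm on the |Pearson r| matrix). Matching is
how gradients from different connectomes — intra-set vs set-to-target, or
embedding vs latent ground truth — are put in a common frame.

## Synthetic scenes

The generator emulates the *structure* the analysis is meant to detect: each
voxel carries latent coordinates (g1, g2); K network centers with Gaussian
bandwidth τ drive unit-variance white-noise source signals; a voxel's time
series is the loading-weighted sum of the sources plus i.i.d. Gaussian noise.
Inter-voxel correlation therefore decays smoothly with latent distance, which
is precisely what diffusion embedding should recover.

The default latent layout is an arch-shaped band — the canonical shape of an
empirical G1×G2 scatter: a motor arm at low G1/low G2, a task-unfocused
(DMN/language-like) arm at high G1/low G2, and a task-focused
(working-memory-like) apex at mid G1/high G2, so no voxel occupies the joint
G1+G2 maximum. The band is tiled by stair-step boxes following
`g2 = 0.55 − 1.35·g1²` (half-thickness 0.18, step 0.1); the apex widens into
a radially deep blob (0.5 × 0.65, density 0.75 relative to the arms). Boxes
in the rising bridge segments get 0.3 relative density: the three zones
remain dense clumps (so cluster-number selection has a defined answer of 3)
while the band stays connected (so the embedding is well posed). Defaults:
V = 1,500 voxels, T = 1,200 timepoints, noise SD 0.5, τ = 0.40, K = 6
centers — two along each arm's ridge and two stacked in the apex, none in
the sparse bridges.

This geometry was designed, and is asserted by the acceptance suite, to make
latent recovery attainable: |Spearman ρ| ≥ 0.95 between gradient 1 and
latent g1 and ≥ 0.90 for gradient 2 at noise SD 0.25. Two of its features are
load-bearing and worth stating explicitly. First, on an arch, variation in g2
lies *along* the band, so the second diffusion component (the arch-height
mode) is monotone in g2; in blob layouts the within-zone g2 variation is pure
band thickness and is structurally unrecoverable from connectivity. Second,
the apex blob gives the three concentric nonmotor representation bands about
0.2 latent units of radial width each — comfortably more than the ~0.1
residual noise of the embedded gradient, so extreme-voxel selections from
adjacent bands remain separable.

Representation labels mimic the double-motor / triple-nonmotor organization:
within each zone, voxels are ranked by distance from the latent origin and
allocated inner-first, so M2 (within motor) and N3 (within each nonmotor
zone) occupy the least extreme positions *by construction*. Task maps
threshold a noisy linear read-out of (g1, g2) at 0.5, mirroring a
medium-effect-size cut on a standardized activity map; the network map is
winner-take-all on the loadings.

What the generator does **not** emulate: hemodynamic/temporal autocorrelation
(white-noise sources; no stage here models temporal structure), head motion,
subject relatedness, 3-D anatomy or surface geometry (voxels carry labels,
not positions, except the optional grid used only by smoothing). Passing
tests therefore demonstrate the correctness and calibration of the
*computational chain*, not robustness to fMRI artifacts.

## Parcellation and the "less extreme" statistic

`extract_extremes` returns exactly `ceil(pct/100 · |region|)` voxels (ties at
the cutoff broken toward the lower voxel id), which makes the count law
testable exactly and the sweep masks nested. High-G1 and High-G2 are computed
within each nonmotor representation, Low-G1 within each motor representation,
and unioned; per-representation submasks are retained for position analyses.

"Less extreme position along a gradient" is formalized as the **median
absolute deviation from the structure-wide gradient median**, compared
between two representations with a percentile bootstrap over voxels (default
1,000 draws, 95 % interval): representation A is declared less extreme than B
only when its score is smaller *and* the bootstrap interval of the difference
excludes zero. The verdict is invariant to any increasing affine rescaling of
the gradient. Single-voxel submasks are computed but flagged unreliable.
This formalization is a package choice — the underlying observation is
usually argued from figure positions without a statistic — and is recorded in
all outputs.

Post-hoc smoothing (`smooth_map`) is mask-renormalized Gaussian smoothing
(`smooth(v·mask)/smooth(mask)`), sigma in voxel units by default. It applies
to derived per-voxel maps such as gradients only, never to time series,
where smoothing would manufacture spurious correlations.

## Clustering

K-means (50 restarts) and spectral clustering (15-nearest-neighbor graph) in
gradient space with Euclidean distance; the cluster count is chosen by mean
silhouette over k = 2…8, ties resolved toward smaller k. When all eight
gradients are clustered the components are standardized first — gradient 1's
much larger range would otherwise dominate — but the two-gradient case is
clustered raw. A selected k whose silhouette is ≤ 0.5 is flagged as weak
structure (Kaufman & Rousseeuw's rule of thumb). A neighbor graph with more
components than clusters is an error; with k or fewer components, spectral
clustering proceeds (separated clusters are the easy case).

## Seed contrasts

Meng, Rosenthal & Rubin's z-test compares the correlations of two seeds with
a shared target while accounting for the seed-seed correlation; the factor
`f` is capped at 1 exactly as in the original method, and p-values are
two-sided (sidedness is otherwise unspecified in this setting). The sample
size `n` behind a correlation matrix is the *caller's* statement — for
group-averaged connectomes an effective n is not derivable from the matrix
itself, so the package requires it explicitly and records it. Per-target
p-values are corrected by Benjamini–Hochberg step-up; the rejection threshold
is reported (0 when nothing is rejected). Contrast seeds are picked at
gradient peaks within representation regions (ties toward the lower voxel
id).

Calibration is part of the acceptance suite: type-I error of the Meng test
within [0.04, 0.06] at α = 0.05 over 10,000 trivariate-normal null
simulations (n = 50), and the realized false-discovery proportion of the full
`seed_contrast` pipeline at or below q + 0.01 over 2,000 all-null scenes
(150 timepoints, 100 targets each — under the global null BH's FDR equals q
exactly, so the replicate count is chosen to keep the Monte-Carlo standard
error near 0.005).

## Problem sizes and runtime

The validation suite and the acceptance script run the full pipeline at
V = 1,500 / T = 1,200 with a 400-voxel target set (seconds per embedding with
the dense eigensolver), 100 random ≤ 40-voxel affinities for the oracle
comparison, and the replicate counts above for calibration. These sizes give
every assertion comfortable statistical margin while keeping a full run in
the low tens of seconds. Real-data use at ≥ 20,000 voxels would need a
sparse/iterative eigensolver and chunked affinity computation, which are out
of scope here.

## Known limitations

- The generative model is one defensible stand-in; any smooth monotone
  loading model would be equally valid, and none is dictated by the
  phenomenon itself.
- Representation labels are inputs (synthetic scheme or atlas file); the
  package never infers anatomy.
- Connectivity values may enter as Pearson r or Fisher z; the `value_kind`
  flag records which, since the embedding is mildly sensitive to the choice.
- Group-average connectome construction (e.g. MIGP-style averaging) is not
  reimplemented; group analyses operate on concatenated normalized runs or on
  supplied precomputed matrices.
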