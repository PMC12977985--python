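# Methods

## The model

The package treats the cortex as a weighted graph over atlas parcels
(360-parcel HCP-MMP1 resolution in the clinical setting; any contiguous
1..N parcel table is accepted). Two modalities share one container:
structural connectivity (SC), nonnegative tractography-derived edge
weights, and functional connectivity (FC), Pearson correlations of parcel
BOLD time series. Missing nodes (lesion-excluded or zero-variance parcels)
are carried by an explicit validity mask, never as NaN or silent zeros, so
every metric operates on the valid submatrix and node count is controlled
explicitly — graph measures such as global efficiency are sensitive to N,
and the ≥ 50% lesion-overlap exclusion rule (inclusive boundary) is designed
to keep node loss minimal.

### Network construction

- FC: Pearson correlation per parcel pair; zero-variance parcels are marked
  invalid. Head motion (mean framewise displacement) is *not* regressed at
  construction; it enters group-level models as a covariate of the
  functional analysis family.
- SC: streamline counts are divided by the sum of endpoint node volumes
  (invnodevol) to remove parcel-size bias.
- Proportional thresholding keeps the `ceil(density * M)` strongest
  upper-triangle edges over valid nodes. Negative FC edges are zeroed first
  (correlation sign is not a connection strength). Ties at the cutoff break
  to the lexicographically smaller (i, j) pair, which makes thresholding
  deterministic across platforms and idempotent at fixed density.
  Thresholding is applied for topology metrics only; coupling and diffusion
  run on unthresholded networks.

### Graph topology

Edge length is the reciprocal weight 1/w. Global efficiency is the mean
inverse shortest-path distance over ordered pairs with disconnected pairs
contributing 0 (Latora–Marchiori); this convention is what keeps the
virtual-lesion analysis finite when a cut vertex is removed. Weighted
clustering uses the Onnela geometric-mean form with weights rescaled by the
network maximum; the network value averages nodes of degree ≥ 2 (nodes with
fewer neighbors have no triangles and carry 0). Node "structural rank" is
the dense rank of strength (weighted degree), ties to the lower parcel id;
degree rank is available as an option since published ranks rarely state
which was used.

The virtual lesion of a target node recomputes efficiency with the node's
row/column removed and compares the percentage drop against a null of
single-node uniform random removals (target excluded), with the add-one
corrected one-sided p = (1 + #{null ≥ observed}) / (n_null + 1); n_null
defaults to 1000.

### Structure–function coupling

Per node: Spearman rank correlation (average ranks for ties) between the
node's SC and FC profiles restricted to jointly valid partners, excluding
the self-connection. Zero SC entries are kept — an absent pathway is
informative data, not missingness. A node with a constant profile has no
defined rank correlation and is flagged rather than assigned 0. Network
summaries are unweighted means over defined nodes; the parcel → network
lookup is user-editable configuration (the synthetic atlas ships a cyclic
assignment over seven canonical systems: Visual, Somatomotor, DAN, VAN,
Limbic, FPN, DMN).

### Network Diffusion Model

Pathology seeded at x₀ spreads as x(t) = e^{−βLt} x₀ with
L = I − D^{−1/2} A D^{−1/2}, the symmetric normalized Laplacian
(eigenvalues in [0, 2]; a random-walk variant is available behind a flag).
The kernel is evaluated by eigendecomposition, which makes the zero-mode
projection ⟨D^{1/2}1, x(t)⟩ exactly conserved and the semigroup property
hold to round-off. Because the kernel depends on β and t only through the
product βt, β is fixed at 1 and t is swept (default grid 0–10, step 0.05,
comfortably covering peaks near t ≈ 2.5 reported for cohorts of this kind).
The epicenter sweep tests every valid parcel as a unit impulse and
correlates each diffusion pattern with the empirical morphometry t-map over
valid nodes; the epicenter is the seed with the highest peak correlation,
ties to the lower parcel id. The t-map is taken as-is (signed); in cohorts
with predominant thickening the deformation pattern is positive-going, and
the full r-matrix is retained so both orientations can be inspected. The
sweep runs on the unthresholded SC.

### Lesion and cognition

Total lesion load = lesioned voxels / intracranial voxels; regional lesion
proportion = lesioned fraction of each parcel (exact integer conservation
against the label volume is tested). DMN white-matter integrity = mean SC
weight over unordered pairs of valid DMN parcels (zeros included), so any
intra-DMN attenuation can only lower it; DMN local lesion load = mean parcel
lesion proportion (mean rather than sum, making it invariant to network
size). Cognitive raw scores are z-scored against the healthy-control mean
and SD per test; latency tests are inverted at the z level (z → −z), which
preserves the control-referenced scale, unlike a raw reciprocal. Domain
scores average member tests (Verbal Fluency is deliberately shared between
Executive and Language; the Global screen is the mean of the MMSE and MoCA
z-scores); demographic variance (age, sex 0/1, education) is removed by OLS
and the standardized residuals are the brain–behavior phenotype.

### Inference

Welch (unequal-variance) t is the default two-sample test for summary
statistics — it, and not the pooled form, reproduces the demographic
t-statistics printed for the clinical cohort — and the 2×2 χ² uses the
Yates continuity correction for the same reason. Mann–Whitney U reports a
tie-corrected, continuity-corrected normal Z, with exact enumeration of the
p-value when n₁·n₂ ≤ 400 and the data are tie-free. Edgewise group
comparison fits OLS of Fisher-z FC on group + covariates per upper-triangle
edge (vectorized across edges; edges missing in more than half the subjects,
or estimable in only one group, are excluded); hyper-/hypo-connected sets
are the top-k most positive/negative group t-statistics (k = 200). Robust
regression is Huber M-estimation (IRLS on the MAD scale, c = 1.345,
convergence when coefficients move < 1e-8 or 50 iterations, flagged rather
than raised on non-convergence). BH-FDR is applied within each analysis
family. Covariates follow the stratified strategy: structural models adjust
for age/sex/TIV, functional additionally for mFD, cognitive models for
age/sex/education.

The sensitivity sweep refits the key integrity regression across network
densities 8–20% and lesion-cutoff values; an effect is *robust* only when
every grid cell succeeds, the coefficient sign is constant, and p < 0.05
everywhere. Failed cells are recorded, never fatal; a single-cell grid is
trivially robust and flagged degenerate.

## The synthetic cohort

No patient MRI of this kind is deposited, so the generator produces the
*statistical structure* the analysis assumes, with fixed defaults that are
the study conditions (44 patients vs 72 controls; 90 nodes by default for
speed, 360 supported):

- **SC**: nodes uniform in the unit cube; edge probability and weight decay
  as exp(−d/0.5) with lognormal weight multipliers; 10% of nodes get a 4×
  connection-probability boost (rich-club-like hubs) and within-system pairs
  a 3× boost (community structure); a distance-MST is added so the graph is
  always one component. Weights are arbitrary streamline-like units.
- **FC**: correlation matrix of T = 500 draws of the linear-Gaussian
  process x = γÃx + ε, Ã = SC rescaled to spectral radius 0.6,
  γ ∈ [0, 1] the coupling strength (default 0.6). This was chosen over a
  hemodynamic simulation because its covariance
  (I − γÃ)^{−1}(I − γÃ)^{−T} is analytic and serves as an oracle in tests;
  node-level SC–FC coupling is monotone in γ.
- **Lesions**: grown on a toy voxel atlas (cubic parcel blocks, 2 mm
  voxels) from a DMN center parcel — the parcel fills nearest-centroid
  first, then spills into surrounding brain — so half-parcel extents hit the
  exclusion boundary exactly. Per-patient extents scatter uniformly in
  [0.5, 2] × 48 voxels.
- **Disconnection**: each patient's intra-DMN edges are multiplied by an
  integrity factor q ~ Uniform(0.3, 1) (attenuation, not deletion, keeping
  integrity continuous); a chain of intra-DMN edges is guaranteed in the
  template so the factor always has substrate, which matters at small
  n_nodes.
- **Morphometry**: thickness ≈ 2.5 mm baseline with 0.1 mm parcel and
  subject noise; patients add 0.15 mm × the standardized forward-diffusion
  pattern from the configured seed at t* = 2.5, so the group t-map is the
  ground-truth target of the epicenter sweep (thickening-positive, matching
  the remodeling direction such cohorts show).
- **Cognition**: latent score = 2.5·q + 0.5·lesion_load − 0.02·(age−45) +
  0.05·(edu−12) + N(0, 0.5); per-test raw scores load 0.7 on the latent
  with unit test noise on realistic scales (MMSE 27 ± 2, Stroop time
  60 ± 15 s inverted, ...). The integrity slope dominates the lesion-load
  slope by construction (lesion loads are ~10⁻²), producing the headline
  dissociation: integrity predicts cognition, lesion volume does not, at the
  default sample sizes. The slope was calibrated once against that design
  contract of the generator (not a fitted quantity) and frozen.
- Demographics match the clinical cohort's printed summaries (age
  40.3 ± 13.2 vs 45.7 ± 14.9, 57% vs 40% male, education 11.3 ± 4.4 vs
  13.0 ± 2.8, 16% seizures).

Every draw descends from one seed via spawned child streams per component,
so the dataset is bit-deterministic and skipping a component (e.g., FC in
power simulations) does not perturb the others.

**What the generator does not emulate:** hemodynamics and BOLD physiology
(including perinidal signal artifacts), vascular geometry and flow, spatial
autocorrelation of real cortical maps, site/scanner effects, and
domain-specific cognitive factor structure (one latent factor drives all
tests). Passing tests therefore demonstrate that the *pipeline logic* is
correct and well-calibrated — recovery of planted effects, honest nulls —
not that the clinical effect sizes would replicate on real data.

## Numerical choices

- Matrix symmetry tolerance on read: 1e-8 (average-symmetrized below it,
  rejected above); diagonal forced to zero.
- Heat kernel exponent groups β·t before multiplying eigenvalues, making
  diffuse(L, x₀, β, t) bit-identical to diffuse(L, x₀, 1, βt).
- Fisher-z clips |r| at 1 − 1e-7 before arctanh.
- Degenerate inputs raise typed errors (DegenerateInputError,
  DimensionError, MatrixFormatError, AlignmentError) rather than returning
  NaN; undefined per-node values (constant coupling profile, constant
  morphometry parcel) are flagged missing, not zeroed.
- The pipeline report omits wall-clock time (written to a sidecar), so
  report.json is byte-identical across reruns with one config and seed.

## Problem sizes

Defaults keep the full test suite under a minute of simulation per check:
synthetic networks of 90 nodes (360 supported), 44 + 72 subjects for power
replicates, 50 replicates for recovery/power rates, 200 for calibration
rates, 500 for the OLS type-I check, and a 20 + 20-subject pipeline run for
end-to-end reproducibility. These sizes are the package's validation
conditions; all are configurable.

## Known limitations

- The epicenter sweep evaluates full heat kernels (O(T·N³) per network);
  fine at N ≤ 360, not tuned for voxel-level graphs.
- β is not fitted (only βt is identifiable from a single map); comparing
  diffusion time scales across cohorts requires a fixed convention.
- Exclusion masks are per-subject; group analyses use the per-subject valid
  sets rather than a common-node intersection, so edgewise models drop
  edges estimable in only one group.
- The Mann–Whitney exact path enumerates only tie-free data; tied data fall
  back to the corrected normal approximation.
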