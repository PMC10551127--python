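# Methods

## Scope and data model

`connectoperm` implements a group analysis of parcel-level resting-state
functional connectomes. It starts where image preprocessing ends: the
inputs are per-subject matrices of BOLD time series (timepoints x
parcels), an atlas lookup table assigning every parcel to one of the
seven canonical cortical systems (VN, SMN, DAN, VAN, LN, FPN, DMN), and
a phenotype table with group membership (patient/control), the four
nuisance covariates (age, sex, mean framewise displacement, total
cortex volume) and clinical scores (SAS, SDS, Wexner). All artifacts
are plain TSV; node order is the atlas row order, a single source of
truth for every matrix downstream.

## Connectivity: ridge partial correlation

Functional connectivity is estimated as Tikhonov-regularized (ridge)
partial correlation. The sample correlation matrix R (computed on
internally standardized columns) is inverted after diagonal loading,

    theta = (R + lambda I)^-1,
    p_ij  = -theta_ij / sqrt(theta_ii * theta_jj),

and p is Fisher r-to-z transformed (arctanh, inputs clipped to
+/-(1 - 1e-7) so outputs stay finite). The ridge acts on the
*correlation*, not covariance, matrix: this makes the estimator
invariant to affine rescaling of any channel and well-posed even when
timepoints < parcels (e.g. 170 timepoints, 400 parcels). The toolbox
this estimator mirrors does not publish its regularization target or
default strength; this is the main reproducibility gap of the approach,
so both are explicit here: default `lambda = 1.0`, configurable on the
CLI, with plain Pearson correlation available as an alternative
estimator. No data-driven lambda tuning is performed in this version —
a fixed lambda keeps all downstream permutation inference deterministic;
a tuning hook can be added at the `ridge_precision` call site.

Numerical conventions: with `lambda = 0` a singular R (T <= N or exact
collinearity) raises an error instructing `lambda > 0`; outcome columns
fitted to numerically zero residual get t = 0 rather than an arbitrary
large statistic. Per-edge magnitudes are *not* monotone in lambda at
small lambda (partial effects re-weight against each other); only the
eventual decay to zero is guaranteed, and that is what the tests assert.

## Binary graph metrics over a density grid

Each z-matrix is thresholded at every density of a proportional grid,
default 10%..34% in steps of 1% (25 graphs per subject), keeping the
k = round(density * N(N-1)/2) edges with the largest *signed* z
(round-half-even; ties broken by ascending lexicographic edge index so
results are deterministic). Thresholding on signed rather than absolute
z follows the binary-FC-graph convention of keeping the strongest
positive couplings; the choice is isolated in `binarize_at_density`.

Per graph the package computes:

* global: mean clustering coefficient C_P (Watts-Strogatz, local value
  0 for degree < 2), characteristic path length L_P (mean shortest path
  over pairs inside the largest connected component; E_glob already
  penalizes disconnection, so L_P keeps its classical meaning), global
  efficiency E_glob (mean 1/d over all pairs, 1/inf = 0), local
  efficiency E_loc (mean over nodes of the efficiency of the
  neighbor-induced subgraph), degree assortativity (endpoint-degree
  Pearson; NaN on degree-regular graphs, excluded from inference with a
  logged count), and the random-graph-normalized gamma = C_P/C_P_rand,
  lambda = L_P/L_P_rand, sigma = gamma/lambda;
* nodal: degree, unnormalized Brandes betweenness, nodal efficiency
  (mean 1/d to all other nodes).

C_P_rand and L_P_rand are means over Maslov-Sneppen degree-preserving
rewirings (10 accepted double-edge swaps per edge, 100x attempt cap;
a complete graph is its own — correct — null). The default is 100 null
graphs per subject-density; the number is a precision knob for
gamma/lambda only and does not affect error control, so the large
simulation studies use 3 (see below).

The threshold-free summary of each metric is the trapezoid-rule area
under its curve over the density axis (AUC); NaN densities are dropped
pairwise with their grid points, and fewer than two finite points is an
error. All kernels (BFS all-pairs, triangle counting, local efficiency,
betweenness, rewiring) are numba-compiled; unit and acceptance tests
pin them to exhaustive brute-force oracles (Floyd-Warshall, triangle and
shortest-path enumeration) to 1e-12 on random graphs, and to networkx.

## Group inference

All group contrasts share one engine: an OLS model

    y = b0 + b1*group + b2*age + b3*sex + b4*meanFD + b5*cortexvol + e

with the group indicator (patient = 1) as the tested contrast, and
Freedman-Lane permutation — outcomes are residualized on the nuisance
model, residual rows are permuted by seeded shuffles, the nuisance fit
is added back, and the full model is refit. With no nuisance columns the
scheme reduces exactly to permuting group labels (tested). P-values use
the add-one convention (1 + #{null >= obs}) / (n_perm + 1), two-sided on
|t| except where noted; default 10,000 permutations.

Family structure follows the reporting granularity of the analysis:

* the 8 global AUC metrics form one max-|t| family (family-wise
  corrected p) with BH-FDR across the family as well;
* each nodal metric forms its own max-stat family over the N parcels;
* the 28 network-block values use uncorrected permutation p with
  BH-FDR across the 28 (no max-stat), the stated procedure for that
  analysis;
* AUC values only are tested, not per-density values — AUC is the
  representative summary, which keeps the families small and
  interpretable.

## Network-Based Statistic

Edge-wise GLM t-statistics are computed for all N(N-1)/2 edges. The
primary threshold is parametric: two-tailed p < 0.001 from the t
distribution with n - rank(X) degrees of freedom (an edge-level
*permutation* p at 0.001 resolution would need >= 10^4 permutations per
edge for no inferential gain; the permutation enters at component
level, as in standard NBS practice). Suprathreshold edges are split by
direction (patients > controls / patients < controls), connected
components are found by union-find, and component size is the *edge
count* (extent). Each direction gets its own permutation null of the
maximum component size via the shared Freedman-Lane engine; corrected
p = (1 + #{null max >= size}) / (n_perm + 1), significant at one-tailed
p < 0.025 per direction. "Null sizes larger than observed" is
implemented as >= with add-one smoothing so p = 0 is impossible.
Components are reported per direction (plus a network-pair tally of
hypo/hyper edge counts and count/possible ratios); a merged union
summary across directions is available from the edge table.

## Network blocks and clinical correlation

Per subject, the z-matrix is reduced to 7 within-network means
(unordered pairs inside each system, diagonal excluded) and 21
between-network means, signed values averaged as-is (negatives not
folded). Every atlas must provide >= 2 parcels per network so the
within-block mean exists; this is validated at atlas load.

Clinical association in the patient group uses partial Pearson
correlation: index and score are each residualized on [1, covariates]
by OLS and the residual correlation is tested with
t = r sqrt(df/(1-r^2)), df = n - 2 - #covariates, two-tailed; BH-FDR is
applied across the whole (index x score) scan. Missing scores are
handled pairwise-complete with the per-pair n reported. Constant
covariate columns (e.g. single-sex patient subsets) duplicate the
intercept and are dropped; genuinely collinear covariates are an error.
The scanned indices default to the 8 global AUC metrics plus any
FDR-significant block values from the upstream stage.

## Synthetic cohorts

The generator emulates the study design rather than the biophysics of
BOLD. Defaults: 35 patients and 40 controls, 170 timepoints at
TR = 2 s, block-structured target correlation (within-network r = 0.4,
between-network r = 0.1), AR(1) temporal autocorrelation phi = 0.3 as
the simplest stand-in producing band-passed-like variance in the
correlation estimates (phi = 0 reduces exactly to i.i.d. rows), and
covariates drawn group-independently (a matched design): age ~
N(47.2, 12.8^2) / N(45.1, 13.1^2), P(male) = 6/35 / 13/40, mean FD
log-normal with median 0.055 mm, cortex volume N(5e5, 5e4^2) mm^3,
SAS/SDS elevated in patients, Wexner recorded for patients only.

Group effects are injected on the patient target correlation, either
per edge or per network block; entries are clipped to |r| <= 0.95 and
the matrix is repaired to positive definiteness by eigenvalue clipping
at 1e-6 (with diagonal renormalization) whenever needed — the repair is
deterministic and flagged in the truth record. The generator does not
model hemodynamics, motion artifacts, spatial autocorrelation within
parcels, or non-Gaussian BOLD features; passing tests therefore
demonstrate the *statistical machinery* (error control, power against
injected covariance differences), not robustness to real-data
artifacts.

## Simulation study sizes

The operating-characteristic studies in `connectoperm.validation` use a
scaled-down cohort — 40 parcels, 20+20 subjects, 1,000 permutations,
3 rewiring nulls — chosen so hundreds of replicates run on one CPU in
minutes while keeping every pipeline stage intact:

* type-I: 200 null cohorts; a cohort counts as a family-wise false
  positive if any global AUC metric reaches max-stat corrected
  p <= 0.05, or any NBS component reaches p < 0.025 in either
  direction. The max-stat family-wise rate should sit inside the exact
  binomial 95% interval around 0.05; NBS is additionally discrete
  (component sizes are small integers), which can only make it
  conservative.
* recovery: a within-LN block decrease of delta r = -0.2 at the study's
  35/40 group sizes (100 runs, target: LN-LN q < 0.05 in >= 80%), and a
  planted connected 20-edge component spanning LN/SMN with a +0.35
  shift on the generating Fisher-z scale (50 runs, target: >= 80% of
  planted edges inside significant components in >= 90% of runs).
* clinical null: 100 patient-group scans with indices and scores
  generated independently; the scan should be FDR-clean in >= 95%.

One master seed drives every study; per-stage and per-replicate seeds
are derived through `numpy.random.SeedSequence` spawn keys, so results
are bit-reproducible and stage seeds never collide.

## Known limitations

* The ridge target/strength of the reference toolbox is unpublished;
  absolute z values are comparable only within a fixed lambda.
* Signed-vs-absolute thresholding and the exact small-world estimator
  variant are convention choices; both affect metric values but not the
  pipeline contracts.
* L_P on a graph whose largest component is a single node is NaN (never
  reached on the default density grid).
* The generator's Gaussianity means heavy-tailed BOLD artifacts and
  motion-coupled effects are out of scope for what the simulations can
  demonstrate.
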