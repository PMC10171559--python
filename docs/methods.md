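# Methods

## Pipeline

One scan enters as a T×n matrix of ROI time courses with a node-to-
network label vector. The stages are:

1. **Network restriction** — keep the nodes of one labeled network
   (at least 2 nodes; node order preserved).
2. **FC computation** — Pearson correlation matrix of the restricted
   time courses (T ≥ 3; a zero-variance ROI is an error naming the
   node, never silently patched).
3. **Normalization** — `none`, `fisher_z` or `degree`, applied to the
   n×n matrix *before* vectorization. Fisher Z is elementwise so the
   order would not matter for it; degree normalization genuinely needs
   the matrix.
4. **Vectorization** — strict upper triangle, row-major, length
   ñ = n(n−1)/2. Row-major order is a package convention; every
   downstream metric is invariant to the choice of bijection.
5. **Cohort assembly** — columns sorted by (subject, session), so each
   subject's sessions are contiguous. Cohorts must be balanced (equal
   session counts, identical session identifiers across subjects);
   unbalanced input is rejected rather than silently handled.
6. **Train/test split** — by sessions, the same sessions for every
   subject. All model state (means, bases, dictionaries, the overlap
   threshold) is estimated on the training half only.
7. **Extraction and scoring** — see below.

## Extractors

All four satisfy one contract: `fit` sees only training columns,
`transform` returns a matrix of exactly the input's shape and column
index, and fitting is deterministic given its seed (eigen/SVD sign
ambiguity is resolved by making each basis vector's first nonzero
coordinate positive).

**PCA.** Per-feature mean ȳ over training columns; basis = top-m̃ left
singular vectors of the centered matrix. Requesting m̃ beyond the
numerical rank is an error. The transform D D^T (Y − ȳ) is an affine
projection: idempotent, and linear after accounting for the mean term.
Explained-variance fractions are recorded for all components.

**Robust PCA.** Principal component pursuit (minimize ‖L‖* + λ_pcp‖S‖₁
s.t. Y = L + S) via the inexact augmented-Lagrangian iteration with
singular-value thresholding; λ_pcp defaults to 1/√max(ñ, p·s_train),
feasibility tolerance 1e−7, budget 500 iterations, non-convergence
raises an error carrying the residual. The sparse part is z-scored per
feature (features with zero variance stay 0 — FC features have
heterogeneous scales, so the standardization axis is the feature, not
the scan). A k-atom dictionary is then learned by alternating
ℓ1-penalized sparse coding (weight λ) and unit-norm dictionary updates
(scikit-learn's batch dictionary learner; its per-iteration objective
history is kept and is non-increasing). At test time the *raw* test
matrix is coded by ordinary least squares and reconstructed,
Sub = D α̃; this follows the literal test-phase rule. A
`standardize_test=True` flag applies the stored training z-score first,
for sensitivity analysis. A rank-deficient dictionary falls back to the
minimum-norm solution with a logged warning.

**K-SVD.** Dictionary initialized from randomly chosen training
columns (seeded), coding by orthogonal matching pursuit with a hard
budget of s0 nonzeros, atoms updated one at a time by a rank-1 SVD of
the residual restricted to the columns using the atom. Unused atoms,
and atoms that collapse onto a near-duplicate of another atom
(|gram| > 0.99, with the duplicate's coefficient mass folded into its
twin first), are replaced by the worst-represented training column —
the usual guard against local minima of the alternation. Test-phase
coding is unconstrained least squares by default (`test_coding="omp"`
is available for sensitivity checks), and the subject-specific part is
the residual Y − D X. Exact dictionary recovery is only identifiable
when codes are sparse relative to the dictionary (s0 ≪ k); in the
near-dense regime (e.g. 3 atoms with 2-sparse codes) even an exact
enumeration coder stalls in local minima, so the recovery tests use
the identifiable regime.

**COBE.** The C orthonormal directions maximizing the summed squared
projection onto each subject block's column space — computed as the
top left singular vectors of the stacked per-block orthonormal bases,
equivalent to the eigendecomposition of Σᵢ QᵢQᵢᵀ. COBE is the one
supervised extractor: its fit consumes per-subject blocks derived from
the cohort index. A top eigenvalue ≤ 1 means no genuinely common
direction exists and is logged. Because the basis is orthonormal, the
test-phase least squares reduces to Sub = Y − D DᵀY, identical for the
pooled matrix and per-subject blocks. Only this subtraction product is
produced; no separate per-subject dictionary is estimated.

Default iteration budgets (K-SVD 30, dictionary learning 100) were set
by convergence behaviour on cohort-sized problems: objective curves are
flat well before the budget in the recovery tests.

## Metrics

**Idiff** uses unordered session pairs, s̃ = s(s−1)/2 of them; the
reported Iself/Iothers are the pair-averaged means. Range [−200, 200];
a cohort with identical sessions and orthogonal subjects scores
exactly 100, anticorrelated subject vectors score 200.

**Overlap** pools the strict upper triangles of the diagonal s×s
blocks of the ps×ps scan-correlation matrix (within-subject,
p·s(s−1)/2 values — unit self-correlations and symmetric duplicates
excluded, since they would bias the threshold) and the full blocks
above the block diagonal (between-subject, C(p,2)·s² values — each
unordered scan pair once). Threshold candidates are the midpoints of
consecutive distinct pooled values plus one point below the minimum
and one above the maximum, which realizes every achievable error
count; the classification rule is "value ≥ t is within-subject", so
equality is assigned to within. Ties in the minimal error are broken
toward the smallest threshold. The degenerate all-equal pool yields
min(#within, #between), not an error. The training-phase threshold is
stored with the model and reused unchanged at test time.

**Ratio** = Idiff / max(Overlap, 1). Overlap is an integer count, so
flooring the denominator at 1 keeps a perfectly separated cohort's
ratio finite and equal to its Idiff.

Grid search selects the parameter point with the maximal
*training*-phase ratio; ties go to the smallest parameter values.
Reference grids for a 10-session design are in
`fcfingerprint.experiments.DEFAULT_GRIDS` (principal components 1–189
step 5; robust-PCA k 25–70 step 5 with λ 0.1–0.5 step 0.05; K-SVD k,
s0 2–8; COBE C 2–5); tests and examples scale these down in proportion
to their smaller cohorts.

## Synthetic cohorts

**FC-vector mode** draws y_{i,j} = √a·g + √b·uᵢ + √c·e_{i,j} with
a = rho_between, b = rho_within − rho_between, c = 1 − rho_within and
g, uᵢ, e_{i,j} iid standard normal of length ñ. Under this
variance-share parameterization the expected Pearson correlation
between scans is exactly rho_within within a subject and rho_between
between subjects, which makes metric recovery analytically checkable:
pair-averaged Iself/Iothers converge to (rho_within, rho_between) and
raw-FC Idiff to 100·(rho_within − rho_between) as ñ grows (verified at
ñ = 2000 within ±0.02 over 20 seeds). Defaults rho_within = 0.6,
rho_between = 0.2 sit in the range of test-retest versus
between-subject FC similarities reported for multi-session resting-
state cohorts.

**Time-series mode** builds each scan as F·(W₀ + ΔWᵢ)ᵀ + ε with one
standard-normal factor time course per labeled network (fresh per
scan), unit block loadings W₀, a dense subject-stable perturbation
ΔWᵢ ~ N(0, subject_scale²) and white noise ε ~ N(0, noise_scale²).
Defaults: subject_scale = 0.3 (subjects identifiable from a few
hundred time points without dominating the shared network structure),
noise_scale = 1.0, dt = 2.0 s (a typical fMRI repetition time).
Downstream FC matrices show block structure by network, subject-stable
deviations, and — because the factor realizations differ per scan —
scan-varying correlated sampling noise in FC space. That last feature
is what makes this mode the right substrate for the component-count
and scan-length experiments: the common-structure dimension seen by
COBE, and the FC noise level seen by every method, vary the way they
do in correlation matrices estimated from finite time series.

**Separable cohort** repeats one vector per subject across sessions,
with subject vectors mean-centered and mutually orthogonal — Hadamard
sign-pattern columns (orthogonality exact in integer arithmetic) when
a power-of-two block of at least p+1 columns fits into ñ, otherwise
Helmert rows (orthonormal and mean-zero to float precision). Hosting p
such vectors requires ñ ≥ p+1.

What the generators do *not* emulate: hemodynamics, temporal
autocorrelation, head motion, physiological noise, non-Gaussian FC
distributions, and unbalanced designs. Tests passing on these cohorts
show the algorithms and metrics behave as specified under the assumed
within/between correlation structure; they do not certify effect sizes
on scanner data.

## Numerical choices and degenerate inputs

- Fisher Z clips |r| at 1 − 1e−7 so exact ±1 maps to a large finite
  value without altering ordering; |r| > 1 beyond 1e−9 is an error.
- Degree normalization is undefined for a node whose off-diagonal
  correlations are all exactly zero; this raises an error naming the
  node (an epsilon patch would mask upstream bugs — real FC rows are
  never exactly zero).
- Re-normalizing an already-normalized matrix is an error.
- Pearson correlation of a zero-variance column is an error everywhere
  (FC, identifiability matrix, overlap pooling).
- Scan truncation keeps floor(minutes·60/dt) rows and rejects requests
  longer than the scan or shorter than 3 points. Truncation applies to
  whatever series is supplied; any upstream filtering is assumed done.
- Experiment designs never re-optimize on test data: replacing the
  test columns with noise leaves fitted models and thresholds
  bit-identical (tested).

## Test and experiment problem sizes

The suite runs on deliberately small cohorts: parameter recovery at
p = 20, s = 4, ñ = 2000 over 20 seeds; directional checks at p = 6–8
with ñ = 300 (FC mode) or 20 ROIs × 150–255 time points (time-series
mode) over 10 seeds, with reduced grids proportional to the
10-session reference design; the split-stability design uses
C(4,2) = 6 plans. Directional
claims are assessed by sign tests: at least 8 of 10 seeds must agree
(one-sided binomial p ≈ 0.055 against a fair coin).

## Known limitations

- Overlap counts each unordered between-subject scan pair once; a
  convention counting ordered pairs would roughly double the counts
  (and halve the ratio) without changing any comparison.
- The robust-PCA extractor's test-phase coding operates on the raw
  test matrix while its dictionary was trained on z-scored features;
  this asymmetry follows the literal test-phase rule and can be
  switched off via `standardize_test`.
- K-SVD recovery is only expected in the s0 ≪ k regime (see above).
- PCP convergence is not guaranteed for adversarial inputs within the
  default budget; the error carries the residual so callers can retry
  with a larger budget.
- Voxel-level FC (ñ on the order of 10¹⁰) is out of scope by design;
  the pipeline assumes ROI-averaged series with node labels supplied
  as an input file.
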