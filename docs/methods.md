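# Methods

## Model and assumptions

The normative model is a standardized PCA of nine phenotype measures in a
reference cohort of autistic individuals: VABS Communication,
Socialization and Daily Living Skills standard scores (higher = better),
ADI-R Socialization, Communication and Restricted/Repetitive-Behavior
algorithm scores (counts, higher = more symptoms), Total IQ, and CBCL
Internalizing and Externalizing T-scores (higher = more problems).  The
model is complete-case: records with any missing measure are rejected at
read time, with the rejection logged.  No imputation, no factor rotation,
no covariate adjustment — the instruments are already age-normed.

Fitting z-scores each measure (sample SD, n−1 denominator), computes the
9×9 correlation matrix, and eigendecomposes it.  Retention uses the
eigenvalue-≥-1 rule first (a component with λ ≥ 1 carries at least one
variable's worth of information; the boundary λ = 1.0 is retained, and the
cutoff and inclusivity are configurable), then extends — never shrinks —
the retained set until cumulative explained variance reaches 70%.  On
cohorts with the published correlation structure this selects k = 3.

Projection of a new individual standardizes their raw measures with the
*reference* means/SDs, rotates with the stored eigenvectors, and divides
each component score by √λ_k, so all coordinates have unit variance in the
reference population.  The normative claim is distributional: the
z-scored coordinates of the reference population are approximately a
spherical multivariate normal.  Under that assumption the projection onto
the unit diagonal `t = Σ_k s_k / √k` is standard normal, the one-sided
quantile Φ(t) is uniform, and `MGFS = 10·Φ(t)` ranks an individual's
general functionality against the reference cohort.  The score is
one-sided by construction (all-negative corner = lowest functionality,
all-positive = highest), unlike two-sided growth-chart percentiles.

## Sign orientation and octants

PCA leaves each axis's sign arbitrary, so each retained component is
anchored: the correlation between a named anchor variable and the
component is forced to a required sign by flipping the column when needed.
Defaults: PC1 ↔ VABS Communication positive (PC1 = general/social
functioning), PC2 ↔ CBCL Internalizing negative (PC2 = fewer behavior
problems in the positive direction), PC3 ↔ ADI-R Communication positive.
Components beyond the anchor table anchor to their largest-|loading|
variable, positive.  An exactly zero anchor correlation is an error
(orientation undefined), and the operation is idempotent.

One tension in the published interpretation is documented rather than
resolved: the loading table gives ADI-R Communication a *positive* 0.73
correlation with PC3, while the accompanying prose reads negative PC3 as
"worse ADI-R Communication" — since higher ADI-R scores mean more
symptoms, these cannot both hold.  The implementation follows the loading
table's signs.

Octants are the sign sectors of the three coordinates; zero counts as "+"
(a measure-zero boundary).  Roman numerals use the fixed table
I=+++, II=−++, III=−−+, IV=+−+, V=++−, VI=−+−, VII=−−−, VIII=+−−; only
I (best) and VII (worst) carry intrinsic meaning, the rest are labels.

## Numerical choices

- Quantile engine: `scipy.special.ndtr`, accurate to ~1e-15.  In double
  precision Φ saturates to exactly 0/1 once |t| exceeds ≈ 8, so the open
  bounds 0 < MGFS < 10 hold on any clinically plausible input but not for
  coordinates beyond ~±8 z-units per axis.
- Display rounding: half-away-from-zero to one decimal (the published
  precision), via `decimal.Decimal`; raw values are always retained.
- Model persistence: JSON with floats serialized at full precision
  (`repr`-exact), so write→read round trips are bit-identical.
- Eigendecomposition: `numpy.linalg.eigh` on the explicitly computed
  correlation matrix; eigenvalues below 1e-10 are never retained (rank
  deficiency logs a warning).  Orthonormality and trace conservation
  (Σλ = p) are validated at 1e-8 after every fit.

## Synthetic reference cohorts

The real reference sample is access-restricted, so the generator draws
Gaussian cohorts whose *population* correlation matrix carries the
published component structure.  Construction: the published
variable-component correlation columns divided by √λ_k are orthonormalized
(QR with sign realignment) into eigenvector candidates u_k; the low-rank
part Σ_k λ_k u_k u_kᵀ is completed with the residual variance
(1 − Σ_k c_jk² per variable) placed on the orthogonal complement of the
component subspace, by alternating complement-projection, PSD-clipping and
diagonal restoration until the diagonal is exactly 1.  Placing the
residual on the complement (rather than adding a diagonal matrix) is what
keeps the target λ's as the matrix's actual leading eigenvalues — a naive
diagonal completion inflates them by the average residual (~0.25).  The
result is symmetric, unit-diagonal and PSD with leading eigenvalues within
5e-3 of (3.49, 1.65, 1.39) and population loadings within 3e-3 of the
published values; fits at n = 2744 recover the eigenvalues within ~±0.06
and cumulative explained variance of 72–73%.

Marginal means/SDs are conventional instrument-style defaults (VABS-like
75/12, ADI-R-like counts, IQ 85/20, CBCL T-scores ~60/10); they are *not*
the reference sample's unpublished statistics.  All component math is
scale-free, so marginals affect only the raw-score columns.  By default
only the three ADI-R variables are clamped at zero — they are counts, and
an unclamped Gaussian occasionally produces invalid negative records —
which touches well under 1% of draws and measurably does not move the
recovered eigenstructure; all other clamping is off because truncation
perturbs correlations.

What the generator does not emulate: discrete/item-level instrument
structure, floor and ceiling effects, skewness, age/sex covariance, and
site effects.  Passing tests therefore demonstrate correctness of the
*method* under its own Gaussian assumption, not robustness of the score to
real-data departures from normality.

## Stability analysis

Structure stability is quantified by refitting on random subsamples
(without replacement) at fractions 0.3–0.8 of the cohort, 20 replicates
per fraction by default, with the full model's k forced so columns stay
comparable.  Agreement per component is Tucker's congruence coefficient
(cosine of the loading vectors) after sign alignment; ≥ 0.95 is reported
as stable, following common factor-analysis practice.  Eigenvalue
deviations are recorded as relative differences.  Sampling is driven by a
mandatory seed through per-fraction spawned generators, so reports are
bit-identical across runs and invariant to which other fractions were
requested.

## Problem sizes and defaults

The shipped configuration is nine variables, three components, reference
n = 2744 (the published reference cohort's size), which is also the size
used by the test suite and the acceptance script.  Recovery checks in the
tests use up to n = 100 000 draws where a tight sample-correlation bound
is asserted.  Longitudinal comparison is simple differencing of scores and
coordinates between consecutive timepoints (later − earlier), with octant
transitions reported; no growth modeling is attempted.

## Known limitations

- Projection of the published case-study subjects from their *raw* scores
  is not reproducible because the reference means/SDs are unpublished;
  the pipeline is pinned from the printed PC coordinates onward instead
  (the `--pc-input` scoring mode exists for exactly this situation).
- The relevance pattern (|loading| > 0.5) has borderline cells (−0.52,
  −0.48) within one or two sampling standard errors of the threshold at
  n = 2744, so an individual synthetic fit can flip a cell; the pattern
  check is therefore a typical-seed property, not a guarantee.
- The MGFS is a rank statistic relative to a specific reference cohort;
  scores computed against different reference fits are not comparable.
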