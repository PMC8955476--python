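# Methods

## Model

The core model is ordinary least squares on a small descriptor subset:
`y = β₀ + Σⱼ βⱼ xⱼ + ε`, with y the pIC50 (−log10 molar IC50) and xⱼ 2D
molecular descriptors consumed as given. The design matrix is always
intercept-augmented; the solve uses the SVD (`numpy.linalg.lstsq`), which is
stable on near-collinear designs. An exactly rank-deficient design raises an
error that names the collinear columns (identified by pivoted QR) rather
than returning a pseudoinverse solution, because a QSAR equation with
aliased descriptors is uninterpretable.

Assumptions inherited from OLS: linear response, homoscedastic Gaussian
noise, descriptors measured without error. Typical QSAR training sets are
tiny (n ≈ 20–30, p ≤ 4), which is why the validation battery below — not
the training R² — carries the evidential weight.

## Statistics conventions

All conventions follow common chemometric (QSARINS-style) reporting and were
checked for internal consistency against the packaged reference values:

- `RMSE = sqrt(RSS/n)` (population denominator), `s = sqrt(RSS/(n−p−1))`
  (degrees-of-freedom denominator). Both are reported; they differ and both
  appear in reference outputs.
- `R²adj = 1 − (1−R²)(n−1)/(n−p−1)`; `F = (R²/p)/((1−R²)/(n−p−1))`.
- Lin's CCC uses population moments throughout:
  `CCC = 2·Sxy / (Sxx + Syy + n(x̄−ȳ)²)`.
- Friedman's lack-of-fit is `LOF = (RSS/n) / (1 − (c + d·p)/n)²` with
  smoothness `d = 1.0` and basis-term count `c = p` by default; both are
  configurable. With these defaults the packaged reference statistics are
  matched at print precision.
- Q²LOO uses the deleted-residual shortcut `eᵢ/(1−hᵢᵢ)` with the hat diagonal
  from the thin QR of the design; an explicit-refit path exists and the test
  suite asserts both agree to 1e-10.
- Q²LMO removes `round(0.30·n)` compounds per iteration (default 2000
  iterations) and scores each left-out block against the retained-set mean;
  the reported Q²LMO is the mean of per-iteration values, which are retained
  for scatter plots.
- Y-scrambling permutes the response uniformly and independently each
  iteration (sampling with replacement across iterations, not exhaustive
  enumeration), refits, and records R² and Q²LOO. Under the null the
  expected scrambled R² is `p/(n−1)`; the observed mean is reported with
  per-iteration values retained. Kxy — the eigenvalue-spread index
  `Σ|λᵢ/Σλ − 1/m| / (2(m−1)/m)` of the correlation matrix of descriptors
  plus response — accompanies the scramble report (NaN for intercept-only
  models, where it is undefined).
- External metrics: `Q²F1 = 1 − PRESS/Σ(y−ȳ_train)²`,
  `Q²F2 = 1 − PRESS/Σ(y−ȳ_test)²`,
  `Q²F3 = 1 − (PRESS/n_test)/(TSS_train/n_train)`; `R²ext` is the squared
  Pearson correlation of observed vs predicted on the test set. A
  single-compound test set leaves Q²F2 undefined (reported NaN); the others
  are still computed.

## Applicability domain

Leverage is `hᵢ = xᵢ(XᵀX)⁻¹xᵢᵀ` with the intercept column included in X —
the warning threshold `h* = 3(p+1)/n` counts p+1 parameters, so the
intercept belongs in the quadratic form. The implementation uses the
Cholesky factor of XᵀX rather than an explicit inverse. Standardized
residuals divide training residuals by the training RMSE and
prediction-set errors by the external RMSE, matching the separate error
scales reported for the two sets; the 3σ rule flags response outliers
against whichever scale applies. Iterative outlier pruning removes response
outliers before structural outliers within a round (largest first, a
deterministic order), refits, and repeats up to `max_rounds`; it refuses to
shrink the training set below p + 3 compounds, logging a warning entry
instead.

## Descriptor selection

The genetic algorithm evolves binary inclusion masks over the pool with a
subset-size cap enforced by random repair (random drop while above the cap;
penalty terms are avoided so fitness values stay comparable across
candidates). Parent selection is fitness-proportional (roulette, after
shifting scores so the worst finite member has weight ≈ 0), crossover is
single-point with probability 1.0, mutation flips one random bit with
per-chromosome probability 0.1, and the top 10 candidates are carried over
unchanged (elitism), which guarantees the final best is never worse than
the best initial member. Defaults: population 200, up to 2000 generations
with early stop after 200 generations without improvement (disable by
setting `early_stop_generations=None`). All randomness flows from a single
seed. Fitness is min-LOF by default, max-Q²LOO as an alternative;
evaluations are memoised per subset, which changes runtime only. Descriptors
enter unscaled — OLS subset selection is invariant to affine descriptor
rescaling only in fit, not in the descriptor values reported, and reference
practice uses raw descriptors.

`exhaustive_select` enumerates every subset up to the size cap (refusing
beyond a configurable count cap) and serves as the exact optimum the GA is
tested against: on 12-descriptor pools with 3 informative descriptors and
signal-to-noise ≥ 5 the GA attains the exhaustive optimum in ≥ 95% of
seeded runs.

## Data handling

Tables are delimited text (comma default, tab accepted) with a header row;
empty cells and `NA` parse as missing values, any other non-numeric cell is
an error naming row and column. Missing values are tolerated at load and
removed by the descriptor filter; fitting a model on a column containing
NaN is an error. The packaged dataset table reproduces its source exactly,
including the block that reprints all 26 rows a second time; the loader
collapses rows identical in all descriptors and activity when
`dedupe=True` (the default for the packaged loader). Unicode minus signs in
typeset tables are normalised to ASCII on parse.

The descriptor pre-filter applies, in order: all-zero removal, missing-value
removal, near-constant removal (modal value frequency above 0.5), then
greedy pairwise decorrelation at |r| > 0.85, always removing from the
currently most-correlated pair the member less correlated with the
activity (the earlier column wins ties; without an activity the later
column is dropped). Processing the most-correlated pair first makes the
filter deterministic and idempotent.

Splitting: a random split draws `round(n/(ratio+1))` test compounds from
the seed; an activity-ranked split assigns every (ratio+1)-th compound of
the activity-sorted order to the test set, giving a test set that spans the
activity range. Published membership lists can be supplied explicitly and
override both, since literature splits rarely follow a mechanical rule —
the packaged reference study's own 20/6 and 18/10 splits are not literal
5:1 rounds, and their exact memberships are unpublished.

## Synthetic data

The generator draws descriptors from a multivariate Gaussian with
independent, exchangeable(ρ) or AR(1)(ρ) correlation and builds the
activity as `β₀ + Xβ + N(0, σ²)`, returning the generating truth alongside
the dataset. Gaussian descriptors are an idealisation — real 2D descriptors
are bounded and often skewed — so passing tests demonstrate correctness of
the estimators and the selection machinery, not robustness to descriptor
pathologies. Decoy descriptors are permutations of existing columns
(preserving marginals, breaking any activity link) alternated with fresh
noise columns.

The "reference regime" preset uses n = 26, p = 4 informative descriptors
with β = (0.5, −0.4, 0.3, 0.2) on unit-variance descriptors and σ chosen so
the population R² is 0.99, mirroring the fit quality of the packaged
reference series. Under this regime the median coefficient relative error
over 100 seeded replicates is below 5% and Q²LOO exceeds 0.95 in ≥ 90% of
replicates.

## Problem sizes and determinism

Every stochastic routine (LMO, scrambling, GA, generator, random splits)
is a pure function of an explicit integer seed; reports retain their
per-iteration values and are bit-reproducible. The test suite runs the
scrambling null at 2000 iterations, the GA-vs-exhaustive comparison over 20
seeds on 12-descriptor pools, and the recovery study over 100 seeds at
n = 26 — sizes chosen to keep Monte-Carlo error well inside the asserted
tolerances while completing in well under a minute.

## Known limitations

- No regularised or weighted regression; rank-deficient subsets are
  rejected, not shrunk.
- The applicability domain is leverage-only; no distance-to-model or
  density variants.
- GA hyperparameters beyond those listed (crossover probability, early-stop
  window) have no published reference values; the defaults are package
  choices and are configurable.
- The packaged reference equations carry coefficients printed to four
  decimals, so reproduction of their outputs is meaningful only to about
  1e-3 in pIC50.
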