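# Methods

## Scope and design

`epimapred` implements a gene-expression-modelling pipeline whose heavy
steps — aggregating ChIP-seq reads into gene-level scores, and the
`XᵀX` / `XᵀY` products of least-squares fitting — are written as
mapper/reducer programs over key–value multisets and run by a small
in-process engine. The engine exists to make a verifiable claim: the
pipeline's output is *bit-identical* for any worker count, so the
parallel decomposition is a pure performance transformation.

### The engine

A program is an ordered sequence of rounds ⟨μ₁,ρ₁,…,μ_R,ρ_R⟩; the engine
runs exactly R rounds (mapper phase, grouping, reducer phase) on the
input multiset. Three choices buy determinism:

- keys are partitioned with a stable CRC32 hash (never Python's
  randomised `hash`);
- each reducer's value list is sorted by a canonical total order over the
  primitive/tuple values the engine carries, fixing floating-point
  summation order;
- each phase's output multiset is canonically re-sorted before the next
  phase.

Backends are `serial` (partitions run sequentially in-process — the
default, and what the tests exercise heavily) and `process-pool`
(partitions fan out to a `ProcessPoolExecutor`; mappers/reducers must be
picklable, which the library's own mappers — partials over module-level
functions — are). There is no fault tolerance, spill-to-disk or
inter-machine transport; the engine demonstrates the decomposition, not a
cluster runtime.

## Scoring model

Raw score: `x_{m,n} = Σ_{|d(r,m)| ≤ d*} w(r)·φ(r,m)` with the window
predicate inclusive at both ends. Parameters:

- `d_star` (bp, default 2000): window half-width, approximating the
  typical width of ChIP-seq binding regions.
- `d0` (bp, default 5000): decay constant of the transcription-factor
  kernel `exp(−|d|/d₀)`. The exponent uses |d|: a signed exponent would
  *amplify* upstream reads, contradicting a decaying affinity, so decay
  is symmetric about the TSS.
- kind `histone` uses φ = 1 exactly (sum of tags), keeping scores
  integral when read weights are integral — this is why the MapReduce
  path can be tested for *exact* equality against an oracle in histone
  mode, and to 1e-9 relative in tf mode (different summation orders).

Distances are strand-aware (downstream positive); strand affects only
the sign, never which reads qualify. A read within `d*` of several TSSs
contributes fully to each such gene — the per-gene sums are independent.
The TSS index is a sorted per-chromosome array with binary search
(O(log M) per lookup); a balanced tree would give the same contract with
more code. Reads on chromosomes absent from the annotation are dropped
with one log line per chromosome.

WIG semantics: a `variableStep`/`fixedStep` record with value *v* is read
as *v* read-equivalents at the record's start; span does not multiply
weight (pre-expand spans upstream for per-base semantics). bedGraph and
bigWig are out of scope.

### Transforms

Feature columns are `ln(x + 1)`-transformed by default (pseudocount 1
preserves zeros; `arsinh` is the alternative and takes no pseudocount),
then quantile-normalised to the mean order-statistic reference across
feature columns; ties receive the mean of their tied reference values,
which preserves within-column rank order. When tie patterns differ
between columns, the post-normalisation sorted multisets can differ
slightly — the identical-multiset invariant holds exactly on tie-free
data. The bias column is never transformed or normalised. Whether
normalisation should run across features or across cell-line samples is
a genuinely open choice; across features is the default because the
matrix being prepared is a single cell line's design matrix. The
response Y is the user's choice of transform (it is not part of the X
pipeline).

## Regression

OLS solves the normal equations with `A = MRMultiply(Xᵀ, X)` and
`B = MRMultiply(Xᵀ, Y)` through the engine, then an N×N solve on one
node — a stable symmetric solve, not an explicit inverse, with a
condition-number guard (cond > 1e12 raises and advises regularisation).
`MRMultiply` is two rounds: round one joins A-row and B-column entries on
the shared inner index and emits partial products keyed by (i,k); round
two sums them.

Ridge uses the penalty matrix `D = I_N` by default, penalising *every*
coefficient including the bias — the strict reading of the ‖β‖² penalty —
with `penalize_bias=False` zeroing the bias entry for the statistical
convention. The augmented-data route (stack `√λ·D` under X, zeros under
Y, fit OLS) is implemented separately and kept as the independent
verification path for the identity
`(X̃ᵀX̃)⁻¹X̃ᵀỸ = (XᵀX + λI)⁻¹XᵀY`; the closed form is the production
path.

λ selection: 10-fold CV over a grid (default 50 log-spaced points in
[1e−4, 1e4] — the rule is stated as solved iteratively, with no solver
given, so grid search realises it), folds formed by a seeded permutation
of genes into near-equal blocks, per-fold loss = mean squared prediction
error. The selected λ is the *largest* grid value whose mean CV error is
≤ min + 1·SE, where SE is the standard error of the k fold errors at the
minimising λ. Per fold, the training Gram products are computed once
(they do not depend on λ) and every grid value is solved against them.

Adjusted R² uses the standard Wherry form
`1 − (1 − R²)(M−1)/(M−p−1)` with `R² = 1 − SSE/SST` (not squared
correlation); *p* counts predictors excluding the bias column. Zero
variance in Y is an error, not a NaN.

## Cross-cell-line analysis

`cross_cell_line_eval` aligns all datasets to the sorted intersection of
their gene ids (computed once), tunes λ within each training cell line
only (test data never informs the model), and records adjusted R² for
every directed (train, test) pair — K² entries, 64 for eight cell lines.
Diagonal dominance is *not* assumed; the interesting structure is
column-wise similarity (a test cell line is predicted about equally well
by any training cell line when the regulatory relationship is shared).

Residual clustering: ε = Y − Ŷ per cell line, columns clustered
agglomeratively with 1 − Pearson correlation distance and average
linkage (both exposed; unstated upstream, these are the standard choices
for expression-residual profiles). Constant residual columns are an
error under the correlation metric. Dendrograms serialise to Newick with
branch lengths from merge-height differences.

## Synthetic data — what it emulates, and what a green test means

The generator states one world: TSSs uniform per chromosome (default
chromosome length 10·d*·genes-per-chromosome, so windows are mostly but
not always isolated — occasional multi-gene windows are a feature),
strands Bernoulli(1/2); per gene/feature a Poisson(target) number of
reads at offsets uniform in [−d*, d*] (uniform offsets make the expected
raw histone score exactly the Poisson mean — a closed-form oracle; a
triangular-peak option exists for realism), plus Poisson background at
1e−6 reads/bp; per-gene targets Gamma(shape 2) with mean
`reads_per_gene = 50`. Expression is `Y = Xβ + N(0, σ²)` generated from
the *processed* matrix (transformed, quantile-normalised, bias column),
so the linear model is exactly true in simulation. `sigma_for_target_r2`
picks σ for a chosen population R²; 0.6 reproduces the operating regime
a real histone-modification model achieves genome-wide. Defaults (1000
genes, 6 features — matching the six promoter-localised histone marks of
the reference design) are fixed once.

A green test therefore establishes that the implementation computes its
stated quantities correctly and deterministically — not that real
ChIP-seq (peak-shaped, GC-biased, mappability-censored reads; non-linear
saturation of expression; batch effects) satisfies the model.

## Numerical choices and limitations

- Histone-mode score equality is exact (integer weights, order-fixed
  sums); tf-mode and matrix products are checked at 1e-9/1e-8 relative.
- Duplicate λ grid values are harmless (max over equals is
  deterministic); fold seed defaults to 0 and is recorded in the fit.
- The engine materialises every phase in memory; it targets desk-scale
  inputs (≈10⁵–10⁶ pairs), not consortium-scale sharded data.
- Lasso/elastic-net are out of scope (no closed-form mapper/reducer
  decomposition); so are peak calling, BAM parsing and enhancer (non-
  promoter) assignment.
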