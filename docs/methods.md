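# Methods

## The model

For one gene measured at `n` spatial pixels (single cells in image-based
assays), with `y_i` the raw count at pixel `i` and `N_i` the pixel's total
count across all measured genes:

    y_i ~ Poisson(N_i λ_i)
    log λ_i = α + x_i β + g_i + e_i
    g ~ MVN(0, σ² h² K)
    e ~ MVN(0, σ² (1 − h²) I)

`x_i` is the scRNA-seq expression of the gene in the cell type mapped to
pixel `i`; `β` measures how much the cell-type signal explains the spatial
pattern.  `g` is a spatially structured random effect with kernel `K`; `e`
is an independent per-pixel nugget capturing non-spatial overdispersion.
`h² ∈ [0, 1]` is the fraction of the random log-rate variance that is
spatial.  Counts are modelled directly — no normalisation of the spatial
data — with `N_i` entering as a Poisson offset.

Two kernel families are supported:

* **Gaussian**: `K_ij = exp(−‖s_i − s_j‖² / (2 l²))`, unit diagonal,
  bandwidth `l` in coordinate units.  The default sensitivity sweep uses
  `{0.5, 1, 2, 5, 10} ×` the median nearest-neighbour distance —
  data-adaptive scales bracketing typical spatial ranges.
* **CAR**: `K = (D − α_s W)⁻¹` from a conditional autoregressive prior on a
  neighbourhood graph.  `W` is binary adjacency, `D = diag(m_i)` the
  neighbour counts, and `α_s ∈ [0, 1)` controls spatial dependence
  (`α_s = 0`: independence; `α_s → 1`: the improper intrinsic
  autoregressive limit, rejected with an explicit error).  The default
  graph is k-nearest-neighbour with `k = 4`, union-symmetrised — a
  scale-free choice across heterogeneous pixel densities; a radius graph is
  available.  Isolated pixels get a unit CAR diagonal so the precision
  stays invertible.  The CAR `K` is deliberately *not* rescaled to a unit
  diagonal (the prior defines the covariance directly), so `h²` values are
  not directly comparable between the CAR and Gaussian families.

## Inference: PQL with average-information REML

The marginal likelihood integrates over `n` random effects and has no
closed form.  We use penalized quasi-likelihood: a second-order expansion
of the Poisson log-likelihood around the current linear predictor `η`
yields a working Gaussian response (pseudodata)

    ỹ_i = η_i + (y_i − μ_i) / μ_i,   μ_i = N_i exp(η_i),  weights w_i = μ_i,

which follows a linear mixed model with covariance
`V = σ²h²K + σ²(1−h²)I + diag(1/w)`.  Each outer iteration recomputes the
pseudodata, updates the variance components by average-information (AI)
REML, the fixed effects by generalized least squares, and the random
effects by BLUP:

    ĝ = σ̂²ĥ² K V⁻¹(ỹ − α̂ − xβ̂),   ê = σ̂²(1−ĥ²) V⁻¹(ỹ − α̂ − xβ̂).

`H0: β = 0` is tested by the Wald statistic `β̂/se(β̂)` from the final
working model against a standard normal.

Numerical choices:

* Variance components are carried as `θ = (σ²h², σ²(1−h²))`, both clipped
  at `1e-8`; this is the standard AI-REML parameterisation and reaches the
  `h² = 0/1` boundaries exactly (where the corresponding BLUP is exactly
  zero).  Reported `h²` snaps to the boundary below `1e-4` / above
  `1 − 1e-4`.
* AI steps use step-halving (max 12 halvings) so the working REML
  log-likelihood never decreases across accepted steps; a non-positive-
  definite `V` gets `1e-6` jitter once.
* Initialisation: `α₀ = log(mean(y/N))`, `β₀ = 0`, `σ²₀ = 1`, `h²₀ = 0.5` —
  a neutral start.  Convergence: relative change of `(α, β, σ², h²)` below
  `1e-5`, at most 100 outer iterations; a non-converged fit returns the
  last iterate flagged `converged=False`.
* `η` is clipped at ±30 (with a warning) to keep `μ` finite.  Zero-count
  pixels are handled exactly (`ỹ = η − 1`); only pixels with `N_i = 0` are
  dropped, upstream.
* `K = I` makes the likelihood flat in `h²` (the two components coincide);
  this is flagged with a warning rather than an error.
* A constant covariate (collinear with the intercept) and an all-zero
  count vector are rejected as unidentifiable.

PQL is an approximation: with small counts it is known to attenuate
estimates.  The tests quantify rather than hide this — the fit agrees with
a plain Poisson GLM to `1e-3` relative when the random effects vanish and
the offsets are large, and with a directly optimised Laplace-approximate
MLE within 15% on `β` at `n = 25`.

## Mapping between modalities

* **Centers.** Each cell type's center is its average expression profile.
  By default counts are depth-normalised to counts-per-10k and
  log1p-transformed before averaging, because the covariate enters a
  log-scale linear predictor; a raw-mean option is retained.
* **Assignment.** Each pixel is assigned the center most
  Pearson-correlated with its shared-gene profile (transformed the same
  way).  Ties break to the lexicographically first type; a constant pixel
  profile gets the globally most common type with a warning.
* **Reference set.** Every shared gene is fitted; genes with `p < 0.05`
  (raw p-values by default, Benjamini-Hochberg optional) form the
  reference set.  *Leak-free covariates:* each fitted gene's covariate
  comes from a pixel assignment computed with that gene excluded from the
  correlation profile.  With the gene's own counts inside the assignment,
  its covariate is tilted toward its own noise and the null rejection rate
  at 0.05 inflates measurably (0.17 at 200 genes × 150 pixels in our
  calibration runs, vs ≈0.06 leave-one-out); at the ~1,000-gene scale of
  real panels the feedback is negligible, but the leave-one-out form is
  correct at any scale.
* **Prediction.** A target gene (present in scRNA-seq, absent from the
  spatial panel) borrows the fit of the reference gene most
  Pearson-correlated with it across cells, on the same transform as the
  centers (flaggable).  Its rate is
  `λ̂_i = exp(α̂ + x_i^(un) β̂ + ĝ_i + ê_i)` with `x^(un)` the assigned
  center's expression of the target; predicted counts are `N_i λ̂_i`.  The
  reference's fitted `ĝ` and `ê` are reused exactly as written — no fresh
  nugget is drawn in the default deterministic "mean" mode, which keeps
  cross-validation reproducible; "sample" mode additionally draws
  `Poisson(N_i λ̂_i)` under an explicit seed.

## Validation machinery

Leave-n-genes-out CV holds out a seeded random subset of the shared genes,
fits the reference set on the remainder only — the training subset even
recomputes its size factors from training genes alone, so held-out counts
cannot reach the fitting path through the offset (a canary test verifies
the reference set is bit-identical after corrupting a held-out gene) — and
scores each held-out gene by the Pearson correlation between observed and
predicted counts (a log1p option exists; counts are the default because
the evaluation target is the measured expression itself).  In a full
application, `N_i` is simply the total over all measured genes.

The downsampling experiment fixes one test split and refits on nested
seeded prefixes of a permuted training pool; because each gene's fit
depends only on that gene (given the pool), fits are cached and the set of
significant candidates grows monotonically with the pool, which makes the
mean correlation between test genes and their chosen references provably
non-decreasing in the training size.  The kernel sweep reruns one split
under each configuration (CAR `α_s` 0.1–0.9, Gaussian bandwidth sweep),
recording failures per configuration without aborting.  An externally
supplied spatially-expressed gene list can stratify CV reporting; no
spatial-expression test is reimplemented here.

## Synthetic data

The generator draws from exactly the generative chain above, so every
estimate can be checked against known truth.  Paired data add the
integration structure: per-type center profiles on the log scale; scRNA-seq
counts Poisson around the cell's type center with log-normal cell depths;
pixels assigned contiguous true types (Voronoi regions of seeded anchors);
spatial counts per gene via the single-gene chain with `x` the
(pixel-centred) true-center expression.

Study conditions (defaults): 400 pixels on a 20×20 grid, offsets
`N_i ~ LogNormal(log 500, 0.3)`, 100 genes, 500 cells, 5 types — the order
of magnitude of image-based panels while staying fast on one CPU.  Half
the genes are null (`β = 0`, spatially flat, `h² = 0`); the other half are
signal genes (`β = 1`, `σ² = 1`, `h² = 0.8`) organised in co-expression
groups of 4 sharing one standardised spatial field realisation, each gene
keeping its own independent nugget (the model treats `e` as per-gene
sequencing error; sharing it between genes would make even spatially flat
genes predictable from their neighbours, which real sequencing noise is
not).  Groups of 4 keep a co-member in the training pool with probability
>0.99 under leave-20-of-100-out.  Each group's between-type effect vector
is standardised to spread exactly `center_sd`: with a raw Gaussian draw
over only 5 types a group's profile occasionally collapses, leaving the
planted co-expressed genes uncorrelated in scRNA-seq space and hence
useless as each other's references, which would defeat the purpose of
planting them.  A literal duplicated scRNA-seq column can be planted for
reference-selection identity tests.

What the generator does *not* emulate: platform noise (optical crowding,
segmentation error), cell-type mixtures within a pixel, batch effects
between the modalities, or mismatched gene nomenclature.  Passing tests
therefore demonstrate correctness of the model, the inference and the
integration machinery under the model's own assumptions — not robustness
to the ways real assays violate them.

## Problem sizes used in tests and the acceptance script

Single-gene checks run at `n = 200–400` pixels; calibration uses 1,000
null replicates at `n = 200` (500 in the acceptance script); parameter
recovery 50 replicates at `n = 400`; the end-to-end CV 100 genes × 400
pixels with 20 held out.  These sizes give Monte-Carlo error comfortably
inside the asserted bands while keeping a full run in minutes on a single
CPU.

## Known limitations

* PQL attenuates variance components for sparse counts; `ĥ²` is noisy at
  a few hundred pixels and its scale depends on the kernel normalisation.
* Exactly one covariate (the mapped cell-type expression) plus an
  intercept; no negative-binomial observation model; no multi-reference
  ensembles; no estimation of `α_s` (it is fixed per run and swept).
* Cell-type labels are required input; no clustering is performed.
* Gene matching is exact (whitespace-trimmed, case-sensitive); no
  ortholog/alias resolution.
* The MERFISH-style rescale-to-counts helper exposes the per-pixel volume
  divisor and the order of operations explicitly, because the published
  preprocessing does not pin the order down; the caller must choose.
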