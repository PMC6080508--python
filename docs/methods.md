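# Methods

## Model and procedure

The unit of analysis is the homoeolog pair: replicate FPKM vectors for
the two diploid parents (A_r, C_o) and the two copies in the
allopolyploid (A_n, C_n), linked by an orthologous pair map. All
pair-level classifications are built from one primitive, a two-sided
two-sample Student's (pooled-variance) *t*-test mapped to a ternary
outcome: EQ when p > alpha, otherwise GT/LT by the sign of the mean
difference. Welch's form is available behind a flag but the pooled form
is the default, matching the convention of the classification framework
this package implements. The bias and dominance tests run on raw FPKM
replicate values; the DEG test runs on log2(FPKM + 1) replicates as a
variance-stabilized alternative, since subgenome-versus-parent calling
spans a much wider dynamic range (a log-scale flag exists for the pair
tests too).

Dominance classification uses only the two pair-total comparisons
(S vs A_r, S vs C_o); the parental comparison A_r vs C_o is recorded
and used solely to orient the transgressive subclasses and to set a
consistency flag on categories whose geometry implies a parental
relation (e.g. category IV implies A_r > C_o). Pairs equal to both
parents are assigned NoChange regardless of the parental test; the
consistency flag preserves the information. No multiple-testing
correction is applied across pairs for the bias/ELD tests (a raw
P <= 0.05 is the framework's convention); BH-FDR is applied per
comparison for DEG calling and across terms for enrichment.

Mechanism labels for ELD pairs are mutually exclusive per pair:
dominant_down, nondominant_up, their joint occurrence
(dominant_down_nondominant_up), nondominant_down, both_down, none,
other. The joint label exists because, at exact means, a pair total
pinned to one parent cannot rise through the nondominant copy alone —
the published mechanism sums correspondingly count the joint cell under
both mechanisms, and `summarize` reproduces that overlapping convention
while the per-pair label stays unambiguous.

## Tunable parameters

| parameter | default | units | notes |
|---|---|---|---|
| alpha (bias/ELD/explain tests) | 0.05 | probability | EQ iff p > alpha |
| expression cutoff | 1 | FPKM | replicate mean; pair-level uses the per-replicate total A_n + C_n |
| DEG FDR cutoff | 0.05 | q-value | BH per subgenome comparison |
| DEG fold-change cutoff | 1 | log2 units | on pseudocounted means |
| pseudocount | 1 | FPKM | log2FC and log-scale testing |
| enrichment FDR cutoff | 0.001 | q-value | one-sided hypergeometric |
| coverage window | 10,000 | bp | tiling, final partial window kept |
| low-ratio threshold | 0.25 | ratio | flags under-covered windows |

## Synthetic data

The simulator draws each pair from a named template — exact means
(A_r, C_o, A_n, C_n) on a unit scale whose truth labels are computed by
the exact-mean classifier, never stored independently — scales it by a
base mean drawn log-uniform from [2, 500] FPKM, and multiplies each
replicate by lognormal noise exp(N(0, sigma^2)) with
sigma = sqrt(log(1 + cv^2)), so the replicate CV equals the requested cv
and values stay non-negative. Defaults: 3 replicates, cv = 0.2, 4-fold
template effects. The default template mixture mirrors the category
composition observed in a resynthesized *B. napus* leaf transcriptome
(~46% no change, ~39% ELD with more ELD-A than ELD-C and more
higher-parent than lower-parent dominance, ~5% additivity, ~9%
transgressive and nearly all of it upward), plus small weights for
bias-transition exemplars and a below-cutoff template that exercises
the expression filter. cv = 0.2 is a convention for well-replicated
RNA-seq of clonal material, not a measured value.

What the generator does **not** emulate: count-level overdispersion
(negative binomial), mapping bias between subgenomes, correlated
replicates, gene-length effects, or homoeolog read misassignment.
Passing tests therefore demonstrate the correctness of the decision
logic and its statistical calibration under a clean noise model, not
robustness to those real-data artifacts.

Depth tracks are per-base Poisson draws at a per-chromosome mean; a
mean of zero emits an all-zero chromosome, the signature the coverage
module is designed to flag.

## Numerical choices

* Degenerate variance (all replicates identical in both samples): p = 1
  and EQ when the constants agree, p = 0 and a directional outcome when
  they differ. "Agree" is a relative comparison at 1e-9, because
  template means are assembled by float arithmetic (3m + m need not be
  bit-identical to 4m); the exact-mean oracle uses the same comparison,
  which is what makes noise-free pipeline output equal the oracle for
  100% of pairs. Template effect gaps are >= 25%, far above the
  tolerance.
* Percentages are computed from integer counts with decimal arithmetic
  and half-to-even rounding at one decimal, reproducing printed figure
  captions exactly.
* BH q-values come from the standard step-up implementation
  (statsmodels); the hypergeometric tail is P(X >= k) via the survival
  function; both are cross-checked against brute-force oracles in the
  test suite.
* Window tiling is 0-based half-open internally; the 1-based
  samtools-depth input is converted at the boundary; the final partial
  window is averaged over its actual width; bases absent from a track
  count as depth zero.
* Ties in enrichment output are broken by (q, p, term id) with a stable
  sort.

## Design decisions taken where the design was open

* "Expressed" is defined on the replicate mean (not every replicate),
  the common FPKM convention; pair-level expression in the polyploid
  uses the per-replicate homoeolog sum so the criterion matches the
  quantity the dominance test uses.
* The DEG caller substitutes the declared t-test machinery for a
  model-based caller; this is recorded in the run manifest and means
  published DEG totals from model-based workflows are not expected to
  be reproduced numerically.
* The simulator's "nondominant up" ELD variant pairs the rise of the
  nondominant copy with a fall of the dominant one (see mechanism
  discussion above); a pure nondominant-up state exists only
  statistically, not at exact means.
* Bias transitions are reported four-way (maintained / novel /
  reverted / switched); three-way summaries fold switched into novel so
  the three classes partition the total.

## Problem sizes and expected metrics

The acceptance script and test suite use: 5,000 pairs (noise-free
oracle agreement, expected 100%), 10,000 pairs at defaults (category
recovery, expected >= 90% with confusion concentrated on single-test
boundaries), 10 x 5,000 null pairs (bias type-I, expected within 3
binomial SDs of 5%), 10 x 1,000 x 2 subgenomes (DEG null, expected ~0),
and 100-kb Poisson tracks at 60x/30x (window-ratio mean, expected 2.0).

## Known limitations

* Category recovery at the default noise level sits near its
  theoretical ceiling: classes defined by equalities (NoChange, ELD,
  additivity) are capped by the t-test's own type-I rate — with two
  EQ decisions at alpha = 0.05, no noise level can push recovery of
  such classes above ~0.95 per test, so overall recovery plateaus
  around 90-95% regardless of cv.
* The pooled t-test with n = 3 lognormal replicates is slightly
  conservative (empirical size ~0.047 at nominal 0.05).
* Enrichment takes annotations as given (no ontology-graph propagation
  or semantic redundancy reduction; a term blacklist hook is provided).
* The coverage module detects loss, not amplification structure; it is
  an integrity check, not a CNV caller.
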