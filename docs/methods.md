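# Methods

## Scope and data model

`phosnet` analyses DGGE fingerprint tables: a samples × bands matrix of
nonnegative intensities in which each band stands in for a bacterial or
fungal taxon.  Three containers carry the data — `BandMatrix` (intensities
plus a band → kingdom map), `SampleTable` (phosphate source with its %P₂O₅,
inoculum, replicate) and `PhenotypeTable` (total dry matter in g/pot,
mycorrhizal colonization as % of root cortex).  Validation is structural:
nonnegative finite intensities, one kingdom label per band, source-consistent
%P₂O₅ (Control 0, CA 2.93, BA 14, SS 18), and colonization forced to zero
without inoculum (mycorrhiza cannot colonize uninoculated pots, so a nonzero
value there is treated as a transcription error).

## Band filtering

Bands present (intensity > 0) in fewer than 25% of samples are dropped; the
boundary is inclusive (2 of 8 samples is kept).  The filter runs once over
all samples, so every per-group network shares a single total node panel —
this is what makes "interacting nodes" (degree ≥ 1) meaningful against the
fixed panel.

## Community structure

Bray–Curtis dissimilarity is computed after rescaling each lane to unit
total signal by default (gel lanes differ in total brightness; a flag
disables it).  PCoA is classical scaling of the Gower-centered −d²/2
matrix: the full eigenvalue spectrum is reported, negative eigenvalues
included, but only positive-eigenvalue axes carry coordinates; proportions
explained are relative to the positive spectrum.  UPGMA is implemented
directly so that merge ties deterministically resolve toward the
lowest-index pair; cophenetic distances and Newick export are provided.

PERMANOVA follows the trace-partition formulation: with hat matrices of the
nested model matrices (intercept; + source; + inoculum), each term's sum of
squares is the trace increment against the Gower-centered matrix, and
pseudo-F compares the term mean square with the residual mean square.
Terms are sequential (Type I) in the stated order; the default design is
balanced, so order does not matter there.  Projectors use the
pseudoinverse, which is robust to the rank deficiency of full dummy
codings.  p-values come from free permutation of sample labels with the
add-one estimator p = (1 + #{F* ≥ F})/(1 + n_perm), so p is never 0; when
the number of distinct label arrangements is ≤ 10,000 the test switches to
exhaustive enumeration (identity included, exact p).  Note a structural
floor of exhaustive two-group p: the mirror assignment induces the same
partition and hence the same F, so the smallest attainable p is 2/N.
F comparisons use a relative tolerance (1e−9·|F|) so that arrangements
whose F equals the observed one up to floating error are counted as ties.

## Phenotype statistics

Dry matter is analysed as a source × inoculum factorial with interaction
(sequential SS when balanced, Type II otherwise; an empty cell is an
error).  Zero-variance layouts report F = 0, p = 1 rather than 0/0.  Tukey
HSD runs on the pooled one-way mean square error with Tukey–Kramer
standard errors and the studentized range distribution; a compact letter
display is exported.  Shapiro–Wilk normality is reported, never enforced.
Simple trends (colonization vs %P₂O₅) use OLS with slope p from t(n−2) and
RSE = √(SSres/(n−2)).

## Network inference

For every unordered pair of filtered bands, Pearson r (raw intensities, or
presence/absence under `binarize`) and Spearman ρ (midranks, ties averaged)
are computed with two-sided p from the t transform with n−2 df.  At n ≤ 10
samples the t approximation is poor — measured deviations from the exact
permutation p reach ≈0.03 (Spearman) and ≈0.10 (Pearson, skewed data) — so
both p-values are replaced by a permutation null over orderings of one band:
all n! orderings up to n = 8, a seeded 50,000-permutation subsample
(identity included) beyond.  The two-sided criterion is |r*| ≥ |r|.
Constant bands yield invalid pairs, excluded from edge calling without
error.

Edges require both tests significant at α (default 0.05, uncorrected — the
protocol this mirrors used raw p < 0.05) *and* sign agreement; the shared
sign is the edge sign.  Sign agreement is the only rule that leaves every
edge unambiguously signed; `edge_rule="either"` is available for
sensitivity analysis, and an optional Benjamini–Hochberg mode adjusts each
p-value family across pairs before thresholding.  All filtered bands stay
in the graph as nodes, interacting or not.

Community detection is spinglass (igraph), which requires connectivity and
therefore runs per connected component with the seeded generator;
components of fewer than 3 nodes become single communities, and isolated
nodes stay outside the partition.  Modularity of the final partition is
Newman–Girvan on the interacting subgraph.

The topology report emits both average-degree conventions (2E/N and E/N
over interacting nodes) and both density conventions (E/(N(N−1)) over the
total panel and over interacting nodes — both with ordered-pair
denominators, which is how published tables of this kind are arithmetically
consistent).  Clustering and average path length are taken over the largest
connected component; the diameter is the maximum finite shortest path.

## Response surface

Four candidate forms: a·e^{bx}, a·e^{bx}+c, a·x·e^{bx}, a·x·e^{bx}+c.
The monotone forms cannot place a maximum inside the dose range, so the
peaked variants are required for an interior optimum; the offset variants
exist because dry matter is bounded away from zero at x = 0 (an unfertilized
pot still grows), which the pure peaked form cannot represent.  Fits are
Levenberg–Marquardt least squares (scipy) initialized from a log-linear
regression, with a grid search over the rate as fallback when the log
transform is unavailable; non-convergence returns a failed-fit result
carrying diagnostics rather than raising.  Reported statistics: R² (clamped
at 0; defined 0 for constant data), RSE = √(SSres/(n−k)), an F test against
the constant model, and linearized (Wald) confidence intervals from the
curve_fit covariance — at the mild curvature of these forms their measured
joint coverage matches the nominal level, so profile likelihood was not
needed.  Among candidates the minimum-RSE fit wins; ties go to the
fewer-parameter form.

The surface evaluates the dry-matter fit and the bacteria–fungi edge-count
fit on a shared [0, x_max] grid (default step 0.01 %P₂O₅), fits an
RSE-selected exponential trend of predicted dry matter against predicted
edge count, and takes the grid argmax of dry matter (ties resolve to the
smallest dose).  Dry-matter fits use replicate-level points, not treatment
means.

## Synthetic generator

`generate_study` draws, per planted edge, one standard-normal factor per
sample; the edge's two bands load ±√strength on it, so the noise-free
latent correlation equals the planted strength with the planted sign.
Idiosyncratic noise (`noise_sd`) attenuates that correlation; per-(band,
source) offsets (`source_effect_sd`, default 1.0) plant the community shift
that PERMANOVA and PCoA detect; the latent score is scaled
(`latent_scale`), exponentiated to lognormal intensities and masked by
Bernoulli dropout (`zero_inflation`, default 0.30), whose zeros exercise
the tied-rank path of Spearman.  Defaults mirror the emulated study's
printed dimensions: 32 samples, 90 + 67 = 157 bands, colonization starting
at 43% and declining at 1.5 %/unit-P₂O₅, dry matter following
c + a·x·e^{bx} with a peak near 11 %P₂O₅ and a control baseline of
6.5 g/pot.  The band-intensity distribution of real gels is unknown;
lognormal is this harness's assumption.

What the generator does *not* emulate: compositionality of lane
normalization, primer or gel-position bias, spatial band bleed, and
phylogenetic correlation among bands.  Passing recovery tests therefore
demonstrate correctness of the inference machinery under the stated
generative model, not performance on real gel data.

Three generator findings shape the recovery benchmark (24 bands, 10
disjoint planted edges of strength 0.8, n = 32, BH edge calling, 20 seeds):
the planted source shift acts as a confounder that both attenuates planted
correlations and creates spurious ones, random dropout destroys rank
correlation far faster than Gaussian noise, and exponentiation strongly
attenuates *negative* Pearson correlations (ρ = −0.99 on the log scale
becomes r ≈ −0.44 at lognormal σ ≈ 0.9).  The benchmark therefore isolates
the inference stage — no source shift, no dropout, latent_scale 0.5 —
and uses the BH mode: with ~280 candidate pairs and ~10 true edges, any
uncorrected α = 0.05 rule is bounded near 60% precision by its
false-positive arithmetic, so the raw-α protocol, while faithful to field
practice, cannot be the recovery yardstick.

## Problem sizes and determinism

Default test and acceptance runs use the full 32 × 157 study for the
pipeline stages, 20 seeds for recovery benchmarks, 100 seeds for coverage
and Monte-Carlo checks, and 500 null datasets (n = 20, 999 permutations)
for the PERMANOVA size check — sizes chosen so each suite completes in
minutes on one CPU while keeping Monte-Carlo error well inside the asserted
bands.  Every stochastic step (simulation, permutation tests, spinglass)
takes an explicit seed; identical seeds give bit-identical outputs,
including exported files.

## Known limitations

Dual-correlation edge calling inherits the biases of correlation networks
on compositional, zero-inflated data (no compositional correction such as
SparCC is attempted — deliberately, as the point is a faithful, testable
implementation of the dual-correlation protocol).  The exhaustive
PERMANOVA p has the 2/N floor noted above.  Spinglass is stochastic per
seed and per-component; different seeds may give different partitions with
slightly different modularity.  The composed surface carries no uncertainty
band beyond the per-fit intervals; its optimum is a prediction under the
selected curve family, not an agronomic recommendation.
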