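# phosnet

Soil microbial co-occurrence networks and phosphate dose–response surfaces
from DGGE band-profile data.

## The problem

How does the solubility of a phosphate fertilizer (%P₂O₅) reshape the
interaction structure of the soil bacterial and fungal communities around a
crop, and can those interactions point to the fertilizer solubility that
maximizes plant biomass?  `phosnet` implements the complete analysis chain
for a greenhouse design of this kind — 4 phosphate sources (an unfertilized
control at 0 %P₂O₅, a low-solubility rock phosphate at 2.93%, a reactive
rock phosphate at 14%, and simple superphosphate at 18%) × 2 mycorrhizal
inoculation levels × 4 replicates = 32 pots, each yielding a DGGE
(denaturing gradient gel electrophoresis) band profile in which every band
acts as an operational taxonomic proxy for a bacterial or fungal group.

The pipeline:

1. **Band filtering** — bands present in < 25% of samples are removed.
2. **Community structure** — Bray–Curtis distances
   (`d = 1 − 2Σmin(x,y)/(Σx+Σy)`), principal coordinates (classical
   scaling), UPGMA dendrograms, and a sequential two-factor PERMANOVA,
   `dist ~ source + inoculum`, with permutation p-values.
3. **Phenotype statistics** — two-factor ANOVA and Tukey HSD for total dry
   matter; ordinary least squares for the colonization-vs-%P₂O₅ decline.
4. **Network inference** (the core) — for every band pair, Spearman ρ and
   Pearson r across samples; an edge requires *both* two-sided p < α with
   agreeing sign, which becomes the edge sign.  Kingdom-partitioned edge
   counts (bacteria–bacteria, fungi–fungi, bacteria–fungi; positive /
   negative), spinglass community detection, Newman–Girvan modularity, and
   a full topology report (average degree, density, clustering, path
   length, diameter — each under both field conventions where published
   usage is inconsistent).
5. **Response surface** — exponential regressions
   (`a·e^{bx}`, `a·e^{bx}+c`, `a·x·e^{bx}`, `a·x·e^{bx}+c`) of dry matter
   and of bacteria–fungi edge counts against %P₂O₅, model selection by
   residual standard error (RSE = √(SSres/(n−k))), composition of the two
   fitted curves onto a shared %P₂O₅ grid, and the grid argmax — the
   predicted optimal fertilizer solubility.

Because studies of this kind rarely deposit raw gel images, the package
ships a first-class synthetic generator (`phosnet.generate_study`) that
emulates the full design: latent Gaussian factors plant signed band–band
correlations of chosen strength, intensities are lognormal with per-source
community shifts, dropout creates the zero-inflated, tie-heavy profiles
typical of gels, and phenotypes follow the published dose–response shapes
(colonization declining linearly from 43% with %P₂O₅; dry matter peaked at
an interior solubility).  Every planted truth is returned, so inference can
be benchmarked end to end.

## Worked example

```python
import phosnet as pn

matrix, samples, phenotypes, truth = pn.generate_study(seed=1)

# one co-occurrence network per phosphate source (α = 0.05, both tests)
networks = pn.infer_networks_by_group(matrix, samples, seed=3)
print(networks["BA"].summary())
```

```
Co-occurrence network [BA]
  nodes: 157 total, 153 interacting (57.5% bacteria, 42.5% fungi)
  edges: 292 (+176/-116, ratio 1.52; bb 101, ff 55, bf 136)
  avg degree 2E/N 3.82 (E/N 1.91); density 0.012 (interacting 0.013)
  communities: 16, modularity 0.711, clustering 0.288, path length 4.92, diameter 11
```

The 157-band panel is kept whole in every group network, so the
interacting-node count (degree ≥ 1) can be read against the total panel.
A positive/negative ratio above 1 reads as net cooperation rather than
competition; modularity above 0.4 indicates well-separated communities.

```python
dist = pn.bray_curtis(pn.filter_low_frequency(matrix))
print(pn.permanova(dist, samples, ("source", "inoculum"),
                   n_perm=999, seed=3).summary())
```

```
PERMANOVA (sequential sums of squares)
Permutations: 999 free permutations

          df     SS      F     R2      p
source     3 2.6792 5.3271 0.3642 0.0010
inoculum   1 0.1506 0.8981 0.0205 0.5770
Residual  27 4.5264    NaN 0.6153    NaN
Total     31 7.3562    NaN 1.0000    NaN
```

Phosphate source explains 36% of community variance here (p = 0.001);
inoculation explains essentially none, matching the generator's defaults
(a planted source shift, no inoculum shift).

Composing the dry-matter and bacteria–fungi edge-count regressions locates
the predicted optimum in the interior of the dose range — around 10.6 %P₂O₅
for this seed — rather than at the most soluble source.

A CLI mirrors the library: `phosnet run-all --seed 1 --out-dir out/` runs
simulation through surface and writes TSV/GraphML/Newick/JSON outputs;
every stochastic subcommand requires an explicit `--seed`.

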