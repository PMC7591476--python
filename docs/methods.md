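# Methods

## Model and procedure

The pipeline characterizes classes of cancer genes by gene-level omic
features and uses the resulting profile to prioritize candidates in GWAS
loci.

**Feature matrix.** 23 features per protein-coding gene (registry in
`cancerfeat.features.DEFAULT_REGISTRY`; 22 are fixed by the aggregation
rules, the last slot is configurable and defaults to the number of distinct
PTM types). Interval-derived features use 1-based inclusive coordinates;
BED input is converted on read. Conventions that matter:

- gene length = longest-transcript span, `end − start + 1`;
- exon statistics pool all exons of all isoforms; UTR means average over
  isoforms possessing that UTR (none ⇒ missing);
- LD-score mean/SD over variants with `start ≤ pos ≤ end`; 0 variants ⇒
  both missing, 1 variant ⇒ SD missing (sample SD, n−1, throughout);
- expression breadth counts tissues with TPM strictly > 1;
- TF windows: promoter `[tss−1000, tss+1000]` (symmetric, hence
  strand-independent), body `[start, end]`, distal
  `[start−100000, end+100000]` *minus the body*, so body and distal are
  disjoint and no site is double counted between them. A peak counts for a
  window when it overlaps it by ≥ 1 bp (closed intervals); windows clip at
  position 1. Body and distal counts are divided by gene length in bp.
- orthologue/paralogue counts, intolerance Z-scores, eQTL, PTM and probe
  counts are pass-through per-gene columns.

**Scaling and association.** Each feature is scaled to mean 0 / sample
SD 1 over its non-missing entries (constant columns → all-zero, logged;
all-missing → error; scaling is idempotent). For every (feature, class)
pair, class membership vs the *background set only* is fit by
maximum-likelihood logistic regression (Newton/IRLS, deviance tolerance
1e−8, ≤ 100 iterations); the slope is the log odds ratio per feature SD.
GWAS-class fits add the scaled genotyping probe count as a covariate to
control coverage confounding. Missing feature values are dropped per fit;
complete separation is flagged, the coefficient reported as NaN, and the
term contributes zero weight to scores. No multiplicity adjustment is
applied to the 23×class association p-values (nominal reporting).

**Scores and evaluation.** `Score(gene, class) = Σᵢ βᵢ xᵢ` over the scaled,
median-imputed matrix (median over the full gene universe; even counts take
the mean of the middle two order statistics; imputation never alters
observed cells). Discrimination is Nagelkerke's pseudo-R² of
`class ~ intercept + score`, computed in-sample — the same genes estimate
the weights and evaluate the score, so R² is optimistically biased, which
is a property of the procedure being replicated, not a bug. Under detected
separation the model log-likelihood is taken at its saturated limit (0),
which makes a perfectly separating score score R² = 1, the formula's limit.
A multivariate fit of all features at once is available as an alternative
weighting; its design-matrix condition number (largest/smallest singular
value) is reported as the collinearity diagnostic.

**Loci and prioritization.** Index variants with p ≤ 5×10⁻⁸ seed loci that
extend to the most distant proxy with D′ ≥ 0.5 (the conventional reading:
the locus extends through correlated variants; the literal complementary
reading D′ < 0.5 is selectable via `extend_through="lt"`). Overlapping
loci merge transitively (closed intervals, ids and tissue clusters
unioned). A gene joins a locus iff its TSS *or* terminator lies inside —
a gene whose body spans the locus with both endpoints outside is not a
member; this is the literal endpoint rule and is a documented sharp edge.
Pleiotropic = ≥ 2 distinct tissue clusters among the locus's index
variants; a gene in any pleiotropic locus is pleiotropic. Within-locus
ranking is by descending class score with ties broken by ascending gene id;
the high set is the top k = 2 per locus (or top p% with ceiling and a floor
of one), a multi-locus gene being high if high anywhere.

**Class construction.** Exclusions are applied to the *original* input
sets: germline∩somatic leaves both; driver genes that are germline or
somatic leave driver, and somatic∩driver leaves somatic (symmetric
treatment of the somatic/driver overlap); survival loses members of the
other three classes and of GWAS loci; GWAS genes lose members of the other
four (the survival/GWAS overlap is removed from both sides). Genes dropped
by these rules re-enter the background set — a consequence of defining
background as "in no cancer class" — so background is not a curated
negative set. Survival genes are called by Benjamini–Hochberg FDR < 0.01
within each dataset, requiring significance in ≥ 2 datasets; the hazard
direction is recorded when all significant datasets agree. The gene
universe excludes any gene overlapping the configured exclusion region
(default: the MHC interval on chr6) by ≥ 1 bp.

**Enrichment.** ORA: hypergeometric upper tail of the query/pathway
overlap within the universe of all scored genes, testing only pathways
with term size ≤ 1000 (counted within the universe) and precision
(overlap/query) ≥ 2.5% — the precision cut is applied before testing, so
filtered pathways absorb no multiplicity burden. BH q-values are emitted
both overall and per annotation source; significance is read at q < 0.05.
GSEA: weighted KS running sum with exponent 1 on |score|, null by
gene-label permutation (one composite "sample" exists, so phenotype
permutation is unavailable), 1000 permutations by default with a fixed
seed; NES = ES / mean |null ES| of the same sign, permutation p with the
+1 correction. Multiple testing is plain BH here, not the g:SCS-style
correction some web tools use — qualitative conclusions (signal pathways
significant, nulls not) are the contract, not any specific tool's
q-values.

## The synthetic-data generator

`generate_dataset` emulates the statistical structure of the study:

1. A latent Gaussian matrix Z (genes × features) with optional correlation
   blocks (`z = √r·u_block + √(1−r)·ε`); defaults plant three blocks
   echoing the empirical clusters (size/isoforms/expression-breadth;
   GC/UTR/exon-length/paralogues; the three intolerance Z-scores).
2. Raw inputs realized monotonically from Z: lognormal gene lengths placed
   round-robin on 22 fixed 100-Mb chromosomes with exponential ~30 kb
   gaps (capacity errors are explicit); isoform/exon tables; lognormal
   TPM across 44 tissues; gamma LD scores over Poisson variant counts;
   Poisson TF peaks in promoter/body/distal windows; Poisson/clipped
   pass-through counts. All distributional forms are artifact choices —
   no claim is made that they match any real database.
3. **Labels from realized features.** Class membership (germline, somatic,
   driver, survival; default prevalences 1/4/2/8%) is Bernoulli from a
   logistic model on the *realized, standardized* feature values with the
   planted log-odds coefficients. Because the label model sees exactly
   what the association stage later fits, the univariate estimand equals
   the planted coefficient whenever features are independent; with
   correlation blocks active, univariate fits estimate *marginal* effects,
   which differ from the planted conditional ones. Default planted effects
   (0.2–0.5 per SD) echo the qualitative cancer-gene profile: longer,
   lower GC, more isoforms, broadly expressed, promoter-TF-rich,
   mutation-intolerant.
4. **GWAS architecture.** Index variants are placed near gene TSSs with
   probability ∝ exp(1.5·standardized gwas-score), carry tissue clusters
   from the 20-cluster vocabulary and genome-wide significant p-values;
   the first quarter form co-located pairs with distinct clusters to force
   locus merging and pleiotropy. Proxies spread U(50, 250) kb around the
   index with D′ ~ U(0, 1). GWAS class membership is therefore
   *positional*: locus genes are enriched for, but not identical to, the
   high-score genes, so GWAS-class feature effects are recovered
   directionally, attenuated by the non-causal neighbours — as in real
   loci.
5. **Pathways.** ~10% of pathways are "signal" (80% of members drawn from
   the top decile of the true gwas score, sizes U(50, 200)); the rest
   sample uniformly (sizes U(20, 400)); one undersized (<20) and one
   oversized (>1000) null pathway are included at sufficient scale to
   exercise the term-size filters.
6. **Missingness** is missing-completely-at-random at the configured rate
   (default 2%), applied to features representable as absent raw records
   (the pass-through columns and UTR lengths); interval-derived features
   go missing only structurally (e.g. a gene with no variants has no LD
   statistics). MCAR is the right match for a pipeline that imputes to the
   median without modelling missingness.

Randomness: a single root seed; each component draws from
`default_rng([component_id, seed])` (PCG64), so streams are independent
and adding a component never perturbs existing output. A fixed seed gives
byte-identical files (deterministic column order, fixed float format,
sorted gene sets).

## What the tests show — and what they do not

The suite checks the pipeline's primitives against independent oracles
(exact rational hypergeometric tails; quadratic interval scans; the 2×2
log-OR identity for logistic slopes; a hand-evaluated Nagelkerke case; an
external GSEA implementation for the KS statistic), and the whole chain on
synthetic data: planted univariate effects are recovered within 3 SE
(~99% of pairs at 10,000 genes), composite-score R² rises strictly with
planted effect magnitude, and the top-2-per-locus high set is strongly
enriched for planted signal pathways while null pathways stay at their
nominal false-positive rate in the low set.

Synthetic data cannot certify real-data behaviour: real omic features have
heavier tails, structured (non-MCAR) missingness, shared technical
covariates and annotation errors; real pathway databases are hierarchical
and overlapping where synthetic pathways are flat random sets; and real
GWAS architecture couples LD, gene density and ascertainment in ways the
uniform-proxy model does not attempt. Passing tests demonstrate
correctness of the computations and recoverability of planted structure,
not biological validity.

Detection power at the enrichment stage has a built-in ceiling worth
knowing: the high set grows linearly with genome size while pathway sizes
stay fixed, so the expected signal-pathway overlap saturates around a
handful of genes and the smallest signal pathways sit near the
significance boundary; at several thousand genes the per-pathway detection
rate is ~90% while the probability that *every* signal pathway clears
q < 0.05 simultaneously in one replicate is markedly lower (~50–60%).
Above ~8,000 genes the 2.5% precision floor, which scales with the query,
starts to silently filter small signal pathways — on real data with larger
locus counts the same interplay between query size and the precision
filter deserves attention.

## Problem sizes and defaults

| parameter | default | note |
|---|---|---|
| `n_genes` | 3,000 | desk-scale genome; tests use 400–10,000 |
| `n_chromosomes` / length | 22 / 100 Mb | fixed constants |
| `n_tissues` | 44 | expression breadth denominator |
| class prevalences | 1/4/2/8 % | germline/somatic/driver/survival |
| `missing_rate` | 0.02 | MCAR, maskable features |
| `n_index_variants` | n/50 (≥10) | GWAS indices |
| `proxies_per_index` | 20 | spans U(50, 250) kb |
| `n_pathways` | 50 | ~10% signal, fraction 0.8 |
| D′ threshold | 0.5, `≥` | locus boundary rule |
| ORA filters | ≤1000, ≥2.5% | term size, precision |
| GSEA | 20–1000, 1000 perms, weight 1 | term sizes, null |
| survival calling | FDR < 0.01, ≥2 datasets | BH per dataset |

Simulation sizes in the test suite (10,000 genes × 20 seeds for parameter
recovery, 5,000 × 20 for the monotonicity study, 6,000 × 20 for
end-to-end detection) were chosen to make the Monte-Carlo checks stable at
a few minutes of runtime.

## Known limitations

- In-sample R² and the univariate-vs-multivariate comparison share data
  between weight estimation and evaluation; an optional held-out split is
  left to users.
- Separation handling is flag-and-exclude; no Firth correction.
- The background set absorbs genes dropped by the class exclusion rules.
- The endpoint rule for locus membership excludes genes that fully span a
  locus.
- GSEA permutes gene labels, not phenotypes; its null ignores inter-gene
  correlation of scores.
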