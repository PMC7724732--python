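# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limits of the package. Notation: n
samples, M SNPs, dosages x ∈ {0,1,2} counting copies of allele a1.

## Genotype QC

Filters run in a fixed order — samples by call rate, then SNPs by MAF,
Hardy–Weinberg, missingness, autosome restriction — and every threshold
is exclusive: a sample at exactly 96% call rate or a SNP at exactly
MAF = 0.05 survives. The HWE test is the exact conditional test on the
heterozygote count given the allele counts (Wigginton-style), two-sided
by summing all configurations no more probable than the observed one;
ties in probability count as extreme (a 1 + 1e-12 relative tolerance
absorbs floating-point ties). The chi-square alternative was rejected
because the exact test is the standard default in array QC and is
well-defined at low counts. QC is idempotent by construction. LD is the
squared Pearson correlation of dosages (composite LD; genotypes are
unphased), with pairwise deletion of missing calls and mean imputation
used nowhere except the GRM.

## GRM and GREML

The GRM is the standardized-dosage average over polymorphic SNPs
(monomorphic-after-imputation SNPs are skipped with a warning and do not
count toward N). GREML fits y = Xb + u + e, u ~ N(0, G σ²ᵤ),
e ~ N(0, I σ²ₑ) by restricted maximum likelihood. Because there are
exactly two components, eigendecomposing G once turns every REML
quantity into O(n) work per iteration; updates are average-information
steps with negative proposals clamped to the variance floor (1e-8) —
the constrained-AI behavior of the standard GREML tools — and an EM step
as fallback when the AI system is singular or proposes a non-finite
point. Convergence: relative log-likelihood change < 1e-8, or relative
parameter change < 1e-10, within 100 iterations; non-convergence is
flagged on the result, never raised. SE(h²) comes from the delta method
on the inverse AI matrix. The implementation was checked against an
independent profile-likelihood grid search (agreement to 4 decimals).

Degenerate case to know about: with G = I the two components are
confounded (only their sum is identified); the fit returns a valid
point on the ridge, flagged when the likelihood cannot settle.

At the boundary the estimator is truncated at zero, so over null
replicates its mean is the positive-part mean ≈ SE/√(2π), not zero;
validation therefore judges the null case against the reported SE and
the nonzero-h² cases against an absolute band.

## Mixed-model association

P3D/EMMAX logic: the variance components are estimated once per trait
under the no-SNP null and the per-SNP test is a GLS Wald test with that
covariance fixed, dosages centered to (−1, 0, 1) coding so δ is a
per-allele additive effect. P-values use a t reference with
n − p − 1 degrees of freedom, which keeps the empirical type-I error at
α = 0.05 inside [0.04, 0.06] at n = 300 in the calibration simulations.
Traits whose null fit lands on the σ²ᵤ = 0 boundary are scanned by
ordinary least squares (the models coincide there); an exact per-SNP
REML refit is available behind `exact_per_snp=True` but is not the
default. FDR is Benjamini–Hochberg per trait (a pooled option exists;
the per-trait choice follows the per-trait reporting convention of the
design). QTL intervals chain significant SNPs per trait and chromosome
while consecutive gaps are strictly below 5 Mbp; a gap of exactly 5 Mbp
starts a new interval — the two natural phrasings of the rule conflict
at the boundary and the strict reading was chosen. Singleton intervals
are kept in the output but flagged, and downstream candidate steps skip
them. SNPs on unplaced scaffolds (non-numeric chromosome labels) are
reported in scans but never clustered.

## Expression layer

Screens: genes kept when mean FPKM ≥ 10; miRNAs when mean CPM is
strictly above 1 (an `strict_per_sample` variant requires CPM > 1 in
every sample; the mean reading is the default because the per-sample
reading is much more aggressive at small n). Stabilization is
log2(x + 1); the pseudo-count is configurable and exists so zero
abundances stay representable.

The external-effects model
Y = μ + Library + Gene + Gene×Farm + Gene×YearSeason + Gene×Age +
Gene×Run + e (library fixed, gene terms random) is fitted by EM-REML on
Henderson's mixed-model equations with dense linear algebra; each
iteration solves the MME and updates σ²_c from û_c and the
corresponding block of the inverse coefficient matrix. This is O(q³)
per iteration in the total number of random levels q, which bounds
practical problem sizes to a few thousand levels — the pipeline
therefore runs it on a gene subsample when reporting. Factors with
fewer than two observed levels are dropped with a warning; a constant
response is an error. Variance shares sum to one by construction. The
model is reported, and abundances are *not* corrected downstream — the
gene main effect dominating the explained variance is the standing
justification.

Year–season has 9 levels in the phenotype design and 6 in the
expression design; both are accepted via the covariate table, and each
module's default follows its own design.

Trait–abundance screens are plain Pearson correlations of log2
abundances against covariate-adjusted traits with the two-sided t test
p = 2·P(T_{n−2} > |r|√((n−2)/(1−r²))), significance at P ≤ 0.05.
Whether adjusted traits keep the grand mean is irrelevant to r and is
not standardized.

## eGWAS

Per (SNP, gene): simple regression of log2 abundance on dosage, no
covariates (the RNA-seq subset is small and the abundance model above
showed external effects explain little). FDR is computed within each
gene's scan by default (`fdr_scope="pooled"` available) — the
transcriptome-wide choice is not obvious and per-gene is the more
conservative labeling for per-gene claims. The cis/trans label uses a
1 Mbp window around the gene body; the label is annotation only and no
step filters on it. The double filter keeps records whose SNP is an
FDR-significant phenotype hit and whose gene correlates with that same
phenotype; the linking trait(s) are recorded.

## AWM

Stages, in order: (1) SNPs with key-trait (VIAB_5) P ≤ 0.01; (2) union
with SNPs associated with at least max(2, ⌈Ap⌉) non-key traits, Ap
being the mean number of associated non-key traits across stage-1 SNPs
(the "≥ 2" floor resolves the dependency-threshold wording; a
sequential variant restricted to stage-1 SNPs sits behind
`selection="sequential"`); (3) keep SNPs either closer than 2 500 bp to
the nearest gene or farther than 1 Mbp from any gene, each kept SNP
assigned to its nearest gene — SNPs on gene-free chromosomes pass the
distance rule but have no gene and drop out with a warning; (4) per
gene, the SNP with the smallest key-trait P. Cells hold signed betas
(not t-statistics) for every trait, then each trait column is z-scored.
Boundary inclusivity at exactly 2 500 bp / exactly 1 Mbp follows the
strict readings (< and >).

Column standardization means the AWM of a handful of genes couples
their profiles (subtracting the cross-gene column mean); co-association
statements are only meaningful against a reasonably sized gene set.

## PCIT

For every trio (x, y, z), first-order partials
r_xy.z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)) and its two
rotations; tolerance ε = mean of |partial/direct| over the trio's three
pairs, skipping pairs whose direct correlation is below 1e-12 (ε
defaults to 1 when no ratio is computable). Edge (x, y) is eliminated
if some z satisfies |r_xy| ≤ |ε·r_xz| and |r_xy| ≤ |ε·r_yz|; ties
eliminate. Absolute values are used throughout the tolerance — signed
ratios can go negative and make the threshold meaningless. Surviving
edges with correlation P ≤ 0.05 are "significant"; the significance
screen runs after elimination by default (switchable). With two
features there are no trios and both survive elimination. The
production code vectorizes over the conditioning node z (n passes of
O(n²)); a deliberately naive O(n³) reference implementation is kept in
the package and the two are held to exact agreement in tests. Output is
invariant to feature order and to positive rescaling of features.
miRNA–gene edges run PCIT on the stacked matrix and keep only
significant *negative* gene–miRNA correlations.

## Networks

SNP network: PCIT over AWM rows (observations = traits; at least 3
traits required). RNA network: PCIT over log2 gene abundances. Shared
network: node-and-edge intersection (edges matched as unordered pairs);
weights taken from the RNA side since abundance correlations are the
more interpretable magnitude; empty intersection warns rather than
raises. Final network: shared ∪ genes significantly correlated with
strictly more than 3 traits ∪ those genes' RNA-network edges (partner
nodes come along) ∪ significant negative miRNA edges touching final
genes. Two wordings of the augmentation threshold exist in the source
design ("more than three" vs "more than four"); "more than three" is
implemented and the threshold is an argument. "Co-associated genes" of
an added gene are read as its RNA-network neighbors, and miRNA edges
are restricted to genes already in the final network — both choices are
the conservative ones and are isolated behind the function's arguments.
Node annotations: n_traits (count of significantly correlated traits),
top_trait (max |r|, ties to the lexicographically smallest trait id),
tf_class from the supplied TF table, in_shared.

## Prediction layer

Candidate pool: final-network genes correlated with ≥ 4 traits, with
abundance > 0 in every sample, mutually non-adjacent in the final
network (greedy, in order of an optional external relevance list, then
descending trait count). All-subsets R²: every nonempty OLS subset,
refused above 20 genes (2²⁰ fits); R² is monotone under subset
inclusion and the tests assert it. Common-gene selection: per trait and
model size the best-R² subset wins (ties to the lexicographically
smallest tuple), gene occurrences are tallied over all winners, top k
(=10) returned — "most commonly present across the per-trait models"
needed a concrete definition and this per-size-winners tally is it,
configurable at the call site. Stepwise: forward entry at P ≤ 0.15,
backward stay at P ≤ 0.15 (the SAS REG STEPWISE defaults), on *raw*
(unadjusted, non-log) abundances; the model is
Y = intercept + Σ GPE_j + e and accuracy is in-sample R² with the
overall F-test P. No cross-validation is attempted — R² here is a
goodness-of-fit summary, not a generalization estimate.

SNP panel: union of non-singleton GWAS interval leads, per-gene eGWAS
lead SNPs, and for each shared-network gene correlated with ≥ 4 traits
the smallest-P GWAS SNP (over all traits) within the gene body ± 2.5 kb;
de-duplicated with source tags, autosomes only. Panel variance
explained: GREML with the GRM restricted to panel SNPs, per trait, with
the farm/season-year/age covariates; missing phenotypes drop listwise.

## Synthetic data generator

What it emulates: the study design — 300 samples, dense genotypes with
block LD, 25 traits (19 measured + 6 ratio) with the catalogue means,
SDs and heritabilities, 3/9/3 covariate levels, RNA-seq on the first 40
samples, log-normal FPKM/CPM with planted signals. Defaults: 5 000 SNPs
in 10-SNP AR(1) blocks (latent rho 0.8, MAF uniform on [0.05, 0.5]),
500 genes, 40 miRNAs — the genotype/expression dimensions are scaled to
what the correlation and network stages can exercise quickly while
keeping every planted structure estimable; each count is a config
field. Seven QTL (0.45–0.55 trait-SD effects) on the traits of the
abnormality/motility/droplet families; six strong single-gene
expression–trait plantings plus ten "hub" genes each tied to four
staggered traits at |r| = 0.45 (so the ≥ 4-trait rules have true
positives); two SNP→gene expression effects placed on QTL SNPs of genes
correlated with the same traits (so the eGWAS double filter has true
positives); eight miRNA→target negative correlations at r = −0.55.

Mechanics worth knowing:

* Genotypes: two latent AR(1) gametes per individual thresholded at the
  allele-frequency quantile; blocks never span chromosomes. Dosage LD is
  attenuated relative to the latent rho by thresholding — markedly so at
  low MAF.
* Phenotypes: per base trait, standardized scale
  fixed effects + Σ β·(standardized dosage) + u + e with
  u ~ N(0, G·h²) from the realized GRM and Var(u) + Var(e) = 1, so
  GREML recovery is well-posed; residuals share a group factor
  (motility / morphology / viability, rho 0.3) to mimic the observed
  phenotype-correlation blocks; ratio traits are literal quotients of
  the simulated raw values.
* Abundances: gene latents are Gaussian-copula mixes of the
  covariate-free trait signals (and planted eQTL dosages) with the
  requested r's, shrunk proportionally if Σr² exceeds 0.9;
  FPKM = 2^(μ + s·z) with ~15% of genes given low means so the FPKM
  screen has work to do; planted genes are kept expressed.
* Annotation: gene g centered on SNP g·stride with a ±110 kb body, so a
  few SNPs per gene sit at distance 0 and pass the AWM proximity rule;
  ~10% of genes get TF/TF-cofactor flags.

What it does *not* emulate — and hence what passing tests do not show
about real data: realistic allele-frequency spectra and LD decay,
pedigree/population structure, count-level sequencing noise or
library-size artifacts, non-Gaussian trait distributions (several real
traits are percentages near their bounds), and any calibrated
between-trait covariance beyond the three group factors.

## Determinism and problem sizes

Every stochastic step draws from named, seed-derived streams
(`SimConfig.rng`), writers emit sorted rows with fixed float formatting,
and the end-to-end test asserts byte-identical outputs across two runs
of the same configuration. The validation suite runs the estimator
recoveries at n = 500 / M = 2 000 (50 replicates per h² level), the
association calibration at 10⁴ null tests and 100 planted-QTL
replicates, and the full pipeline at 300 × 5 000 × 500 × 40 — sizes
chosen so the entire suite completes in a couple of minutes on one CPU
while leaving every recovery check well-powered.

## Known limitations

* Single-component GREML only; no chromosome-partitioned or
  multi-component models.
* The expression variance model's dense MME solver does not scale past a
  few thousand random levels.
* eGWAS has no covariates and no conditional (multi-SNP) analysis.
* PCIT is first-order only; no higher-order partials or Gaussian
  graphical models.
* The RNA model's R² is in-sample; stepwise selection inherits the usual
  selection-bias caveats.
* PLINK text ped/map is the only genotype format (no .bed, no VCF).
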