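# spermnet

Systems-genetics toolkit for semen-quality traits: it integrates a
multi-trait GWAS on dense SNP genotypes with sperm RNA-seq abundances to
move from single-marker associations to gene co-association networks and,
finally, to compact RNA- and SNP-based phenotype predictors.

The intended user is a quantitative geneticist working with an animal-
breeding design: a few hundred individuals (boar ejaculates in the
motivating setting) phenotyped for ~25 computer-assisted semen-analysis
traits (motility MT, velocities VAP/VCL/VSL, viability VIAB, morphology
abnormalities HABN/NABN/TABN, acrosome integrity ACRO, droplets
PDROP/DDROP, each at 5 and 90 min of incubation plus 90/5 ratios),
genotyped on a dense array, with RNA-seq (gene FPKM, miRNA CPM) on a
subset.

## What it computes

1. **Genotype QC** — sample call rate ≥ 0.96, MAF ≥ 0.05, Hardy–Weinberg
   exact test P > 10⁻³, SNP missingness ≤ 5%, autosomes only.
2. **GRM + GREML** — standardized-dosage genomic relationship matrix
   G_jk = (1/N) Σᵢ (x_ij − 2pᵢ)(x_ik − 2pᵢ) / (2pᵢ(1−pᵢ)) and AI-REML
   heritability for the two-component model y = Xb + u + e,
   u ~ N(0, G σ²ᵤ).
3. **Mixed-model GWAS** — per SNP,
   y = μ + δ·SNP + Farm + SeasonYear + Age + u + e, with the variance
   components estimated once under the null and reused for every SNP
   (P3D/EMMAX style); Benjamini–Hochberg FDR per trait; significant SNPs
   chained into QTL intervals (gaps < 5 Mbp merge; singleton intervals
   flagged).
4. **Expression layer** — abundance screens (mean FPKM ≥ 10, mean
   CPM > 1), log2 stabilization, a crossed random-effects model
   quantifying how much library/farm/season/age/run explain of gene
   abundance, and Pearson correlation screens of every feature against
   every adjusted trait (P ≤ 0.05).
5. **eGWAS** — per-(SNP, gene) regression of abundance on dosage; hits
   are kept only when the SNP is also a phenotype-GWAS hit *and* the gene
   correlates with the same trait.
6. **AWM** — the associated weight matrix: one SNP per gene (selected
   around the key phenotype VIAB_5, with the Ap dependency rule and the
   < 2.5 kb / > 1 Mb gene-distance rule), columns z-scored per trait.
7. **PCIT networks** — partial-correlation-with-information-theory edge
   filtering over AWM rows (SNP network) and over gene abundances (RNA
   network): edge (x,y) is dropped when some z makes
   |r_xy| ≤ ε·|r_xz| and |r_xy| ≤ ε·|r_yz| for the trio tolerance
   ε = mean |partial/direct|.
8. **Network integration** — the *shared* network (edges present in both
   SNP and RNA networks), then the *final* network (shared + genes
   correlated with > 3 traits + their RNA neighbors + significant
   negative miRNA–gene edges), with node annotations (trait counts, top
   trait, TF class, shared membership).
9. **Prediction** — all-subsets R² over a candidate gene pool, the 10
   most shared genes fed to SAS-style stepwise regression per trait
   (entry/stay P = 0.15), and a SNP panel (GWAS leads + eGWAS leads +
   per-network-gene top SNPs) whose per-trait variance explained comes
   from GREML on the panel-restricted GRM.

A synthetic-data generator (`spermnet.sim`) reproduces the study
structure — 300 samples, LD-blocked genotypes, 25 correlated traits with
farm(3)/season-year(9)/age(3) fixed effects, planted QTL/eQTL and planted
expression–trait and miRNA–target correlations — so the whole pipeline is
testable end to end without any external data.

All genomic coordinates are 1-based inclusive.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from spermnet import SimConfig, run_pipeline

result = run_pipeline(SimConfig(seed=11))
print(result.summary_frame().to_string(index=False))
```

prints

```
network  n_nodes  n_edges
    snp       67      253
    rna      386     2602
 shared        6        3
  final      264      493
```

i.e. the AWM retained 67 genes whose PCIT co-association network has 253
edges, the RNA co-abundance network spans the 386 genes passing the FPKM
screen, 3 edges are supported by both data types (the high-confidence
shared core), and augmenting with highly trait-correlated genes and
miRNA edges yields a 264-node final network.

```python
print(result.panel_variance.head(6).to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

```
  trait  var_explained    se  converged
    CON          0.000 0.011       True
 VIAB_5          0.000 0.012       True
VIAB_90          0.000 0.014       True
    ORT          0.000 0.014       True
   HABN          0.405 0.175       True
   NABN          0.005 0.014       True
```

HABN (head abnormalities) carries two planted QTL whose simulated
variance fraction is 0.356; the GREML estimate from the SNP panel, 0.405
(SE 0.175), recovers it within one standard error.  Traits without
planted QTL sit at the zero boundary.

```python
print(result.rna_models["VCL_5"].summary())
```

```
RNA model for VCL_5: R^2 = 0.137, P = 0.0188
  intercept: 65.31
  gene0318: -0.399
```

A thin CLI mirrors the main stages: `spermnet qc`, `spermnet h2`,
`spermnet pcit`, `spermnet pipeline` (see `--help`).

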