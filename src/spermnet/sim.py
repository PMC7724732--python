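"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a boar AI-stud study design: ~300 ejaculates from
distinct boars genotyped on a dense SNP array, 25 semen-quality traits
(concentration, viability, morphology abnormalities, CASA motility
kinetics, each at 5 and 90 min of incubation plus 90/5 ratios) recorded
with farm (3 levels), season-year (9 levels) and age (3 levels) fixed
effects, and sperm RNA-seq abundance matrices (gene FPKM, miRNA CPM) for a
subset of animals.

Genotypes carry block-wise LD through an AR(1) Gaussian copula on latent
gametes; phenotypes combine fixed effects, planted QTL on standardized
dosages, a polygenic term drawn from the realized GRM, and group-factor
residual correlations among physiologically related traits; abundances are
log-normal with Gaussian-copula planted trait correlations and planted
negative miRNA->target correlations.

Everything is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import AbundanceMatrix, GenotypeMatrix

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_abundances",
    "simulate_annotation",
    "BASE_TRAITS",
    "RATIO_TRAITS",
    "ALL_TRAITS",
]

# trait catalogue: name -> (mean, sd, h2) for the 19 directly measured traits.
# Ratio traits are derived as value_90 / value_5.
BASE_TRAITS: dict[str, tuple[float, float, float]] = {
    "CON": (141.3, 65.5, 0.13),
    "VIAB_5": (90.1, 6.3, 1e-6),
    "VIAB_90": (77.4, 17.3, 0.14),
    "ORT": (79.8, 12.5, 0.13),
    "HABN": (2.1, 5.9, 0.16),
    "NABN": (3.0, 4.9, 1e-6),
    "TABN": (2.7, 3.4, 0.09),
    "PDROP": (3.5, 5.1, 0.12),
    "DDROP": (4.5, 4.5, 0.06),
    "MT_5": (75.4, 18.1, 0.21),
    "MT_90": (64.1, 22.0, 0.39),
    "VAP_5": (34.0, 10.2, 0.17),
    "VAP_90": (30.8, 9.5, 0.35),
    "VCL_5": (46.2, 12.5, 0.11),
    "VCL_90": (39.7, 10.2, 0.35),
    "VSL_5": (27.0, 8.3, 0.23),
    "VSL_90": (25.9, 8.3, 0.34),
    "ACRO_5": (7.0, 5.6, 0.08),
    "ACRO_90": (16.4, 12.6, 0.06),
}

#: 90/5 ratio traits and the base pair each divides
RATIO_TRAITS: dict[str, tuple[str, str]] = {
    "R_MT": ("MT_90", "MT_5"),
    "R_VAP": ("VAP_90", "VAP_5"),
    "R_VCL": ("VCL_90", "VCL_5"),
    "R_VSL": ("VSL_90", "VSL_5"),
    "R_VIAB": ("VIAB_90", "VIAB_5"),
    "R_ACRO": ("ACRO_90", "ACRO_5"),
}

ALL_TRAITS: list[str] = list(BASE_TRAITS) + list(RATIO_TRAITS)

# physiological trait groups sharing a residual factor (emulates the
# observed phenotype-correlation block structure)
_TRAIT_GROUPS = {
    "motility": ["MT_5", "MT_90", "VAP_5", "VAP_90", "VCL_5", "VCL_90", "VSL_5", "VSL_90"],
    "morphology": ["HABN", "NABN", "TABN", "ACRO_5", "ACRO_90", "PDROP", "DDROP"],
    "viability": ["VIAB_5", "VIAB_90", "ORT"],
}


def _default_qtl_map() -> list[tuple[int, int, float]]:
    """Planted QTL (snp index, trait index, effect in trait-SD units).

    Traits chosen among those with genuine association signal in this kind
    of study (head/neck abnormalities, abnormal acrosomes, motility,
    droplets); effect sizes are large enough for a 300-sample scan to see.
    """
    t = list(BASE_TRAITS)
    return [
        (40, t.index("HABN"), 0.55),
        (850, t.index("HABN"), 0.50),
        (1700, t.index("NABN"), 0.50),
        (2500, t.index("ACRO_5"), 0.55),
        (3300, t.index("MT_5"), 0.50),
        (3305, t.index("MT_90"), 0.50),
        (4200, t.index("PDROP"), 0.45),
    ]


def _default_expr_trait_corr() -> list[tuple[int, int, float]]:
    t = list(BASE_TRAITS)
    out = [
        (0, t.index("HABN"), 0.60),
        (1, t.index("HABN"), -0.50),
        (2, t.index("ACRO_5"), 0.55),
        (3, t.index("MT_5"), 0.50),
        (4, t.index("MT_90"), -0.55),
        (5, t.index("VIAB_5"), 0.50),
    ]
    # hub genes each tied to four staggered traits, so genes correlated
    # with >= 4 phenotypes exist for the network-augmentation and
    # candidate-pool stages
    for g in range(6, 16):
        for k in range(4):
            out.append((g, (3 * g + k) % len(t), 0.45 if (g + k) % 2 else -0.45))
    return out


def _default_eqtl_map() -> list[tuple[int, int, float]]:
    """Planted SNP -> gene-expression effects (snp idx, gene idx, latent r).

    Chosen on SNPs that are also phenotype QTL and genes correlated with
    the same trait, so the expression-GWAS double filter has true
    positives to find.
    """
    return [(40, 0, 0.65), (2500, 2, 0.65)]


def _default_mirna_targets() -> list[tuple[int, int, float]]:
    return [(m, 2 * m, -0.55) for m in range(8)]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the emulated design: 300 samples, 5000 SNPs in
    10-SNP LD blocks (rho 0.8), 500 genes, 40 miRNAs, 25 traits with the
    catalogue means/SD/h2, farm 3 x season-year 9 x age 3 fixed effects,
    planted QTL and expression-trait correlations as module defaults.
    """

    n_samples: int = 300
    n_snps: int = 5000
    n_genes: int = 500
    n_mirnas: int = 40
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.8
    n_chroms: int = 18
    n_traits: int = 25
    h2_per_trait: list[float] = field(
        default_factory=lambda: [v[2] for v in BASE_TRAITS.values()]
    )
    qtl_map: list[tuple[int, int, float]] = field(default_factory=_default_qtl_map)
    expr_trait_corr: list[tuple[int, int, float]] = field(
        default_factory=_default_expr_trait_corr
    )
    eqtl_map: list[tuple[int, int, float]] = field(default_factory=_default_eqtl_map)
    mirna_target_map: list[tuple[int, int, float]] = field(
        default_factory=_default_mirna_targets
    )
    fixed_effect_levels: tuple[int, int, int] = (3, 9, 3)
    fixed_effect_sd: float = 0.3
    trait_group_rho: float = 0.3
    missing_rate: float = 0.0
    frac_low_expr: float = 0.15
    n_rnaseq_samples: int = 40
    seed: int = 20140901

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if len(self.h2_per_trait) != len(BASE_TRAITS):
            raise ValueError(f"h2_per_trait must list {len(BASE_TRAITS)} values")
        if any(not 0.0 <= h <= 1.0 for h in self.h2_per_trait):
            raise ValueError("h2 values must be in [0, 1]")
        for snp, trait, _ in self.qtl_map:
            if not 0 <= snp < self.n_snps:
                raise ValueError(f"QTL snp index {snp} out of range")
            if not 0 <= trait < len(BASE_TRAITS):
                raise ValueError(f"QTL trait index {trait} must hit a base trait")
        for gene, trait, r in self.expr_trait_corr:
            if not 0 <= gene < self.n_genes:
                raise ValueError(f"expr corr gene index {gene} out of range")
            if not 0 <= trait < len(BASE_TRAITS):
                raise ValueError(f"expr corr trait index {trait} out of range")
            if abs(r) >= 1:
                raise ValueError("planted |r| must be < 1")
        for mi, gi, r in self.mirna_target_map:
            if not 0 <= mi < self.n_mirnas or not 0 <= gi < self.n_genes:
                raise ValueError("miRNA target indices out of range")
            if abs(r) >= 1:
                raise ValueError("planted |r| must be < 1")
        for snp, gene, r in self.eqtl_map:
            if not 0 <= snp < self.n_snps or not 0 <= gene < self.n_genes:
                raise ValueError("eQTL indices out of range")
            if abs(r) >= 1:
                raise ValueError("planted |r| must be < 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for a named stream, derived from seed."""
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(stream.encode()) % (2**31)])
        return np.random.default_rng(ss)


def _snp_positions(cfg: SimConfig) -> pd.DataFrame:
    """Spread SNPs over autosomes at 100 kb spacing (1-based bp)."""
    per_chrom = int(np.ceil(cfg.n_snps / cfg.n_chroms))
    chroms, bps = [], []
    for j in range(cfg.n_snps):
        c = j // per_chrom + 1
        k = j % per_chrom
        chroms.append(str(c))
        bps.append(100_000 * k + 50_001)
    return pd.DataFrame(
        {
            "snp_id": [f"snp{j:05d}" for j in range(cfg.n_snps)],
            "chrom": chroms,
            "bp": bps,
            "a1": ["A"] * cfg.n_snps,
            "a2": ["G"] * cfg.n_snps,
        }
    )


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw 0/1/2 dosages with block-wise AR(1) linkage disequilibrium.

    Each individual carries two latent gametes; within an LD block the
    latent Gaussians follow an AR(1) with parameter ``ld_rho`` and are
    thresholded at the allele-frequency quantile, so adjacent SNPs show
    haplotype-level correlation ~ld_rho while blocks are independent.
    """
    rng = cfg.rng("genotypes")
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)
    thresholds = norm.ppf(freqs)

    snp_map = _snp_positions(cfg)
    # blocks never span a chromosome boundary
    per_chrom = int(np.ceil(cfg.n_snps / cfg.n_chroms))
    block_start = np.array(
        [(j % per_chrom) % cfg.ld_block_size == 0 or j % per_chrom == 0 for j in range(cfg.n_snps)]
    )

    n, m = cfg.n_samples, cfg.n_snps
    dosage = np.zeros((n, m), dtype=float)
    for gamete in range(2):
        z = rng.standard_normal((n, m))
        lat = np.empty((n, m))
        for j in range(m):
            if block_start[j]:
                lat[:, j] = z[:, j]
            else:
                lat[:, j] = cfg.ld_rho * lat[:, j - 1] + np.sqrt(1 - cfg.ld_rho**2) * z[:, j]
        dosage += (lat < thresholds).astype(float)

    if cfg.missing_rate > 0:
        mask = rng.random((n, m)) < cfg.missing_rate
        dosage[mask] = np.nan

    samples = [f"boar{i:04d}" for i in range(n)]
    dos = pd.DataFrame(dosage, index=samples, columns=snp_map["snp_id"].tolist())
    return GenotypeMatrix(dos, snp_map)


def _standardized_dosage(geno: GenotypeMatrix, j: int) -> np.ndarray:
    x = geno.mean_imputed()[:, j]
    s = x.std()
    if s == 0:
        raise ValueError(f"QTL SNP {j} is monomorphic")
    return (x - x.mean()) / s


def simulate_phenotypes(geno: GenotypeMatrix, cfg: SimConfig) -> pd.DataFrame:
    """Trait table: 19 base + 6 ratio traits plus farm/season_year/age columns.

    Per base trait (standardized scale): fixed effects + planted QTL terms +
    polygenic u ~ N(0, G sigma_u^2) from the realized GRM + residual, with
    sigma_u^2 / (sigma_u^2 + sigma_e^2) equal to the trait's h2 (QTL effects
    come on top).  Correlated residuals within physiological trait groups.
    Ratio traits are value_90 / value_5 of the simulated raw values.
    """
    if any(h > 0 for h in cfg.h2_per_trait) and geno.n_snps == 0:
        raise ValueError("nonzero h2 requires SNPs for the polygenic term")
    rng = cfg.rng("phenotypes")
    n = geno.n_samples

    # polygenic factor root from the realized GRM
    from .relatedness import compute_grm

    grm = compute_grm(geno).to_numpy()
    d, U = np.linalg.eigh(grm)
    d = np.clip(d, 0.0, None)
    G_root = U * np.sqrt(d)

    levels = cfg.fixed_effect_levels
    farm = rng.integers(0, levels[0], size=n)
    season_year = rng.integers(0, levels[1], size=n)
    age = rng.integers(0, levels[2], size=n)
    farm_eff = rng.normal(0, cfg.fixed_effect_sd, size=levels[0])
    season_eff = rng.normal(0, cfg.fixed_effect_sd, size=levels[1])
    age_eff = rng.normal(0, cfg.fixed_effect_sd, size=levels[2])
    fixed_part = farm_eff[farm] + season_eff[season_year] + age_eff[age]

    group_factor = {g: rng.standard_normal(n) for g in _TRAIT_GROUPS}
    trait_group = {t: g for g, ts in _TRAIT_GROUPS.items() for t in ts}

    qtl_by_trait: dict[int, list[tuple[int, float]]] = {}
    for snp_j, trait_j, beta in cfg.qtl_map:
        qtl_by_trait.setdefault(trait_j, []).append((snp_j, beta))

    raw = {}
    core = {}
    for tj, (name, (mean, sd, _)) in enumerate(BASE_TRAITS.items()):
        h2 = cfg.h2_per_trait[tj]
        u = G_root @ rng.standard_normal(n) * np.sqrt(h2)
        rho = cfg.trait_group_rho
        g = trait_group.get(name)
        shared = group_factor[g] if g is not None else 0.0
        eps = rng.standard_normal(n)
        e = np.sqrt(1.0 - h2) * (np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps)
        qtl_part = np.zeros(n)
        for snp_j, beta in qtl_by_trait.get(tj, []):
            qtl_part += beta * _standardized_dosage(geno, snp_j)
        latent = fixed_part + qtl_part + u + e
        core[name] = u + e + qtl_part  # covariate-free signal, for planting
        raw[name] = mean + sd * latent

    traits = pd.DataFrame(raw, index=geno.sample_ids)
    for rname, (num, den) in RATIO_TRAITS.items():
        denom = traits[den].replace(0, np.nan)
        traits[rname] = traits[num] / denom
    traits = traits[ALL_TRAITS[: cfg.n_traits]]
    traits["farm"] = [f"farm{v+1}" for v in farm]
    traits["season_year"] = [f"sy{v+1}" for v in season_year]
    traits["age"] = [f"age{v+1}" for v in age]
    traits.attrs["core_signal"] = pd.DataFrame(core, index=geno.sample_ids)
    # standardized dosages of planted expression-QTL SNPs, for the
    # abundance generator (keeps its signature genotype-free)
    eqtl_snps = sorted({snp for snp, _, _ in cfg.eqtl_map})
    traits.attrs["eqtl_dosages"] = pd.DataFrame(
        {j: _standardized_dosage(geno, j) for j in eqtl_snps}, index=geno.sample_ids
    )
    return traits


def simulate_abundances(
    cfg: SimConfig, traits: pd.DataFrame
) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """Gene FPKM and miRNA CPM matrices with planted correlations.

    Gene latents are standard normal with the requested Pearson r to the
    covariate-free trait signal (Gaussian copula); FPKM = 2**(mu + s*z)
    with a ``frac_low_expr`` fraction of genes given means below the
    FPKM >= 10 screen.  miRNA latents get planted negative correlations to
    their target genes' latents; CPM = 2**(mu + s*z).
    Only the first ``n_rnaseq_samples`` samples carry RNA-seq data.
    """
    rng = cfg.rng("abundances")
    core: pd.DataFrame | None = traits.attrs.get("core_signal")
    if core is None:
        # traits re-read from disk: fall back to covariate-adjusted residuals
        from .gwas import adjust_phenotypes

        core = adjust_phenotypes(traits)[list(BASE_TRAITS)]
    rna_samples = list(traits.index[: cfg.n_rnaseq_samples])
    n = len(rna_samples)
    base_names = list(BASE_TRAITS)

    eqtl_dos: pd.DataFrame | None = traits.attrs.get("eqtl_dosages")

    # gene latents: planted trait correlations plus planted SNP effects;
    # if a gene's summed r^2 exceeds 0.9 the r's are shrunk proportionally
    # to keep a valid correlation structure
    z_gene = rng.standard_normal((cfg.n_genes, n))
    planted: dict[int, list[tuple[np.ndarray, float]]] = {}
    for gi, ti, r in cfg.expr_trait_corr:
        t = core[base_names[ti]].loc[rna_samples].to_numpy()
        planted.setdefault(gi, []).append(((t - t.mean()) / t.std(), r))
    for snp_j, gi, r in cfg.eqtl_map:
        if eqtl_dos is None:
            warnings.warn("no eQTL dosages attached to traits; eQTL planting skipped")
            break
        d = eqtl_dos[snp_j].loc[rna_samples].to_numpy()
        planted.setdefault(gi, []).append(((d - d.mean()) / d.std(), r))
    for gi, targets in planted.items():
        tot = sum(r * r for _, r in targets)
        scale = np.sqrt(0.9 / tot) if tot > 0.9 else 1.0
        sig = np.zeros(n)
        for vec, r in targets:
            sig += (r * scale) * vec
        tot = min(tot, 0.9)
        z_gene[gi] = sig + np.sqrt(1.0 - tot) * rng.standard_normal(n)

    low = rng.random(cfg.n_genes) < cfg.frac_low_expr
    # keep genes carrying planted signal expressed (they must pass the screen)
    low[list(planted)] = False
    mu = np.where(low, rng.normal(1.2, 0.4, cfg.n_genes), rng.normal(5.0, 1.2, cfg.n_genes))
    s = rng.uniform(0.4, 0.8, cfg.n_genes)
    fpkm = np.power(2.0, mu[:, None] + s[:, None] * z_gene)

    gene_ids = [f"gene{g:04d}" for g in range(cfg.n_genes)]
    genes = AbundanceMatrix(
        pd.DataFrame(fpkm, index=gene_ids, columns=rna_samples), kind="mRNA"
    )

    # miRNA latents with planted negative correlations to target genes
    z_mir = rng.standard_normal((cfg.n_mirnas, n))
    for mi, gi, r in cfg.mirna_target_map:
        zg = (z_gene[gi] - z_gene[gi].mean()) / z_gene[gi].std()
        z_mir[mi] = r * zg + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    mu_m = rng.normal(6.0, 1.2, cfg.n_mirnas)
    s_m = rng.uniform(0.4, 0.8, cfg.n_mirnas)
    cpm = np.power(2.0, mu_m[:, None] + s_m[:, None] * z_mir)
    mir_ids = [f"mir{m:03d}" for m in range(cfg.n_mirnas)]
    mirnas = AbundanceMatrix(
        pd.DataFrame(cpm, index=mir_ids, columns=rna_samples), kind="miRNA"
    )
    return genes, mirnas


def simulate_annotation(cfg: SimConfig) -> pd.DataFrame:
    """Gene annotation table aligned with the simulated SNP map.

    Gene g is centered on SNP index g*stride (stride = n_snps / n_genes),
    with a body wide enough (+-110 kb at the default 100 kb SNP spacing)
    that a handful of nearby SNPs fall inside it at distance 0 and so
    pass the AWM proximity rule.  A random ~10% of genes are flagged TF
    or TF-cofactor.
    """
    rng = cfg.rng("annotation")
    snp_map = _snp_positions(cfg)
    rows = []
    stride = max(1, cfg.n_snps // max(cfg.n_genes, 1))
    half_width = 110_000
    for g in range(cfg.n_genes):
        j = (g * stride) % cfg.n_snps
        chrom = snp_map.loc[j, "chrom"]
        center = int(snp_map.loc[j, "bp"])
        rows.append(
            {
                "gene_id": f"gene{g:04d}",
                "chrom": chrom,
                "start": max(1, center - half_width),
                "end": center + half_width,
                "biotype": "coding",
                "tf_class": "none",
            }
        )
    ann = pd.DataFrame(rows)
    flags = rng.random(cfg.n_genes)
    ann.loc[flags < 0.05, "tf_class"] = "TF"
    ann.loc[(flags >= 0.05) & (flags < 0.10), "tf_class"] = "TF-cofactor"
    return ann
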