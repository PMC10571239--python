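"""Synthetic paired genotype/expression cohorts with planted pathway-routed effects.

The generator emulates the shape of a case/control neuroimaging-initiative
cohort: biallelic SNPs in Hardy-Weinberg proportions with a uniform MAF
spectrum, coding SNPs placed inside per-gene CDS intervals, genes assigned to
pathways (so the constraint mask is non-trivial), log-scale Gaussian
expression, and a three-level diagnosis (CN / MCI / AD) whose binary collapse
(CN vs MCI/AD) is driven by a logistic model on

    eta = beta_g * z(causal-pathway genotype burden) + beta_e * e + intercept

where e is a per-sample latent expression factor loaded onto the causal
expression genes.  The intercept is calibrated so the expected case fraction
matches the configured class mix.  SNPs are simulated independently (no
linkage disequilibrium).

All outputs are written in the exact formats the pipeline consumes (PLINK
trio, BED6, GMT, TSV), plus a ground-truth sidecar that the pipeline never
reads.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, VariantRecord, write_plink

_GENE_SPAN = 10_000  # bp allotted per gene on the synthetic chromosome
_CDS_OFFSET = 1_000
_CDS_LEN = 3_000


@dataclass
class SimConfig:
    n_samples: int = 626
    n_snps: int = 1500
    n_genes_geno: int = 300
    n_genes_expr: int = 200
    n_pathways: int = 186
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_pathways: int = 3
    beta_g: float = 1.0
    beta_e: float = 1.0
    n_causal_expr_genes: int = 10
    intercept: float | None = None  # None -> calibrated to the class mix
    class_mix: tuple[int, int, int] = (212, 317, 97)  # CN, MCI, AD
    frac_intergenic_snps: float = 0.10
    frac_unpathwayed_genes: float = 0.05
    max_pathways_per_gene: int = 3
    expr_location: float = 7.0  # log2-intensity-like scale
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_samples, self.n_snps, self.n_genes_geno,
                  self.n_genes_expr, self.n_pathways, self.n_causal_pathways,
                  self.n_causal_expr_genes)
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not all(np.isfinite([self.beta_g, self.beta_e])):
            raise ValueError("effect sizes must be finite")
        if any(c < 0 for c in self.class_mix) or sum(self.class_mix) == 0:
            raise ValueError(f"infeasible class mix {self.class_mix}")
        if self.class_mix[1] + self.class_mix[2] == 0 or self.class_mix[0] == 0:
            raise ValueError("class mix needs both CN and MCI/AD mass")


@dataclass
class SimTruth:
    causal_pathways: list[str]
    causal_geno_genes: list[str]
    causal_expr_genes: list[str]
    linear_predictor: np.ndarray
    label_probs: np.ndarray

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# ground truth sidecar; never read by the pipeline\n")
            fh.write("kind\tname\tvalue\n")
            for p in self.causal_pathways:
                fh.write(f"causal_pathway\t{p}\t1\n")
            for g in self.causal_geno_genes:
                fh.write(f"causal_geno_gene\t{g}\t1\n")
            for g in self.causal_expr_genes:
                fh.write(f"causal_expr_gene\t{g}\t1\n")
            for i, (eta, pr) in enumerate(zip(self.linear_predictor, self.label_probs)):
                fh.write(f"sample\tS{i:04d}\t{eta:.6f},{pr:.6f}\n")


@dataclass
class SimCohort:
    config: SimConfig
    genotypes: GenotypeMatrix
    cds: list[tuple[str, int, int, str]]
    gene_sets: list[tuple[str, str, list[str]]]  # (name, description, members)
    expression: pd.DataFrame  # samples x expression genes
    phenotypes: pd.Series  # CN / MCI / AD per sample
    truth: SimTruth
    paths: dict[str, str] = field(default_factory=dict)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(eta0: np.ndarray, target: float) -> float:
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(eta0 + mid).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(cfg: SimConfig, out_dir=None) -> SimCohort:
    """Draw one cohort; if ``out_dir`` is given, also write all pipeline inputs.

    Same seed -> byte-identical output files.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    geno_genes = [f"GENE{i:04d}" for i in range(cfg.n_genes_geno)]
    expr_genes = [f"EXPR{i:04d}" for i in range(cfg.n_genes_expr)]
    pathway_names = [f"PATHWAY_{j:03d}" for j in range(cfg.n_pathways)]

    # --- genome layout: one CDS interval per gene on chromosome 1 ----------
    cds = [
        ("1", i * _GENE_SPAN + _CDS_OFFSET, i * _GENE_SPAN + _CDS_OFFSET + _CDS_LEN, g)
        for i, g in enumerate(geno_genes)
    ]

    n_coding = int(round((1.0 - cfg.frac_intergenic_snps) * cfg.n_snps))
    gene_of_snp = rng.integers(0, cfg.n_genes_geno, size=n_coding)
    used: set[int] = set()

    def draw_pos(lo: int, hi: int) -> int:
        while True:  # redraw within the same window to keep positions unique
            p = int(rng.integers(lo, hi)) + 1  # 1-based
            if p not in used:
                used.add(p)
                return p

    positions = []
    for gi in gene_of_snp:
        start = int(gi) * _GENE_SPAN + _CDS_OFFSET
        positions.append(draw_pos(start, start + _CDS_LEN))
    for _ in range(cfg.n_snps - n_coding):  # intergenic, between CDS blocks
        gi = int(rng.integers(0, cfg.n_genes_geno))
        start = gi * _GENE_SPAN + _CDS_OFFSET + _CDS_LEN + 1_000
        positions.append(draw_pos(start, start + 2_000))

    order = np.argsort(positions, kind="stable")
    alleles = np.array(list("ACGT"))
    variants = []
    for rank, idx in enumerate(order):
        a = rng.choice(4, size=2, replace=False)
        variants.append(VariantRecord(
            snp_id=f"rs{rank + 1:06d}", chrom="1", pos=positions[idx],
            allele_minor=str(alleles[a[0]]), allele_major=str(alleles[a[1]]),
        ))

    maf = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    codes = rng.binomial(2, maf[None, :], size=(cfg.n_samples, cfg.n_snps)).astype(np.int8)
    genotypes = GenotypeMatrix(samples=samples, variants=variants, codes=codes)

    # --- pathway membership -------------------------------------------------
    members: dict[str, list[str]] = {p: [] for p in pathway_names}
    gene_pathways: dict[str, list[str]] = {}
    n_unpathwayed = int(round(cfg.frac_unpathwayed_genes * cfg.n_genes_geno))
    pathwayed = geno_genes[: cfg.n_genes_geno - n_unpathwayed]
    for g in pathwayed:
        k = int(rng.integers(1, cfg.max_pathways_per_gene + 1))
        for j in rng.choice(cfg.n_pathways, size=min(k, cfg.n_pathways), replace=False):
            members[pathway_names[j]].append(g)
            gene_pathways.setdefault(g, []).append(pathway_names[j])
    for p in pathway_names:  # GMT sets must be non-empty
        if not members[p]:
            g = pathwayed[int(rng.integers(0, len(pathwayed)))]
            members[p].append(g)
            gene_pathways.setdefault(g, []).append(p)
    gene_sets = [(p, "synthetic gene set", members[p]) for p in pathway_names]

    # --- planted effects ----------------------------------------------------
    eligible = [p for p in pathway_names if len(members[p]) >= 2] or pathway_names
    causal_pathways = [
        eligible[j] for j in rng.choice(len(eligible),
                                        size=min(cfg.n_causal_pathways, len(eligible)),
                                        replace=False)
    ]
    causal_geno_genes = sorted({g for p in causal_pathways for g in members[p]})
    causal_gene_idx = {g for g in causal_geno_genes}
    snp_in_causal = np.array([
        geno_genes[gene_of_snp[i]] in causal_gene_idx if i < n_coding else False
        for i in range(cfg.n_snps)
    ])[order]
    # plant the effect on cohort-folded codes, i.e. what the pipeline's
    # allele normalization produces after subsetting
    col_freq = codes.mean(axis=0) / 2.0
    folded = np.where(col_freq[None, :] > 0.5, 2 - codes, codes)
    burden = folded[:, snp_in_causal].sum(axis=1).astype(float)
    sd = burden.std()
    z_g = (burden - burden.mean()) / sd if sd > 0 else np.zeros_like(burden)

    latent = rng.normal(size=cfg.n_samples)
    causal_expr = [
        expr_genes[j] for j in rng.choice(cfg.n_genes_expr,
                                          size=min(cfg.n_causal_expr_genes, cfg.n_genes_expr),
                                          replace=False)
    ]
    expr = rng.normal(loc=cfg.expr_location, scale=1.0,
                      size=(cfg.n_samples, cfg.n_genes_expr))
    for g in causal_expr:
        j = expr_genes.index(g)
        # unit loading on the latent disease factor, modest per-gene noise:
        # the case-control mean shift of each causal gene tracks beta_e's
        # contribution to the liability
        expr[:, j] = cfg.expr_location + latent + 0.5 * rng.normal(size=cfg.n_samples)
    expression = pd.DataFrame(expr, index=samples, columns=expr_genes)

    # --- labels -------------------------------------------------------------
    cn, mci, ad = cfg.class_mix
    case_frac = (mci + ad) / (cn + mci + ad)
    eta0 = cfg.beta_g * z_g + cfg.beta_e * latent
    intercept = (cfg.intercept if cfg.intercept is not None
                 else _calibrate_intercept(eta0, case_frac))
    eta = eta0 + intercept
    probs = _sigmoid(eta)
    is_case = rng.random(cfg.n_samples) < probs
    mci_frac = mci / (mci + ad)
    stage = np.where(rng.random(cfg.n_samples) < mci_frac, "MCI", "AD")
    labels3 = pd.Series(np.where(is_case, stage, "CN"), index=samples, name="diagnosis")
    for cls in ("CN", "MCI", "AD"):  # splits need every stratum populated
        if (labels3 == cls).sum() < 3:
            raise ValueError(
                f"class mix {cfg.class_mix} at n={cfg.n_samples} left stratum "
                f"{cls!r} with <3 samples; infeasible configuration"
            )

    truth = SimTruth(
        causal_pathways=sorted(causal_pathways),
        causal_geno_genes=causal_geno_genes,
        causal_expr_genes=sorted(causal_expr),
        linear_predictor=eta,
        label_probs=probs,
    )
    cohort = SimCohort(config=cfg, genotypes=genotypes, cds=cds, gene_sets=gene_sets,
                       expression=expression, phenotypes=labels3, truth=truth)
    if out_dir is not None:
        cohort.paths = write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: SimCohort, out_dir) -> dict[str, str]:
    """Write every pipeline input format; deterministic bytes for a fixed cohort."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    prefix = os.path.join(out_dir, "cohort")
    bed, bim, fam = write_plink(cohort.genotypes, prefix)

    cds_path = os.path.join(out_dir, "cds.bed")
    with open(cds_path, "w") as fh:
        for chrom, start, end, gene in cohort.cds:
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\t0\t+\n")

    gmt_path = os.path.join(out_dir, "pathways.gmt")
    with open(gmt_path, "w") as fh:
        for name, desc, genes in cohort.gene_sets:
            fh.write("\t".join((name, desc, *genes)) + "\n")

    expr_path = os.path.join(out_dir, "expression.tsv")
    df = cohort.expression.copy()
    df.index.name = "sample_id"
    df.to_csv(expr_path, sep="\t", float_format="%.6f")

    pheno_path = os.path.join(out_dir, "phenotype.tsv")
    pheno = cohort.phenotypes.rename_axis("sample_id").reset_index()
    pheno.to_csv(pheno_path, sep="\t", index=False)

    truth_path = os.path.join(out_dir, "truth.tsv")
    cohort.truth.to_tsv(truth_path)

    return {"bed": bed, "bim": bim, "fam": fam, "cds": cds_path, "gmt": gmt_path,
            "expression": expr_path, "phenotype": pheno_path, "truth": truth_path}


FIXTURE_CONFIG = SimConfig(
    n_samples=160,
    n_snps=400,
    n_genes_geno=50,
    n_genes_expr=40,
    n_pathways=186,
    n_causal_pathways=2,
    beta_g=2.0,
    beta_e=2.0,
    n_causal_expr_genes=6,
    class_mix=(54, 81, 25),
    seed=2024,
)


def small_fixture(out_dir=None) -> SimCohort:
    """Deterministic miniature cohort exercising the full 186-pathway mask width.

    Small enough (160 samples, 400 SNPs, 50 genotype genes) that the complete
    encode -> mask -> prep -> train -> evaluate chain runs in seconds.
    """
    return simulate_cohort(FIXTURE_CONFIG, out_dir=out_dir)
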