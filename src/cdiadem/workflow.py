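"""End-to-end glue: encode -> mask -> prep -> train -> evaluate -> explain.

Thin orchestration over the stage modules so the CLI, the test-suite and
scripted studies all run the identical pipeline.  Expression values are
z-scored per gene with training-split statistics; gene burdens are fed raw.
SMOTE balances the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import attribution as attr_mod
from . import cohort as cohort_mod
from . import evaluation
from . import genotypes as geno_mod
from . import network as net_mod
from . import pathways as path_mod


def encode_genotypes(bed_path, bim_path, fam_path, cds_path,
                     maf_threshold: float = 0.05,
                     impute_missing: bool = False) -> geno_mod.GeneAggregateMatrix:
    """Read a PLINK trio, normalize alleles, MAF-filter, and aggregate per gene."""
    gm = geno_mod.read_plink(bed_path, bim_path, fam_path)
    gm = geno_mod.normalize_alleles(gm)
    gm = geno_mod.filter_maf(gm, maf_threshold)
    gene_map = geno_mod.map_snps_to_genes(gm.variants, cds_path)
    return geno_mod.aggregate_by_gene(gm, gene_map, impute_missing=impute_missing)


@dataclass
class PreparedData:
    split: cohort_mod.SplitBundle
    train_geno: np.ndarray  # SMOTE-balanced
    train_expr: np.ndarray
    train_onehot: np.ndarray
    val_geno: np.ndarray
    val_expr: np.ndarray
    val_onehot: np.ndarray
    test_geno: np.ndarray
    test_expr: np.ndarray
    test_labels: np.ndarray  # binary 0/1, natural prevalence
    geno_genes: list[str]
    expr_genes: list[str]


def prepare(bundle: cohort_mod.CohortBundle,
            fractions=(0.56, 0.30, 0.14),
            k_neighbors: int = 5,
            seed: int = 0) -> PreparedData:
    """Stratified split, expression scaling, SMOTE on the training split."""
    split = cohort_mod.stratified_split(bundle, fractions=fractions, seed=seed)
    train = split.view("train")
    test = split.view("test")
    val = split.view("validation")

    mu, sd = cohort_mod.zscore_fit(train.expr)
    expr = {name: cohort_mod.zscore_apply(v.expr, mu, sd).to_numpy()
            for name, v in (("train", train), ("test", test), ("validation", val))}

    n_geno = train.geno.shape[1]
    stacked = np.hstack([train.geno.to_numpy(dtype=float), expr["train"]])
    balanced, labels_bal = cohort_mod.smote_oversample(
        stacked, train.labels2.to_numpy(), k_neighbors=k_neighbors, seed=seed
    )
    return PreparedData(
        split=split,
        train_geno=balanced[:, :n_geno],
        train_expr=balanced[:, n_geno:],
        train_onehot=cohort_mod.one_hot(labels_bal),
        val_geno=val.geno.to_numpy(dtype=float),
        val_expr=expr["validation"],
        val_onehot=cohort_mod.one_hot(val.labels2.to_numpy()),
        test_geno=test.geno.to_numpy(dtype=float),
        test_expr=expr["test"],
        test_labels=(test.labels2.to_numpy() == cohort_mod.POSITIVE).astype(int),
        geno_genes=list(train.geno.columns),
        expr_genes=list(train.expr.columns),
    )


@dataclass
class StudyResult:
    trained: net_mod.TrainedModel
    report: evaluation.EvalReport
    prepared: PreparedData
    mask: path_mod.PathwayMask


def run_study(geno_agg: geno_mod.GeneAggregateMatrix,
              expression: pd.DataFrame,
              phenotypes: pd.Series,
              collection: path_mod.GeneSetCollection,
              config: net_mod.ModelConfig | None = None,
              constrained: bool = True,
              fractions=(0.56, 0.30, 0.14),
              k_neighbors: int = 5,
              seed: int = 0) -> StudyResult:
    """Train one model on an aligned cohort and evaluate it on the test split."""
    config = config or net_mod.ModelConfig(seed=seed)
    bundle = cohort_mod.align_cohort(geno_agg.to_frame(), expression, phenotypes)
    prepared = prepare(bundle, fractions=fractions, k_neighbors=k_neighbors, seed=seed)
    mask = path_mod.build_mask(prepared.geno_genes, collection)

    if constrained:
        model = net_mod.build_constrained_model(config, mask, len(prepared.expr_genes))
    else:
        model = net_mod.build_unconstrained_model(
            config, len(prepared.geno_genes), len(prepared.expr_genes),
            width=mask.n_pathways,
        )
    trained = net_mod.train(
        model,
        (prepared.train_geno, prepared.train_expr, prepared.train_onehot),
        (prepared.val_geno, prepared.val_expr, prepared.val_onehot),
        config,
    )
    probs = net_mod.predict(model, prepared.test_geno, prepared.test_expr).probs
    report = evaluation.evaluate(prepared.test_labels, probs[:, 1])
    return StudyResult(trained=trained, report=report, prepared=prepared, mask=mask)


def simulate_and_run(sim_cfg,
                     config: net_mod.ModelConfig | None = None,
                     constrained: bool = True,
                     maf_threshold: float = 0.05):
    """Draw a synthetic cohort and push it through the complete pipeline.

    Uses the simulation seed for the split/SMOTE/model seeds as well, so one
    integer reproduces the whole study.  Returns (StudyResult, SimCohort).
    """
    from . import simulate as sim_mod

    c = sim_mod.simulate_cohort(sim_cfg)
    gm = geno_mod.normalize_alleles(c.genotypes)
    gm = geno_mod.filter_maf(gm, maf_threshold)
    gene_map = geno_mod.map_snps_to_genes(gm.variants, c.cds)
    agg = geno_mod.aggregate_by_gene(gm, gene_map)
    collection = path_mod.GeneSetCollection(
        [path_mod.GeneSet(n, d, tuple(m)) for n, d, m in c.gene_sets]
    )
    config = config or net_mod.ModelConfig(seed=sim_cfg.seed)
    result = run_study(agg, c.expression, c.phenotypes, collection,
                       config=config, constrained=constrained, seed=sim_cfg.seed)
    return result, c


def explain_study(result: StudyResult,
                  n_background: int = 100,
                  n_explain: int = 40,
                  n_coalitions: int = 32,
                  k: int = 20,
                  seed: int = 0):
    """Shapley attribution of the trained model on (a subset of) the test split.

    Background = a seeded random subset of the balanced training samples.
    Returns ({branch: AttributionMatrix}, {branch: FeatureRanking}).
    """
    rng = np.random.default_rng(seed)
    p = result.prepared
    n_bg = min(n_background, p.train_geno.shape[0])
    bg_idx = rng.choice(p.train_geno.shape[0], size=n_bg, replace=False)
    n_ex = min(n_explain, p.test_geno.shape[0])
    ex_idx = rng.choice(p.test_geno.shape[0], size=n_ex, replace=False)

    test_view = result.prepared.split.view("test")
    geno_df = pd.DataFrame(p.test_geno[ex_idx], columns=p.geno_genes,
                           index=[test_view.samples[i] for i in ex_idx])
    expr_df = pd.DataFrame(p.test_expr[ex_idx], columns=p.expr_genes,
                           index=list(geno_df.index))
    attr_g, attr_e = attr_mod.shapley_attribute(
        result.trained.model,
        p.train_geno[bg_idx], p.train_expr[bg_idx],
        geno_df, expr_df,
        n_coalitions=n_coalitions, seed=seed,
    )
    attrs = {"genotype": attr_g, "expression": attr_e}
    rankings = {b: attr_mod.rank_features(a, k=k) for b, a in attrs.items()}
    return attrs, rankings
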