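"""Shapley-value feature attribution and top-k biomarker ranking.

A model-agnostic sampling-permutation estimator: for each explained sample a
random feature ordering is drawn, features are revealed one at a time on top
of a background sample, and each feature is credited with its marginal change
in the positive-class (MCI/AD) probability.  Averaging over orderings gives
an unbiased estimate of the Shapley value of the game v(S) = f(x_S, b_not-S)
marginalized over the background set.  Because each ordering telescopes from
f(b) to f(x), local accuracy holds exactly:

    sum_i phi_i  =  f(x) - mean_b f(b)   for every explained sample.

Backgrounds are cycled deterministically over the permutations, so with
n_permutations a multiple of the background size every background is used
equally often.  Both input branches are attributed jointly as one game over
the concatenated feature vector, then split back into branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import DualInputNetwork, predict

_CHUNK_ROWS = 8192


@dataclass
class AttributionMatrix:
    """Per-sample Shapley values for one input branch."""

    values: pd.DataFrame  # explained samples x features
    baseline: float  # E[f(background)] over the backgrounds actually used
    branch: str  # "genotype" | "expression"

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        df = self.values.copy()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


@dataclass
class FeatureRanking:
    table: pd.DataFrame  # columns: feature, mean_abs_shap; descending
    k: int
    top_k: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.top_k = self.table.head(min(self.k, len(self.table))).reset_index(drop=True)


def shapley_values(f, X, background, n_permutations: int, rng: np.random.Generator):
    """Permutation-sampling Shapley estimates for callable ``f`` on rows of X.

    ``f`` maps a 2D float array to a 1D array of outputs.  Returns
    (phi matrix, baseline scalar).
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if background.shape[0] == 0:
        raise ValueError("background must be non-empty")
    n, d = X.shape
    n_bg = background.shape[0]

    bg_cycle = np.arange(n_permutations) % n_bg
    baseline = float(np.asarray(f(background), dtype=float)[bg_cycle].mean())

    phi = np.zeros((n, d))
    perms_per_chunk = max(1, _CHUNK_ROWS // (d + 1))
    for i in range(n):
        x = X[i]
        for start in range(0, n_permutations, perms_per_chunk):
            chunk = range(start, min(start + perms_per_chunk, n_permutations))
            rows = []
            perms = []
            for p in chunk:
                perm = rng.permutation(d)
                perms.append(perm)
                b = background[bg_cycle[p]]
                pos = np.empty(d, dtype=int)
                pos[perm] = np.arange(d)
                # row k: features with permutation position < k revealed from x
                reveal = pos[None, :] < np.arange(d + 1)[:, None]
                rows.append(np.where(reveal, x[None, :], b[None, :]))
            vals = np.asarray(f(np.concatenate(rows, axis=0)), dtype=float)
            vals = vals.reshape(len(perms), d + 1)
            marginals = np.diff(vals, axis=1)  # contribution of perm[k] at step k
            for perm, m in zip(perms, marginals):
                phi[i, perm] += m
    phi /= n_permutations
    return phi, baseline


def shapley_attribute(model: DualInputNetwork,
                      background_geno, background_expr,
                      explain_geno, explain_expr,
                      n_coalitions: int = 64,
                      seed: int = 0) -> tuple[AttributionMatrix, AttributionMatrix]:
    """Joint Shapley attribution of both branches for the MCI/AD probability.

    One game is played over the concatenated [genotype | expression] feature
    vector, then the attribution matrix is split back into the two branches.
    """
    bg_g = np.asarray(background_geno, dtype=float)
    bg_e = np.asarray(background_expr, dtype=float)
    ex_g_df = explain_geno if isinstance(explain_geno, pd.DataFrame) else None
    ex_e_df = explain_expr if isinstance(explain_expr, pd.DataFrame) else None
    ex_g = np.asarray(explain_geno, dtype=float)
    ex_e = np.asarray(explain_expr, dtype=float)
    ng = ex_g.shape[1]

    def f(Z):
        return predict(model, Z[:, :ng], Z[:, ng:]).probs[:, 1]

    rng = np.random.default_rng(seed)
    phi, baseline = shapley_values(
        f, np.hstack([ex_g, ex_e]), np.hstack([bg_g, bg_e]), n_coalitions, rng
    )
    geno_cols = list(ex_g_df.columns) if ex_g_df is not None else [f"gene_{j}" for j in range(ng)]
    expr_cols = (list(ex_e_df.columns) if ex_e_df is not None
                 else [f"expr_{j}" for j in range(ex_e.shape[1])])
    index = list(ex_g_df.index) if ex_g_df is not None else list(range(ex_g.shape[0]))
    return (
        AttributionMatrix(pd.DataFrame(phi[:, :ng], index=index, columns=geno_cols),
                          baseline, "genotype"),
        AttributionMatrix(pd.DataFrame(phi[:, ng:], index=index, columns=expr_cols),
                          baseline, "expression"),
    )


def rank_features(attr: AttributionMatrix, k: int = 20) -> FeatureRanking:
    """Rank features by mean |Shapley value|, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = attr.values.abs().mean(axis=0)
    order = np.lexsort((np.array(scores.index, dtype=object), -scores.to_numpy()))
    table = pd.DataFrame({
        "feature": scores.index.to_numpy()[order],
        "mean_abs_shap": scores.to_numpy()[order],
    })
    return FeatureRanking(table=table, k=k)


def attribution_report(rankings: dict[str, FeatureRanking],
                       attributions: dict[str, AttributionMatrix],
                       out_dir, k: int = 20) -> dict[str, str]:
    """Write per-branch top-k tables, plot-data TSVs and beeswarm-style figures."""
    import os

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    written = {}
    for branch, ranking in rankings.items():
        top_path = os.path.join(out_dir, f"top{k}_{branch}.tsv")
        ranking.top_k.to_csv(top_path, sep="\t", index=False)
        written[f"top_{branch}"] = top_path

        attr = attributions[branch]
        feats = ranking.top_k["feature"].tolist()
        plot_data = attr.values[feats].melt(var_name="feature", value_name="shap_value")
        data_path = os.path.join(out_dir, f"beeswarm_{branch}.tsv")
        plot_data.to_csv(data_path, sep="\t", index=False)
        written[f"plot_data_{branch}"] = data_path

        fig, ax = plt.subplots(figsize=(6, 0.3 * len(feats) + 1.5))
        rng = np.random.default_rng(0)
        for y, feat in enumerate(reversed(feats)):
            vals = attr.values[feat].to_numpy()
            jitter = rng.uniform(-0.25, 0.25, size=vals.size)
            ax.scatter(vals, np.full(vals.size, y) + jitter, s=8, alpha=0.6)
        ax.set_yticks(range(len(feats)))
        ax.set_yticklabels(list(reversed(feats)), fontsize=7)
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("Shapley value (impact on P(MCI/AD))")
        ax.set_title(f"Top {len(feats)} features — {branch} branch")
        fig.tight_layout()
        fig_path = os.path.join(out_dir, f"beeswarm_{branch}.png")
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)
        written[f"figure_{branch}"] = fig_path
    return written
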