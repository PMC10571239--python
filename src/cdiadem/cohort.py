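"""Cohort assembly: modality alignment, stratified splitting, SMOTE balancing, label encoding.

The binary classification target is CN vs MCI/AD, but splitting stratifies on
the three-level diagnosis (CN / MCI / AD) so each split preserves the cohort's
diagnostic composition.  SMOTE is applied to the training split only, on the
concatenation of the two input blocks (gene burdens | expression) so synthetic
samples stay coherent across modalities; validation and test retain their
natural class prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

CLASSES3 = ("CN", "MCI", "AD")
NEGATIVE, POSITIVE = "CN", "MCI/AD"


@dataclass
class CohortBundle:
    """Sample-aligned genotype burdens, expression, and diagnosis labels."""

    samples: list[str]
    geno: pd.DataFrame  # samples x genotype genes
    expr: pd.DataFrame  # samples x expression genes
    labels3: pd.Series  # CN / MCI / AD

    def __post_init__(self) -> None:
        for name, obj in (("geno", self.geno), ("expr", self.expr), ("labels3", self.labels3)):
            if list(obj.index) != list(self.samples):
                raise ValueError(f"{name} index does not match the sample list")
        bad = set(self.labels3) - set(CLASSES3)
        if bad:
            raise ValueError(f"unknown diagnosis labels: {sorted(bad)}")

    @property
    def labels2(self) -> pd.Series:
        return self.labels3.map(lambda d: NEGATIVE if d == "CN" else POSITIVE)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, indices: np.ndarray) -> "CohortBundle":
        samples = [self.samples[i] for i in indices]
        return CohortBundle(
            samples=samples,
            geno=self.geno.iloc[indices],
            expr=self.expr.iloc[indices],
            labels3=self.labels3.iloc[indices],
        )


def align_cohort(geno: pd.DataFrame, expr: pd.DataFrame, phenotypes: pd.Series) -> CohortBundle:
    """Restrict all modalities to their common samples, in genotype order."""
    common = [s for s in geno.index if s in expr.index and s in phenotypes.index]
    if not common:
        raise ValueError("no samples shared across genotype, expression and phenotype tables")
    return CohortBundle(
        samples=common,
        geno=geno.loc[common],
        expr=expr.loc[common],
        labels3=phenotypes.loc[common],
    )


def read_phenotypes(path) -> pd.Series:
    """Phenotype TSV with columns sample_id, diagnosis."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "diagnosis"} <= set(df.columns):
        raise ValueError(f"{path}: phenotype table needs sample_id and diagnosis columns")
    return df.set_index("sample_id")["diagnosis"]


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------

@dataclass
class SplitBundle:
    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray
    bundle: CohortBundle

    def __post_init__(self) -> None:
        parts = [self.train, self.test, self.validation]
        joined = np.concatenate(parts)
        if len(set(joined.tolist())) != joined.size or joined.size != self.bundle.n_samples:
            raise ValueError("split indices must partition the cohort exactly")

    def view(self, which: str) -> CohortBundle:
        return self.bundle.subset(getattr(self, which))

    def manifest(self) -> pd.DataFrame:
        rows = []
        for which in ("train", "test", "validation"):
            for i in getattr(self, which):
                rows.append((self.bundle.samples[i], which))
        return pd.DataFrame(rows, columns=["sample_id", "split"])


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    # hand the leftover units to the largest fractional remainders (stable ties)
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def stratified_split(
    bundle: CohortBundle,
    fractions: tuple[float, float, float] = (0.56, 0.30, 0.14),
    seed: int = 0,
) -> SplitBundle:
    """Per-stratum train/test/validation allocation by largest-remainder rounding.

    Strata are the three diagnosis classes; each needs at least 3 samples.
    Reproducible for a fixed seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    parts: dict[str, list[np.ndarray]] = {"train": [], "test": [], "validation": []}
    labels = bundle.labels3.to_numpy()
    for stratum in CLASSES3:
        idx = np.flatnonzero(labels == stratum)
        if idx.size == 0:
            continue
        if idx.size < 3:
            raise ValueError(f"stratum {stratum!r} has only {idx.size} samples; need >= 3")
        rng.shuffle(idx)
        n_train, n_test, n_val = _largest_remainder(idx.size, tuple(fractions))
        parts["train"].append(idx[:n_train])
        parts["test"].append(idx[n_train:n_train + n_test])
        parts["validation"].append(idx[n_train + n_test:])
    return SplitBundle(
        train=np.sort(np.concatenate(parts["train"])),
        test=np.sort(np.concatenate(parts["test"])),
        validation=np.sort(np.concatenate(parts["validation"])),
        bundle=bundle,
    )


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_oversample(
    features: np.ndarray,
    labels2: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to exact class balance.

    Each synthetic sample is x + lam * (x' - x) with lam ~ U[0, 1], x a
    minority sample and x' one of its ``k_neighbors`` nearest minority
    neighbours (Euclidean).  Originals are preserved verbatim and come first
    in the output; already-balanced input is returned unchanged.
    """
    features = np.asarray(features, dtype=float)
    labels2 = np.asarray(labels2)
    if features.shape[0] != labels2.shape[0]:
        raise ValueError("features and labels differ in length")
    classes, counts = np.unique(labels2, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes.tolist()}")
    if counts[0] == counts[1]:
        return features, labels2

    minority = classes[np.argmin(counts)]
    n_new = int(abs(counts[0] - counts[1]))
    min_idx = np.flatnonzero(labels2 == minority)
    if min_idx.size <= k_neighbors:
        raise ValueError(
            f"minority class has {min_idx.size} samples, need > k_neighbors={k_neighbors}; "
            "use a smaller k"
        )
    X_min = features[min_idx]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]  # drop self

    rng = np.random.default_rng(seed)
    base = rng.integers(0, X_min.shape[0], size=n_new)
    pick = rng.integers(0, k_neighbors, size=n_new)
    lam = rng.random(n_new)
    x = X_min[base]
    x_prime = X_min[neigh[base, pick]]
    synthetic = x + lam[:, None] * (x_prime - x)

    features_out = np.vstack([features, synthetic])
    labels_out = np.concatenate([labels2, np.full(n_new, minority, dtype=labels2.dtype)])
    return features_out, labels_out


def one_hot(labels2) -> np.ndarray:
    """CN -> (1, 0); MCI/AD -> (0, 1)."""
    labels2 = np.asarray(labels2)
    out = np.zeros((labels2.shape[0], 2), dtype=float)
    for i, lab in enumerate(labels2):
        if lab == NEGATIVE:
            out[i, 0] = 1.0
        elif lab == POSITIVE:
            out[i, 1] = 1.0
        else:
            raise ValueError(f"unknown binary label {lab!r}")
    return out


def zscore_fit(X: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-feature mean/std from training data (std floored at 1e-8)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0).clip(lower=1e-8)
    return mu, sd


def zscore_apply(X: pd.DataFrame, mu: pd.Series, sd: pd.Series) -> pd.DataFrame:
    return (X - mu) / sd
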