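"""The constrained dual-input classifier and its unconstrained comparator.

The constrained network routes per-gene SNP burdens through a pathway layer
whose gene -> pathway edges are fixed by a binary membership mask (absent
edges are exactly zero throughout training), transforms the pathway features
with a length-preserving 1D convolution, and fuses the result with a dense
embedding of the expression input before batch normalization, three hidden
layers and a 2-node softmax output (CN vs MCI/AD).  The comparator replaces
the pathway machinery with an unconstrained dense layer plus an
embedding-style (width, 3) expansion, and has no hidden stack.

Layer stack (constrained, 14 layers counting both inputs):

    geno input (n_genes) -> masked dense (P) -> reshape (P, 1)
      -> conv1d (P, 12) -> flatten (12 P) -> dense (150)
    expr input (n_expr)  -> dense (150)
    concatenate (300) -> batch norm -> dense (180) -> dense (30)
      -> dense (15) -> dense (2, softmax)

With the 186-pathway mask this reproduces the published widths
(flatten 2232, concatenation 300).
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .layers import (
    Adam, BatchNorm, Conv1D, Dense, Flatten, Input, Layer, MaskedDense,
    PositionwiseExpansion, Reshape, cross_entropy, softmax,
)
from .pathways import PathwayMask
from . import evaluation


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier; published values are the defaults."""

    conv_filters: int = 12
    conv_kernel: int = 12
    branch_dense: int = 150
    hidden: tuple[int, int, int] = (180, 30, 15)
    n_outputs: int = 2
    embedding_depth: int = 3
    bn_momentum: float = 0.99
    bn_epsilon: float = 1e-3
    loss: str = "binary_crossentropy"
    optimizer: str = "adam"
    learning_rate: float = 0.005
    epochs: int = 80
    batch_size: int = 32
    early_stop_monitor: str = "val_loss"
    patience: int = 10
    min_delta: float = 0.0
    hidden_activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        widths = (self.conv_filters, self.branch_dense, *self.hidden, self.n_outputs)
        if any(w < 1 for w in widths):
            raise ValueError("all layer widths must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


class _Concatenate(Layer):
    def __init__(self, widths: tuple[int, int], name: str = "concatenate"):
        self.widths = widths
        self.name = name

    def forward(self, parts, training=False):
        return np.concatenate(parts, axis=1)

    def backward(self, grad):
        return grad[:, :self.widths[0]], grad[:, self.widths[0]:]


class DualInputNetwork:
    """Two input branches joined by concatenation and a shared trunk."""

    def __init__(self, geno_branch, expr_branch, trunk, manifest, kind: str,
                 config: ModelConfig, mask_bits=None):
        self.geno_branch = geno_branch
        self.expr_branch = expr_branch
        self.trunk = trunk
        self.manifest = manifest  # list of (layer name, output shape, n params)
        self.kind = kind
        self.config = config
        self.mask_bits = mask_bits
        self._concat = _Concatenate((geno_branch[-1].b.size, expr_branch[-1].b.size))

    # -- plumbing -----------------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        return [*self.geno_branch, *self.expr_branch, *self.trunk]

    @property
    def n_layers(self) -> int:
        return len(self.manifest)

    def forward(self, geno: np.ndarray, expr: np.ndarray, training: bool = False) -> np.ndarray:
        hg = np.asarray(geno, dtype=float)
        for layer in self.geno_branch:
            hg = layer.forward(hg, training)
        he = np.asarray(expr, dtype=float)
        for layer in self.expr_branch:
            he = layer.forward(he, training)
        h = self._concat.forward((hg, he), training)
        for layer in self.trunk:
            h = layer.forward(h, training)
        return h  # logits

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.trunk):
            g = layer.backward(g)
        gg, ge = self._concat.backward(g)
        for layer in reversed(self.geno_branch):
            gg = layer.backward(gg)
        for layer in reversed(self.expr_branch):
            ge = layer.backward(ge)

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for l in self.layers for p in l.params]
        for l in self.layers:
            if isinstance(l, BatchNorm):
                state.extend([l.running_mean.copy(), l.running_var.copy()])
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for l in self.layers:
            for p in l.params:
                p[...] = next(it)
        for l in self.layers:
            if isinstance(l, BatchNorm):
                l.running_mean[...] = next(it)
                l.running_var[...] = next(it)

    def write_manifest(self, path) -> None:
        """Plain-text architecture manifest for framework-free auditing."""
        with open(path, "w") as fh:
            fh.write("layer\toutput_shape\tn_params\n")
            for name, shape, n in self.manifest:
                fh.write(f"{name}\t{shape}\t{n}\n")


def _check(name: str, got, expected) -> None:
    if got != expected:
        raise ValueError(f"layer {name!r}: output shape {got}, expected {expected}")


def build_constrained_model(config: ModelConfig, mask: PathwayMask,
                            n_expr_genes: int) -> DualInputNetwork:
    """Assemble the pathway-constrained network; raises if any shape deviates."""
    rng = np.random.default_rng(config.seed)
    P = mask.n_pathways
    n_genes = mask.n_genes
    act = config.hidden_activation

    geno = [
        Input(n_genes, "geno_input"),
        MaskedDense(mask.bits.astype(float), rng, activation=act, name="pathways"),
        Reshape((P, 1), name="reshape"),
        Conv1D(1, config.conv_filters, config.conv_kernel, rng, activation=act, name="conv1d"),
        Flatten(name="flatten"),
    ]
    flat_width = P * config.conv_filters
    geno.append(Dense(flat_width, config.branch_dense, rng, activation=act, name="geno_dense"))

    expr = [
        Input(n_expr_genes, "expr_input"),
        Dense(n_expr_genes, config.branch_dense, rng, activation=act, name="expr_dense"),
    ]

    concat_width = 2 * config.branch_dense
    trunk: list[Layer] = [BatchNorm(concat_width, config.bn_momentum, config.bn_epsilon)]
    w = concat_width
    for i, h in enumerate(config.hidden, start=1):
        trunk.append(Dense(w, h, rng, activation=act, name=f"hidden_{i}"))
        w = h
    trunk.append(Dense(w, config.n_outputs, rng, activation="linear", name="output_softmax"))

    manifest = [
        ("geno_input", (n_genes,), 0),
        ("pathways", (P,), geno[1].n_params()),
        ("reshape", (P, 1), 0),
        ("conv1d", (P, config.conv_filters), geno[3].n_params()),
        ("flatten", (flat_width,), 0),
        ("geno_dense", (config.branch_dense,), geno[5].n_params()),
        ("expr_input", (n_expr_genes,), 0),
        ("expr_dense", (config.branch_dense,), expr[1].n_params()),
        ("concatenate", (concat_width,), 0),
        ("batch_norm", (concat_width,), trunk[0].n_params()),
    ]
    w = concat_width
    for i, h in enumerate(config.hidden, start=1):
        manifest.append((f"hidden_{i}", (h,), trunk[i].n_params()))
        w = h
    manifest.append(("output_softmax", (config.n_outputs,), trunk[-1].n_params()))

    _check("flatten", flat_width, P * config.conv_filters)
    _check("concatenate", concat_width, 2 * config.branch_dense)
    expected_layers = 10 + len(config.hidden) + 1
    _check("model", len(manifest), expected_layers)
    return DualInputNetwork(geno, expr, trunk, manifest, "constrained", config,
                            mask_bits=mask.bits.copy())


def build_unconstrained_model(config: ModelConfig, n_geno_genes: int,
                              n_expr_genes: int, width: int = 186) -> DualInputNetwork:
    """The 9-layer comparator: dense + embedding-style expansion, no mask, no hidden stack.

    The embedding internals are a reconstruction (a trainable position-wise
    (width, 3) expansion); the published description fixes only the layer
    count and the embedding shape.
    """
    rng = np.random.default_rng(config.seed)
    act = config.hidden_activation
    d = config.embedding_depth

    geno = [
        Input(n_geno_genes, "geno_input"),
        Dense(n_geno_genes, width, rng, activation=act, name="geno_dense_wide"),
        PositionwiseExpansion(width, d, rng, name="embedding"),
        Flatten(name="flatten"),
        Dense(width * d, config.branch_dense, rng, activation=act, name="geno_dense"),
    ]
    expr = [
        Input(n_expr_genes, "expr_input"),
        Dense(n_expr_genes, config.branch_dense, rng, activation=act, name="expr_dense"),
    ]
    concat_width = 2 * config.branch_dense
    trunk = [Dense(concat_width, config.n_outputs, rng, activation="linear",
                   name="output_softmax")]

    manifest = [
        ("geno_input", (n_geno_genes,), 0),
        ("geno_dense_wide", (width,), geno[1].n_params()),
        ("embedding", (width, d), geno[2].n_params()),
        ("flatten", (width * d,), 0),
        ("geno_dense", (config.branch_dense,), geno[4].n_params()),
        ("expr_input", (n_expr_genes,), 0),
        ("expr_dense", (config.branch_dense,), expr[1].n_params()),
        ("concatenate", (concat_width,), 0),
        ("output_softmax", (config.n_outputs,), trunk[0].n_params()),
    ]
    _check("model", len(manifest), 9)
    return DualInputNetwork(geno, expr, trunk, manifest, "unconstrained", config)


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictionBatch:
    probs: np.ndarray  # samples x 2, rows sum to 1; column order (CN, MCI/AD)
    labels: np.ndarray = field(init=False)  # argmax; tie -> index 0 (CN)

    def __post_init__(self) -> None:
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        self.labels = self.probs.argmax(axis=1)


@dataclass
class TrainedModel:
    model: DualInputNetwork
    history: pd.DataFrame
    best_epoch: int


def predict(model: DualInputNetwork, geno: np.ndarray, expr: np.ndarray) -> PredictionBatch:
    logits = model.forward(geno, expr, training=False)
    return PredictionBatch(probs=softmax(logits))


def _epoch_metrics(model, geno, expr, y_onehot, prefix: str) -> dict:
    probs = predict(model, geno, expr).probs
    loss = cross_entropy(probs, y_onehot)
    y_true = y_onehot.argmax(axis=1)
    y_pred = probs.argmax(axis=1)
    counts = evaluation.confusion(y_true, y_pred)
    m = evaluation.metrics(counts)
    auc, _ = evaluation.roc_auc(y_true, probs[:, 1])
    return {
        f"{prefix}_loss": loss,
        f"{prefix}_auc": auc,
        f"{prefix}_accuracy": m.accuracy,
        f"{prefix}_precision": m.precision,
        f"{prefix}_recall": m.recall,
    }


def train(model: DualInputNetwork,
          train_bundle: tuple[np.ndarray, np.ndarray, np.ndarray],
          val_bundle: tuple[np.ndarray, np.ndarray, np.ndarray],
          config: ModelConfig | None = None) -> TrainedModel:
    """Minibatch Adam on 2-class cross-entropy with early stopping.

    ``train_bundle``/``val_bundle`` are (geno, expr, one-hot labels); the
    training inputs are expected to be SMOTE-balanced.  Stops after
    ``patience`` epochs without validation-loss improvement beyond
    ``min_delta`` and restores the best-validation parameters.  AUC,
    accuracy, precision and recall are recorded per epoch for both sets.
    """
    config = config or model.config
    Xg, Xe, Y = (np.asarray(a, dtype=float) for a in train_bundle)
    Vg, Ve, Vy = (np.asarray(a, dtype=float) for a in val_bundle)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.layers, learning_rate=config.learning_rate)

    n = Xg.shape[0]
    best_loss = np.inf
    best_state = model.get_state()
    best_epoch = 0
    stall = 0
    rows = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(Xg[idx], Xe[idx], training=True)
            probs = softmax(logits)
            loss = cross_entropy(probs, Y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            model.backward((probs - Y[idx]) / idx.size)
            optimizer.step()

        row = {"epoch": epoch}
        row.update(_epoch_metrics(model, Xg, Xe, Y, "train"))
        row.update(_epoch_metrics(model, Vg, Ve, Vy, "val"))
        rows.append(row)

        val_loss = row["val_loss"]
        if val_loss < best_loss - config.min_delta:
            best_loss = val_loss
            best_state = model.get_state()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    model.set_state(best_state)
    history = pd.DataFrame(rows)
    return TrainedModel(model=model, history=history, best_epoch=best_epoch)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(trained: TrainedModel, out_prefix) -> None:
    """Write <prefix>.npz (parameters), <prefix>.json (config) and a manifest TSV."""
    out_prefix = os.fspath(out_prefix)
    model = trained.model
    state = model.get_state()
    arrays = {f"param_{i}": a for i, a in enumerate(state)}
    if model.mask_bits is not None:
        arrays["mask_bits"] = model.mask_bits
    np.savez(out_prefix + ".npz", **arrays)
    meta = {
        "kind": model.kind,
        "config": asdict(model.config),
        "n_geno": model.geno_branch[0].width,
        "n_expr": model.expr_branch[0].width,
        "best_epoch": trained.best_epoch,
        "n_state_arrays": len(state),
    }
    with open(out_prefix + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)
    model.write_manifest(out_prefix + ".manifest.tsv")
    trained.history.to_csv(out_prefix + ".history.tsv", sep="\t", index=False)


def load_model(prefix) -> TrainedModel:
    prefix = os.fspath(prefix)
    with open(prefix + ".json") as fh:
        meta = json.load(fh)
    cfg = meta["config"]
    cfg["hidden"] = tuple(cfg["hidden"])
    config = ModelConfig(**cfg)
    data = np.load(prefix + ".npz")
    if meta["kind"] == "constrained":
        bits = data["mask_bits"]
        mask = PathwayMask(genes=[f"g{i}" for i in range(bits.shape[0])],
                           pathways=[f"p{j}" for j in range(bits.shape[1])],
                           bits=bits)
        model = build_constrained_model(config, mask, meta["n_expr"])
    else:
        model = build_unconstrained_model(config, meta["n_geno"], meta["n_expr"])
    state = [data[f"param_{i}"] for i in range(meta["n_state_arrays"])]
    model.set_state(state)
    history = pd.read_csv(prefix + ".history.tsv", sep="\t")
    return TrainedModel(model=model, history=history, best_epoch=meta["best_epoch"])
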