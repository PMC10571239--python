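"""Gene-set (GMT) parsing and the binary gene x pathway constraint mask.

The mask fixes which gene -> pathway edges exist in the constrained input
branch of the classifier: bit (g, p) is 1 iff gene g is a member of pathway p
in the source collection.  Genes that belong to no pathway keep all-zero rows
by default, so their contribution through the constrained layer is exactly
zero.  Gene symbols are matched by exact, case-sensitive equality; no alias
resolution is attempted.
"""

from __future__ import annotations

import hashlib
import logging
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class GmtParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene-set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def members(self, name: str) -> tuple[str, ...]:
        for s in self.sets:
            if s.name == name:
                return s.members
        raise KeyError(name)


@dataclass
class PathwayMask:
    """Binary genes x pathways grid; rows follow the gene list order."""

    genes: list[str]
    pathways: list[str]
    bits: np.ndarray  # uint8, shape (n_genes, n_pathways)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (len(self.genes), len(self.pathways)):
            raise ValueError("mask shape does not match gene/pathway lists")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)

    def to_tsv(self, path, source_path=None) -> None:
        """Export the mask with a provenance header (source file hash)."""
        with open(path, "w") as fh:
            if source_path is not None:
                digest = hashlib.sha256(open(source_path, "rb").read()).hexdigest()
                fh.write(f"# collection={os.fspath(source_path)} sha256={digest}\n")
            df = pd.DataFrame(self.bits, index=self.genes, columns=self.pathways)
            df.index.name = "gene"
            df.to_csv(fh, sep="\t")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated name, description, members.

    Set order and member order are preserved; duplicate members within a set
    are collapsed with a warning.  Lines with fewer than three fields raise a
    parse error naming the line.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            members = [g for g in fields[2:] if g]
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} has duplicate members; collapsed",
                    stacklevel=2,
                )
            sets.append(GeneSet(name=name, description=description, members=tuple(deduped)))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection.sets:
            fh.write("\t".join((s.name, s.description, *s.members)) + "\n")


def build_mask(gene_list: list[str], collection: GeneSetCollection) -> PathwayMask:
    """Binary membership mask with rows in ``gene_list`` order, columns in collection order."""
    if not gene_list:
        raise ValueError("gene_list must be non-empty")
    if len(set(gene_list)) != len(gene_list):
        raise ValueError("gene_list must be deduplicated")
    row = {g: i for i, g in enumerate(gene_list)}
    bits = np.zeros((len(gene_list), len(collection)), dtype=np.uint8)
    for p, s in enumerate(collection.sets):
        for g in s.members:
            i = row.get(g)
            if i is not None:
                bits[i, p] = 1
    if bits.size and not bits.any():
        logger.warning(
            "pathway mask is all-zero: no gene in the input list belongs to any set; "
            "the constrained branch will carry no genotype signal"
        )
    return PathwayMask(genes=list(gene_list), pathways=collection.names, bits=bits)


def mask_summary(mask: PathwayMask) -> dict:
    """Coverage statistics: pathway count, covered genes, density, per-pathway sizes."""
    per_pathway = mask.bits.sum(axis=0).astype(int)
    covered = int((mask.bits.sum(axis=1) > 0).sum())
    density = float(mask.bits.sum()) / mask.bits.size if mask.bits.size else 0.0
    return {
        "n_pathways": mask.n_pathways,
        "n_genes": mask.n_genes,
        "genes_covered": covered,
        "density": density,
        "genes_per_pathway": dict(zip(mask.pathways, per_pathway.tolist())),
    }
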