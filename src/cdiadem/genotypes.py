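"""PLINK 1.x binary genotype I/O, MAF filtering, additive encoding and per-gene burden aggregation.

Genotypes are stored as minor-allele counts (additive encoding): 0 = homozygous
major, 1 = heterozygous, 2 = homozygous minor, with ``MISSING`` (-1) marking
no-calls.  The PLINK 1.x binary trio (.bed/.bim/.fam) is read and written
directly: the .bed payload is variant-major, two bits per genotype
(00 = hom A1, 01 = missing, 10 = het, 11 = hom A2), with A1 taken as the minor
allele per the .bim column convention.

Coding SNPs are mapped to genes through a BED file of CDS intervals (0-based,
half-open) carrying gene symbols in the name column; the per-gene burden of a
sample is the sum of the additive codes of all SNPs mapped to that gene.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

MISSING = -1

_PLINK_MAGIC = b"\x6c\x1b"
_VARIANT_MAJOR = b"\x01"

# 2-bit PLINK code -> minor-allele count (A1 = minor).  01 is the missing code.
_BITS_TO_CODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_CODE_TO_BITS = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Raised for malformed PLINK binary files (bad magic, truncation, ...)."""


class BedParseError(ValueError):
    """Raised for malformed CDS annotation (BED) lines."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant; ``allele_minor`` is the .bim A1 allele."""

    snp_id: str
    chrom: str
    pos: int  # 1-based base-pair coordinate
    allele_minor: str
    allele_major: str

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        if self.allele_minor == self.allele_major:
            raise ValueError(f"{self.snp_id}: minor and major alleles are identical")


@dataclass
class GenotypeMatrix:
    """samples x variants grid of additive codes in {0,1,2} plus MISSING."""

    samples: list[str]
    variants: list[VariantRecord]
    codes: np.ndarray  # int8, shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        valid = np.isin(self.codes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.codes[~valid])
            raise ValueError(f"invalid additive codes present: {bad.tolist()}")
        ids = [v.snp_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            raise ValueError(f"duplicate snp_id in panel: {dupes}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def snp_index(self, snp_id: str) -> int:
        for i, v in enumerate(self.variants):
            if v.snp_id == snp_id:
                return i
        raise KeyError(snp_id)


@dataclass
class GeneMap:
    """SNP -> gene assignments derived from CDS intervals."""

    pairs: list[tuple[str, str]]  # (snp_id, gene_symbol)
    snps_by_gene: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        by_gene: dict[str, list[str]] = {}
        for snp, gene in self.pairs:
            by_gene.setdefault(gene, []).append(snp)
        self.snps_by_gene = by_gene

    @property
    def genes(self) -> list[str]:
        return sorted(self.snps_by_gene)


@dataclass
class GeneAggregateMatrix:
    """samples x genes burden grid; integer counts before SMOTE, continuous after."""

    samples: list[str]
    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValueError("values shape does not match sample/gene lists")
        if (self.values < 0).any():
            raise ValueError("gene burdens must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.genes)

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "GeneAggregateMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy())


# ---------------------------------------------------------------------------
# PLINK binary trio I/O
# ---------------------------------------------------------------------------

def read_plink(bed_path, bim_path, fam_path) -> GenotypeMatrix:
    """Read a PLINK 1.x binary trio into additive minor-allele counts.

    Sample order follows the .fam file and variant order the .bim file.
    Raises :class:`PlinkFormatError` on bad magic bytes or a payload whose
    size is inconsistent with the .bim/.fam row counts.
    """
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 2:
        raise PlinkFormatError(f"{fam_path}: .fam needs at least FID and IID columns")
    samples = fam.iloc[:, 1].tolist()

    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] != 6:
        raise PlinkFormatError(f"{bim_path}: .bim must have 6 columns, got {bim.shape[1]}")
    variants = [
        VariantRecord(snp_id=r[1], chrom=r[0], pos=int(r[3]),
                      allele_minor=r[4], allele_major=r[5])
        for r in bim.itertuples(index=False)
    ]

    with open(bed_path, "rb") as fh:
        header = fh.read(3)
        payload = fh.read()
    if header[:2] != _PLINK_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes {header[:2]!r}")
    if header[2:3] != _VARIANT_MAJOR:
        raise PlinkFormatError(f"{bed_path}: only variant-major mode (0x01) is supported")

    n_samples, n_variants = len(samples), len(variants)
    bytes_per_variant = (n_samples + 3) // 4
    expected = n_variants * bytes_per_variant
    if len(payload) != expected:
        raise PlinkFormatError(
            f"{bed_path}: payload is {len(payload)} bytes, expected {expected} "
            f"for {n_samples} samples x {n_variants} variants (truncated or mismatched trio)"
        )

    if n_variants == 0 or n_samples == 0:
        codes = np.empty((n_samples, n_variants), dtype=np.int8)
    else:
        raw = np.frombuffer(payload, dtype=np.uint8).reshape(n_variants, bytes_per_variant)
        # unpack the four 2-bit fields of every byte, low bits = first sample
        two_bit = np.stack([(raw >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
        two_bit = two_bit.reshape(n_variants, bytes_per_variant * 4)[:, :n_samples]
        codes = _BITS_TO_CODE[two_bit].T.copy()

    return GenotypeMatrix(samples=samples, variants=variants, codes=codes)


def write_plink(genotypes: GenotypeMatrix, out_prefix) -> tuple[str, str, str]:
    """Write a bit-exact PLINK 1.x variant-major trio; returns the three paths."""
    out_prefix = os.fspath(out_prefix)
    bed_path, bim_path, fam_path = (out_prefix + ext for ext in (".bed", ".bim", ".fam"))

    n_samples, n_variants = genotypes.n_samples, genotypes.n_variants
    bytes_per_variant = (n_samples + 3) // 4
    buf = io.BytesIO()
    buf.write(_PLINK_MAGIC + _VARIANT_MAJOR)
    if n_variants and bytes_per_variant:
        lut = np.zeros(256, dtype=np.uint8)
        for code, bits in _CODE_TO_BITS.items():
            lut[code & 0xFF] = bits  # int8 view: MISSING (-1) -> index 255
        two_bit = lut[genotypes.codes.T.astype(np.uint8)]
        padded = np.zeros((n_variants, bytes_per_variant * 4), dtype=np.uint8)
        padded[:, :n_samples] = two_bit
        packed = (padded[:, 0::4]
                  | (padded[:, 1::4] << 2)
                  | (padded[:, 2::4] << 4)
                  | (padded[:, 3::4] << 6))
        buf.write(packed.astype(np.uint8).tobytes())
    with open(bed_path, "wb") as fh:
        fh.write(buf.getvalue())

    with open(bim_path, "w") as fh:
        for v in genotypes.variants:
            fh.write(f"{v.chrom}\t{v.snp_id}\t0\t{v.pos}\t{v.allele_minor}\t{v.allele_major}\n")
    with open(fam_path, "w") as fh:
        for s in genotypes.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    return bed_path, bim_path, fam_path


# ---------------------------------------------------------------------------
# MAF filtering and allele normalization
# ---------------------------------------------------------------------------

def minor_allele_frequency(genotypes: GenotypeMatrix, snp_index: int) -> float:
    """Cohort minor-allele frequency of one SNP, folded into [0, 0.5]."""
    col = genotypes.codes[:, snp_index]
    called = col[col != MISSING]
    if called.size == 0:
        raise ValueError(
            f"SNP {genotypes.variants[snp_index].snp_id}: all calls missing, MAF undefined"
        )
    freq = float(called.sum()) / (2.0 * called.size)
    return min(freq, 1.0 - freq)


def normalize_alleles(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Recode SNPs whose A1 allele is not minor in the current cohort.

    After subsetting samples the .bim minor allele may be the cohort-major
    one; such SNPs are recoded as 2 - code (missing preserved) and their
    allele labels swapped, so "additive = minor-allele count" stays true.
    """
    codes = genotypes.codes.copy()
    variants = list(genotypes.variants)
    for j in range(genotypes.n_variants):
        col = codes[:, j]
        called = col != MISSING
        if not called.any():
            continue
        freq = float(col[called].sum()) / (2.0 * called.sum())
        if freq > 0.5:
            col[called] = 2 - col[called]
            v = variants[j]
            variants[j] = replace(v, allele_minor=v.allele_major, allele_major=v.allele_minor)
    return GenotypeMatrix(samples=list(genotypes.samples), variants=variants, codes=codes)


def filter_maf(genotypes: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Keep exactly the SNPs with cohort MAF >= ``threshold`` (order preserved)."""
    if not 0.0 <= threshold < 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5), got {threshold}")
    keep = [
        j for j in range(genotypes.n_variants)
        if minor_allele_frequency(genotypes, j) >= threshold
    ]
    return GenotypeMatrix(
        samples=list(genotypes.samples),
        variants=[genotypes.variants[j] for j in keep],
        codes=genotypes.codes[:, keep],
    )


# ---------------------------------------------------------------------------
# CDS mapping and aggregation
# ---------------------------------------------------------------------------

def read_cds_bed(path) -> list[tuple[str, int, int, str]]:
    """Parse a BED file of CDS intervals: (chrom, start, end, gene_symbol).

    Intervals are 0-based half-open; the gene symbol is the BED name column.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected >=4 BED columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer interval bounds") from exc
            if start < 0 or end <= start:
                raise BedParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            intervals.append((fields[0], start, end, fields[3]))
    return intervals


def map_snps_to_genes(variants: list[VariantRecord], cds_annotation) -> GeneMap:
    """Assign coding SNPs to genes whose CDS interval contains them.

    ``cds_annotation`` is a BED path or a pre-parsed interval list.  A SNP at
    1-based position ``pos`` maps to gene g iff ``pos - 1`` lies in some
    0-based half-open CDS interval of g on the same chromosome; SNPs hitting
    overlapping CDS of several genes map to each, and SNPs in no CDS are
    dropped.
    """
    if isinstance(cds_annotation, (str, os.PathLike)):
        cds_annotation = read_cds_bed(cds_annotation)
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, gene in cds_annotation:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, gene)

    pairs: list[tuple[str, str]] = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        genes = sorted({iv.data for iv in tree.at(v.pos - 1)})
        pairs.extend((v.snp_id, g) for g in genes)
    return GeneMap(pairs=pairs)


def aggregate_by_gene(
    genotypes: GenotypeMatrix,
    gene_map: GeneMap,
    impute_missing: bool = False,
) -> GeneAggregateMatrix:
    """Sum additive codes per gene: values[s, g] = sum of codes over SNPs of g.

    Genes are ordered lexicographically.  Missing genotypes raise unless
    ``impute_missing`` is set, in which case each SNP's missing calls are
    filled with its per-SNP modal code (ties -> smaller code).
    """
    index = {v.snp_id: j for j, v in enumerate(genotypes.variants)}
    for snp, _ in gene_map.pairs:
        if snp not in index:
            raise KeyError(f"mapped SNP {snp} absent from genotype matrix")

    codes = genotypes.codes.astype(np.int64)
    if (codes == MISSING).any():
        if not impute_missing:
            raise ValueError(
                "missing genotypes present; pass impute_missing=True to mode-fill per SNP"
            )
        for j in range(codes.shape[1]):
            col = codes[:, j]
            miss = col == MISSING
            if miss.any():
                observed = col[~miss]
                if observed.size == 0:
                    raise ValueError(
                        f"SNP {genotypes.variants[j].snp_id}: all calls missing, cannot impute"
                    )
                mode = np.bincount(observed, minlength=3).argmax()
                col[miss] = mode

    genes = gene_map.genes
    values = np.zeros((genotypes.n_samples, len(genes)), dtype=np.int64)
    for k, gene in enumerate(genes):
        cols = [index[s] for s in gene_map.snps_by_gene[gene]]
        values[:, k] = codes[:, cols].sum(axis=1)
    return GeneAggregateMatrix(samples=list(genotypes.samples), genes=genes, values=values)
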