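"""PLINK I/O, MAF filtering, CDS mapping and gene aggregation."""

import numpy as np
import pytest

from cdiadem import genotypes as G

from conftest import random_genotype_matrix


def _write_trio(tmp_path, bed_bytes: bytes, bim: str, fam: str):
    paths = (tmp_path / "t.bed", tmp_path / "t.bim", tmp_path / "t.fam")
    paths[0].write_bytes(bed_bytes)
    paths[1].write_text(bim)
    paths[2].write_text(fam)
    return paths


class TestPlinkIO:
    def test_hand_decoded_two_sample_one_snp(self, tmp_path):
        # payload byte 0b00001100: sample0 -> bits 00 (hom A1 = 2 minor
        # alleles), sample1 -> bits 11 (hom A2 = 0)
        bed = b"\x6c\x1b\x01" + bytes([0b00001100])
        paths = _write_trio(tmp_path, bed,
                            "1\trs1\t0\t100\tA\tG\n",
                            "F1 S1 0 0 0 -9\nF2 S2 0 0 0 -9\n")
        gm = G.read_plink(*paths)
        assert gm.codes[:, 0].tolist() == [2, 0]
        assert gm.samples == ["S1", "S2"]
        assert gm.variants[0].allele_minor == "A"

    def test_missing_code_decodes(self, tmp_path):
        bed = b"\x6c\x1b\x01" + bytes([0b00001001])  # 01 = missing, 10 = het
        paths = _write_trio(tmp_path, bed,
                            "1\trs1\t0\t100\tA\tG\n",
                            "F1 S1 0 0 0 -9\nF2 S2 0 0 0 -9\n")
        gm = G.read_plink(*paths)
        assert gm.codes[:, 0].tolist() == [G.MISSING, 1]

    def test_bad_magic_raises(self, tmp_path):
        paths = _write_trio(tmp_path, b"\x00\x00\x01\x00",
                            "1\trs1\t0\t100\tA\tG\n", "F1 S1 0 0 0 -9\n")
        with pytest.raises(G.PlinkFormatError, match="magic"):
            G.read_plink(*paths)

    def test_truncated_payload_raises(self, tmp_path):
        paths = _write_trio(tmp_path, b"\x6c\x1b\x01",
                            "1\trs1\t0\t100\tA\tG\n", "F1 S1 0 0 0 -9\n")
        with pytest.raises(G.PlinkFormatError, match="payload"):
            G.read_plink(*paths)

    def test_duplicate_snp_id_raises(self, tmp_path):
        bed = b"\x6c\x1b\x01" + bytes([0b11, 0b11])
        paths = _write_trio(tmp_path, bed,
                            "1\trs1\t0\t100\tA\tG\n1\trs1\t0\t200\tC\tT\n",
                            "F1 S1 0 0 0 -9\n")
        with pytest.raises(ValueError, match="duplicate"):
            G.read_plink(*paths)

    def test_empty_sample_list_gives_header_only_bed(self, tmp_path):
        gm = G.GenotypeMatrix(samples=[], variants=[], codes=np.empty((0, 0), np.int8))
        bed, bim, fam = G.write_plink(gm, tmp_path / "empty")
        assert open(bed, "rb").read() == b"\x6c\x1b\x01"
        assert open(fam).read() == ""

    def test_write_inverse_of_read_example(self, tmp_path):
        gm = G.GenotypeMatrix(
            samples=["S1", "S2"],
            variants=[G.VariantRecord("rs1", "1", 100, "A", "G")],
            codes=np.array([[2], [0]], np.int8),
        )
        bed, _, _ = G.write_plink(gm, tmp_path / "inv")
        assert open(bed, "rb").read()[3] == 0b00001100

    @pytest.mark.parametrize("missing_rate", [0.0, 0.1])
    def test_roundtrip_bit_exact(self, tmp_path, missing_rate):
        rng = np.random.default_rng(7)
        gm = random_genotype_matrix(rng, 20, 50, missing_rate=missing_rate)
        paths = G.write_plink(gm, tmp_path / "rt")
        back = G.read_plink(*paths)
        assert back.samples == gm.samples
        assert [v.snp_id for v in back.variants] == [v.snp_id for v in gm.variants]
        np.testing.assert_array_equal(back.codes, gm.codes)
        # second write must be byte-stable
        paths2 = G.write_plink(back, tmp_path / "rt2")
        for a, b in zip(paths, paths2):
            assert open(a, "rb").read() == open(b, "rb").read()


class TestMaf:
    def test_monomorphic_is_zero(self):
        gm = random_genotype_matrix(np.random.default_rng(0), 4, 1)
        gm.codes[:, 0] = 0
        assert G.minor_allele_frequency(gm, 0) == 0.0

    def test_all_heterozygous_is_half(self):
        gm = random_genotype_matrix(np.random.default_rng(0), 4, 1)
        gm.codes[:, 0] = 1
        assert G.minor_allele_frequency(gm, 0) == 0.5

    def test_against_allele_tally_oracle(self):
        rng = np.random.default_rng(11)
        gm = random_genotype_matrix(rng, 200, 5, missing_rate=0.05)
        for j in range(5):
            col = gm.codes[:, j]
            called = col[col != G.MISSING]
            # oracle: explicit per-allele tally over the 2N called alleles
            minor = int(called.sum())
            total = 2 * len(called)
            expected = min(minor / total, 1 - minor / total)
            assert G.minor_allele_frequency(gm, j) == pytest.approx(expected)

    def test_all_missing_raises(self):
        gm = random_genotype_matrix(np.random.default_rng(0), 4, 1)
        gm.codes[:, 0] = G.MISSING
        with pytest.raises(ValueError, match="missing"):
            G.minor_allele_frequency(gm, 0)

    def test_normalize_alleles_folds_majority_coded_snp(self):
        gm = random_genotype_matrix(np.random.default_rng(0), 4, 1)
        gm.codes[:, 0] = [2, 2, 2, 1]  # A1 frequency 7/8 > 0.5
        out = G.normalize_alleles(gm)
        assert out.codes[:, 0].tolist() == [0, 0, 0, 1]
        assert out.variants[0].allele_minor == gm.variants[0].allele_major
        np.testing.assert_array_equal(gm.codes[:, 0], [2, 2, 2, 1])  # input untouched


class TestFilterMaf:
    def test_threshold_zero_is_identity(self):
        gm = random_genotype_matrix(np.random.default_rng(3), 30, 20)
        out = G.filter_maf(gm, 0.0)
        np.testing.assert_array_equal(out.codes, gm.codes)

    def test_rare_snp_removed(self):
        gm = random_genotype_matrix(np.random.default_rng(3), 100, 2)
        gm.codes[:, 0] = 0
        gm.codes[0, 0] = 1  # MAF 0.005
        gm.codes[:, 1] = 1  # MAF 0.5
        out = G.filter_maf(gm, 0.05)
        assert [v.snp_id for v in out.variants] == ["rs00001"]

    def test_matches_per_snp_oracle_and_bounds(self):
        gm = random_genotype_matrix(np.random.default_rng(5), 50, 40)
        t = 0.2
        out = G.filter_maf(gm, t)
        kept = {v.snp_id for v in out.variants}
        for j, v in enumerate(gm.variants):
            maf = G.minor_allele_frequency(gm, j)
            assert (v.snp_id in kept) == (maf >= t)

    def test_bad_threshold_raises(self):
        gm = random_genotype_matrix(np.random.default_rng(3), 10, 2)
        with pytest.raises(ValueError):
            G.filter_maf(gm, 0.7)


class TestCdsMapping:
    def _variant(self, pos, chrom="1", snp_id="rs1"):
        return G.VariantRecord(snp_id, chrom, pos, "A", "G")

    def test_boundary_inclusive_start(self):
        gmap = G.map_snps_to_genes([self._variant(100)], [("1", 99, 100, "GENE1")])
        assert gmap.pairs == [("rs1", "GENE1")]

    def test_off_by_one_exclusive(self):
        # 1-based pos 100 -> 0-based 99, not inside [100, 200)
        gmap = G.map_snps_to_genes([self._variant(100)], [("1", 100, 200, "GENE1")])
        assert gmap.pairs == []

    def test_chromosome_must_match(self):
        gmap = G.map_snps_to_genes([self._variant(150, chrom="2")],
                                   [("1", 100, 200, "GENE1")])
        assert gmap.pairs == []

    def test_overlapping_cds_maps_to_both(self):
        gmap = G.map_snps_to_genes(
            [self._variant(150)],
            [("1", 100, 200, "GENE1"), ("1", 120, 180, "GENE2")],
        )
        assert sorted(gmap.pairs) == [("rs1", "GENE1"), ("rs1", "GENE2")]

    def test_against_all_pairs_oracle(self):
        rng = np.random.default_rng(17)
        variants = [self._variant(int(rng.integers(1, 5000)), chrom=str(rng.integers(1, 4)),
                                  snp_id=f"rs{i}") for i in range(1000)]
        intervals = [(str(rng.integers(1, 4)), int(s := rng.integers(0, 4900)),
                      int(s + rng.integers(10, 300)), f"GENE{k}") for k in range(60)]
        expected = sorted(
            {(v.snp_id, g) for v in variants for (c, s, e, g) in intervals
             if c == v.chrom and s <= v.pos - 1 < e}
        )
        got = G.map_snps_to_genes(variants, intervals)
        assert sorted(set(got.pairs)) == expected

    def test_malformed_bed_names_line(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("1\t100\t200\tGENE1\n1\t100\n")
        with pytest.raises(G.BedParseError, match=":2:"):
            G.read_cds_bed(bad)


class TestAggregation:
    def test_trivial_sums(self):
        gm = random_genotype_matrix(np.random.default_rng(1), 3, 2)
        gm.codes[:] = [[0, 2], [0, 2], [0, 0]]
        gmap = G.GeneMap(pairs=[("rs00000", "GENEA"), ("rs00001", "GENEA")])
        agg = G.aggregate_by_gene(gm, gmap)
        assert agg.values[:, 0].tolist() == [2, 2, 0]

    def test_against_double_loop_oracle(self):
        rng = np.random.default_rng(23)
        gm = random_genotype_matrix(rng, 10, 30)
        pairs = [(f"rs{j:05d}", f"GENE{rng.integers(0, 8)}")
                 for j in range(30) if rng.random() < 0.7]
        gmap = G.GeneMap(pairs=pairs)
        agg = G.aggregate_by_gene(gm, gmap)
        for s in range(10):
            for k, gene in enumerate(agg.genes):
                total = 0
                for snp, g in pairs:
                    if g == gene:
                        total += int(gm.codes[s, gm.snp_index(snp)])
                assert agg.values[s, k] == total

    def test_gene_order_lexicographic(self):
        gm = random_genotype_matrix(np.random.default_rng(1), 3, 3)
        gmap = G.GeneMap(pairs=[("rs00000", "ZZZ"), ("rs00001", "AAA"), ("rs00002", "MMM")])
        assert G.aggregate_by_gene(gm, gmap).genes == ["AAA", "MMM", "ZZZ"]

    def test_missing_raises_without_imputation(self):
        gm = random_genotype_matrix(np.random.default_rng(2), 5, 2, missing_rate=0.3)
        gmap = G.GeneMap(pairs=[("rs00000", "GENEA")])
        with pytest.raises(ValueError, match="missing"):
            G.aggregate_by_gene(gm, gmap)
        agg = G.aggregate_by_gene(gm, gmap, impute_missing=True)
        assert (agg.values >= 0).all()

    def test_unknown_snp_in_map_raises(self):
        gm = random_genotype_matrix(np.random.default_rng(2), 5, 2)
        with pytest.raises(KeyError):
            G.aggregate_by_gene(gm, G.GeneMap(pairs=[("rs99999", "GENEA")]))

    def test_column_sums_invariant_under_sample_permutation(self):
        rng = np.random.default_rng(29)
        gm = random_genotype_matrix(rng, 12, 15)
        pairs = [(f"rs{j:05d}", f"GENE{j % 4}") for j in range(15)]
        agg = G.aggregate_by_gene(gm, G.GeneMap(pairs=pairs))
        perm = rng.permutation(12)
        gm2 = G.GenotypeMatrix(samples=[gm.samples[i] for i in perm],
                               variants=gm.variants, codes=gm.codes[perm])
        agg2 = G.aggregate_by_gene(gm2, G.GeneMap(pairs=pairs))
        np.testing.assert_array_equal(agg.values.sum(axis=0), agg2.values.sum(axis=0))
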