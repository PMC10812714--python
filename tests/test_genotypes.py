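"""Genotype I/O, HWE exact test, filter cascade, LD pruning, site utilities."""

import numpy as np
import pandas as pd
import pytest

from popgenscan import (
    MISSING,
    FilterCriteria,
    apply_filters,
    gc_content,
    hwe_exact_p,
    ld_prune,
    read_popmap,
    read_vcf,
    ts_tv_ratio,
    write_vcf,
)
from popgenscan.genotypes import VCFFormatError, dosage_r2
from popgenscan.simulate import SimConfig, simulate

from _oracles import hwe_exact_enum
from conftest import make_dataset


VCF_3x2 = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1,length=10000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/0\t0/1
1\t200\t.\tC\tT\t.\t.\t.\tGT\t1/1\t./.
1\t300\t.\tG\tA\t.\t.\t.\tGT\t0|1\t1|1
"""


class TestVcfIO:
    def test_gt_to_dosage_mapping(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(VCF_3x2)
        vt, gm = read_vcf(str(path))
        assert gm.sample_ids == ["s1", "s2"]
        expected = np.array([[0, 1], [2, MISSING], [1, 2]])
        np.testing.assert_array_equal(gm.values, expected)
        assert list(vt.pos) == [100, 200, 300]

    def test_empty_vcf(self, tmp_path):
        path = tmp_path / "e.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        )
        vt, gm = read_vcf(str(path))
        assert len(vt) == 0 and gm.n_loci == 0

    def test_write_examples(self, tmp_path):
        vt, gm = make_dataset([[1], [MISSING]])
        out = tmp_path / "o.vcf"
        write_vcf(vt, gm, str(out))
        body = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert body[0].endswith("0/1")
        assert body[1].endswith("./.")

    def test_round_trip_on_simulation(self, tmp_path):
        vt, gm, _, _ = simulate(
            SimConfig(seed=3, n_snps=500, contigs=[("1", 100_000)], sweeps=[])
        )
        path = tmp_path / "sim.vcf"
        write_vcf(vt, gm, str(path), contig_lengths={"1": 100_000})
        vt2, gm2 = read_vcf(str(path))
        np.testing.assert_array_equal(gm.values, gm2.values)
        np.testing.assert_array_equal(vt.pos, vt2.pos)
        assert gm.sample_ids == gm2.sample_ids

    def test_malformed_header_raises(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("not a vcf at all\n")
        with pytest.raises(VCFFormatError):
            read_vcf(str(path))


class TestPopmap:
    def test_basic(self, tmp_path):
        p = tmp_path / "pm.tsv"
        p.write_text("s1\tA\ns2\tA\ns3\tB\ns4\tB\n")
        pm = read_popmap(str(p))
        assert len(pm.assignments) == 4
        assert pm.populations == ["A", "B"]

    def test_study_design_sizes(self, tmp_path):
        sizes = {"AB": 12, "AF": 5, "BG": 11, "CH": 12, "MR": 5}
        lines = [
            f"{pop}_{i}\t{pop}" for pop, n in sizes.items() for i in range(n)
        ]
        p = tmp_path / "pm.tsv"
        p.write_text("\n".join(lines) + "\n")
        pm = read_popmap(str(p))
        assert len(pm.assignments) == 45
        assert pm.populations == list(sizes)

    def test_duplicate_and_empty(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("s1\tA\ns1\tB\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_popmap(str(p))
        e = tmp_path / "empty.tsv"
        e.write_text("")
        with pytest.raises(ValueError, match="no samples"):
            read_popmap(str(e))


class TestHweExact:
    @pytest.mark.parametrize(
        "counts,expected",
        [((5, 0, 0), 1.0), ((1, 0, 1), 1 / 3), ((0, 2, 0), 1.0)],
    )
    def test_small_configurations(self, counts, expected):
        assert hwe_exact_p(*counts) == pytest.approx(expected)

    def test_matches_enumeration_up_to_10_individuals(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 11))
            n_aa = int(rng.integers(0, n + 1))
            n_het = int(rng.integers(0, n - n_aa + 1))
            n_AA = n - n_aa - n_het
            p = hwe_exact_p(n_AA, n_het, n_aa)
            assert p == pytest.approx(float(hwe_exact_enum(n_AA, n_het, n_aa)), abs=1e-12)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)


class TestApplyFilters:
    def test_toy_cascade(self):
        # 6 loci: triallelic, MAF 0.02, 20% missing, HWE-violating, 2 clean
        n = 25
        clean = [1] * 12 + [0] * 13
        dosages = np.array(
            [
                clean,  # triallelic (flag set below)
                [1] + [0] * (n - 1),  # pooled MAF 0.02
                clean[:20] + [MISSING] * 5,  # 20% missing
                [1] * n,  # all-het: extreme HWE violation
                clean,
                list(reversed(clean)),
            ],
            dtype=np.int8,
        )
        vt, gm = make_dataset(dosages)
        vt.df.loc[0, "biallelic_snp"] = False
        vt2, gm2, report = apply_filters(vt, gm, FilterCriteria(min_call_rate=1e-9))
        assert report.n_retained == 2
        assert report.removed["biallelic"] == 1
        assert report.removed["maf"] == 1
        assert report.removed["missing"] == 1
        assert report.removed["hwe"] == 1
        report.check_conservation()

    def test_disabled_thresholds_identity(self, rng):
        dosages = rng.integers(0, 3, size=(30, 8)).astype(np.int8)
        vt, gm = make_dataset(dosages)
        off = FilterCriteria(
            maf_min=0.0, max_missing_rate=1.0, hwe_p_min=0.0, min_call_rate=1e-9
        )
        vt2, gm2, report = apply_filters(vt, gm, off)
        assert report.n_retained == 30
        np.testing.assert_array_equal(gm2.values, gm.values)

    def test_empty_input(self):
        vt, gm = make_dataset(np.zeros((0, 3), dtype=np.int8))
        vt2, gm2, report = apply_filters(vt, gm)
        assert len(vt2) == 0 and report.n_input == 0 and report.n_retained == 0

    def test_idempotent_and_conserved(self, rng):
        for seed in range(5):
            local = np.random.default_rng(seed)
            dosages = local.integers(0, 3, size=(80, 12)).astype(np.int8)
            dosages[local.random((80, 12)) < 0.15] = MISSING
            vt, gm = make_dataset(dosages)
            vt1, gm1, rep1 = apply_filters(vt, gm)
            rep1.check_conservation()
            vt2, gm2, rep2 = apply_filters(vt1, gm1)
            assert rep2.n_retained == rep1.n_retained
            assert sum(rep2.removed.values()) == 0

    def test_bad_criteria_rejected(self):
        vt, gm = make_dataset([[0, 1]])
        with pytest.raises(ValueError):
            apply_filters(vt, gm, FilterCriteria(maf_min=0.7))


class TestLdPrune:
    def test_identical_adjacent_dropped(self):
        _, gm = make_dataset([[0, 1, 2, 0, 1], [0, 1, 2, 0, 1]])
        assert list(ld_prune(gm)) == [0]

    def test_independent_kept(self):
        # orthogonal dosage patterns: r^2 = 0
        _, gm = make_dataset([[0, 0, 1, 1], [0, 1, 0, 1]])
        assert list(ld_prune(gm)) == [0, 1]

    def test_chain_hand_trace(self):
        # r2(1,2) = 1 > 0.2 so locus 2 dropped; r2(1,3) small so 3 kept
        l1 = [0, 1, 2, 0, 1, 2, 0, 1]
        l3 = [0, 0, 1, 1, 0, 2, 2, 1]
        assert dosage_r2(np.array(l1), np.array(l3)) <= 0.2
        _, gm = make_dataset([l1, l1, l3])
        assert list(ld_prune(gm)) == [0, 2]

    def test_no_high_r2_pair_survives(self, rng):
        dosages = rng.integers(0, 3, size=(40, 15)).astype(np.int8)
        _, gm = make_dataset(dosages)
        kept = ld_prune(gm, window_snps=10, step_snps=3, r2_threshold=0.3)
        vals = gm.values[kept]
        for a in range(len(kept)):
            for b in range(a + 1, min(a + 10, len(kept))):
                if kept[b] - kept[a] < 10:
                    r2 = dosage_r2(vals[a], vals[b])
                    assert np.isnan(r2) or r2 <= 0.3

    def test_window_too_small(self):
        _, gm = make_dataset([[0, 1]])
        with pytest.raises(ValueError):
            ld_prune(gm, window_snps=1)


class TestSiteUtilities:
    def test_ts_tv(self):
        vt, _ = make_dataset(np.zeros((4, 2), dtype=np.int8))
        vt.df["ref"] = ["A", "C", "G", "A"]
        vt.df["alt"] = ["G", "T", "A", "C"]
        assert ts_tv_ratio(vt) == 3.0

    def test_ts_tv_edges(self):
        vt, _ = make_dataset(np.zeros((1, 2), dtype=np.int8))
        vt.df["ref"], vt.df["alt"] = ["A"], ["C"]
        assert ts_tv_ratio(vt) == 0.0
        vt.df["alt"] = ["G"]
        assert ts_tv_ratio(vt) == float("inf")

    @pytest.mark.parametrize(
        "seq,expected", [("GCGC", 1.0), ("ATAT", 0.0), ("ATGCNN", 0.5)]
    )
    def test_gc_content(self, tmp_path, seq, expected):
        fa = tmp_path / "g.fa"
        fa.write_text(f">chr1\n{seq}\n")
        assert gc_content(str(fa)) == pytest.approx(expected)

    def test_gc_content_no_bases(self, tmp_path):
        fa = tmp_path / "n.fa"
        fa.write_text(">chr1\nNNNN\n")
        with pytest.raises(ValueError):
            gc_content(str(fa))
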