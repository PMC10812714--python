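"""Window construction, window statistics, outlier calling, gene annotation."""

import numpy as np
import pandas as pd
import pytest

from popgenscan import (
    MISSING,
    call_outliers,
    genes_in_windows,
    log2_pi_ratio,
    make_windows,
    scan,
    tajimas_d,
    window_fst,
    window_pi,
    zscore,
)
from popgenscan.sweep import tajima_constants, tajimas_d_from_sites
from popgenscan.simulate import SimConfig, simulate, truth_windows

from _oracles import pi_pairwise_counting, tajimas_d_rational
from conftest import make_dataset, two_pop_map


class TestMakeWindows:
    def test_one_mb_contig_19_windows(self):
        w = make_windows({"1": 1_000_000}, 100_000, 50_000)
        assert len(w) == 19
        assert w["start"].iloc[0] == 0 and w["start"].iloc[-1] == 900_000

    def test_short_contig_none(self):
        assert len(make_windows({"1": 90_000}, 100_000, 50_000)) == 0

    def test_tiling_when_step_equals_size(self):
        w = make_windows({"1": 1_050_000}, 100_000, 100_000)
        assert len(w) == 10
        assert (w["end"] - w["start"] == 100_000).all()

    def test_step_larger_than_size_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"1": 1_000_000}, 100_000, 200_000)


class TestWindowFst:
    def test_mean_and_min_snps(self):
        windows = pd.DataFrame({"chrom": ["1", "1"], "start": [0, 100], "end": [100, 200]})
        site_theta = pd.DataFrame(
            {
                "chrom": ["1"] * 5,
                "pos": [10, 20, 30, 110, 120],
                "theta": [1.0, 1.0, 1.0, 0.5, np.nan],
            }
        )
        out = window_fst(site_theta, windows, min_snps=1)
        assert list(out["fst_mean"]) == [1.0, 0.5]
        assert list(out["n_snps"]) == [3, 1]
        out2 = window_fst(site_theta, windows, min_snps=2)
        assert len(out2) == 1  # second window has only 1 usable site

    def test_threshold_boundary_dropped(self, rng):
        windows = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [100_000]})
        site_theta = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(1, 50), "theta": rng.random(49)}
        )
        assert len(window_fst(site_theta, windows, min_snps=50)) == 0

    def test_random_equals_groupby(self, rng):
        pos = np.sort(rng.choice(10_000, 300, replace=False)) + 1
        theta = rng.random(300)
        site_theta = pd.DataFrame({"chrom": "1", "pos": pos, "theta": theta})
        windows = make_windows({"1": 10_000}, 1000, 1000)
        out = window_fst(site_theta, windows, min_snps=1)
        for w in out.itertuples(index=False):
            mask = (pos - 1 >= w.start) & (pos - 1 < w.end)
            assert w.fst_mean == pytest.approx(theta[mask].mean(), abs=1e-12)


class TestZscore:
    def test_simple(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1])

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            zscore([2.0, 2.0, 2.0])

    def test_normalization_identity(self, rng):
        z = zscore(rng.random(100))
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-12)


class TestWindowPi:
    def test_single_site_hand_value(self):
        # 2 diploids, dosages [1, 1]: copies 0,1,0,1 -> mean pairwise
        # difference 4/6 per site; window of 100 bp
        vt, gm = make_dataset(np.array([[1, 1]], dtype=np.int8), positions=[50])
        pm = two_pop_map(2, 0)
        windows = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [100]})
        pi = window_pi(gm, pm, "A", windows, vt)
        assert pi.iloc[0] == pytest.approx((4 / 6) / 100, abs=1e-15)

    def test_no_segregating_sites_zero(self):
        vt, gm = make_dataset(np.zeros((3, 4), dtype=np.int8))
        pm = two_pop_map(4, 0)
        windows = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [1000]})
        assert window_pi(gm, pm, "A", windows, vt).iloc[0] == 0.0

    def test_equals_pairwise_counting_oracle(self, rng):
        for _ in range(20):
            n_loci = int(rng.integers(1, 15))
            d = rng.integers(0, 3, size=(n_loci, 6)).astype(np.int8)
            pos = np.sort(rng.choice(500, n_loci, replace=False)) + 1
            vt, gm = make_dataset(d, positions=pos)
            pm = two_pop_map(6, 0)
            windows = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [500]})
            pi = window_pi(gm, pm, "A", windows, vt).iloc[0]
            assert pi == pytest.approx(pi_pairwise_counting(d, 500), abs=1e-12)

    def test_missing_data_uses_per_site_copies(self):
        d = np.array([[1, MISSING, 1, 0]], dtype=np.int8)
        vt, gm = make_dataset(d, positions=[10])
        pm = two_pop_map(4, 0)
        windows = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [100]})
        pi = window_pi(gm, pm, "A", windows, vt).iloc[0]
        # 6 copies, 2 alt: pi_site = (6/5)*2*(1/3)*(2/3)
        assert pi == pytest.approx((6 / 5) * 2 * (1 / 3) * (2 / 3) / 100, abs=1e-15)


class TestLog2Ratio:
    @pytest.mark.parametrize(
        "control,test,expected",
        [(0.002, 0.0005, 2.0), (0.001, 0.001, 0.0), (0.001, 0.002, -1.0)],
    )
    def test_values(self, control, test, expected):
        assert log2_pi_ratio(control, test) == pytest.approx(expected)

    def test_degenerate(self):
        assert log2_pi_ratio(0.001, 0.0) == float("inf")
        assert np.isnan(log2_pi_ratio(0.0, 0.0))


class TestTajimasD:
    def test_no_segregating_sites_missing(self):
        vt, gm = make_dataset(np.zeros((5, 4), dtype=np.int8))
        pm = two_pop_map(4, 0)
        windows = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [1000]})
        d = tajimas_d(gm, pm, "A", next(windows.itertuples(index=False)), vt)
        assert np.isnan(d)

    def test_zero_numerator(self):
        # construct S sites whose total pi equals S/a1 by scaling impossible;
        # instead verify numerator sign flips around the S/a1 point via oracle
        n = 10
        k = tajima_constants(n)
        freqs = [(5, n)] * 4  # common variants: positive D
        assert tajimas_d_rational(freqs) > 0
        rare = [(1, n)] * 4
        assert tajimas_d_rational(rare) < 0

    def test_matches_rational_oracle(self):
        n = 10  # 5 diploids, complete data
        counts = [1, 1, 5, 9, 2]
        # build dosage columns realizing each site frequency
        d = np.zeros((5, 5), dtype=np.int8)
        for s, k in enumerate(counts):
            full, rem = divmod(k, 2)
            d[s, :full] = 2
            if rem:
                d[s, full] = 1
        vt, gm = make_dataset(d, positions=[10, 20, 30, 40, 50])
        pm = two_pop_map(5, 0)
        windows = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [100]})
        got = tajimas_d(gm, pm, "A", next(windows.itertuples(index=False)), vt)
        want = tajimas_d_rational([(min(k, 10 - k), 10) for k in counts])
        assert got == pytest.approx(want, abs=1e-12)


class TestCallOutliers:
    def _rows(self, zfst, ratio):
        n = len(zfst)
        return pd.DataFrame(
            {
                "chrom": "1",
                "start": np.arange(n) * 100,
                "end": np.arange(1, n + 1) * 100,
                "zfst": zfst,
                "log2_ratio": ratio,
            }
        )

    def test_exact_top_count(self, rng):
        vals = rng.permutation(100).astype(float)
        rows, th = call_outliers(self._rows(vals, vals[::-1].copy()), 0.95)
        assert rows["fst_outlier"].sum() == 5
        assert rows["pi_outlier"].sum() == 5
        assert th.realized_zfst_cutoff == pytest.approx(95.0)

    def test_joint_is_intersection(self, rng):
        z = np.arange(100, dtype=float)
        r = np.arange(100, dtype=float)
        r[[99, 98]] = -1  # knock two of the top-5 fst windows out of pi's top-5
        rows, _ = call_outliers(self._rows(z, r), 0.95)
        fst_set = set(rows.index[rows["fst_outlier"]])
        pi_set = set(rows.index[rows["pi_outlier"]])
        joint = set(rows.index[rows["joint_outlier"]])
        assert joint == fst_set & pi_set

    def test_too_few_windows(self, rng):
        vals = rng.random(19)
        with pytest.raises(ValueError):
            call_outliers(self._rows(vals, vals), 0.95)


class TestGenesInWindows:
    GFF = (
        "##gff-version 3\n"
        "1\tsrc\tgene\t151\t250\t.\t+\t.\tID=gene1;Name=GENEA\n"
        "1\tsrc\tgene\t51\t150\t.\t+\t.\tID=gene2;Name=GENEB\n"
    )

    def test_half_open_overlap(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(self.GFF)
        windows = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [100]})
        out = genes_in_windows(windows, str(gff))
        # gene1 spans [150,250) -> no overlap with [0,100); gene2 [50,150) does
        assert len(out) == 1
        assert out["genes"].iloc[0] == "GENEB"

    def test_matches_interval_scan(self, tmp_path, rng):
        genes = []
        for i in range(30):
            s = int(rng.integers(0, 5000))
            e = s + int(rng.integers(50, 500))
            genes.append((s, e, f"G{i}"))
        gff = tmp_path / "r.gff3"
        gff.write_text(
            "##gff-version 3\n"
            + "".join(
                f"1\tsrc\tgene\t{s + 1}\t{e}\t.\t+\t.\tID=G{i};Name={name}\n"
                for i, (s, e, name) in enumerate(genes)
            )
        )
        windows = make_windows({"1": 6000}, 1000, 500)
        out = genes_in_windows(windows, str(gff))
        got = {(w.start, w.genes) for w in out.itertuples(index=False)}
        want = {}
        for w in windows.itertuples(index=False):
            hits = [name for s, e, name in genes if s < w.end and e > w.start]
            if hits:
                want[w.start] = hits
        assert {s for s, _ in got} == set(want)
        for s, names in got:
            assert set(names.split(",")) == set(want[s])


class TestScanRecovery:
    def test_planted_sweeps_dominate_joint_outliers(self):
        cfg = SimConfig(seed=41, n_snps=20_000)
        vt, gm, pm, truth = simulate(cfg)
        rows, th = scan(vt, gm, pm, "BG", contig_lengths=cfg.contig_lengths)
        tw = truth_windows(truth, rows)
        joint = rows["joint_outlier"].to_numpy()
        assert joint.sum() > 0
        # every joint outlier lies in a planted sweep
        assert (joint & ~tw).sum() == 0
        # directionality: negative D in the swept test population, below control
        assert rows.loc[tw, "tajd_test"].mean() < 0
        assert rows.loc[tw, "tajd_test"].mean() < rows.loc[tw, "tajd_control"].mean()
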