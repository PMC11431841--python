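"""Mendelian screening, call-rate filters, depth/MQ flags, problematic table."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import capconcord as cc
from capconcord import qc
from capconcord.containers import MISSING, Trio

from conftest import make_matrix


def oracle_consistent(f: int, m: int, c: int) -> bool:
    """Independent gamete-set oracle: enumerate child genotypes explicitly."""
    gametes = {0: {0}, 1: {0, 1}, 2: {1}}
    children = {gf + gm for gf in gametes[f] for gm in gametes[m]}
    return c in children


class TestMendelian:
    def test_all_27_combinations_match_oracle(self):
        inconsistent = 0
        for f, m, c in product(range(3), repeat=3):
            expect = oracle_consistent(f, m, c)
            assert qc.mendelian_consistent(f, m, c) == expect
            assert qc.CONSISTENT[f, m, c] == expect
            inconsistent += not expect
        assert inconsistent == 12

    def test_examples(self):
        assert not qc.mendelian_consistent(0, 0, 2)
        for c in (0, 1, 2):
            assert qc.mendelian_consistent(1, 1, c)

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            qc.mendelian_consistent(0, MISSING, 1)


class TestMiFilter:
    def _matrix_with_violation(self):
        # samples: f, m, c; site 0 consistent, site 1 violated, site 2 has a
        # missing parent (uninformative)
        calls = [[0, 0, MISSING], [0, 0, 0], [0, 2, 1]]
        return make_matrix(calls, samples=["f", "m", "c"]), [Trio("c", "f", "m")]

    def test_rates_and_threshold(self):
        g, trios = self._matrix_with_violation()
        kept, table = qc.mi_filter(g, trios, threshold=0.05)
        assert table["mi_rate"].tolist()[:2] == [0.0, 1.0]
        assert np.isnan(table["mi_rate"].iloc[2])  # no informative trio
        assert table["kept"].tolist() == [True, False, True]
        assert kept.n_sites == 2

    def test_threshold_extremes(self):
        g, trios = self._matrix_with_violation()
        kept_all, _ = qc.mi_filter(g, trios, threshold=1.0)
        assert kept_all.n_sites == 3  # mi_rate > 1.0 never holds
        kept_none, _ = qc.mi_filter(g, trios, threshold=0.0)
        assert kept_none.n_sites == 2  # only the violated site goes

    def test_sex_chromosome_sites_untested(self):
        g, trios = self._matrix_with_violation()
        g.sites["chrom"] = "X"
        kept, table = qc.mi_filter(g, trios)
        assert table["mi_rate"].isna().all()
        assert kept.n_sites == 3

    def test_mi_rate_threshold_arithmetic(self):
        # 6 of 100 informative trios inconsistent -> 0.06 > 0.05 -> removed
        rng = np.random.default_rng(0)
        n_trios = 100
        samples = []
        calls = []
        trios = []
        for t in range(n_trios):
            f, m = f"f{t}", f"m{t}"
            c = f"c{t}"
            samples += [f, m, c]
            if t < 6:
                calls += [[0], [0], [2]]  # violation
            else:
                calls += [[1], [1], [int(rng.integers(0, 3))]]  # always consistent
            trios.append(Trio(c, f, m))
        g = make_matrix(np.array(calls), samples=samples)
        kept, table = qc.mi_filter(g, trios, threshold=0.05)
        assert table["mi_rate"].iloc[0] == pytest.approx(0.06)
        assert kept.n_sites == 0


class TestSampleCallRate:
    def test_below_threshold_dropped(self):
        calls = np.zeros((2, 100), dtype=np.int8)
        calls[1, :11] = MISSING  # call rate 0.89
        g = make_matrix(calls)
        kept, dropped = qc.sample_call_rate_filter(g, threshold=0.90)
        assert dropped == ["s1"]
        assert kept.samples == ["s0"]

    def test_identity_cases(self):
        g = make_matrix([[0, 1], [2, 0]])
        kept, dropped = qc.sample_call_rate_filter(g)
        assert dropped == [] and kept.n_samples == 2
        kept0, _ = qc.sample_call_rate_filter(g, threshold=0.0)
        assert kept0.n_samples == 2

    def test_all_removed_errors(self):
        g = make_matrix([[MISSING, MISSING]])
        with pytest.raises(ValueError):
            qc.sample_call_rate_filter(g, threshold=0.5)


class TestSitePass:
    @pytest.mark.parametrize(
        "depth,qual,expect",
        [(260, 60, True), (80, 60, False), (260, 20, False), (100, 20.01, True)],
    )
    def test_boundaries(self, depth, qual, expect):
        stats = pd.DataFrame({"depth_snp": [depth], "qual": [qual]})
        assert qc.site_pass_flags(stats).iloc[0] == expect


class TestIqrOutliers:
    def test_hand_example(self):
        # type-7 quartiles of {100 x8, 5, 900} are Q1 = Q3 = 100, IQR = 0
        depths = np.array([100.0] * 8 + [5.0, 900.0])
        flags = qc.iqr_depth_outliers(depths)
        assert flags[8] == "low" and flags[9] == "high"
        assert (flags[:8] == "none").all()

    def test_constant_vector_no_flags(self):
        flags = qc.iqr_depth_outliers(np.full(10, 42.0))
        assert (flags == "none").all()

    @given(st.integers(0, 2**31 - 1), st.floats(-1e5, 1e5))
    def test_translation_invariance(self, seed, shift):
        depths = np.random.default_rng(seed).gamma(5, 50, 40)
        np.testing.assert_array_equal(
            qc.iqr_depth_outliers(depths), qc.iqr_depth_outliers(depths + shift)
        )

    @given(st.integers(0, 2**31 - 1))
    def test_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        depths = rng.gamma(5, 50, 30)
        perm = rng.permutation(30)
        np.testing.assert_array_equal(
            qc.iqr_depth_outliers(depths)[perm], qc.iqr_depth_outliers(depths[perm])
        )

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            qc.iqr_depth_outliers(np.array([1.0, 2.0, 3.0]))


class TestCentralFlags:
    def test_examples_and_boundary(self):
        stats = pd.DataFrame(
            {"depth_snp": [300.0, 100.0, 250.0, 10.0], "depth_ave": [250.0, 250.0, 250.0, 0.0]}
        )
        central = qc.central_capture_flags(stats)
        assert central.iloc[0] == True  # noqa: E712
        assert central.iloc[1] == False  # noqa: E712
        assert central.iloc[2] == True  # equality counts as central
        assert pd.isna(central.iloc[3])  # depth_ave == 0 undefined


class TestLowMqRegions:
    def test_run_detection(self):
        sites = pd.DataFrame(
            {
                "chrom": ["1"] * 5,
                "pos": [1_000_000 * i for i in range(1, 6)],
                "mq": [60, 30, 30, 30, 60],
            }
        )
        regions = qc.detect_low_mq_regions(sites)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_sites) == (2_000_000, 4_000_000, 3)
        assert r.mean_mq == pytest.approx(30.0)

    def test_short_run_ignored(self):
        sites = pd.DataFrame(
            {"chrom": ["1"] * 3, "pos": [10, 20, 30], "mq": [60, 30, 60]}
        )
        assert qc.detect_low_mq_regions(sites, min_run=3) == []

    def test_run_at_chromosome_end_and_multi_chrom(self):
        sites = pd.DataFrame(
            {
                "chrom": ["1"] * 4 + ["2"] * 3,
                "pos": [10, 20, 30, 40, 5, 6, 7],
                "mq": [60, 30, 30, 30, 30, 30, 30],
            }
        )
        regions = qc.detect_low_mq_regions(sites)
        assert [(r.chrom, r.start, r.end) for r in regions] == [
            ("1", 20, 40),
            ("2", 5, 7),
        ]

    def test_unsorted_raises(self):
        sites = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [20, 10], "mq": [30, 30]}
        )
        with pytest.raises(ValueError, match="sorted"):
            qc.detect_low_mq_regions(sites)

    def test_bed_output_converts_coordinates(self, tmp_path):
        regions = [cc.RegionInterval("1", 20, 40, 30.0, 3)]
        path = tmp_path / "r.bed"
        qc.regions_to_bed(regions, path)
        line = path.read_text().splitlines()[1]
        assert line.split("\t")[:3] == ["1", "19", "40"]


class TestProblematicTable:
    def _sites(self, n):
        return pd.DataFrame(
            {
                "snp_id": [f"m{i}" for i in range(n)],
                "chrom": ["1"] * n,
                "pos": range(100, 100 + n),
                "ref": ["A"] * n,
                "alt": ["G"] * n,
            }
        )

    def test_reasons_and_union_semantics(self):
        sites = self._sites(4)
        depth_flag = np.array(["none", "low", "none", "none"], dtype=object)
        central = pd.Series([True, False, True, True])
        conc = np.array([0.4, 0.9, np.nan, 1.0])
        tab = qc.build_problematic_table(
            sites, depth_flag, central, concordance=conc
        )
        assert len(tab) == 2  # union, no double counting
        assert tab.loc[tab["snp_id"] == "m0", "reasons"].iloc[0] == "low_concordance"
        # one row for the site that is both a low outlier and non-central
        r1 = tab.loc[tab["snp_id"] == "m1", "reasons"].iloc[0]
        assert set(r1.split(",")) == {"depth_outlier_low", "non_central"}

    def test_boundary_concordance_is_problematic(self):
        sites = self._sites(1)
        tab = qc.build_problematic_table(
            sites,
            np.array(["none"], dtype=object),
            pd.Series([True]),
            concordance=np.array([0.5]),  # <= threshold flags
        )
        assert len(tab) == 1

    def test_clean_input_empty(self):
        sites = self._sites(3)
        tab = qc.build_problematic_table(
            sites,
            np.array(["none"] * 3, dtype=object),
            pd.Series([True] * 3),
            concordance=np.array([1.0, 1.0, 1.0]),
        )
        assert tab.empty
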