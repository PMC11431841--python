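"""Array TSV / VCF round trips, duplicate resolution and platform alignment."""

import numpy as np
import pandas as pd
import pytest

import capconcord as cc
from capconcord.containers import MISSING

from conftest import make_matrix


class TestArrayMatrix:
    def test_round_trip_exact(self, default_sim, tmp_path):
        _, _, arr, _ = default_sim
        path = tmp_path / "arr.tsv"
        cc.write_array_matrix(arr, path)
        back = cc.read_array_matrix(path)
        assert back.samples == arr.samples
        assert (back.calls == arr.calls).all()
        pd.testing.assert_frame_equal(back.sites, arr.sites)

    def test_call_rates(self, tmp_path):
        g = make_matrix([[0, 1, 2], [2, MISSING, 0], [1, 1, 1], [0, 0, MISSING]])
        # one NA among 4 calls for site 1 -> site call rate 0.75
        assert g.site_call_rates()[1] == pytest.approx(0.75)
        assert g.sample_call_rates()[0] == 1.0
        assert g.sample_call_rates()[1] == pytest.approx(2 / 3)

    def test_invalid_call_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "snp_id\tchrom\tpos\talleles\ts1\n"
            "a\t1\t100\tA/G\t1\n"
            "b\t1\t200\tA/G\t3\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            cc.read_array_matrix(path)

    def test_malformed_row_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "snp_id\tchrom\tpos\talleles\ts1\na\t1\t100\tAG\t1\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            cc.read_array_matrix(path)


class TestVcf:
    def test_round_trip(self, default_sim, tmp_path):
        _, truth, _, seq = default_sim
        path = tmp_path / "seq.vcf"
        cc.write_vcf(seq.genotypes, seq.allele_depth, seq.site_stats, path)
        res = cc.read_vcf_genotypes(path)
        assert res.genotypes.samples == seq.genotypes.samples
        assert (res.genotypes.calls == seq.genotypes.calls).all()
        assert (res.allele_depth.ref == seq.allele_depth.ref).all()
        assert (res.allele_depth.alt == seq.allele_depth.alt).all()
        np.testing.assert_allclose(
            res.site_stats["depth_snp"], seq.site_stats["depth_snp"], atol=1e-3
        )
        np.testing.assert_allclose(
            res.site_stats["mq"], seq.site_stats["mq"], atol=1e-6
        )

    def test_multiallelic_and_missing_gt(self, tmp_path):
        path = tmp_path / "mini.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=MQ,Number=1,Type=Float,Description="x">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t100\ta\tA\tG\t50\tPASS\tMQ=60\tGT:AD\t0/1:12,14\t./.:0,0\n"
            "1\t200\tb\tA\tG,T\t50\tPASS\tMQ=60\tGT:AD\t0/1:5,5\t0/0:9,1\n"
            "1\t300\tc\tA\tG\t50\tPASS\tMQ=60\tGT:AD\t1/1:0,30\t0/0:30,0\n"
        )
        res = cc.read_vcf_genotypes(path)
        assert res.genotypes.n_sites == 2  # multiallelic skipped
        assert res.n_skipped == 1 and res.skip_reasons == {"multiallelic": 1}
        assert res.genotypes.calls[0, 0] == 1  # GT=0/1
        assert res.genotypes.calls[1, 0] == MISSING  # GT=./.
        assert res.allele_depth.ref[0, 0] == 12
        assert res.allele_depth.alt[0, 0] == 14
        assert res.genotypes.calls[0, 1] == 2 and res.genotypes.calls[1, 1] == 0

    def test_unreadable_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            cc.read_vcf_genotypes(tmp_path / "nope.vcf")


class TestResolveDuplicates:
    def _dups(self):
        g = make_matrix(
            [[0, 1, 2], [1, MISSING, 0], [2, MISSING, 1], [0, 1, MISSING]]
        )
        # sites 0 and 1 duplicate the same position; call rates 1.0 vs 0.5
        g.sites.loc[1, "pos"] = g.sites.loc[0, "pos"]
        return g

    def test_keeps_higher_call_rate(self):
        g = self._dups()
        out = cc.resolve_duplicate_sites(g, seed=0)
        assert out.n_sites == 2
        assert "m0" in list(out.sites["snp_id"])
        assert "m1" not in list(out.sites["snp_id"])

    def test_tie_is_seed_deterministic(self):
        g = make_matrix([[0, 1], [1, 0]])
        g.sites.loc[1, "pos"] = g.sites.loc[0, "pos"]  # equal call rates
        first = cc.resolve_duplicate_sites(g, seed=123).sites["snp_id"].tolist()
        again = cc.resolve_duplicate_sites(g, seed=123).sites["snp_id"].tolist()
        assert first == again

    def test_idempotent_and_identity(self):
        g = self._dups()
        once = cc.resolve_duplicate_sites(g, seed=0)
        twice = cc.resolve_duplicate_sites(once, seed=0)
        assert (once.calls == twice.calls).all()
        clean = make_matrix([[0, 1, 2]])
        out = cc.resolve_duplicate_sites(clean, seed=0)
        assert (out.calls == clean.calls).all()


class TestIntersect:
    def test_subset_and_order(self):
        seq = make_matrix([[0, 1, 2, 0, 1]])
        arr = make_matrix([[2, 1, 0]])
        arr.sites["pos"] = [104, 102, 100]  # shares seq positions 100..104
        res = cc.intersect_common_sites(seq, arr)
        assert list(res.seq.sites["pos"]) == [100, 102, 104]
        assert list(res.arr.sites["pos"]) == [100, 102, 104]
        assert res.seq.samples == res.arr.samples
        assert (res.arr.calls == [[0, 1, 2]]).all()

    def test_swapped_alleles_recode(self):
        seq = make_matrix([[0]])
        arr = make_matrix([[0]])
        arr.sites.loc[0, ["ref", "alt"]] = ["G", "A"]  # swapped vs A/G
        res = cc.intersect_common_sites(seq, arr)
        assert res.n_swapped == 1
        assert res.arr.calls[0, 0] == 2  # 0 recoded to 2

    def test_incompatible_alleles_dropped(self):
        seq = make_matrix([[0, 1]])
        arr = make_matrix([[0, 1]])
        arr.sites.loc[1, "alt"] = "C"  # A/C vs A/G
        res = cc.intersect_common_sites(seq, arr)
        assert res.n_allele_mismatch == 1
        assert res.seq.n_sites == 1

    def test_missing_preserved_under_swap(self):
        seq = make_matrix([[0], [1]])
        arr = make_matrix([[MISSING], [1]])
        arr.sites.loc[0, ["ref", "alt"]] = ["G", "A"]
        res = cc.intersect_common_sites(seq, arr)
        assert res.arr.calls[0, 0] == MISSING
        assert res.arr.calls[1, 0] == 1

    def test_no_overlap_errors(self):
        seq = make_matrix([[0]])
        arr = make_matrix([[0]], samples=["other"])
        with pytest.raises(ValueError, match="shared samples"):
            cc.intersect_common_sites(seq, arr)
        arr2 = make_matrix([[0]], chrom="2")
        with pytest.raises(ValueError, match="shared .chrom, pos."):
            cc.intersect_common_sites(seq, arr2)
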