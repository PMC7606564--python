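"""Enrichment statistics, TPM, NAD ratios, small-RNA clustering, BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nadscape.core import SampleMeta, samples_to_frame
from nadscape.enrich import (cluster_small_rnas, enrichment_test,
                             nad_ratio_qpcr, nad_ratio_tpm, size_factors, tpm)
from nadscape.stats import bh_fdr


def _meta():
    return samples_to_frame([SampleMeta(f"{g}{r}", "wt", g, r)
                             for g in "SN" for r in (1, 2, 3)])


COLS = ["S1", "S2", "S3", "N1", "N2", "N3"]


class TestSizeFactors:
    def test_doubled_sample_gets_double_factor(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]},
                              index=["g1", "g2", "g3"])
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_single_sample_factor_is_one(self):
        counts = pd.DataFrame({"a": [10, 20]}, index=["g1", "g2"])
        assert size_factors(counts)["a"] == pytest.approx(1.0)

    def test_matches_bruteforce_median_of_ratios(self, rng):
        counts = pd.DataFrame(rng.integers(1, 200, size=(5, 3)),
                              index=list("abcde"), columns=["x", "y", "z"])
        sf = size_factors(counts)
        logg = np.log(counts.to_numpy(float))
        ref = np.exp(logg.mean(axis=1))
        for j, c in enumerate(counts.columns):
            expected = np.median(counts.to_numpy(float)[:, j] / ref)
            assert sf[c] == pytest.approx(expected)

    def test_no_universally_expressed_feature_raises(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="pseudo-count"):
            size_factors(counts)


class TestEnrichmentTest:
    def _run(self, rows, **kw):
        counts = pd.DataFrame(rows, columns=COLS)
        counts.index = [f"g{i}" for i in range(len(counts))]
        return enrichment_test(counts, _meta(), **kw)

    def test_identical_groups_are_ns_with_unit_fc(self):
        res = self._run([[50, 52, 48, 50, 52, 48], [5, 6, 4, 5, 6, 4]])
        assert (res["verdict"] == "ns").all()
        assert np.allclose(res["fc"], 1.0, atol=0.01)

    def test_strong_contrast_called_enriched(self):
        res = self._run([[100, 110, 90, 10, 9, 11]] + [[50, 52, 48, 50, 52, 48]] * 5)
        assert res.loc[0, "verdict"] == "enriched"
        assert res.loc[0, "fc"] == pytest.approx(10, rel=0.2)

    def test_p_value_within_order_of_magnitude_of_rate_ratio_oracle(self):
        rows = [[30, 33, 27, 15, 14, 16]] + [[40, 38, 42, 41, 39, 40]] * 10
        res = self._run(rows, disp_floor=1e-6)
        s_tot, n_tot = 30 + 33 + 27, 15 + 14 + 16
        oracle = sps.binomtest(s_tot, s_tot + n_tot, 0.5).pvalue
        assert 0.1 * oracle <= res.loc[0, "p_value"] <= 10 * oracle

    def test_fc_just_below_threshold_is_ns_even_with_tiny_p(self):
        # true FC = 1.40 < 1.414: strict threshold keeps it ns
        rows = [[1400, 1401, 1399, 1000, 1001, 999]] + [[50] * 6] * 10
        res = self._run(rows)
        assert res.loc[0, "p_value"] < 1e-4
        assert 1.39 < res.loc[0, "fc"] < 1.414
        assert res.loc[0, "verdict"] == "ns"

    def test_all_zero_feature_is_ns_with_p_one(self):
        res = self._run([[0] * 6, [50, 52, 48, 50, 52, 48]])
        assert res.loc[0, "p_value"] == 1.0 and res.loc[0, "verdict"] == "ns"

    def test_requires_two_replicates_per_group(self):
        counts = pd.DataFrame([[1, 2]], columns=["S1", "N1"], index=["g"])
        meta = samples_to_frame([SampleMeta("S1", "wt", "S", 1),
                                 SampleMeta("N1", "wt", "N", 1)])
        with pytest.raises(ValueError, match="replicates"):
            enrichment_test(counts, meta)

    def test_type_one_error_calibrated_on_null_simulations(self):
        """Null generator data (rho = 0, equal depths): the NB Wald test
        rejects at the nominal 5% level within +-2 points."""
        from nadscape.readproc import count_features
        from nadscape.simulate import SimConfig, make_genome, simulate_reads
        hits = []
        for seed in range(20):
            rng = np.random.default_rng(4000 + seed)
            cfg = SimConfig(n_genes=500, null_fraction=1.0, reads_per_gene=3000,
                            small_rna_fraction=0.0)
            genome, annots, truths = make_genome(cfg, rng)
            aln, _s, samples, _m = simulate_reads(
                genome, annots, truths, cfg, "dxo1d_npy1d_rai1d", rng)
            counts, _ = count_features(aln, annots)
            res = enrichment_test(counts, samples_to_frame(samples),
                                  strain="dxo1d_npy1d_rai1d")
            hits.append((res["p_value"] < 0.05).mean())
        assert 0.03 <= np.mean(hits) <= 0.07

    def test_agrees_with_deseq2_on_simulated_counts(self):
        """Independent cross-check: pyDESeq2 on the same count matrix gives
        near-identical log2 fold changes."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats
        from nadscape.readproc import count_features
        from nadscape.simulate import SimConfig, make_genome, simulate_reads
        rng = np.random.default_rng(5)
        cfg = SimConfig(n_genes=80, reads_per_gene=2000)
        genome, annots, truths = make_genome(cfg, rng)
        aln, _s, samples, _m = simulate_reads(
            genome, annots, truths, cfg, "dxo1d_npy1d_rai1d", rng)
        counts, _ = count_features(aln, annots)
        meta = samples_to_frame(samples)
        mine = enrichment_test(counts, meta,
                               strain="dxo1d_npy1d_rai1d").set_index("feature_id")
        cT = counts.T
        md = meta.set_index("sample_id")[["group"]].loc[cT.index]
        dds = DeseqDataSet(counts=cT, metadata=md, design="~group", quiet=True)
        dds.deseq2()
        st = DeseqStats(dds, contrast=["group", "S", "N"], quiet=True)
        st.summary()
        merged = mine.join(st.results_df, how="inner")
        r = np.corrcoef(merged["log2fc"], merged["log2FoldChange"])[0, 1]
        assert r > 0.99
        agree = ((merged["p_value"] < 0.05) == (merged["pvalue"] < 0.05)).mean()
        assert agree > 0.9


class TestTpmAndRatios:
    def test_single_feature_gets_all_mass(self):
        t = tpm(pd.DataFrame({"s": [7]}, index=["g"]), pd.Series({"g": 500}))
        assert t.at["g", "s"] == pytest.approx(1e6)

    def test_length_normalization_ratio(self):
        counts = pd.DataFrame({"s": [100, 100]}, index=["a", "b"])
        t = tpm(counts, pd.Series({"a": 1000, "b": 2000}))
        assert t.at["a", "s"] / t.at["b", "s"] == pytest.approx(2.0)

    def test_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, size=(10, 2)),
                              index=[f"g{i}" for i in range(10)],
                              columns=["x", "y"])
        lengths = pd.Series(rng.integers(200, 2000, size=10),
                            index=counts.index)
        t = tpm(counts, lengths)
        assert np.allclose(t.sum(axis=0), 1e6, atol=1e-6)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            tpm(pd.DataFrame({"s": [1]}, index=["g"]), pd.Series({"g": 0}))

    def test_ratio_linearity(self):
        nad = pd.Series({"a": 10.0, "b": 20.0})
        allc = pd.Series({"a": 10.0, "b": 10.0})
        r = nad_ratio_tpm(0.02, nad, allc).set_index("feature_id")["ratio"]
        assert r["a"] == pytest.approx(0.02)
        assert r["b"] == pytest.approx(0.04)

    def test_ratio_invariant_to_library_depth(self, rng):
        # multiplying all counts of one sample by a constant changes no TPM,
        # hence no ratio
        counts = pd.DataFrame(rng.integers(1, 500, size=(8, 2)),
                              index=[f"g{i}" for i in range(8)],
                              columns=["S1", "T1"])
        lengths = pd.Series(rng.integers(200, 900, size=8), index=counts.index)
        t1 = tpm(counts, lengths)
        t2 = tpm(counts.assign(S1=counts["S1"] * 13), lengths)
        r1 = nad_ratio_tpm(0.03, t1["S1"], t1["T1"])["ratio"]
        r2 = nad_ratio_tpm(0.03, t2["S1"], t2["T1"])["ratio"]
        assert np.allclose(r1, r2)

    def test_ratio_omits_zero_denominator_and_validates_k(self):
        nad = pd.Series({"a": 10.0, "b": 5.0})
        allc = pd.Series({"a": 10.0, "b": 0.0})
        out = nad_ratio_tpm(0.02, nad, allc)
        assert out["feature_id"].tolist() == ["a"]
        with pytest.raises(ValueError):
            nad_ratio_tpm(0.0, nad, allc)

    @pytest.mark.parametrize("s,bg,nc,expected", [
        (10, 2, 88, 8 / 98),
        (5, 8, 95, 0.0),   # background exceeds signal: clipped
        (5, 0, 95, 0.05),
    ])
    def test_qpcr_ratio_formula(self, s, bg, nc, expected):
        assert nad_ratio_qpcr(s, bg, nc) == pytest.approx(expected)

    def test_qpcr_zero_denominator_is_missing(self):
        assert np.isnan(nad_ratio_qpcr(0, 0, 0))


class TestSmallRnaClusters:
    @staticmethod
    def _df(rows):
        return pd.DataFrame(rows, columns=["sequence", "strand",
                                           "copies_S", "copies_N"])

    def test_identical_sequences_form_one_cluster(self):
        out = cluster_small_rnas(self._df([("ACGTACGTACGT", "+", 30, 10),
                                           ("ACGTACGTACGT", "+", 5, 2)]))
        assert len(out) == 1
        assert out.loc[0, ["copies_S", "copies_N"]].tolist() == [35, 12]
        assert out.loc[0, "enrichment"] == pytest.approx(35 / 12)

    def test_similarity_threshold_separates_clusters(self):
        a = "ACGTACGTACGT"
        b = "TGCAAGGTACGT"  # 5 of 12 differ -> 58% identity
        out = cluster_small_rnas(self._df([(a, "+", 10, 1), (b, "+", 8, 1)]))
        assert len(out) == 2

    def test_opposite_strands_never_cluster(self):
        a = "ACGTACGTACGT"
        out = cluster_small_rnas(self._df([(a, "+", 10, 1), (a, "-", 8, 1)]))
        assert len(out) == 2

    def test_copy_number_ratio_cap(self):
        a = "ACGTACGTACGT"
        b = "ACGTACGTACGA"  # 92% identical
        out = cluster_small_rnas(self._df([(a, "+", 1000, 0), (b, "+", 10, 0)]))
        assert len(out) == 2  # ratio 100 > 50 keeps them apart
        out = cluster_small_rnas(self._df([(a, "+", 300, 0), (b, "+", 10, 0)]))
        assert len(out) == 1  # ratio 31 is allowed

    def test_zero_n_copies_flagged_not_guessed(self):
        out = cluster_small_rnas(self._df([("ACGTACGTACGT", "+", 10, 0)]))
        assert out.loc[0, "status"] == "n_zero"
        assert np.isinf(out.loc[0, "enrichment"])


class TestBhFdr:
    def test_textbook_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate_inputs(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_bruteforce_definition_and_monotone(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 50))
            got = bh_fdr(p)
            n = p.size
            brute = np.empty(n)
            order = np.argsort(p)
            prev = 1.0
            for rank_idx in range(n - 1, -1, -1):
                i = order[rank_idx]
                prev = min(prev, p[i] * n / (rank_idx + 1))
                brute[i] = prev
            assert np.allclose(got, brute)
            assert (np.diff(got[order]) >= -1e-12).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_rank_monotonicity(self, p):
        p = np.asarray(p)
        q = bh_fdr(p)
        assert ((q >= 0) & (q <= 1)).all()
        assert (q >= p / p.size - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
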