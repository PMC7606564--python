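"""TSS clusters, the linear trend test, sharp-A calls, promoter matrices,
TSS shifts and the transcript-leader length index."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nadscape.core import GenomeAnnotation
from nadscape.tss import (TrendResult, call_sharp_a, compute_tli,
                          detect_tss_clusters, linear_trend_test,
                          promoter_matrix, trend_statistic, tss_shift_table)


def _table(tl, s, n):
    return pd.DataFrame({"tl": tl, "count_S": s, "count_N": n})


class TestClusterDetection:
    def test_point_mass_gives_single_cluster(self):
        out = detect_tss_clusters(np.full(30, 40), np.full(10, 40), 120)
        assert len(out) == 1
        assert out.loc[0].tolist() == [40, 30, 10]

    def test_two_separated_spikes_give_two_clusters(self):
        tl_s = np.concatenate([np.full(30, 20), np.full(20, 60)])
        out = detect_tss_clusters(tl_s, np.array([], dtype=int), 120)
        assert out["tl"].tolist() == [20, 60]
        assert out["count_S"].tolist() == [30, 20]

    def test_greedy_matches_bruteforce_oracle(self, rng):
        """Oracle: literal re-implementation of the greedy sliding-window
        extraction on dense count vectors."""

        def oracle(pooled, window=18, min_reads=2):
            pooled = pooled.astype(float).copy()
            spans = []
            while True:
                sums = np.array([pooled[j:j + window].sum()
                                 for j in range(len(pooled) - window + 1)])
                j = int(np.argmax(sums))
                if sums[j] < min_reads:
                    break
                spans.append(j)
                pooled[j:j + window] = 0
            return spans

        for _ in range(30):
            max_tl = 60
            n = int(rng.integers(2, 12))
            tl_s = rng.integers(0, max_tl + 1, size=n)
            tl_n = rng.integers(0, max_tl + 1, size=int(rng.integers(0, 8)))
            pooled = (np.bincount(tl_s, minlength=max_tl + 1)
                      + np.bincount(tl_n, minlength=max_tl + 1))
            got = detect_tss_clusters(tl_s, tl_n, max_tl)
            assert len(got) == len(oracle(pooled))
            assert got["count_S"].sum() + got["count_N"].sum() >= 0

    def test_cluster_representatives_sorted_and_nonoverlapping(self, rng):
        tl_s = rng.integers(0, 121, size=200)
        out = detect_tss_clusters(tl_s, np.array([], dtype=int), 120)
        assert (np.diff(out["tl"]) > 0).all()


class TestTrendStatistic:
    def test_independent_table_gives_zero_trend(self):
        res = linear_trend_test(_table([50, 100], [10, 10], [10, 10]))
        assert res.testable
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.m2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_perfect_association_reaches_m2_of_n_minus_one(self):
        res = linear_trend_test(_table([50, 100], [15, 0], [0, 15]))
        assert abs(res.r) == pytest.approx(1.0)
        assert res.m2 == pytest.approx(29.0)
        assert res.p == pytest.approx(sps.chi2.sf(29.0, 1))

    def test_equals_per_observation_expansion(self):
        r, m2, p = trend_statistic([10, 5], [5, 10], [40, 90])
        x = np.concatenate([np.repeat(2, 15), np.repeat(1, 15)])
        y = np.concatenate([np.repeat([40, 90], [10, 5]),
                            np.repeat([40, 90], [5, 10])])
        r_o = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(r_o, abs=1e-12)
        assert m2 == pytest.approx(29 * r_o ** 2, abs=1e-12)

    def test_oracle_equivalence_on_random_tables(self, rng):
        worst = 0.0
        for _ in range(200):
            n = int(rng.integers(2, 7))
            y = np.sort(rng.choice(np.arange(1, 150), size=n, replace=False))
            s = rng.integers(0, 25, size=n)
            t = rng.integers(0, 25, size=n)
            if s.sum() == 0 or t.sum() == 0:
                continue
            r, m2, _ = trend_statistic(s, t, y.astype(float))
            x = np.concatenate([np.repeat(2, s.sum()), np.repeat(1, t.sum())])
            yy = np.concatenate([np.repeat(y, s), np.repeat(y, t)])
            if np.std(x) == 0 or np.std(yy) == 0:
                continue
            r_o = np.corrcoef(x, yy)[0, 1]
            worst = max(worst, abs(r - r_o),
                        abs(m2 - (x.size - 1) * r_o ** 2))
        assert worst < 1e-10

    @pytest.mark.parametrize("tl,s,n", [
        ([50, 100], [5, 5], [5, 5]),        # n_obs = 20 < 30
        ([50], [40], [40]),                 # single cluster
        ([50, 100], [20, 20], [0, 0]),      # empty N row
    ])
    def test_untestable_configurations_flagged_not_raised(self, tl, s, n):
        res = linear_trend_test(_table(tl, s, n))
        assert not res.testable and np.isnan(res.p)

    def test_depth_normalization_makes_n_row_scale_invariant(self):
        base = _table([30, 80, 110], [40, 10, 25], [10, 20, 8])
        doubled = _table([30, 80, 110], [40, 10, 25], [20, 40, 16])
        r1, r2 = linear_trend_test(base), linear_trend_test(doubled)
        assert r1.r == pytest.approx(r2.r)
        assert r1.m2 == pytest.approx(r2.m2)


class TestSharpA:
    @staticmethod
    def _setup(tl_counts, base_at_mode="A"):
        """One +strand gene; plant reads at given TL -> count mapping and a
        chosen genome base under the modal position."""
        annot = GenomeAnnotation("g1", "chr1", "+", tls_pos=200,
                                 canonical_tss=150, tes_pos=500)
        rows = []
        for tl, c in tl_counts.items():
            pos = 200 - tl
            rows += [("chr1", pos, pos + 40, "+", "s")] * c
        aln = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                          "sample_id"])
        mode_tl = max(tl_counts, key=lambda k: tl_counts[k])
        seq = ["T"] * 700
        seq[200 - mode_tl] = base_at_mode
        return aln, {"g1": annot}, {"chr1": "".join(seq)}

    def test_sharp_ratio_and_base_rule(self):
        aln, annots, genome = self._setup({40: 40, 41: 5})
        out = call_sharp_a(aln, annots, genome, ["s"])
        assert out.loc[0, "sharp_value"] == pytest.approx(8.0)
        assert bool(out.loc[0, "is_sharp_a"])

    def test_threshold_is_strict(self):
        aln, annots, genome = self._setup({40: 12, 41: 4})
        out = call_sharp_a(aln, annots, genome, ["s"])
        assert out.loc[0, "sharp_value"] == pytest.approx(3.0)
        assert not bool(out.loc[0, "is_sharp_a"])

    def test_non_a_base_never_sharp_a(self):
        aln, annots, genome = self._setup({40: 50, 41: 2}, base_at_mode="G")
        out = call_sharp_a(aln, annots, genome, ["s"])
        assert out.loc[0, "sharp_value"] > 4
        assert not bool(out.loc[0, "is_sharp_a"])

    def test_zero_upstream_count_floored_to_one(self):
        aln, annots, genome = self._setup({40: 30})
        out = call_sharp_a(aln, annots, genome, ["s"])
        assert out.loc[0, "sharp_value"] == pytest.approx(30.0)


class TestPromoterMatrix:
    GENES = {"g1": GenomeAnnotation("g1", "chr1", "+", tls_pos=100,
                                    canonical_tss=60, tes_pos=300)}

    def test_degenerate_windows_have_high_ic_and_aag_consensus(self):
        seq = "T" * 50 + "AAG" + "A" * 8 + "T" * 300
        genome = {"chr1": seq}
        calls = pd.DataFrame({"gene_id": ["g1"] * 25, "tss_pos": [50] * 25})
        pm = promoter_matrix(calls, self.GENES, genome)
        assert (pm.ic > 1.7).all()
        cons = pm.consensus()
        assert cons[10:13] == "AAG"  # positions +1..+3

    def test_uniform_windows_have_near_zero_ic(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=4000))}
        genes = {f"g{i}": GenomeAnnotation(f"g{i}", "chr1", "+",
                                           tls_pos=i * 3 + 60,
                                           canonical_tss=i * 3 + 20,
                                           tes_pos=i * 3 + 300)
                 for i in range(1000)}
        calls = pd.DataFrame({"gene_id": list(genes),
                              "tss_pos": [20 + 3 * i for i in range(1000)]})
        pm = promoter_matrix(calls, genes, genome)
        assert (pm.ic < 0.2).all()

    def test_off_contig_window_skipped(self):
        calls = pd.DataFrame({"gene_id": ["g1"], "tss_pos": [5]})
        pm = promoter_matrix(calls, self.GENES, {"chr1": "ACGT" * 100})
        assert pm.n_sites == 0

    def test_columns_sum_to_one(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=500))}
        calls = pd.DataFrame({"gene_id": ["g1"], "tss_pos": [60]})
        pm = promoter_matrix(calls, self.GENES, genome)
        assert np.allclose(pm.pfm.sum(axis=0), 1.0)


class TestTssShift:
    def test_identical_distributions_are_unshifted(self, rng):
        tl = rng.integers(30, 60, size=80)
        out = tss_shift_table({"g": tl}, {"g": tl.copy()})
        assert out.loc[0, "delta"] == 0
        assert out.loc[0, "direction"] == "none"

    def test_large_upstream_shift_called_distal(self, rng):
        ref = 40 + rng.integers(-2, 3, size=50)
        s = 100 + rng.integers(-2, 3, size=50)
        out = tss_shift_table({"g": s}, {"g": ref})
        assert out.loc[0, "direction"] == "distal"
        assert out.loc[0, "delta"] == pytest.approx(60, abs=4)

    def test_point_reference_uses_sign_test(self, rng):
        s = 70 + rng.integers(-2, 3, size=60)
        out = tss_shift_table({"g": s}, {"g": 40.0})
        assert out.loc[0, "direction"] == "distal"
        out2 = tss_shift_table({"g": s}, {"g": 70.0})
        assert out2.loc[0, "direction"] == "none"


class TestTli:
    def test_identical_distributions_give_zero(self, rng):
        tl = rng.integers(20, 80, size=100)
        tli, res = compute_tli(tl, tl.copy(), window_length=120)
        assert tli == pytest.approx(0.0)

    def test_shift_scaled_by_window(self, rng):
        a = 40 + rng.integers(-1, 2, size=200)
        b = 60 + rng.integers(-1, 2, size=200)
        tli, res = compute_tli(a, b, window_length=120)
        assert tli == pytest.approx(20 / 120, abs=0.01)
        assert res.testable and res.p < 1e-6
        # doubling the window halves the index exactly
        tli2, _ = compute_tli(a, b, window_length=240)
        assert tli2 == pytest.approx(tli / 2)

    def test_antisymmetry(self, rng):
        a = rng.integers(20, 60, size=150)
        b = rng.integers(40, 90, size=150)
        t_ab, _ = compute_tli(a, b, 120)
        t_ba, _ = compute_tli(b, a, 120)
        assert t_ab == pytest.approx(-t_ba)
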