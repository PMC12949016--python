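"""Allelic ingestion, SNP filtering, biallelic calling and the Yates chi-square."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from xci_scope.allelic import (
    AllelicCountSet,
    aggregate_gene_calls,
    call_allelic_expression,
    contingency_test,
    filter_snps,
    map_snps_to_genes,
    xist_allele_sharing,
)

from conftest import make_matrix


def make_set(ad, dp, gene_ids=None, positions=None):
    ad, dp = np.asarray(ad), np.asarray(dp)
    n_snps, n_cells = ad.shape
    snps = pd.DataFrame(
        {
            "chromosome": ["X"] * n_snps,
            "position": positions if positions is not None else np.arange(1, n_snps + 1) * 100,
            "ref_allele": ["A"] * n_snps,
            "alt_allele": ["G"] * n_snps,
            "gene_id": gene_ids if gene_ids is not None else [f"gene{i}" for i in range(n_snps)],
            "region_class": ["exonic"] * n_snps,
        }
    )
    return AllelicCountSet(
        snps=snps,
        alt_depth=sp.csr_matrix(ad),
        total_depth=sp.csr_matrix(dp),
        cell_ids=pd.Index([f"c{i}" for i in range(n_cells)], name="barcode"),
    )


class TestValidationAndMapping:
    def test_ad_above_dp_is_hard_error(self):
        with pytest.raises(ValueError, match="AD exceeds DP"):
            make_set([[5]], [[3]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            AllelicCountSet(
                snps=pd.DataFrame({"chromosome": ["X"], "position": [1], "ref_allele": ["A"],
                                   "alt_allele": ["G"], "gene_id": ["g"], "region_class": ["exonic"]}),
                alt_depth=sp.csr_matrix(np.zeros((2, 3))),
                total_depth=sp.csr_matrix(np.zeros((2, 3))),
                cell_ids=pd.Index(["c0", "c1", "c2"]),
            )

    def test_containment_assignment_and_multi_flag(self):
        s = make_set([[0], [0], [0]], [[2], [2], [2]], positions=[1500, 1550, 9999])
        genes = make_matrix([[1, 1, 1]], chroms=["X", "X", "X"]).genes
        # g0 spans 1000-1100, g1 2000-2100... widen g0/g1 to overlap position 1550
        genes.loc["g0", ["start", "end"]] = [1000, 1600]
        genes.loc["g1", ["start", "end"]] = [1540, 2100]
        mapped = map_snps_to_genes(s, genes)
        assert mapped.snps["gene_id"].tolist()[0] == "g0"
        assert mapped.snps["gene_id"].tolist()[1] == "MULTI"
        assert pd.isna(mapped.snps["gene_id"].tolist()[2])


class TestFilterSnps:
    @pytest.mark.parametrize(
        "ad_row,dp_row,kept",
        [
            ([9, 10], [9, 10], False),  # depth 19 < 20
            ([1, 0], [13, 12], False),  # MAF 1/25 = 0.04 < 0.05
            ([5, 0], [13, 12], True),  # depth 25, MAF 0.2
        ],
    )
    def test_depth_and_maf_boundaries(self, ad_row, dp_row, kept):
        s = make_set([ad_row], [dp_row])
        assert (filter_snps(s).n_snps == 1) == kept

    def test_multi_gene_snps_dropped(self):
        s = make_set([[10]], [[30]], gene_ids=["MULTI"])
        assert filter_snps(s).n_snps == 0

    @given(st.integers(min_value=0, max_value=60))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_min_count(self, cut):
        rng = np.random.default_rng(0)
        dp = rng.integers(0, 30, size=(12, 4))
        ad = rng.binomial(dp, 0.4)
        s = make_set(ad, dp)
        low = set(filter_snps(s, min_count=cut).snps["position"])
        high = set(filter_snps(s, min_count=cut + 5).snps["position"])
        assert high <= low


class TestAllelicCalls:
    def _genes(self):
        genes = make_matrix([[1, 1, 1]], chroms=["X", "X", "X"],
                            statuses=["inactivated"] * 3).genes
        return genes

    def test_biallelic_and_monoallelic_rules(self):
        # one SNP per gene; cell0: ref=3/alt=2 -> biallelic; cell1: ref=5 -> mono;
        # cell2: single read -> uninformative
        ad = [[2, 0, 0]]
        dp = [[5, 5, 1]]
        s = make_set(ad, dp, gene_ids=["g0"])
        table = call_allelic_expression(s, self._genes(), "inactivated")
        calls = table.gene_calls.set_index("cell_id")["call"]
        assert calls["c0"] == "biallelic"
        assert calls["c1"] == "monoallelic"
        assert "c2" not in calls.index

    def test_opposite_phase_snps_do_not_fake_biallelic(self):
        # same gene, two SNPs, monoallelic cell expressing ref at one and alt
        # at the other (opposite phases): still monoallelic
        ad = [[0], [4]]
        dp = [[3], [4]]
        s = make_set(ad, dp, gene_ids=["g0", "g0"])
        table = call_allelic_expression(s, self._genes(), "inactivated")
        assert table.gene_calls["call"].tolist() == ["monoallelic"]

    def test_majority_aggregation_matches_enumeration_oracle(self):
        for combo in itertools.product(["biallelic", "monoallelic", "uninformative"], repeat=3):
            informative = [c for c in combo if c != "uninformative"]
            if not informative:
                expected = "uninformative"
            else:
                n_bi = informative.count("biallelic")
                n_mono = informative.count("monoallelic")
                expected = "biallelic" if n_bi >= n_mono else "monoallelic"  # ties -> biallelic
            assert aggregate_gene_calls(list(combo)) == expected

    def test_alternative_rules(self):
        assert aggregate_gene_calls(["biallelic", "monoallelic", "monoallelic"], rule="any") == "biallelic"
        assert aggregate_gene_calls(["biallelic", "monoallelic", "monoallelic"], rule="all") == "monoallelic"

    def test_synthetic_truth_discrimination(self, small_cohort, small_matrix):
        m = small_matrix
        s = filter_snps(map_snps_to_genes(small_cohort.allelic, m.genes))
        table = call_allelic_expression(s, m.genes, "inactivated")
        truth = small_cohort.truth["xci_state"]
        joined = pd.DataFrame({"call": table.cell_calls}).join(truth)
        bi_rate = lambda st_: (joined.loc[joined["xci_state"] == st_, "call"] == "biallelic").mean()
        assert bi_rate("XaXa_reactivated") >= 0.85
        assert 1 - bi_rate("Xa_duplicated") >= 0.85
        assert 1 - bi_rate("XaXi") >= 0.85


class TestXistSharing:
    def _profile(self, n, sample="s1", status="XISTpos"):
        return pd.DataFrame(
            {"sample_id": [sample] * n, "xist_status": [status] * n},
            index=pd.Index([f"c{i}" for i in range(n)], name="barcode"),
        )

    def test_all_cells_same_allele_gives_one(self):
        ad = [np.full(10, 0)]
        dp = [np.full(10, 4)]
        s = make_set(ad, dp, gene_ids=["XIST"])
        res = xist_allele_sharing(s, self._profile(10))
        assert res["sharing_fraction"].iloc[0] == pytest.approx(1.0)

    def test_even_split_gives_half(self):
        ad = [np.array([4] * 5 + [0] * 5)]
        dp = [np.full(10, 4)]
        s = make_set(ad, dp, gene_ids=["XIST"])
        res = xist_allele_sharing(s, self._profile(10))
        assert res["sharing_fraction"].iloc[0] == pytest.approx(0.5)

    def test_no_xist_snps_not_evaluable(self):
        s = make_set([[0]], [[4]], gene_ids=["other"])
        res = xist_allele_sharing(s, self._profile(1))
        assert np.isnan(res["sharing_fraction"]).all()

    def test_simulated_shared_xi_samples(self, small_cohort, small_matrix):
        from xci_scope.xci_dosage import compute_xci_profile

        profile = compute_xci_profile(small_matrix)
        s = filter_snps(map_snps_to_genes(small_cohort.allelic, small_matrix.genes))
        res = xist_allele_sharing(s, profile).set_index("sample_id")
        for sid, sex in zip(["S01", "S02", "S03"], ["XX", "XX", "XY"]):
            if sex == "XX":
                assert res.loc[sid, "sharing_fraction"] >= 0.95


class TestYatesChiSquare:
    @staticmethod
    def _oracle(a, b, c, d):
        # independent closed-form evaluation, written before the implementation
        n = a + b + c + d
        diff = abs(a * d - b * c)
        if diff <= n / 2:
            return 0.0
        return n * (diff - n / 2) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))

    def test_no_association_gives_zero(self):
        res = contingency_test([[10, 10], [10, 10]])
        assert res.chi2_yates == 0.0
        assert res.p_two_sided == pytest.approx(1.0)

    def test_hand_oracle_value(self):
        res = contingency_test([[20, 80], [80, 20]])
        assert res.chi2_yates == pytest.approx(self._oracle(20, 80, 80, 20), abs=1e-12)
        ref = chi2_contingency(np.array([[20, 80], [80, 20]]), correction=True)
        assert res.chi2_yates == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-9)

    def test_random_tables_match_oracle_and_scipy(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            a, b, c, d = rng.integers(1, 200, size=4)
            res = contingency_test([[a, b], [c, d]])
            assert res.chi2_yates == pytest.approx(self._oracle(a, b, c, d), abs=1e-9)

    @given(st.tuples(*[st.integers(min_value=1, max_value=500)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_yates_never_exceeds_uncorrected(self, cells):
        a, b, c, d = cells
        res = contingency_test([[a, b], [c, d]])
        uncorrected = chi2_contingency(np.array([[a, b], [c, d]]), correction=False).statistic
        assert res.chi2_yates <= uncorrected + 1e-12

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_test([[0, 0], [5, 5]])

    def test_synthetic_cohort_association_is_significant(self, small_cohort, small_matrix):
        from xci_scope.cnv_x import classify_xaxa, infer_relative_dosage, x_duplication_proportion
        from xci_scope.xci_dosage import compute_xci_profile

        m = small_matrix
        profile = compute_xci_profile(m)
        ref = m.cell_ids[(m.cell_meta["broad_lineage"] == "immune").to_numpy()]
        d = infer_relative_dosage(m, ref)
        profile["x_dup_proportion"] = x_duplication_proportion(d)
        profile["xaxa_call"] = classify_xaxa(profile)
        s = filter_snps(map_snps_to_genes(small_cohort.allelic, m.genes))
        table = call_allelic_expression(s, m.genes, "inactivated")
        joined = profile.join(table.cell_calls.rename("allelic"), how="inner")
        sub = joined[joined["xaxa_call"].isin(["XaXa_like", "XaXi"]) & joined["allelic"].isin(["biallelic", "monoallelic"])]
        ct = pd.crosstab(sub["xaxa_call"], sub["allelic"])
        res = contingency_test(ct.to_numpy())
        assert res.p_two_sided < 1e-4
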