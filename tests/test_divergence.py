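"""Global alignment, percent divergence, nPD normalization, pair enumeration."""

import itertools

import numpy as np
import pytest

from genescape.divergence import (
    align_global,
    divergence_from_values,
    enumerate_pairs,
    normalize_npd,
    pairwise_divergence,
)
from genescape.errors import UndefinedValueError

from oracles import AffineOracle


class TestAlignGlobal:
    def test_self_alignment_is_identical(self):
        res = align_global("MKV", "MKV")
        assert res.identity_percent == 100.0 and res.divergence_percent == 0.0

    def test_single_mismatch(self):
        res = align_global("AAAA", "AAAT")
        assert res.identity_percent == pytest.approx(75.0)
        assert "-" not in res.aligned_a + res.aligned_b

    def test_single_gap_column(self):
        res = align_global("MKV", "MV")
        assert (res.aligned_a + res.aligned_b).count("-") == 1
        assert res.identity_percent == pytest.approx(100 * 2 / 3, abs=5e-4)

    def test_degapped_rows_equal_inputs(self):
        res = align_global("MKVLLAG", "MLAG")
        assert res.aligned_a.replace("-", "") == "MKVLLAG"
        assert res.aligned_b.replace("-", "") == "MLAG"

    def test_identity_symmetric(self):
        rng = np.random.default_rng(0)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(20):
            a = "".join(rng.choice(aas, rng.integers(3, 12)))
            b = "".join(rng.choice(aas, rng.integers(3, 12)))
            assert align_global(a, b).identity_percent == pytest.approx(
                align_global(b, a).identity_percent
            )

    def test_bad_symbols_listed(self):
        with pytest.raises(ValueError, match="B, J"):
            align_global("MKBJ", "MV")
        with pytest.raises(ValueError):
            align_global("", "MV")

    def test_matches_dp_oracle_on_short_peptides(self):
        oracle = AffineOracle()
        rng = np.random.default_rng(1)
        letters = np.array(list("AGLK"))
        for _ in range(60):
            a = "".join(rng.choice(letters, rng.integers(1, 6)))
            b = "".join(rng.choice(letters, rng.integers(1, 6)))
            best, idents = oracle.optimal_identities(a, b)
            res = align_global(a, b)
            assert res.score == best
            assert round(res.identity_percent, 9) in idents


class TestPairwiseDivergence:
    def test_identity_filter_and_divergence(self):
        recs = divergence_from_values(["A", "B", "C"], [0.0, 20.0, 75.0], ("gg", "hs"))
        assert [r.divergence_percent for r in recs] == [0.0, 20.0, 75.0]
        assert [r.included for r in recs] == [True, True, False]  # identity 25 < 30

    def test_identical_catalogs_all_zero(self):
        cats = {"a": {"G1": "MKVL", "G2": "GARP"}, "b": {"G1": "MKVL", "G2": "GARP"}}
        recs = pairwise_divergence(cats, ("a", "b"))
        assert all(r.divergence_percent == 0.0 and r.included for r in recs)

    def test_no_shared_genes_is_an_error(self):
        with pytest.raises(ValueError):
            pairwise_divergence({"a": {"G1": "MK"}, "b": {"G2": "MK"}}, ("a", "b"))

    def test_nan_values_skipped(self):
        recs = divergence_from_values(["A", "B"], [10.0, np.nan], ("x", "y"))
        assert [r.symbol for r in recs] == ["A"]


class TestNormalizeNPD:
    def test_simple_ratios(self):
        recs = divergence_from_values(["A", "B", "C"], [10.0, 20.0, 30.0], ("x", "y"))
        npd = [r.npd for r in normalize_npd(recs)]
        assert npd == pytest.approx([0.5, 1.0, 1.5])

    def test_unit_mean_by_construction(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 60, 500)
        recs = normalize_npd(divergence_from_values([f"G{i}" for i in range(500)], vals, ("x", "y")))
        included = [r.npd for r in recs if r.included]
        assert np.mean(included) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        # stay below the 30%-identity exclusion cut even after rescaling,
        # so the included set is unchanged
        syms = [f"G{i}" for i in range(50)]
        vals = np.linspace(1, 50, 50)
        npd1 = [r.npd for r in normalize_npd(divergence_from_values(syms, vals, ("x", "y")))]
        npd3 = [r.npd for r in normalize_npd(divergence_from_values(syms, vals * 1.3, ("x", "y")))]
        assert npd1 == pytest.approx(npd3)

    def test_excluded_records_get_no_npd(self):
        recs = normalize_npd(divergence_from_values(["A", "B"], [10.0, 90.0], ("x", "y")))
        assert recs[1].npd is None

    def test_all_excluded_is_an_error(self):
        recs = divergence_from_values(["A"], [95.0], ("x", "y"))
        with pytest.raises(UndefinedValueError):
            normalize_npd(recs)


class TestEnumeratePairs:
    def test_study_panel_counts(self):
        ps = enumerate_pairs([f"AV{i}" for i in range(8)], [f"NA{i}" for i in range(4)])
        assert ps.counts == {
            "avian//avian": 28,
            "avian//non_avian": 32,
            "non_avian//non_avian": 6,
        }

    def test_class_blocks_in_listing_order(self):
        ps = enumerate_pairs(["a1", "a2"], ["n1", "n2"])
        assert [t for *_, t in ps.pairs] == (
            ["avian//avian"] + ["avian//non_avian"] * 4 + ["non_avian//non_avian"]
        )

    @pytest.mark.parametrize("na,nn", [(2, 1), (5, 3), (8, 4)])
    def test_counts_match_combinatorics(self, na, nn):
        ps = enumerate_pairs([f"a{i}" for i in range(na)], [f"n{i}" for i in range(nn)])
        assert ps.counts["avian//avian"] == na * (na - 1) // 2
        assert ps.counts["avian//non_avian"] == na * nn
        assert ps.counts["non_avian//non_avian"] == nn * (nn - 1) // 2
        assert len(ps.pairs) == len(set((a, b) for a, b, _ in ps.pairs))
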