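"""Downstream summaries: fold changes, modules, enzymes, HQ MAGs, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magquant import summary
from magquant.io import parse_module_expression
from magquant.model import (
    AGG_MEDIAN,
    AGG_SUM,
    KeyEnzymeGroup,
    ProcessMetadata,
    UNBINNED,
    ValidationError,
)
from .conftest import make_catalog, make_mags

counts_st = st.floats(min_value=0, max_value=1e5, allow_nan=False)


class TestFoldChange:
    def test_equal_counts_give_zero(self):
        assert summary.log2fc(5.0, 5.0) == pytest.approx(0.0)

    def test_forced_value_six_vs_zero(self):
        assert summary.log2fc(6.0, 0.0, 2.0) == pytest.approx(2.0)

    def test_default_offset_is_two(self):
        assert summary.DEFAULT_OFFSET == 2.0

    def test_nonpositive_offset_rejected(self):
        with pytest.raises(ValidationError):
            summary.log2fc(1.0, 1.0, 0.0)

    @given(x=counts_st, y=counts_st, s=st.floats(0.5, 10))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, x, y, s):
        assert summary.log2fc(x, y, s) == pytest.approx(-summary.log2fc(y, x, s), abs=1e-9)

    def test_record_list_matches_vectorized_table(self):
        m = pd.DataFrame({"D1": [6.0, 3.0], "D2": [0.0, 3.0]}, index=["K1", "K2"])
        records = summary.log2_fold_change(m, ("D1", "D2"))
        table = summary.fold_change_table(m, ("D1", "D2"))
        for rec in records:
            assert rec.log2fc == pytest.approx(table.at[rec.ko_id, "log2fc"])
        assert records[0].log2fc == pytest.approx(2.0)


class TestDeriveOffset:
    def test_linear_interpolation_then_half_up_rounding(self):
        m = pd.DataFrame({"a": [0, 0, 1, 2, 3], "b": [4, 5, 6, 7, 10]}, dtype=float)
        # sorted pool percentile 30 (linear) = 1.7 -> rounds to 2
        assert summary.derive_offset(m) == 2.0

    def test_constant_matrix_returns_the_constant(self):
        m = pd.DataFrame({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert summary.derive_offset(m) == 5.0

    def test_floor_of_one_with_warning(self):
        m = pd.DataFrame({"a": [0.0, 0.0, 0.0, 100.0]})
        with pytest.warns(UserWarning, match="clamped"):
            assert summary.derive_offset(m) == 1.0

    def test_nonzero_universe_drops_zeros(self):
        m = pd.DataFrame({"a": [0.0, 0.0, 0.0, 4.0, 4.0]})
        assert summary.derive_offset(m, universe="nonzero") == 4.0


class TestMaxPairwiseFoldChange:
    def test_flat_row_is_zero(self):
        assert summary.max_pairwise_fold_change([4.0, 4.0, 4.0]) == pytest.approx(0.0)

    def test_forced_zero_zero_six(self):
        assert summary.max_pairwise_fold_change([0.0, 0.0, 6.0], 2.0) == pytest.approx(2.0)

    @given(row=st.tuples(counts_st, counts_st, counts_st))
    @settings(max_examples=100, deadline=None)
    def test_matches_exhaustive_pair_oracle(self, row):
        got = summary.max_pairwise_fold_change(row, 2.0)
        brute = max(
            abs(np.log2((a + 2.0) / (b + 2.0))) for a, b in itertools.combinations(row, 2)
        )
        assert got == pytest.approx(brute, abs=1e-9)


class TestModuleLogic:
    MOD4 = parse_module_expression("M1", "K1 K2 K3 K4")

    @pytest.mark.parametrize(
        "kos, pct, retained",
        [
            ({"K1", "K2", "K3", "K4"}, 100.0, True),
            ({"K1", "K2", "K3"}, 75.0, True),  # missing one block still retained
            ({"K1", "K2"}, 50.0, False),
        ],
    )
    def test_four_block_module_scoring(self, kos, pct, retained):
        (score,) = summary.module_completeness(kos, [self.MOD4])
        assert score.completeness_pct == pytest.approx(pct)
        assert score.retained is retained

    def test_alternatives_and_complexes(self):
        mod = parse_module_expression("M2", "K1,K2 K3+K4")
        (s1,) = summary.module_completeness({"K2", "K3"}, [mod])
        assert s1.blocks_satisfied == 1  # complex needs both K3 and K4
        (s2,) = summary.module_completeness({"K2", "K3", "K4"}, [mod])
        assert s2.blocks_satisfied == 2

    @given(
        extra=st.sets(st.sampled_from(["K1", "K2", "K3", "K4", "K9"]), max_size=5),
        base=st.sets(st.sampled_from(["K1", "K2", "K3", "K4"]), max_size=4),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_under_ko_addition(self, base, extra):
        (before,) = summary.module_completeness(base, [self.MOD4])
        (after,) = summary.module_completeness(base | extra, [self.MOD4])
        assert after.blocks_satisfied >= before.blocks_satisfied


class TestModuleActivity:
    def catalog(self):
        return make_catalog(
            [
                ("g1", "c1", "M1", 900, "K1", 90.0, 1e-30),
                ("g2", "c1", "M1", 600, "K2", 90.0, 1e-30),
                ("g3", "c1", "M1", 500, "K9", 90.0, 1e-30),
            ]
        )

    def test_module_share_of_mag_spectra(self):
        mod = parse_module_expression("M00002", "K1 K2")
        spectra = pd.DataFrame({"D2": [3.0, 2.8, 94.2]}, index=["g1", "g2", "g3"])
        act = summary.module_activity("M1", mod, spectra, self.catalog())
        assert act["D2"] == pytest.approx(0.058)

    def test_unexpressed_module_is_zero(self):
        mod = parse_module_expression("M1", "K7")
        spectra = pd.DataFrame({"D1": [3.0, 2.0, 5.0]}, index=["g1", "g2", "g3"])
        act = summary.module_activity("M1", mod, spectra, self.catalog())
        assert act["D1"] == 0.0

    def test_all_spectra_in_module_is_one(self):
        mod = parse_module_expression("M1", "K1 K2 K9")
        spectra = pd.DataFrame({"D1": [3.0, 2.0, 5.0]}, index=["g1", "g2", "g3"])
        act = summary.module_activity("M1", mod, spectra, self.catalog())
        assert act["D1"] == pytest.approx(1.0)

    def test_zero_spectra_mag_warns_and_returns_zero(self):
        mod = parse_module_expression("M1", "K1")
        spectra = pd.DataFrame({"D1": [0.0, 0.0, 0.0]}, index=["g1", "g2", "g3"])
        with pytest.warns(UserWarning):
            act = summary.module_activity("M1", mod, spectra, self.catalog())
        assert act["D1"] == 0.0


class TestEnzymeSummary:
    AGCN = pd.DataFrame({"D1": [1.0, 3.0], "D2": [2.0, 2.0]}, index=["K1", "K2"])
    SPECTRA = pd.DataFrame({"D1": [5.0, 7.0], "D2": [0.0, 1.0]}, index=["K1", "K2"])

    def test_median_for_subunits_sum_for_similar(self):
        groups = [
            KeyEnzymeGroup("complex", ("K1", "K2"), AGG_MEDIAN, "acidogenesis"),
            KeyEnzymeGroup("family", ("K1", "K2"), AGG_SUM, "acidogenesis"),
        ]
        out = summary.enzyme_level_summary(self.AGCN, self.SPECTRA, groups)
        assert out.at["complex", ("agcn", "D1")] == pytest.approx(2.0)
        assert out.at["family", ("agcn", "D1")] == pytest.approx(4.0)

    def test_spectral_counts_always_summed(self):
        groups = [KeyEnzymeGroup("complex", ("K1", "K2"), AGG_MEDIAN, "acidogenesis")]
        out = summary.enzyme_level_summary(self.AGCN, self.SPECTRA, groups)
        assert out.at["complex", ("spectra", "D1")] == pytest.approx(12.0)

    def test_unknown_mode_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            KeyEnzymeGroup("x", ("K1",), "mean", "acidogenesis")


class TestSpectralThresholdFilter:
    def test_boundary_inclusive(self):
        t = pd.DataFrame({"D1": [9.0, 0.0], "D2": [9.0, 10.0], "D3": [9.0, 0.0]}, index=["low", "edge"])
        out = summary.spectral_threshold_filter(t)
        assert list(out.index) == ["edge"]

    def test_empty_table_passes_through(self):
        t = pd.DataFrame(columns=["D1"])
        assert len(summary.spectral_threshold_filter(t)) == 0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.uniform(0, 30, (20, 3)), columns=["D1", "D2", "D3"])
        once = summary.spectral_threshold_filter(t)
        pd.testing.assert_frame_equal(summary.spectral_threshold_filter(once), once)


class TestHqMagFilter:
    def profiles(self, mags, g=None, p=None):
        idx = list(mags.mag_ids) + [UNBINNED]
        g = pd.DataFrame({"D1": g if g is not None else [1.0] * len(idx)}, index=idx)
        p = pd.DataFrame({"D1": p if p is not None else [1.0] * len(idx)}, index=idx)
        return g, p

    def test_completeness_boundary_is_strict(self):
        mags = make_mags([("M1", 50.0, 1.0)])
        g, p = self.profiles(mags)
        assert len(summary.hq_mag_filter(mags, g, p)) == 0

    def test_typical_hq_mag_included(self):
        mags = make_mags([("M1", 83.0, 3.0)])
        g, p = self.profiles(mags, g=[0.1, 99.9], p=[2.65, 97.35])
        hq = summary.hq_mag_filter(mags, g, p)
        assert list(hq.mag_ids) == ["M1"]

    def test_abundance_clause_excludes_rare_mags(self):
        mags = make_mags([("M1", 90.0, 9.0)])
        g, p = self.profiles(mags, g=[0.4, 99.6], p=[0.4, 99.6])
        assert len(summary.hq_mag_filter(mags, g, p)) == 0

    def test_contamination_boundary_is_strict(self):
        mags = make_mags([("M1", 90.0, 10.0)])
        g, p = self.profiles(mags)
        assert len(summary.hq_mag_filter(mags, g, p)) == 0

    def test_missing_profile_row_is_an_error(self):
        mags = make_mags([("M1", 90.0, 1.0), ("M2", 90.0, 1.0)])
        g = pd.DataFrame({"D1": [1.0]}, index=["M1"])
        with pytest.raises(ValidationError, match="M2"):
            summary.hq_mag_filter(mags, g, g)

    def test_invariant_to_row_order(self):
        mags = make_mags([("M1", 83.0, 3.0), ("M2", 60.0, 2.0), ("M3", 40.0, 2.0)])
        shuffled = make_mags([("M3", 40.0, 2.0), ("M1", 83.0, 3.0), ("M2", 60.0, 2.0)])
        idx = ["M1", "M2", "M3", UNBINNED]
        g = pd.DataFrame({"D1": [5.0, 1.0, 5.0, 89.0]}, index=idx)
        a = summary.hq_mag_filter(mags, g, g)
        b = summary.hq_mag_filter(shuffled, g.loc[idx[::-1]], g)
        assert list(a.mag_ids) == list(b.mag_ids)


class TestSummarizeCategories:
    def test_all_hq_abundant_no_unbinned(self):
        mags = make_mags([("M1", 90.0, 1.0), ("M2", 90.0, 1.0)])
        idx = ["M1", "M2", UNBINNED]
        g = pd.DataFrame({"D1": [60.0, 40.0, 0.0]}, index=idx)
        out = summary.summarize_categories(mags, None, g, g)
        col = out[("genomic", "D1")]
        assert col.tolist() == pytest.approx([0.0, 0.0, 100.0])

    def test_known_composition_matches_hand_partition(self):
        mags = make_mags(
            [("M1", 90.0, 1.0), ("M2", 90.0, 1.0), ("M3", 30.0, 1.0)]
        )
        idx = ["M1", "M2", "M3", UNBINNED]
        g = pd.DataFrame({"D1": [50.0, 0.3, 10.0, 39.7], "D2": [20.0, 0.2, 30.0, 49.8]}, index=idx)
        p = pd.DataFrame({"D1": [40.0, 0.1, 20.0, 39.9], "D2": [10.0, 0.1, 40.0, 49.9]}, index=idx)
        out = summary.summarize_categories(mags, None, g, p)
        # M1 HQ above (max 50), M2 HQ below (max 0.3), M3 low quality
        assert out.at["hq_above_threshold", ("genomic", "D1")] == pytest.approx(50.0)
        assert out.at["hq_below_threshold", ("genomic", "D1")] == pytest.approx(0.3)
        assert out.at["unbinned_and_low_quality", ("genomic", "D1")] == pytest.approx(49.7)
        assert out.at["unbinned_and_low_quality", ("proteomic", "D2")] == pytest.approx(89.9)

    def test_columns_sum_to_100(self):
        rng = np.random.default_rng(2)
        mags = make_mags([(f"M{i}", rng.uniform(30, 100), rng.uniform(0, 15)) for i in range(8)])
        idx = list(mags.mag_ids) + [UNBINNED]
        raw = rng.uniform(0, 1, (9, 3))
        g = pd.DataFrame(100 * raw / raw.sum(axis=0), index=idx, columns=["D1", "D2", "D3"])
        out = summary.summarize_categories(mags, None, g, g)
        assert np.allclose(out.sum(axis=0), 100.0, atol=0.01)


class TestKeyPathwayPresence:
    def test_single_expressed_ko_marks_category(self):
        cat = make_catalog(
            [
                ("g1", "c1", "M1", 900, "K00399", 90.0, 1e-30),
                ("g2", "c1", "M1", 600, "K00925", 90.0, 1e-30),
            ]
        )
        groups = [
            KeyEnzymeGroup("mcr", ("K00399",), AGG_MEDIAN, "methanogenesis"),
            KeyEnzymeGroup("ack", ("K00925",), AGG_SUM, "acidogenesis"),
        ]
        spectra = pd.DataFrame({"D1": [4.0, 0.0], "D2": [0.0, 0.0]}, index=["g1", "g2"])
        out = summary.key_pathway_presence("M1", groups, spectra, cat)
        assert out.at["methanogenesis", "D1"]
        assert not out.at["methanogenesis", "D2"]
        assert not out.at["acidogenesis", "D1"]

    def test_zero_spectra_all_false(self):
        cat = make_catalog([("g1", "c1", "M1", 900, "K00399", 90.0, 1e-30)])
        groups = [KeyEnzymeGroup("mcr", ("K00399",), AGG_MEDIAN, "methanogenesis")]
        spectra = pd.DataFrame({"D1": [0.0]}, index=["g1"])
        out = summary.key_pathway_presence("M1", groups, spectra, cat)
        assert not out.to_numpy().any()

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(3)
        kos = [f"K{i:05d}" for i in range(6)]
        cat = make_catalog(
            [(f"g{i}", "c1", "M1", 900, kos[i], 90.0, 1e-30) for i in range(6)]
        )
        groups = [
            KeyEnzymeGroup(f"e{i}", (kos[2 * i], kos[2 * i + 1]), AGG_SUM, cat_name)
            for i, cat_name in enumerate(["hydrolysis", "acidogenesis", "acetogenesis"])
        ]
        spectra = pd.DataFrame(
            rng.integers(0, 2, (6, 3)).astype(float), index=[f"g{i}" for i in range(6)], columns=["D1", "D2", "D3"]
        )
        out = summary.key_pathway_presence("M1", groups, spectra, cat)
        for g in groups:
            for cond in ("D1", "D2", "D3"):
                brute = any(
                    spectra.at[f"g{i}", cond] > 0
                    for i in range(6)
                    if kos[i] in g.ko_ids
                )
                assert out.at[g.ad_category, cond] == brute


class TestMetadataCorrelations:
    def meta(self):
        return ProcessMetadata(
            pd.DataFrame(
                {"temperature": [44.5, 50.0, 56.3], "olr": [4.53, 4.32, 0.41]},
                index=pd.Index(["D1", "D2", "D3"], name="condition_id"),
            )
        )

    def test_exact_linear_gives_plus_one(self):
        taxa = pd.DataFrame({"D1": [44.5], "D2": [50.0], "D3": [56.3]}, index=["t1"])
        out = summary.metadata_correlations(taxa, self.meta())
        assert out.at["t1", "temperature"] == pytest.approx(1.0)

    def test_exact_negative_linear_gives_minus_one(self):
        taxa = pd.DataFrame({"D1": [-44.5], "D2": [-50.0], "D3": [-56.3]}, index=["t1"])
        out = summary.metadata_correlations(taxa, self.meta())
        assert out.at["t1", "temperature"] == pytest.approx(-1.0)

    def test_constant_vector_reported_missing_not_zero(self):
        meta = ProcessMetadata(
            pd.DataFrame(
                {"hrt": [70.0, 70.0, 70.0]},
                index=pd.Index(["D1", "D2", "D3"], name="condition_id"),
            )
        )
        taxa = pd.DataFrame({"D1": [1.0], "D2": [2.0], "D3": [3.0]}, index=["t1"])
        with pytest.warns(UserWarning, match="undefined"):
            out = summary.metadata_correlations(taxa, meta)
        assert np.isnan(out.at["t1", "hrt"])

    def test_replicates_expand_via_condition_map(self):
        taxa = pd.DataFrame(
            {"D1_r1": [44.5], "D1_r2": [44.5], "D2_r1": [50.0], "D3_r1": [56.3]},
            index=["t1"],
        )
        cmap = pd.Series({"D1_r1": "D1", "D1_r2": "D1", "D2_r1": "D2", "D3_r1": "D3"})
        out = summary.metadata_correlations(taxa, self.meta(), cmap)
        assert out.at["t1", "temperature"] == pytest.approx(1.0)

    def test_dimension_mismatch_is_an_error(self):
        taxa = pd.DataFrame({"X1": [1.0], "X2": [2.0], "X3": [3.0]}, index=["t1"])
        with pytest.raises(ValidationError):
            summary.metadata_correlations(taxa, self.meta())
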