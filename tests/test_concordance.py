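"""Cross-exposure, cross-sex and cross-tissue comparison statistics."""

import numpy as np
import pandas as pd
import pytest

from crossomics.concordance import (
    FeatureSetCollection,
    compare_tables,
    cross_tissue_match,
    cross_tissue_sharing_test,
    direction_concordance,
    exposure_sharing_profile,
    region_set_annotation,
    sex_concordance,
)
from crossomics.genomic_io import interval_key


def collection_from(layout, kind="DEG", tissue="liver", sex="female",
                    make=None):
    """layout: exposure -> list of (feature, log2fc)."""
    coll = FeatureSetCollection()
    for exposure, feats in layout.items():
        tbl = make([f for f, _ in feats], [e for _, e in feats])
        coll.add(exposure, sex, tissue, kind, tbl)
    return coll


class TestExposureSharing:
    def test_counts_and_bins(self, diff_table_factory):
        coll = collection_from(
            {"bpa": [("A", 1), ("B", 1)], "tbt": [("B", 1), ("C", -1)],
             "pb": [("D", 1)]},
            make=diff_table_factory,
        )
        res = exposure_sharing_profile(coll, "female", "liver", "DEG")
        per = res["per_feature"].set_index(["exposure", "feature"])
        assert per.loc[("bpa", "B"), "n_exposures_any"] == 2
        assert per.loc[("bpa", "A"), "n_exposures_any"] == 1
        s = res["summary"]
        assert s["n_features"] == 4  # A, B, C, D
        assert s["fraction_shared_ge2"] == pytest.approx(0.25)
        assert s["fraction_by_count"]["1"] == pytest.approx(0.75)

    def test_same_direction_count_respects_sign(self, diff_table_factory):
        coll = collection_from(
            {"bpa": [("B", 1.0)], "tbt": [("B", -1.0)]},
            make=diff_table_factory,
        )
        res = exposure_sharing_profile(coll, "female", "liver", "DEG")
        per = res["per_feature"].set_index(["exposure", "feature"])
        assert per.loc[("bpa", "B"), "n_exposures_any"] == 2
        assert per.loc[("bpa", "B"), "n_exposures_same_direction"] == 1

    def test_disjoint_sets_share_nothing(self, diff_table_factory):
        coll = collection_from(
            {"a": [("X", 1)], "b": [("Y", 1)], "c": [("Z", 1)]},
            make=diff_table_factory,
        )
        res = exposure_sharing_profile(coll, "female", "liver", "DEG")
        assert res["summary"]["fraction_shared_ge2"] == 0.0

    def test_dmr_sharing_uses_interval_overlap(self, diff_table_factory):
        coll = FeatureSetCollection()
        t1 = diff_table_factory([interval_key("chr1", 100, 300)], [0.3])
        t1["delta"] = 0.3
        t2 = diff_table_factory([interval_key("chr1", 299, 500)], [0.2])
        t2["delta"] = 0.2
        coll.add("bpa", "female", "liver", "DMR", t1)
        coll.add("tbt", "female", "liver", "DMR", t2)
        res = exposure_sharing_profile(coll, "female", "liver", "DMR")
        assert res["summary"]["fraction_shared_ge2"] == 1.0

    def test_single_exposure_is_an_error(self, diff_table_factory):
        coll = collection_from({"bpa": [("A", 1)]}, make=diff_table_factory)
        with pytest.raises(ValueError, match=">= 2"):
            exposure_sharing_profile(coll, "female", "liver", "DEG")


class TestCrossTissueMatch:
    def test_gene_sets_match_by_id(self, diff_table_factory):
        a = diff_table_factory(["A", "B", "C"], [1, 1, -1])
        b = diff_table_factory(["B", "C", "D"], [1, 1, 1])
        pairs = cross_tissue_match(a, b, "DEG")
        assert sorted(pairs["feature_a"]) == ["B", "C"]

    def test_dmr_single_base_rule(self, diff_table_factory):
        a = diff_table_factory([interval_key("chr1", 100, 300)], [0.3])
        a["delta"] = 0.3
        b = diff_table_factory([interval_key("chr1", 299, 400)], [0.2])
        b["delta"] = 0.2
        assert len(cross_tissue_match(a, b, "DMR")) == 1
        b2 = diff_table_factory([interval_key("chr1", 300, 400)], [0.2])
        b2["delta"] = 0.2
        assert len(cross_tissue_match(a, b2, "DMR")) == 0

    def test_dar_exact_mode_requires_identical_coordinates(self, diff_table_factory):
        a = diff_table_factory([interval_key("chr1", 0, 200)], [1.0])
        b = diff_table_factory([interval_key("chr1", 0, 201)], [1.0])
        assert len(cross_tissue_match(a, b, "DAR")) == 0
        assert len(cross_tissue_match(a, b, "DAR", dar_mode="overlap",
                                      dar_min_overlap=100)) == 1

    def test_multi_partner_dmr_yields_pair_per_partner(self, diff_table_factory):
        a = diff_table_factory([interval_key("chr1", 0, 1000)], [0.3])
        a["delta"] = 0.3
        b = diff_table_factory(
            [interval_key("chr1", 10, 20), interval_key("chr1", 500, 600)],
            [0.2, -0.2],
        )
        b["delta"] = [0.2, -0.2]
        pairs = cross_tissue_match(a, b, "DMR")
        assert len(pairs) == 2


class TestDirectionConcordance:
    def test_two_of_three_agree(self):
        pairs = pd.DataFrame({"effect_a": [1, 1, -1], "effect_b": [2, -3, -1]})
        frac, nzero = direction_concordance(pairs)
        assert frac == pytest.approx(2 / 3)
        assert nzero == 0

    def test_zero_effects_excluded_and_counted(self):
        pairs = pd.DataFrame({"effect_a": [1, 0], "effect_b": [1, 5]})
        frac, nzero = direction_concordance(pairs)
        assert frac == 1.0
        assert nzero == 1

    def test_empty_is_missing_not_zero(self):
        frac, _ = direction_concordance(pd.DataFrame(columns=["effect_a", "effect_b"]))
        assert np.isnan(frac)


class TestSharingTest:
    def test_full_containment_probability(self, diff_table_factory):
        a = diff_table_factory(list("ABCDE"), [1] * 5)
        b = diff_table_factory(list("ABCDE"), [1] * 5)
        res = cross_tissue_sharing_test(a, b, universe=10)
        assert res["p"] == pytest.approx(1 / 252, rel=1e-9)

    def test_no_sharing_gives_p_one(self, diff_table_factory):
        a = diff_table_factory(["A"], [1])
        b = diff_table_factory(["B"], [1])
        assert cross_tissue_sharing_test(a, b, universe=10)["p"] == 1.0

    def test_universe_policies(self, diff_table_factory):
        a = diff_table_factory(list("AB"), [1, 1], p=[1e-6, 1e-6])
        extra_a = diff_table_factory(["C"], [0.0], significant=[False])
        a = pd.concat([a, extra_a], ignore_index=True)
        b = diff_table_factory(list("BD"), [1, 1])
        inter = cross_tissue_sharing_test(a, b, universe="intersection")
        union = cross_tissue_sharing_test(a, b, universe="union")
        assert inter["N"] == 1  # only B tested in both
        assert union["N"] == 4
        with pytest.raises(ValueError, match="outside"):
            cross_tissue_sharing_test(a, b, universe=["B"])

    def test_swap_symmetry(self, diff_table_factory, rng):
        feats_a = [f"g{i}" for i in rng.choice(60, 25, replace=False)]
        feats_b = [f"g{i}" for i in rng.choice(60, 30, replace=False)]
        a = diff_table_factory(feats_a, rng.normal(size=25))
        b = diff_table_factory(feats_b, rng.normal(size=30))
        r1 = cross_tissue_sharing_test(a, b, universe=60)
        r2 = cross_tissue_sharing_test(b, a, universe=60)
        assert r1["s"] == r2["s"]
        assert r1["p"] == pytest.approx(r2["p"], rel=1e-12)


class TestCompareTables:
    def test_shared_singleton_has_missing_correlation(self, diff_table_factory):
        a = diff_table_factory(["A", "B"], [1, 2])
        b = diff_table_factory(["B", "C"], [2, 1])
        rep = compare_tables(a, b, "DEG")
        assert rep["n_pairs"] == 1
        assert np.isnan(rep["correlation"])
        assert rep["a_only"] == 1 and rep["b_only"] == 1

    def test_proportional_effects_correlate_perfectly(self, diff_table_factory):
        a = diff_table_factory(["A", "B", "C"], [1, 2, 3])
        b = diff_table_factory(["A", "B", "C"], [2, 4, 6])
        rep = compare_tables(a, b, "DEG")
        assert rep["correlation"] == pytest.approx(1.0)
        assert rep["direction_concordance"] == 1.0
        b_neg = diff_table_factory(["A", "B", "C"], [-2, -4, -6])
        rep2 = compare_tables(a, b_neg, "DEG")
        assert rep2["correlation"] == pytest.approx(-1.0)
        assert rep2["direction_concordance"] == 0.0

    def test_tissue_swap_preserves_shared_count_and_p(self, diff_table_factory, rng):
        feats_a = [f"g{i}" for i in rng.choice(100, 40, replace=False)]
        feats_b = [f"g{i}" for i in rng.choice(100, 35, replace=False)]
        a = diff_table_factory(feats_a, rng.normal(size=40))
        b = diff_table_factory(feats_b, rng.normal(size=35))
        r1 = compare_tables(a, b, "DEG", universe=100)
        r2 = compare_tables(b, a, "DEG", universe=100)
        assert r1["n_pairs"] == r2["n_pairs"]
        assert r1["hypergeom_p"] == pytest.approx(r2["hypergeom_p"], rel=1e-12)
        assert (r1["a_only"], r1["b_only"]) == (r2["b_only"], r2["a_only"])

    def test_sex_concordance_wiring(self, diff_table_factory):
        coll = FeatureSetCollection()
        coll.add("bpa", "female", "blood", "DEG",
                 diff_table_factory(["A", "B", "C"], [1, 2, 3]))
        coll.add("bpa", "male", "blood", "DEG",
                 diff_table_factory(["B", "C", "D"], [2, 3, 1]))
        rep = sex_concordance(coll, "bpa", "blood", "DEG")
        assert rep["side_a"] == "female"
        assert rep["n_pairs"] == 2


class TestRegionAnnotation:
    def test_feature_overlapping_two_regions_counts_once(self, diff_table_factory):
        feats = diff_table_factory(
            [interval_key("chr1", 0, 500), interval_key("chr1", 1000, 1100),
             interval_key("chr2", 0, 100)],
            [1, 1, 1],
        )
        regions = pd.DataFrame({"chrom": ["chr1", "chr1"],
                                "start": [10, 300], "end": [20, 400]})
        flags, total = region_set_annotation(feats, regions)
        assert total == 1
        assert flags[interval_key("chr1", 0, 500)]

    def test_empty_region_set_counts_zero(self, diff_table_factory):
        feats = diff_table_factory([interval_key("chr1", 0, 500)], [1])
        flags, total = region_set_annotation(
            feats, pd.DataFrame(columns=["chrom", "start", "end"])
        )
        assert total == 0
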