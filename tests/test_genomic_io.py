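"""Readers/writers and interval algebra."""

import warnings

import numpy as np
import pandas as pd
import pytest

from crossomics.genomic_io import (
    CountMatrix,
    ParseError,
    SchemaError,
    check_chromosome_compatibility,
    intersect_regions,
    interval_key,
    intervals_from_keys,
    merge_regions,
    parse_interval_key,
    read_bed,
    read_count_matrix,
    read_cytosine_report,
    read_differential_table,
    read_sample_sheet,
    write_bed,
    write_count_matrix,
    write_cytosine_report,
    write_differential_table,
    write_sample_sheet,
)


def brute_force_pairs(a, b, min_overlap):
    out = []
    for ai, x in a.iterrows():
        for bi, y in b.iterrows():
            if x["chrom"] != y["chrom"]:
                continue
            ov = min(x["end"], y["end"]) - max(x["start"], y["start"])
            if ov >= min_overlap:
                out.append((ai, bi))
    return set(out)


def random_intervals(rng, n, chroms=("chr1", "chr2")):
    chrom = rng.choice(chroms, size=n)
    start = rng.integers(0, 5000, size=n)
    length = rng.integers(1, 400, size=n)
    return pd.DataFrame({"chrom": chrom, "start": start, "end": start + length})


class TestCytosineReport:
    def test_one_based_positions_shift_to_internal(self, tmp_path):
        f = tmp_path / "r.tsv"
        f.write_text("chr1\t100\t+\t7\t3\nchr1\t200\t-\t0\t12\n")
        df = read_cytosine_report(f)
        assert df["pos"].tolist() == [99, 199]
        assert df["meth"].tolist() == [7, 0]

    def test_round_trip_is_lossless(self, tmp_path):
        f = tmp_path / "r.tsv"
        f.write_text("chr1\t100\t+\t7\t3\nchr2\t5\t+\t1\t9\n")
        df = read_cytosine_report(f)
        g = tmp_path / "w.tsv"
        write_cytosine_report(df, g)
        assert read_cytosine_report(g).equals(df)

    def test_empty_file_warns_and_yields_empty(self, tmp_path):
        f = tmp_path / "empty.tsv"
        f.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            df = read_cytosine_report(f)
        assert len(df) == 0

    @pytest.mark.parametrize(
        "line",
        ["chr1\t100\t+\tx\t3", "chr1\t0\t+\t1\t3", "chr1\t100\t*\t1\t3",
         "chr1\t100\t+\t-1\t3", "chr1\t100"],
    )
    def test_malformed_lines_name_the_line(self, tmp_path, line):
        f = tmp_path / "bad.tsv"
        f.write_text("chr1\t50\t+\t1\t1\n" + line + "\n")
        with pytest.raises(ParseError, match=":2"):
            read_cytosine_report(f)


class TestBed:
    def test_basic_and_round_trip(self, tmp_path, rng):
        f = tmp_path / "a.bed"
        f.write_text("chr1\t0\t200\n")
        df = read_bed(f)
        assert df.iloc[0].tolist() == ["chr1", 0, 200]
        iv = random_intervals(rng, 100).sort_values(
            ["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        out = tmp_path / "b.bed"
        write_bed(iv, out, {"mode": "test"})
        back = read_bed(out)
        assert back[["chrom", "start", "end"]].equals(iv[["chrom", "start", "end"]])

    def test_empty_interval_rejected(self, tmp_path):
        f = tmp_path / "bad.bed"
        f.write_text("chr1\t5\t5\n")
        with pytest.raises(ValueError):
            read_bed(f)


class TestIntersect:
    def test_single_base_overlap_matches(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [199], "end": [300]})
        hits = intersect_regions(a, b)
        assert len(hits) == 1
        assert hits["overlap"].iloc[0] == 1

    def test_bookended_intervals_do_not_match(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [200], "end": [300]})
        assert len(intersect_regions(a, b)) == 0

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            a = random_intervals(rng, int(rng.integers(1, 200)))
            b = random_intervals(rng, int(rng.integers(1, 200)))
            min_ov = int(rng.integers(1, 50))
            got = intersect_regions(a, b, min_overlap=min_ov)
            assert set(zip(got["a_index"], got["b_index"])) == brute_force_pairs(a, b, min_ov)

    def test_disjoint_chromosomes_warn(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        b = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [10]})
        with pytest.warns(UserWarning, match="no chromosome"):
            intersect_regions(a, b)


class TestMerge:
    def test_bookended_same_direction_merges(self):
        df = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 200],
                           "end": [200, 400], "direction": ["up", "up"]})
        out = merge_regions(df, max_gap=0, require_same_direction=True)
        assert len(out) == 1
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (0, 400)

    def test_opposite_directions_stay_apart(self):
        df = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 200],
                           "end": [200, 400], "direction": ["up", "down"]})
        assert len(merge_regions(df, 0, True)) == 2

    def test_gap_tolerance(self):
        df = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 250], "end": [200, 400]})
        assert len(merge_regions(df, max_gap=0)) == 2
        assert len(merge_regions(df, max_gap=50)) == 1

    def test_idempotent_and_nonmergeable(self, rng):
        for _ in range(10):
            df = random_intervals(rng, 100)
            gap = int(rng.integers(0, 100))
            once = merge_regions(df, max_gap=gap)
            twice = merge_regions(once[["chrom", "start", "end"]], max_gap=gap)
            assert once[["chrom", "start", "end"]].reset_index(drop=True).equals(
                twice[["chrom", "start", "end"]].reset_index(drop=True)
            )
            # consecutive outputs per chromosome are separated by > gap
            for _, g in once.groupby("chrom"):
                gaps = g["start"].to_numpy()[1:] - g["end"].to_numpy()[:-1]
                assert np.all(gaps > gap)

    def test_members_track_inputs(self):
        df = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [0, 100, 900],
                           "end": [150, 300, 1000]})
        out = merge_regions(df, max_gap=0)
        assert sorted(map(len, out["members"])) == [1, 2]


class TestTables:
    def test_count_matrix_round_trip(self, tmp_path, rng):
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(5, 4)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(4)],
        )
        samples = pd.DataFrame(
            {"group": ["control", "control", "exposed", "exposed"],
             "sex": "female", "tissue": "liver", "exposure": "toxA"},
            index=pd.Index([f"s{i}" for i in range(4)], name="sample"),
        )
        cm = CountMatrix(counts=counts, samples=samples)
        write_count_matrix(cm, tmp_path / "c.tsv", tmp_path / "s.tsv")
        back = read_count_matrix(tmp_path / "c.tsv", tmp_path / "s.tsv")
        assert back.counts.equals(counts)
        assert back.group_samples("control") == ["s0", "s1"]

    def test_metadata_must_cover_samples(self):
        counts = pd.DataFrame({"s0": [1], "s1": [2]}, index=["g0"])
        samples = pd.DataFrame({"group": ["control"], "sex": ["f"],
                                "tissue": ["liver"], "exposure": ["a"]},
                               index=pd.Index(["s0"], name="sample"))
        with pytest.raises(ValueError, match="missing"):
            CountMatrix(counts=counts, samples=samples)

    def test_differential_table_round_trip_and_schema(self, tmp_path,
                                                      diff_table_factory):
        tbl = diff_table_factory(["a", "b", "c"], [1.0, -2.0, 0.5])
        f = tmp_path / "d.tsv"
        write_differential_table(tbl, f, {"kind": "DEG"})
        back = read_differential_table(f)
        assert back["feature"].tolist() == ["a", "b", "c"]
        assert np.allclose(back["log2fc"], tbl["log2fc"])
        bad = tmp_path / "bad.tsv"
        bad.write_text("feature\tp\n" "a\t0.1\n")
        with pytest.raises(SchemaError, match="log2fc"):
            read_differential_table(bad)

    def test_padj_below_p_warns_but_keeps_row(self, tmp_path, diff_table_factory):
        tbl = diff_table_factory(["a"], [1.0], padj=[0.001], p=[0.01])
        f = tmp_path / "d.tsv"
        write_differential_table(tbl, f)
        with pytest.warns(UserWarning, match="padj < p"):
            back = read_differential_table(f)
        assert len(back) == 1

    def test_sample_sheet_round_trip(self, tmp_path):
        samples = pd.DataFrame(
            {"group": ["control"], "sex": ["female"], "tissue": ["blood"],
             "exposure": ["toxA"]},
            index=pd.Index(["s1"], name="sample"),
        )
        write_sample_sheet(samples, tmp_path / "sheet.tsv")
        back = read_sample_sheet(tmp_path / "sheet.tsv")
        assert back.loc["s1", "tissue"] == "blood"


class TestIntervalKeys:
    def test_round_trip(self):
        key = interval_key("chr10", 5, 105)
        assert key == "chr10:5-105"
        assert parse_interval_key(key) == ("chr10", 5, 105)

    def test_frame_from_keys(self):
        df = intervals_from_keys(["chr1:0-10", "chr2:5-8"])
        assert df["end"].tolist() == [10, 8]
        with pytest.raises(ValueError):
            intervals_from_keys(["chr1_0_10"])
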