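"""Ratio computation, strand collapse, intersection and DMR threshold calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methomics import MethylSimConfig, synthio
from methomics import methcall
from methomics.errors import ConfigError, DataError, ParseError

from conftest import make_ratio_table


def bruteforce_dmr_status(normal_mean, tumor_mean, diff=0.4, hypo=0.3, hyper=0.7):
    """Independent re-statement of the three-threshold decision rule."""
    if abs(tumor_mean - normal_mean) <= diff:
        return "not_dmr"
    if tumor_mean < hypo:
        return "hypo"
    if tumor_mean > hyper:
        return "hyper"
    return "indeterminate"


def write_report(path, rows):
    with open(path, "w") as fh:
        for chrom, pos, strand, m, u in rows:
            fh.write(f"{chrom}\t{pos}\t{strand}\t{m}\t{u}\tCpG\tCGG\n")


class TestReadCytosineReport:
    def test_strand_counts_are_summed_onto_plus_coordinate(self, tmp_path):
        p = tmp_path / "s.tsv"
        write_report(p, [("chr1", 100, "+", 3, 1), ("chr1", 101, "-", 1, 3)])
        rec = methcall.read_cytosine_report(p)
        assert len(rec) == 1
        row = rec.iloc[0]
        assert (row["pos"], row["meth_count"], row["total_count"]) == (100, 4, 8)

    def test_empty_file_gives_empty_records(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert len(methcall.read_cytosine_report(p)) == 0

    def test_min_coverage_boundary_is_inclusive(self, tmp_path):
        p = tmp_path / "s.tsv"
        write_report(p, [("chr1", 100, "+", 4, 5), ("chr1", 200, "+", 5, 5)])
        rec = methcall.read_cytosine_report(p, min_coverage=10)
        assert rec["pos"].tolist() == [200]  # total 9 dropped, total 10 kept

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chr1\t100\t+\t3\t1\tCpG\tCGG\nchr1\tXX\t+\t1\t1\tCpG\tCGG\n")
        with pytest.raises(ParseError, match="line 2"):
            methcall.read_cytosine_report(p)

    def test_bad_strand_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chr1\t100\t*\t3\t1\tCpG\tCGG\n")
        with pytest.raises(ParseError, match="strand"):
            methcall.read_cytosine_report(p)


class TestComputeRatios:
    def test_ratio_arithmetic(self):
        rec = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [100, 110, 120],
             "meth_count": [5, 0, 7], "total_count": [10, 8, 7]}
        )
        table = methcall.compute_ratios({"s1": rec}, {"s1": "tumor"})
        assert table.ratios["s1"].tolist() == [0.5, 0.0, 1.0]

    def test_zero_total_is_a_data_error(self):
        rec = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [100], "meth_count": [0], "total_count": [0]}
        )
        with pytest.raises(DataError):
            methcall.compute_ratios({"s1": rec}, {"s1": "tumor"})

    def test_missing_group_label_rejected(self):
        rec = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [100], "meth_count": [1], "total_count": [2]}
        )
        with pytest.raises(ConfigError):
            methcall.compute_ratios({"s1": rec}, {})


class TestIntersect:
    @staticmethod
    def _records(positions):
        return pd.DataFrame(
            {"chrom": ["chr1"] * len(positions), "pos": positions,
             "meth_count": [1] * len(positions), "total_count": [2] * len(positions)}
        )

    def test_intersection_of_three_sets(self):
        table = methcall.compute_ratios(
            {
                "s1": self._records([100, 110, 120]),
                "s2": self._records([110, 120, 130]),
                "s3": self._records([110, 120]),
            },
            {"s1": "tumor", "s2": "tumor", "s3": "normal"},
        )
        out = methcall.intersect_cpgs(table)
        assert out.ratios.index.get_level_values("pos").tolist() == [110, 120]

    def test_single_sample_is_identity(self):
        table = methcall.compute_ratios(
            {"n": self._records([100, 110])}, {"n": "normal"}
        )
        out = methcall.intersect_cpgs(table)
        pd.testing.assert_frame_equal(out.ratios, table.ratios)

    def test_empty_intersection_warns_and_returns_empty(self, caplog):
        table = methcall.compute_ratios(
            {"a": self._records([100]), "b": self._records([200])},
            {"a": "tumor", "b": "normal"},
        )
        with caplog.at_level("WARNING"):
            out = methcall.intersect_cpgs(table)
        assert len(out.ratios) == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_matches_bruteforce_set_intersection_on_simulation(self, small_methylome):
        _, tables, truth = small_methylome
        # go through files to exercise the real reader path
        import tempfile

        with tempfile.TemporaryDirectory() as d:
            paths = synthio.write_cytosine_reports(tables, d)
            recs = {s: methcall.read_cytosine_report(p) for s, p in paths.items()}
        table = methcall.compute_ratios(recs, truth.samples)
        out = methcall.intersect_cpgs(table)
        expected = None
        for rec in recs.values():
            keys = set(zip(rec["chrom"], rec["pos"]))
            expected = keys if expected is None else expected & keys
        assert set(out.ratios.index) == expected


class TestCallDmrs:
    def test_clear_hypomethylation(self):
        table = make_ratio_table(
            {"t": [0.10], "n": [0.85]}, {"t": "tumor", "n": "normal"}
        )
        calls = methcall.call_dmrs(table)
        assert calls["status"].tolist() == ["hypo"]
        assert calls["diff"].iloc[0] == pytest.approx(-0.75)

    def test_difference_exactly_at_threshold_is_not_dmr(self):
        table = make_ratio_table(
            {"t": [0.90], "n": [0.50]}, {"t": "tumor", "n": "normal"}
        )
        calls = methcall.call_dmrs(table)
        assert calls["status"].tolist() == ["not_dmr"]

    def test_mid_range_tumor_mean_is_indeterminate(self):
        table = make_ratio_table(
            {"t": [0.55], "n": [0.10]}, {"t": "tumor", "n": "normal"}
        )
        assert methcall.call_dmrs(table)["status"].tolist() == ["indeterminate"]

    def test_requires_both_groups(self):
        table = make_ratio_table({"t": [0.5]}, {"t": "tumor"})
        with pytest.raises(ConfigError):
            methcall.call_dmrs(table)

    def test_missing_ratios_rejected(self):
        table = make_ratio_table(
            {"t": [0.5, np.nan], "n": [0.2, 0.3]}, {"t": "tumor", "n": "normal"}
        )
        with pytest.raises(DataError):
            methcall.call_dmrs(table)

    def test_signed_mode_only_flags_methylation_loss(self):
        table = make_ratio_table(
            {"t": [0.95, 0.10], "n": [0.10, 0.95]}, {"t": "tumor", "n": "normal"}
        )
        signed = methcall.call_dmrs(table, mode="normal_minus_tumor")
        assert signed["status"].tolist() == ["not_dmr", "hypo"]

    def test_group_permutation_leaves_calls_unchanged(self, rng):
        vals = {f"t{i}": rng.uniform(0, 1, 50) for i in range(4)}
        vals.update({f"n{i}": rng.uniform(0, 1, 50) for i in range(3)})
        groups = {s: ("tumor" if s.startswith("t") else "normal") for s in vals}
        table = make_ratio_table(vals, groups)
        shuffled = make_ratio_table(
            {s: vals[s] for s in ["t2", "n1", "t0", "n2", "t3", "n0", "t1"]}, groups
        )
        pd.testing.assert_frame_equal(
            methcall.call_dmrs(table), methcall.call_dmrs(shuffled)
        )

    def test_matches_bruteforce_rule_on_random_table(self, rng):
        vals = {
            "t1": rng.uniform(0, 1, 300), "t2": rng.uniform(0, 1, 300),
            "n1": rng.uniform(0, 1, 300), "n2": rng.uniform(0, 1, 300),
        }
        table = make_ratio_table(
            vals, {"t1": "tumor", "t2": "tumor", "n1": "normal", "n2": "normal"}
        )
        calls = methcall.call_dmrs(table)
        for _, row in calls.iterrows():
            nm = (vals["n1"][_] + vals["n2"][_]) / 2
            tm = (vals["t1"][_] + vals["t2"][_]) / 2
            assert row["status"] == bruteforce_dmr_status(nm, tm)


@settings(max_examples=50, deadline=None)
@given(total=st.integers(1, 500), m1=st.integers(0, 500), m2=st.integers(0, 500))
def test_ratio_monotone_in_meth_count(total, m1, m2):
    m1, m2 = sorted((min(m1, total), min(m2, total)))
    def ratio(m):
        rec = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [100], "meth_count": [m], "total_count": [total]}
        )
        t = methcall.compute_ratios({"s": rec}, {"s": "tumor"})
        return t.ratios["s"].iloc[0]
    assert ratio(m1) <= ratio(m2)


def test_dmr_bed_output_roundtrip(tmp_path):
    table = make_ratio_table(
        {"t": [0.1, 0.9], "n": [0.9, 0.2]}, {"t": "tumor", "n": "normal"}
    )
    calls = methcall.call_dmrs(table)
    p = tmp_path / "dmr.tsv"
    methcall.write_dmr_table(calls, p, header_comment="test")
    again = methcall.read_dmr_table(p)
    assert again["pos"].tolist() == calls["pos"].tolist()
    assert again["status"].tolist() == calls["status"].tolist()
    # BED interval is 0-based half-open
    raw = pd.read_csv(p, sep="\t", comment="#")
    assert (raw["end"] - raw["start"] == 1).all()
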