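"""Kozak context classification, uORF scanning, and frequency tables."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polysel.io import TranscriptModel
from polysel.seq_features import (
    KozakCategory,
    UorfMode,
    feature_frequency,
    feature_table,
    find_uorfs,
    kozak_call,
    kozak_classify,
    kozak_context,
)

from oracles import uorf_scan


def _model(utr5, cds="ATGGGCTAA", gene="g"):
    return TranscriptModel(f"{gene}.1", gene, utr5, cds, True)


class TestKozakContext:
    def test_standard_positions(self):
        assert kozak_context(_model("AAA", "ATGGGC")) == ("A", "G")

    def test_empty_utr(self):
        assert kozak_context(_model("", "ATGC")) == (None, "C")

    def test_short_utr_missing_minus3(self):
        assert kozak_context(_model("TT", "ATGC")) == (None, "C")

    def test_short_cds_missing_plus4(self):
        assert kozak_context(_model("AAAA", "ATG")) == ("A", None)


@pytest.mark.parametrize(
    "minus3, plus4, has_utr, expected",
    [
        ("A", "G", True, KozakCategory.STRONG),
        ("G", "G", True, KozakCategory.STRONG),
        ("T", "G", True, KozakCategory.ADEQUATE),
        ("A", "C", True, KozakCategory.ADEQUATE),
        ("T", "C", True, KozakCategory.WEAK),
        (None, "G", True, KozakCategory.ADEQUATE),  # 1-2 nt UTR, +4 matches
        (None, "C", True, KozakCategory.WEAK),
        ("A", "G", False, KozakCategory.NO_UTR),
        ("N", "G", True, KozakCategory.ADEQUATE),  # N never matches -3
    ],
)
def test_kozak_classify(minus3, plus4, has_utr, expected):
    assert kozak_classify(minus3, plus4, has_utr) is expected


def test_every_transcript_gets_exactly_one_category(rng):
    bases = np.array(list("ACGT"))
    for _ in range(200):
        utr = "".join(rng.choice(bases, size=int(rng.integers(0, 12))))
        cds = "ATG" + "".join(rng.choice(bases, size=9))
        call = kozak_call(_model(utr, cds))
        assert call.category in KozakCategory
        assert (call.category is KozakCategory.NO_UTR) == (len(utr) == 0)


class TestFindUorfs:
    def test_hand_readable_example(self):
        records = find_uorfs("ATGTAACC", "ATGGGC")
        assert len(records) == 1
        (r,) = records
        assert (r.start_offset, r.stop_offset, r.contained, r.length_codons) == (
            0, 3, True, 1
        )

    def test_no_atg_no_records(self):
        assert find_uorfs("CCCCCC", "ATGGGC") == []

    def test_any_start_reaches_into_cds(self):
        # uORF ATG at offset 2 finds its in-frame stop inside the CDS
        utr = "CCATGCC"
        cds = "CTAAGG"
        assert find_uorfs(utr, cds, UorfMode.CONTAINED) == []
        records = find_uorfs(utr, cds, UorfMode.ANY_START)
        assert [r.start_offset for r in records] == [2]
        assert records[0].stop_offset == 8  # first base of TAA, within the CDS
        assert not records[0].contained
        assert records[0].length_codons == 2

    def test_n_never_matches(self):
        assert find_uorfs("ANGTAA", "ATGGGC") == []
        # stop codon containing N is not a stop: frame runs on
        records = find_uorfs("ATGTNA", "ATGGGC", UorfMode.ANY_START)
        assert records and records[0].stop_offset != 3

    def test_minimal_uorf_is_one_codon(self):
        (r,) = find_uorfs("ATGTAA", "ATGGGC")
        assert r.length_codons == 1

    def test_matches_exhaustive_oracle(self, rng):
        bases = np.array(list("ACGTN"), dtype=object)
        probs = [0.24, 0.24, 0.24, 0.24, 0.04]
        for _ in range(200):
            utr = "".join(rng.choice(bases, size=int(rng.integers(0, 120)), p=probs))
            cds = "ATG" + "".join(rng.choice(bases, size=30, p=probs))
            for mode in UorfMode:
                got = [
                    (r.start_offset, r.stop_offset, r.contained, r.length_codons)
                    for r in find_uorfs(utr, cds, mode)
                ]
                assert got == uorf_scan(utr, cds, mode.value)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_frame_shift_property(self, seed):
        """Prepending 3 non-ATG-forming bases shifts starts by 3, nothing else."""
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        utr = "".join(rng.choice(bases, size=int(rng.integers(0, 60))))
        cds = "ATG" + "".join(rng.choice(bases, size=12))
        prefix = "CCC"  # cannot create an ATG at the junction (no A/T lead-in)
        if utr.startswith("G"):  # avoid CCC+G..: CCG contains no ATG anyway
            pass
        before = find_uorfs(utr, cds, UorfMode.ANY_START)
        after = find_uorfs(prefix + utr, cds, UorfMode.ANY_START)
        assert [r.start_offset + 3 for r in before] == [r.start_offset for r in after]
        assert [r.length_codons for r in before] == [r.length_codons for r in after]


class TestFrequencyTable:
    def _calls(self, cats):
        return {
            f"g{i}": kozak_call(
                _model(
                    {"S": "AAA", "A": "TTT", "W": "TTT", "N": ""}[c],
                    {"S": "ATGGGGTAA", "A": "ATGGGGTAA", "W": "ATGCGGTAA",
                     "N": "ATGGGGTAA"}[c],
                    gene=f"g{i}",
                )
            )
            for i, c in enumerate(cats)
        }

    def test_arithmetic_on_five_genes(self):
        calls = self._calls("SSSAW")
        table = feature_frequency(
            {"set1": set(calls)}, calls, {g: 0 for g in calls}, set(calls)
        )
        row = table.rows["set1"]
        assert (row["strong_pct"], row["adequate_pct"], row["weak_pct"],
                row["no_utr_pct"]) == (60.0, 20.0, 20.0, 0.0)
        assert row["uorf_pct"] == 0.0 and row["n"] == 5

    def test_empty_set_gives_missing_row(self):
        calls = self._calls("S")
        table = feature_frequency({"empty": set()}, calls, {}, set(calls))
        assert table.rows["empty"]["strong_pct"] is None
        assert table.rows["empty"]["n"] == 0

    def test_unresolved_members_counted_not_percented(self):
        calls = self._calls("SS")
        table = feature_frequency(
            {"set1": {"g0", "g1", "ghost"}}, calls, {"g0": 1}, set(calls)
        )
        row = table.rows["set1"]
        assert row["n"] == 2 and row["n_unresolved"] == 1
        assert row["strong_pct"] == 100.0 and row["uorf_pct"] == 50.0

    def test_percentages_partition_to_100(self, rng):
        cats = rng.choice(list("SAWN"), size=97)
        calls = self._calls("".join(cats))
        table = feature_frequency({}, calls, {}, set(calls))
        row = table.rows["total_genes"]
        total = sum(row[k] for k in ("strong_pct", "adequate_pct", "weak_pct",
                                     "no_utr_pct"))
        assert 99.8 <= total <= 100.2

    def test_uorf_pct_independent_of_partition(self):
        calls = self._calls("SSAA")
        uorfs = {"g0": 1, "g1": 0, "g2": 3, "g3": 0}
        universe = set(calls)
        t1 = feature_frequency({"a": {"g0", "g1"}, "b": {"g2", "g3"}}, calls, uorfs, universe)
        t2 = feature_frequency({"all": universe}, calls, uorfs, universe)
        assert t1.rows["total_genes"]["uorf_pct"] == t2.rows["total_genes"]["uorf_pct"] == 50.0

    def test_byte_identical_output(self, tmp_path):
        calls = self._calls("SAWNS")
        args = ({"s": {"g0", "g2"}}, calls, {"g0": 2}, set(calls))
        feature_frequency(*args).to_tsv(tmp_path / "a.tsv")
        feature_frequency(*args).to_tsv(tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_half_up_rounding(self):
        # 1 of 8 = 12.5% must round to 12.5; 1 of 16 = 6.25 -> 6.3 (half-up)
        calls = self._calls("S" * 15 + "W")
        table = feature_frequency({}, calls, {}, set(calls))
        assert table.rows["total_genes"]["weak_pct"] == 6.3


def test_feature_table_columns():
    models = [_model("AAA", "ATGGGGTAA", "g1"), _model("", "ATGCGGTAA", "g2")]
    frame = feature_table(models)
    assert list(frame.columns) == [
        "gene_id", "minus3", "plus4", "kozak_category",
        "n_uorfs_contained", "n_uorfs_any",
    ]
    assert frame.loc[1, "kozak_category"] == "NO_UTR"
    assert frame.loc[1, "minus3"] == "."
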