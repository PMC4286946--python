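"""Cleaning contract (adapter trim -> quality -> length) and unique-tag
collapsing."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pirnapipe as pp
from pirnapipe.reads import find_adapter
from pirnapipe.simulate import DEFAULT_ADAPTER


def _read(seq: str, q: int = 40, id: str = "r") -> pp.SmallRNARead:
    return pp.SmallRNARead(id, seq, chr(q + 33) * len(seq))


class TestCleaning:
    def test_short_read_discarded_at_boundary(self):
        clean, stats = pp.clean_reads([_read("A" * 17), _read("ACGT" * 5)])
        assert [r.sequence for r in clean] == ["ACGT" * 5]
        assert stats.total_reads == 2 and stats.clean_reads == 1

    def test_long_read_discarded_at_boundary(self):
        # 45 nt exceeds the small-RNA selection window, 44 nt does not
        seqs = ["AC" * 22 + "G", "AC" * 22]
        clean, _ = pp.clean_reads([_read(s) for s in seqs])
        assert [len(r.sequence) for r in clean] == [44]

    def test_mean_quality_threshold_is_inclusive(self):
        keep = _read("ACGTACGTACGTACGTACGT", q=13)
        drop = _read("ACGTACGTACGTACGTACGT", q=12)
        clean, _ = pp.clean_reads([keep, drop])
        assert [r.id for r in clean] == [keep.id]

    def test_n_containing_read_discarded(self):
        clean, _ = pp.clean_reads([_read("ACGTNACGTACGTACGTACGT")])
        assert clean == []

    def test_adapter_trimmed_to_insert(self):
        insert = "TACGTACGGATCCTAGGCATCGATCG"
        read = _read(insert + DEFAULT_ADAPTER)
        clean, _ = pp.clean_reads([read])
        assert [r.sequence for r in clean] == [insert]

    def test_partial_adapter_suffix_trimmed(self):
        insert = "TACGTACGGATCCTAGGCATCGATCG"
        read = _read(insert + DEFAULT_ADAPTER[:8])
        clean, _ = pp.clean_reads([read])
        assert [r.sequence for r in clean] == [insert]

    def test_adapter_with_mismatch_trimmed(self):
        insert = "TACGTACGGATCCTAGGCATCGATCG"
        mutated = DEFAULT_ADAPTER[:10] + "A" + DEFAULT_ADAPTER[11:]
        assert mutated != DEFAULT_ADAPTER
        pos = find_adapter(insert + mutated, DEFAULT_ADAPTER)
        assert pos == len(insert)

    def test_quality_decided_by_insert_not_adapter(self):
        # good insert + low-quality adapter tail must be retained
        insert = "TACGTACGGATCCTAGGCATCGATCG"
        seq = insert + DEFAULT_ADAPTER
        qual = chr(40 + 33) * len(insert) + chr(2 + 33) * len(DEFAULT_ADAPTER)
        clean, _ = pp.clean_reads([pp.SmallRNARead("r", seq, qual)])
        assert [r.sequence for r in clean] == [insert]

    def test_simulated_adapter_bearing_reads_restore_insert_length(self, pgc_sim):
        reads, truth = pgc_sim
        info = {r.read_id: r for r in truth.reads.itertuples(index=False)}
        probe = DEFAULT_ADAPTER[:10]
        checked = 0
        clean, _ = pp.clean_reads(
            pp.SmallRNARead(*r) for r in reads[:20_000])
        for r in clean:
            t = info[r.id]
            if not t.has_adapter:
                continue
            # inserts that contain the adapter probe internally are genuinely
            # ambiguous and excluded
            if probe in r.sequence:
                continue
            assert len(r.sequence) == t.insert_len
            checked += 1
        assert checked > 500

    def test_low_quality_rate_filters_expected_fraction(self, toy_genome):
        profile = pp.example_profiles(1_000)["PGC"]
        profile.low_quality_rate = 0.2
        reads, _ = pp.simulate_library(toy_genome, profile, seed=77)
        _, stats = pp.clean_reads(pp.SmallRNARead(*r) for r in reads)
        se = np.sqrt(1_000 * 0.2 * 0.8)
        assert abs(stats.clean_reads - 800) <= 3 * se

    def test_cleaning_is_idempotent(self, pgc_clean):
        clean, _ = pgc_clean
        again, stats = pp.clean_reads(clean[:5_000])
        assert again == clean[:5_000]
        assert stats.clean_reads == 5_000

    def test_raising_quality_threshold_is_monotone(self, pgc_sim):
        reads = [pp.SmallRNARead(*r) for r in pgc_sim[0][:5_000]]
        kept = [
            pp.clean_reads(reads, pp.CleaningConfig(min_mean_quality=q))[1].clean_reads
            for q in (0, 5, 13, 20, 30, 36)]
        assert kept == sorted(kept, reverse=True)

    def test_empty_input(self):
        clean, stats = pp.clean_reads([])
        assert clean == [] and stats.total_reads == 0 and stats.clean_reads == 0

    def test_malformed_fastq_names_record(self, tmp_path):
        bad = tmp_path / "bad.fastq"
        bad.write_text("@ok\nACGT\n+\nIIII\nnot-a-header\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError, match="index 1"):
            list(pp.read_fastq(bad))

    def test_fastq_roundtrip(self, tmp_path):
        reads = [_read("ACGTACGTACGTACGTAC", id=f"r{i}") for i in range(5)]
        from pirnapipe.reads import write_fastq

        write_fastq(reads, tmp_path / "x.fastq")
        assert list(pp.read_fastq(tmp_path / "x.fastq")) == reads


class TestCollapse:
    def test_hand_countable_example(self):
        tags = pp.TagSet.from_samples(
            {"s1": ["AAAAAAAAAAAAAAAAAA", "AAAAAAAAAAAAAAAAAA",
                    "CCCCCCCCCCCCCCCCCC"]})
        assert len(tags) == 2
        by_seq = {t.sequence: t.count("s1") for t in tags}
        assert by_seq == {"AAAAAAAAAAAAAAAAAA": 2, "CCCCCCCCCCCCCCCCCC": 1}

    def test_empty_input_empty_set(self):
        tags = pp.TagSet.from_samples({"s1": []})
        assert len(tags) == 0 and tags.clean_totals == {"s1": 0}

    @given(st.lists(st.text(alphabet="ACGT", min_size=18, max_size=24),
                    max_size=60))
    def test_counts_conserve_clean_reads(self, seqs):
        tags = pp.TagSet.from_samples({"s": seqs})
        assert sum(t.count("s") for t in tags) == len(seqs)
        assert len(tags) == len(set(seqs))

    def test_session_library_conservation(self, pgc_tagset, pgc_clean):
        _, stats = pgc_clean
        assert sum(t.count("PGC") for t in pgc_tagset) == stats.clean_reads

    def test_germcell_library_has_higher_tag_diversity(self, pgc_clean,
                                                       cef_clean, pgc_tagset,
                                                       cef_sim):
        """Cluster-derived libraries collapse to many distinct low-copy tags;
        miRNA/rRNA-dominated somatic libraries to fewer high-copy ones."""
        cef_cleaned, cef_stats = cef_clean
        cef_tags = pp.TagSet.from_samples(
            {"CEF": [r.sequence for r in cef_cleaned]})
        _, pgc_stats = pgc_clean
        pgc_ratio = len(pgc_tagset) / pgc_stats.clean_reads
        cef_ratio = len(cef_tags) / cef_stats.clean_reads
        assert pgc_ratio > cef_ratio

    def test_fasta_dialect(self, tmp_path):
        tags = pp.TagSet.from_samples({"s1": ["ACGTACGTACGTACGTAC"] * 3})
        tags.write_fasta(tmp_path / "t.fa")
        assert (tmp_path / "t.fa").read_text() == ">tag0_x3\nACGTACGTACGTACGTAC\n"

    def test_tsv_roundtrip(self, tmp_path):
        tags = pp.TagSet.from_samples({
            "a": ["ACGTACGTACGTACGTAC", "ACGTACGTACGTACGTAC"],
            "b": ["TTTTACGTACGTACGTAC"]})
        tags.write_tsv(tmp_path / "t.tsv")
        back = pp.TagSet.read_tsv(tmp_path / "t.tsv")
        assert back.sample_names == ["a", "b"]
        assert {t.sequence: t.counts for t in back} == {
            t.sequence: t.counts for t in tags}
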