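"""piRNA cluster prediction: signature classification, strand bias,
acceptance conjunction, oracle equivalence and planted-cluster recovery."""

from __future__ import annotations

import numpy as np
import pytest

import pirnapipe as pp
from pirnapipe.mapping import MappingLocus, TagMapping
from pirnapipe.validation import cluster_recovery, cluster_scan_oracle

CHROM_LEN = {"chr1": 100_000}


def _make_mappings(loci_spec):
    """loci_spec: list of (tag, start, end, strand)."""
    by_tag: dict[str, list[MappingLocus]] = {}
    for tag, start, end, strand in loci_spec:
        by_tag.setdefault(tag, []).append(MappingLocus(
            tag=tag, chrom="chr1", start=start, end=end, strand=strand,
            identity=1.0, coverage=1.0))
    return {tag: TagMapping(tag, loci, n_loci=len(loci))
            for tag, loci in by_tag.items()}


def _pirna_tag(i: int) -> str:
    # distinct 26-nt tags starting with T (1U-positive, typical length)
    body = np.random.default_rng(i).integers(0, 4, 25)
    return "T" + "".join("ACGT"[b] for b in body)


class TestPingPongSignature:
    @pytest.mark.parametrize("seq,expected", [
        ("TATTTCCTAACGTCCAGCCTGAACC", True),    # 1U
        ("GGGGGGGGGAGGGGGGGGGG", True),         # 10A only
        ("CCAGAACACACTTGGCCTTCCGGGCTG", True),  # published repeat tag: 10A
        ("CTGTGAGTGTGTGAGTGCGGCGGCGCG", False),  # neither 1U nor 10A
        ("AAGGACCTCTGAGAATTGCTTTCT", False),
        ("GGGGGGGGGTGGGGGGGGGG", False),
    ])
    def test_classification(self, seq, expected):
        assert pp.one_u_ten_a(seq) is expected

    def test_short_sequence_false_with_warning(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert pp.one_u_ten_a("TACGTACG") is False


class TestStrandBias:
    def test_single_strand_scores_weighted_count(self):
        assert pp.strand_bias_score(8.0, 0.0) == pytest.approx(8.0)

    def test_boundary_thirteen_to_ten(self):
        assert pp.strand_bias_score(13, 10) == pytest.approx(1.3)

    def test_equal_strands_fail_threshold(self):
        assert pp.strand_bias_score(7, 7) == pytest.approx(1.0)

    def test_symmetry(self):
        assert pp.strand_bias_score(3, 12) == pp.strand_bias_score(12, 3)


class TestScanClusters:
    def _dense_spec(self, n, start=50_000, strand="+"):
        return [(_pirna_tag(i), start + 40 * i, start + 40 * i + 26, strand)
                for i in range(n)]

    def test_empty_input(self):
        assert pp.scan_clusters({}, CHROM_LEN) == []

    def test_zero_genome_length_raises(self):
        with pytest.raises(ValueError, match="genome length"):
            pp.scan_clusters(_make_mappings(self._dense_spec(6)), {"chr1": 0})

    def test_min_loci_boundary(self):
        """Five perfect loci are rejected purely by the locus floor; six are
        accepted."""
        five = pp.scan_clusters(_make_mappings(self._dense_spec(5)), CHROM_LEN)
        assert five and not any(c.accepted for c in five)
        six = pp.scan_clusters(_make_mappings(self._dense_spec(6)), CHROM_LEN)
        assert sum(c.accepted for c in six) == 1
        cluster = next(c for c in six if c.accepted)
        assert cluster.n_loci == 6
        assert cluster.start == 50_000 and cluster.end == 50_226
        assert cluster.frac_1u10a == 1.0 and cluster.frac_typical_length == 1.0

    def test_mixed_strands_rejected_by_bias(self):
        spec = self._dense_spec(8) + self._dense_spec(8, start=50_020,
                                                      strand="-")
        found = pp.scan_clusters(_make_mappings(spec), CHROM_LEN)
        assert found and not any(c.accepted for c in found)
        assert found[0].strand_bias_score == pytest.approx(1.0)

    def test_atypical_lengths_rejected(self):
        spec = [(_pirna_tag(i)[:20], 50_000 + 40 * i, 50_020 + 40 * i, "+")
                for i in range(10)]
        found = pp.scan_clusters(_make_mappings(spec), CHROM_LEN)
        assert found and not any(c.accepted for c in found)

    def test_output_independent_of_input_order(self):
        spec = self._dense_spec(10)
        fwd = pp.scan_clusters(_make_mappings(spec), CHROM_LEN)
        rev = pp.scan_clusters(_make_mappings(spec[::-1]), CHROM_LEN)
        assert [(c.chrom, c.start, c.end, c.accepted, c.n_loci) for c in fwd] \
            == [(c.chrom, c.start, c.end, c.accepted, c.n_loci) for c in rev]

    def test_tightening_thresholds_never_adds_clusters(self, pgc_mappings,
                                                       genome_1mb,
                                                       pgc_clusters):
        base = {(c.chrom, c.start, c.end) for c in pgc_clusters if c.accepted}
        tighter = [
            pp.ClusterParams(min_loci=20),
            pp.ClusterParams(density_alpha=0.001),
            pp.ClusterParams(min_strand_bias_score=3.0),
            pp.ClusterParams(min_1u10a_fraction=0.9),
            pp.ClusterParams(min_length_fraction=0.9),
        ]
        for params in tighter:
            got = {(c.chrom, c.start, c.end)
                   for c in pp.scan_clusters(pgc_mappings,
                                             genome_1mb.chrom_lengths, params)
                   if c.accepted}
            assert got <= base

    def test_uniform_background_yields_no_accepted_clusters(self):
        """Poisson background only: candidate windows stay near the alpha
        budget and composition filters reject every candidate (20 seeds)."""
        n, glen, window = 10_000, 1_000_000, 5_000
        n_windows = 2 * glen // window  # half-overlapping grid
        total_candidates = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            starts = rng.integers(0, glen - 44, n)
            spec = []
            for i, s in enumerate(starts):
                L = int(rng.integers(18, 45))
                strand = "+" if rng.random() < 0.5 else "-"
                body = "".join("ACGT"[b] for b in rng.integers(0, 4, L))
                spec.append((body, int(s), int(s) + L, strand))
            found = pp.scan_clusters(_make_mappings(spec), {"chr1": glen})
            assert not any(c.accepted for c in found)
            total_candidates += len(found)
        budget = 0.05 * n_windows
        sd = np.sqrt(20 * budget)
        assert total_candidates <= 20 * budget + 3 * sd


class TestOracleEquivalence:
    def test_scan_matches_window_enumeration_oracle(self, toy_genome):
        profile = pp.example_profiles(8_000)["PGC"]
        reads, _ = pp.simulate_library(toy_genome, profile, seed=55)
        clean, _ = pp.clean_reads(pp.SmallRNARead(*r) for r in reads)
        tags = pp.TagSet.from_samples({"s": [r.sequence for r in clean]})
        mappings = pp.map_tags([t.sequence for t in tags], toy_genome)
        got = pp.scan_clusters(mappings, toy_genome.chrom_lengths)
        want = cluster_scan_oracle(mappings, toy_genome.chrom_lengths)
        assert [(c.chrom, c.start, c.end, c.accepted) for c in got] == want
        assert sum(c.accepted for c in got) >= 1  # the planted cluster


class TestRecoveryAndCalls:
    def test_planted_clusters_recovered(self, pgc_clusters, pgc_sim):
        _, truth = pgc_sim
        accepted = [c for c in pgc_clusters if c.accepted]
        recovered, planted, false = cluster_recovery(accepted, truth.clusters)
        assert planted == 3 and recovered == 3 and false == 0

    def test_accepted_cluster_covers_planted_loci(self, pgc_clusters, pgc_sim):
        _, truth = pgc_sim
        accepted = [c for c in pgc_clusters if c.accepted]
        cluster_reads = truth.reads[truth.reads["class"] == "repeat_piRNA_cluster"]
        covered = sum(
            any(c.chrom == r.chrom and c.start <= r.start and r.end <= c.end
                for c in accepted)
            for r in cluster_reads.drop_duplicates(["start", "end", "strand"])
                                  .itertuples(index=False))
        n_loci = len(cluster_reads.drop_duplicates(["start", "end", "strand"]))
        assert covered / n_loci >= 0.95

    def test_no_accepted_clusters_no_pirnas(self, pgc_mappings,
                                            pgc_annotations):
        calls, origin = pp.call_pirnas([], pgc_mappings, pgc_annotations)
        assert calls == [] and origin.n_pirnas.sum() == 0

    def test_truth_recovery_of_called_pirnas(self, pgc_clusters, pgc_mappings,
                                             pgc_annotations, pgc_sim):
        """>=80% of cluster-class tags are called piRNAs; <=5% of background
        tags leak in; the modal origin is repeat."""
        reads, truth = pgc_sim
        calls, origin = pp.call_pirnas(pgc_clusters, pgc_mappings,
                                       pgc_annotations)
        called = {c.tag for c in calls}
        seq_by_id = {r[0]: r[1] for r in reads}
        truth_ok = truth.reads[~truth.reads.low_quality]

        def tags_of(cls):
            sub = truth_ok[truth_ok["class"] == cls]
            return {seq_by_id[r.read_id][:r.insert_len]
                    for r in sub.itertuples(index=False)} & set(pgc_mappings)

        cluster_tags = tags_of("repeat_piRNA_cluster")
        background_tags = tags_of("random_background") - cluster_tags
        assert len(called & cluster_tags) / len(cluster_tags) >= 0.80
        assert len(called & background_tags) / len(background_tags) <= 0.05
        assert origin.loc[origin.n_pirnas.idxmax(), "category"] == "repeat"

    def test_calls_have_locus_in_accepted_cluster(self, pgc_clusters,
                                                  pgc_mappings,
                                                  pgc_annotations):
        accepted = [c for c in pgc_clusters if c.accepted]
        calls, _ = pp.call_pirnas(pgc_clusters, pgc_mappings, pgc_annotations)
        for call in calls[:300]:
            assert any(
                c.chrom == l.chrom and l.start < c.end and c.start < l.end
                for l in pgc_mappings[call.tag].loci
                for c in accepted if c.cluster_id in call.clusters)


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            pp.ClusterParams(density_alpha=1.5)
        with pytest.raises(ValueError):
            pp.ClusterParams(min_loci=1)
        with pytest.raises(ValueError):
            pp.ClusterParams(locus_weighting="nope")
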