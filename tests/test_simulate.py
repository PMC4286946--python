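"""Synthetic genome/library generator: determinism, packing, composition
recovery and planted-signal guarantees."""

from __future__ import annotations

import collections

import numpy as np
import pytest

import pirnapipe as pp
from pirnapipe.simulate import SIMULATED_CLASSES


def _bare_spec(**kw) -> pp.GenomeSpec:
    defaults = dict(repeat_copies=0, gene_models=0, n_clusters=0,
                    structural_rna_loci={})
    defaults.update(kw)
    return pp.GenomeSpec(**defaults)


class TestBuildGenome:
    def test_empty_feature_set_is_valid(self, tmp_path):
        genome = pp.build_genome(_bare_spec(chrom_length=5_000, seed=1),
                                 tmp_path)
        assert genome.features == []
        assert len(genome.sequences["chr1"]) == 5_000
        assert (tmp_path / "genome.fa").exists()
        reread = pp.GenomeModel.from_files(tmp_path / "genome.fa",
                                           tmp_path / "features.gff3")
        assert reread.sequences == genome.sequences

    def test_deterministic_outputs(self, tmp_path):
        spec = pp.GenomeSpec(chrom_length=50_000, repeat_copies=5,
                             gene_models=2, n_clusters=1,
                             cluster_length=2_000, seed=7)
        a, b = tmp_path / "a", tmp_path / "b"
        pp.build_genome(spec, a)
        pp.build_genome(spec, b)
        for name in ("genome.fa", "features.gff3", "features.bed"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_repeat_packing_count_and_overlap(self):
        spec = _bare_spec(chrom_length=100_000, repeat_copies=20, seed=3)
        genome = pp.build_genome(spec)
        repeats = genome.features_by_category("repeat")
        assert len(repeats) == 20
        assert sum(f.length for f in repeats) == 6_000
        # brute-force overlap scan
        ivs = sorted((f.start, f.end) for f in repeats)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2

    def test_features_within_bounds_and_stranded(self, genome_1mb):
        for f in genome_1mb.features:
            assert 0 <= f.start < f.end <= len(genome_1mb.sequences[f.chrom])
            assert f.strand in "+-"

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="infeasible packing"):
            pp.build_genome(pp.GenomeSpec(chrom_length=10_000, seed=1))
        with pytest.raises(ValueError, match="packing.*repeat"):
            pp.build_genome(_bare_spec(chrom_length=10_000, repeat_copies=26,
                                       seed=5))


class TestSimulateLibrary:
    def test_zero_depth_is_empty_not_error(self, toy_genome):
        profile = pp.example_profiles(depth=0)["PGC"]
        reads, truth = pp.simulate_library(toy_genome, profile, seed=1)
        assert reads == []
        assert len(truth.reads) == 0
        assert len(truth.clusters) == 1  # planted clusters still reported

    def test_weight_on_missing_class_raises(self):
        genome = pp.build_genome(_bare_spec(chrom_length=20_000, seed=2))
        profile = pp.LibraryProfile(
            class_weights={"miRNA_like": 0.5, "random_background": 0.5},
            depth=100)
        with pytest.raises(ValueError, match="miRNA_like"):
            pp.simulate_library(genome, profile, seed=1)

    def test_deterministic_fastq(self, toy_genome):
        profile = pp.example_profiles(2_000)["PGC"]
        r1, t1 = pp.simulate_library(toy_genome, profile, seed=9)
        r2, t2 = pp.simulate_library(toy_genome, profile, seed=9)
        assert r1 == r2
        assert t1.reads.equals(t2.reads)

    def test_read_and_truth_conservation(self, pgc_sim):
        reads, truth = pgc_sim
        assert len(reads) == 50_000
        assert len(truth.reads) == 50_000
        assert truth.reads.read_id.is_unique

    def test_composition_recovers_class_weights(self, pgc_sim):
        _, truth = pgc_sim
        weights = pp.example_profiles()["PGC"].class_weights
        observed = truth.reads["class"].value_counts()
        n = len(truth.reads)
        for cls in SIMULATED_CLASSES:
            p = weights.get(cls, 0.0)
            se = np.sqrt(n * p * (1 - p))
            assert abs(observed.get(cls, 0) - n * p) <= 3 * se + 1

    def test_one_u_fraction_of_cluster_reads(self, pgc_sim):
        reads, truth = pgc_sim
        seq_by_id = {r[0]: r[1] for r in reads}
        sub = truth.reads[truth.reads["class"] == "repeat_piRNA_cluster"]
        assert len(sub) >= 10_000
        first = [seq_by_id[row.read_id][0] for row in sub.itertuples(index=False)]
        assert np.mean([b == "T" for b in first]) >= 0.85

    def test_planted_clusters_pass_default_acceptance_by_construction(
            self, pgc_sim, genome_1mb):
        """Observed planted-cluster loci satisfy every default threshold:
        >= 6 distinct loci, strand-bias score >= 1.3, >= 75% typical length
        (26-32 nt) and >= 75% with the 1U/10A signature."""
        reads, truth = pgc_sim
        seq_by_id = {r[0]: r[1] for r in reads}
        cluster_reads = truth.reads[truth.reads["class"] == "repeat_piRNA_cluster"]
        for row in truth.clusters.itertuples(index=False):
            sub = cluster_reads[cluster_reads.feature_id == row.cluster_id]
            loci = sub.drop_duplicates(["start", "end", "strand"])
            assert len(loci) >= 6
            lengths = (loci.end - loci.start)
            assert ((lengths >= 26) & (lengths <= 32)).mean() >= 0.75
            main = (loci.strand == row.main_strand).sum()
            assert pp.strand_bias_score(main, len(loci) - main) >= 1.3
            sigs = [pp.one_u_ten_a(seq_by_id[r.read_id][:r.insert_len])
                    for r in loci.itertuples(index=False)]
            assert np.mean(sigs) >= 0.75
            # all planted loci fall inside the planted interval
            assert (loci.start >= row.start).all() and (loci.end <= row.end).all()

    def test_adapter_and_quality_flags_match_rates(self, pgc_sim):
        _, truth = pgc_sim
        profile = pp.example_profiles()["PGC"]
        n = len(truth.reads)
        for col, rate in (("has_adapter", profile.adapter_rate),
                          ("low_quality", profile.low_quality_rate)):
            se = np.sqrt(n * rate * (1 - rate))
            assert abs(truth.reads[col].sum() - n * rate) <= 3 * se

    def test_profile_validation(self):
        with pytest.raises(ValueError, match="sum"):
            pp.LibraryProfile(class_weights={"miRNA_like": 0.4})
        with pytest.raises(ValueError, match="unknown read classes"):
            pp.LibraryProfile(class_weights={"nope": 1.0})
        with pytest.raises(ValueError, match="one_u_fraction"):
            pp.LibraryProfile(class_weights={"miRNA_like": 1.0},
                              one_u_fraction=1.5)
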