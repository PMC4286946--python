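"""Shared fixtures: one 1-Mb germ-cell-like simulation reused across the
suite, plus small toy genomes for oracle checks."""

from __future__ import annotations

import pytest
from hypothesis import settings

import pirnapipe as pp

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def genome_1mb() -> pp.GenomeModel:
    return pp.build_genome(pp.GenomeSpec(seed=101))


@pytest.fixture(scope="session")
def pgc_sim(genome_1mb):
    profile = pp.example_profiles(50_000)["PGC"]
    return pp.simulate_library(genome_1mb, profile, seed=202)


@pytest.fixture(scope="session")
def cef_sim(genome_1mb):
    profile = pp.example_profiles(50_000)["CEF"]
    return pp.simulate_library(genome_1mb, profile, seed=203)


@pytest.fixture(scope="session")
def pgc_clean(pgc_sim):
    reads, _ = pgc_sim
    return pp.clean_reads(pp.SmallRNARead(*r) for r in reads)


@pytest.fixture(scope="session")
def cef_clean(cef_sim):
    reads, _ = cef_sim
    return pp.clean_reads(pp.SmallRNARead(*r) for r in reads)


@pytest.fixture(scope="session")
def pgc_tagset(pgc_clean) -> pp.TagSet:
    clean, _ = pgc_clean
    return pp.TagSet.from_samples({"PGC": [r.sequence for r in clean]})


@pytest.fixture(scope="session")
def pgc_mappings(pgc_tagset, genome_1mb):
    return pp.map_tags([t.sequence for t in pgc_tagset], genome_1mb)


@pytest.fixture(scope="session")
def pgc_annotations(pgc_mappings, genome_1mb):
    return pp.annotate_tags(pgc_mappings, genome_1mb)


@pytest.fixture(scope="session")
def pgc_clusters(pgc_mappings, genome_1mb):
    return pp.scan_clusters(pgc_mappings, genome_1mb.chrom_lengths)


@pytest.fixture(scope="session")
def toy_genome() -> pp.GenomeModel:
    """100-kb genome with one planted cluster, for oracle-scale checks."""
    spec = pp.GenomeSpec(chrom_length=100_000, repeat_copies=10, gene_models=3,
                         n_clusters=1, cluster_length=2_000,
                         structural_rna_loci={"tRNA": 3, "rRNA": 1, "snRNA": 1,
                                              "snoRNA": 1, "scRNA": 1,
                                              "miRNA": 3},
                         seed=31)
    return pp.build_genome(spec)


@pytest.fixture(scope="session")
def reference_pirnas():
    from pirnapipe import reference

    return reference.top_pirnas()
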