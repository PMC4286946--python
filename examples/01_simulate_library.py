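"""Build a toy genome with planted piRNA clusters and simulate a germ-cell
small-RNA library with truth labels."""

import collections

import pirnapipe as pp

genome = pp.build_genome(pp.GenomeSpec(chrom_length=500_000, seed=1))
profile = pp.example_profiles(depth=20_000)["PGC"]
reads, truth = pp.simulate_library(genome, profile, seed=1)

print(f"genome: {genome.total_length:,} nt, {len(genome.features)} features")
print(truth.clusters.to_string(index=False))
print("\nread classes:")
for cls, n in collections.Counter(truth.reads["class"]).most_common():
    print(f"  {cls:22s} {n:6d}")

# The planted clusters above are the ground truth that the cluster scanner
# (example 05) must rediscover; the class counts follow the profile weights,
# dominated by repeat-derived piRNA-cluster reads as in germ cells.
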