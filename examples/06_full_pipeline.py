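"""Run the whole pipeline on four simulated samples and print the report
tables (library stats, upregulation by category, piRNA origins)."""

import tempfile
from pathlib import Path

import pirnapipe as pp

outdir = Path(tempfile.mkdtemp(prefix="pirnapipe_demo_"))
config = pp.PipelineConfig(
    outdir=outdir, seed=11,
    profiles=pp.example_profiles(depth=10_000),
    genome_spec=pp.GenomeSpec(chrom_length=500_000, seed=11))
result = pp.run_pipeline(config)

print("library stats:")
for name, st in result.stats.items():
    print(f"  {name:7s} clean {st.clean_reads:6d}/{st.total_reads}  "
          f"unique {st.unique_tags}")

print("\nupregulated tags by category (count/pct per focal sample):")
up = result.upregulation
print(up[(up[[c for c in up.columns if c.startswith('count_')]] > 0)
         .any(axis=1)].to_string(index=False))

print("\npiRNA origin distribution:")
print(result.pirna_origin.to_string(index=False))
print(f"\nfull report bundle under: {outdir}/report")

# The germ-cell-like sample (PGC) shows the most upregulated repeat-derived
# tags and by far the most called piRNAs; the somatic CEF sample shows almost
# none - the contrast the pipeline is designed to quantify.
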