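"""End-to-end orchestration: simulate/clean -> collapse -> map -> annotate ->
quantify -> predict piRNA clusters -> report tables.

One ``PipelineConfig`` drives a deterministic run: a fixed seed is recorded in
the run manifest together with parameters and input checksums, and re-running
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_tags, summarize_distributions
from .clusters import ClusterParams, call_pirnas, scan_clusters, write_clusters_bed
from .expression import expression_table, upregulation_table, write_expression_tsv
from .genome import GenomeModel
from .mapping import MappingParams, SeedIndex, map_tags, write_eland, write_loci_bed
from .reads import CleaningConfig, SmallRNARead, TagSet, clean_reads, read_fastq, write_fastq
from .simulate import GenomeSpec, LibraryProfile, build_genome, example_profiles, simulate_library
from .simulate import write_fastq as write_sim_fastq

log = logging.getLogger("pirnapipe")


@dataclass
class PipelineConfig:
    outdir: str | Path
    seed: int = 0
    samples: dict[str, str] = field(default_factory=dict)   # name -> FASTQ path
    profiles: dict[str, LibraryProfile] = field(default_factory=dict)  # simulated
    genome_fasta: str | None = None
    genome_gff3: str | None = None
    genome_spec: GenomeSpec | None = None
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    mapping: MappingParams = field(default_factory=MappingParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    min_overlap_frac: float = 0.5
    fc_cutoff: float = 2.0
    pseudocount: float = 0.01
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.samples and not self.profiles:
            raise ValueError("pipeline config defines no samples "
                             "(need FASTQ paths or simulator profiles)")
        if self.samples and self.profiles:
            raise ValueError("give either FASTQ samples or simulator profiles, not both")
        if self.profiles and self.genome_spec is None and self.genome_fasta is None:
            raise ValueError("simulated samples need a genome_spec or genome files")
        if not self.profiles and self.genome_fasta is None:
            raise ValueError("FASTQ samples need genome_fasta/genome_gff3")
        for name, path in self.samples.items():
            if not Path(path).exists():
                raise ValueError(f"FASTQ for sample {name!r} not found: {path}")
        for path in (self.genome_fasta, self.genome_gff3):
            if path is not None and not Path(path).exists():
                raise ValueError(f"genome file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {
            "outdir": raw.get("outdir", "pirnapipe_out"),
            "seed": int(raw.get("seed", 0)),
            "samples": dict(raw.get("samples", {})),
        }
        if raw.get("example_profiles"):
            kwargs["profiles"] = example_profiles(
                depth=int(raw.get("depth", 50_000)))
        elif "profiles" in raw:
            kwargs["profiles"] = {
                name: LibraryProfile(name=name, **spec)
                for name, spec in raw["profiles"].items()}
        genome = raw.get("genome", {})
        kwargs["genome_fasta"] = genome.get("fasta")
        kwargs["genome_gff3"] = genome.get("gff3")
        if "spec" in genome:
            kwargs["genome_spec"] = GenomeSpec(**genome["spec"])
        for key, factory in [("cleaning", CleaningConfig), ("mapping", MappingParams),
                             ("cluster", ClusterParams)]:
            if key in raw:
                section = dict(raw[key])
                if key == "cluster" and "pirna_length_range" in section:
                    section["pirna_length_range"] = tuple(section["pirna_length_range"])
                kwargs[key] = factory(**section)
        for key in ("min_overlap_frac", "fc_cutoff", "pseudocount", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class PipelineResult:
    outdir: Path
    genome: GenomeModel
    stats: dict[str, Any]
    tagset: TagSet
    annotations: dict[str, Any]
    expression: pd.DataFrame
    upregulation: pd.DataFrame
    clusters: dict[str, list]
    pirna_origin: pd.DataFrame
    manifest: dict[str, Any]


@contextmanager
def _stage(name: str):
    log.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    log.info("stage %s: done", name)


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sample_seed(base: int, index: int) -> int:
    return (base * 1_000_003 + 7919 * (index + 1)) % (2 ** 31)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    for sub in ("genome", "samples", "tags", "mapping", "expression",
                "clusters", "report"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    checksums: dict[str, str] = {}

    with _stage("genome"):
        if config.genome_fasta is not None:
            genome = GenomeModel.from_files(config.genome_fasta, config.genome_gff3)
            checksums["genome_fasta"] = _md5(Path(config.genome_fasta))
        else:
            genome = build_genome(config.genome_spec, outdir / "genome")

    sample_names = list(config.profiles or config.samples)
    clean_by_sample: dict[str, list[SmallRNARead]] = {}
    stats: dict[str, Any] = {}
    truths = {}
    with _stage("clean"):
        for i, name in enumerate(sample_names):
            sdir = outdir / "samples" / name
            sdir.mkdir(parents=True, exist_ok=True)
            if config.profiles:
                profile = config.profiles[name]
                raw, truth = simulate_library(genome, profile,
                                              _sample_seed(config.seed, i))
                truths[name] = truth
                write_sim_fastq(raw, sdir / "raw.fastq")
                truth.to_tsv(sdir / "truth_reads.tsv", sdir / "truth_clusters.tsv")
                reads = (SmallRNARead(*r) for r in raw)
            else:
                path = Path(config.samples[name])
                checksums[f"fastq_{name}"] = _md5(path)
                reads = read_fastq(path)
            clean, st = clean_reads(reads, config.cleaning)
            clean_by_sample[name] = clean
            write_fastq(clean, sdir / "clean.fastq")
            stats[name] = st
            log.info("sample %s: %d/%d clean reads", name, st.clean_reads,
                     st.total_reads)

    with _stage("collapse"):
        tagset = TagSet.from_samples(clean_by_sample)
        for name in sample_names:
            stats[name].unique_tags = tagset.unique_counts(name)
        tagset.write_tsv(outdir / "tags" / "tags.tsv")
        tagset.write_fasta(outdir / "tags" / "tags.fa")

    with _stage("map"):
        index = SeedIndex(genome, config.mapping.resolve_k(genome.total_length))
        mappings = map_tags([t.sequence for t in tagset], genome,
                            config.mapping, index=index)
        write_loci_bed(mappings.values(), outdir / "mapping" / "loci.bed")
        write_eland(mappings.values(), outdir / "mapping" / "loci.eland.tsv")

    with _stage("annotate"):
        annotations = annotate_tags(mappings, genome, config.min_overlap_frac)
        pd.DataFrame(
            [{"sequence": r.tag, "category": r.category, "n_loci": r.n_loci,
              "repeat_subtype": r.repeat_subtype or "."}
             for r in annotations.values()]
        ).to_csv(outdir / "mapping" / "annotation.tsv", sep="\t", index=False)

    with _stage("quantify"):
        expr = expression_table(tagset, config.fc_cutoff, config.pseudocount)
        write_expression_tsv(expr, outdir / "expression" / "expression.tsv")
        upreg = upregulation_table(expr, annotations, sample_names)
        upreg.to_csv(outdir / "report" / "upregulation.tsv", sep="\t", index=False)

    clusters_by_sample: dict[str, list] = {}
    origin_rows = []
    with _stage("clusters"):
        for name in sample_names:
            present = {t.sequence for t in tagset if t.count(name) > 0}
            cl = scan_clusters(mappings, genome.chrom_lengths, config.cluster,
                               restrict_tags=present)
            clusters_by_sample[name] = cl
            write_clusters_bed(cl, outdir / "clusters" / f"{name}.clusters.bed")
            calls, origin = call_pirnas(cl, mappings, annotations,
                                        restrict_tags=present)
            pd.DataFrame(
                [{"sequence": c.tag, "clusters": ",".join(c.clusters),
                  "origin": c.origin_category} for c in calls]
            ).to_csv(outdir / "clusters" / f"{name}.pirnas.tsv",
                     sep="\t", index=False)
            row = {"sample": name, "input_unique_tags": len(present),
                   "n_pirnas": len(calls)}
            row.update({f"origin_{r.category}": int(r.n_pirnas)
                        for r in origin.itertuples(index=False)})
            origin_rows.append(row)
    pirna_origin = pd.DataFrame(origin_rows)

    with _stage("report"):
        lib_rows = []
        for name in sample_names:
            st = stats[name]
            lib_rows.append({
                "sample": name, "total_reads": st.total_reads,
                "total_bases": st.total_bases, "clean_reads": st.clean_reads,
                "clean_bases": st.clean_bases, "min_len": st.min_len,
                "max_len": st.max_len, "unique_tags": st.unique_tags})
        pd.DataFrame(lib_rows).to_csv(outdir / "report" / "library_stats.tsv",
                                      sep="\t", index=False)
        pirna_origin.to_csv(outdir / "report" / "pirna_origin.tsv",
                            sep="\t", index=False)
        for name in sample_names:
            counts = {t.sequence: t.count(name) for t in tagset}
            cat_df, len_df = summarize_distributions(annotations, counts)
            cat_df.to_csv(outdir / "report" / f"category_distribution_{name}.tsv",
                          sep="\t", index=False, float_format="%.4f")
            len_df.to_csv(outdir / "report" / f"length_distribution_{name}.tsv",
                          sep="\t", index=False, float_format="%.4f")

        manifest = {
            "pirnapipe_version": __version__,
            "seed": config.seed,
            "samples": sample_names,
            "parameters": {
                "cleaning": dataclasses.asdict(config.cleaning),
                "mapping": dataclasses.asdict(config.mapping),
                "cluster": dataclasses.asdict(config.cluster),
                "min_overlap_frac": config.min_overlap_frac,
                "fc_cutoff": config.fc_cutoff,
                "pseudocount": config.pseudocount,
                "genome_spec": (dataclasses.asdict(config.genome_spec)
                                if config.genome_spec else None),
            },
            "input_checksums": checksums,
        }
        (outdir / "report" / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(outdir=outdir, genome=genome, stats=stats,
                          tagset=tagset, annotations=annotations,
                          expression=expr, upregulation=upreg,
                          clusters=clusters_by_sample,
                          pirna_origin=pirna_origin, manifest=manifest)
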