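"""Synthetic genome and small-RNA library simulator with known truth labels.

The generator emulates the statistical structure of germline small-RNA
libraries: repeat-derived piRNA clusters with 1U/10A and strand bias, a few
high-copy miRNA-like species around 22 nt, rRNA/tRNA degradation fragments,
genic fragments, random background, 3' adapter read-through and a low-quality
read fraction.  Germ-cell-like profiles peak at 26 nt among unique tags while
total reads peak at 22 nt; somatic profiles peak at 22 nt throughout.

All randomness flows from one integer seed through a named
``numpy.random.Generator``; identical (spec, profile, seed) yields
byte-identical outputs.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import Feature, GenomeModel, revcomp

#: 33-nt Illumina-style small-RNA 3' adapter used for read-through simulation.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC"

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

SIMULATED_CLASSES = [
    "repeat_piRNA_cluster", "genic_piRNA", "miRNA_like", "rRNA_fragment",
    "tRNA_fragment", "exon_fragment", "intron_fragment", "random_background",
]

#: Genome feature category each read class is drawn from (None = anywhere).
CLASS_SOURCE = {
    "repeat_piRNA_cluster": ["piRNA_cluster"],
    "genic_piRNA": ["exon", "intron"],
    "miRNA_like": ["miRNA"],
    "rRNA_fragment": ["rRNA"],
    "tRNA_fragment": ["tRNA"],
    "exon_fragment": ["exon"],
    "intron_fragment": ["intron"],
    "random_background": [],
}


def _normalized(dist: dict[int, float]) -> dict[int, float]:
    total = float(sum(dist.values()))
    if total <= 0:
        raise ValueError("length distribution has zero mass")
    return {int(k): v / total for k, v in sorted(dist.items())}


def pirna_length_distribution() -> dict[int, float]:
    """Cluster/genic piRNA lengths: peaked at 26 nt, >= 75% mass in 26-32."""
    return _normalized({24: 0.04, 25: 0.08, 26: 0.30, 27: 0.20, 28: 0.15,
                        29: 0.09, 30: 0.06, 31: 0.04, 32: 0.03, 33: 0.01})


def mirna_length_distribution() -> dict[int, float]:
    return _normalized({21: 0.15, 22: 0.60, 23: 0.20, 24: 0.05})


def fragment_length_distribution() -> dict[int, float]:
    """Degradation fragments: broad 18-40 nt, no sharp mode."""
    return _normalized({n: 1.0 for n in range(18, 41)})


def background_length_distribution() -> dict[int, float]:
    return _normalized({n: 1.0 for n in range(18, 45)})


def default_length_distributions() -> dict[str, dict[int, float]]:
    return {
        "repeat_piRNA_cluster": pirna_length_distribution(),
        "genic_piRNA": pirna_length_distribution(),
        "miRNA_like": mirna_length_distribution(),
        "rRNA_fragment": fragment_length_distribution(),
        "tRNA_fragment": fragment_length_distribution(),
        "exon_fragment": fragment_length_distribution(),
        "intron_fragment": fragment_length_distribution(),
        "random_background": background_length_distribution(),
    }


@dataclass
class GenomeSpec:
    """Parameters of the toy reference genome with planted features."""

    n_chromosomes: int = 1
    chrom_length: int = 1_000_000
    repeat_copies: int = 60          # dispersed LINE/CR1-like insertions
    repeat_length: int = 300
    gene_models: int = 20
    exons_per_gene: int = 4
    exon_length: int = 150
    intron_length: int = 800
    structural_rna_loci: dict[str, int] = field(default_factory=lambda: {
        "tRNA": 8, "rRNA": 4, "snRNA": 3, "snoRNA": 3, "scRNA": 3, "miRNA": 8,
    })
    n_clusters: int = 3              # planted piRNA cluster intervals
    cluster_length: int = 3_000
    repeat_divergence: float = 0.08  # per-base mutation rate per repeat copy
    base_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    STRUCTURAL_LENGTHS = {
        "tRNA": 75, "rRNA": 1500, "snRNA": 150, "snoRNA": 100,
        "scRNA": 300, "miRNA": 22,
    }

    def planted_length(self) -> int:
        gene_len = (self.exons_per_gene * self.exon_length
                    + (self.exons_per_gene - 1) * self.intron_length)
        structural = sum(self.STRUCTURAL_LENGTHS[c] * n
                         for c, n in self.structural_rna_loci.items())
        return (self.n_clusters * self.cluster_length
                + self.gene_models * gene_len
                + self.repeat_copies * self.repeat_length
                + structural)


@dataclass
class LibraryProfile:
    """Composition and signal parameters of one simulated library."""

    class_weights: dict[str, float]
    length_distributions: dict[str, dict[int, float]] = field(
        default_factory=default_length_distributions)
    one_u_fraction: float = 0.9      # cluster/genic piRNA reads starting with T
    ten_a_fraction: float = 0.5      # ... with A at position 10
    strand_main_fraction: float = 0.95
    adapter_rate: float = 0.10
    low_quality_rate: float = 0.05
    depth: int = 50_000
    adapter: str = DEFAULT_ADAPTER
    cluster_distinct_loci: int = 600     # distinct tag loci planted per cluster
    fragment_diversity: dict[str, int] = field(default_factory=lambda: {
        "rRNA_fragment": 120, "tRNA_fragment": 40,
        "exon_fragment": 10, "intron_fragment": 10,
    })
    fragment_antisense_rate: float = 0.10
    name: str = "sample"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        unknown = set(self.class_weights) - set(SIMULATED_CLASSES)
        if unknown:
            raise ValueError(f"unknown read classes: {sorted(unknown)}")
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class weights sum to {total}, expected 1")
        for name, value in [
            ("one_u_fraction", self.one_u_fraction),
            ("ten_a_fraction", self.ten_a_fraction),
            ("strand_main_fraction", self.strand_main_fraction),
            ("adapter_rate", self.adapter_rate),
            ("low_quality_rate", self.low_quality_rate),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        for cls, dist in self.length_distributions.items():
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ValueError(f"length distribution for {cls} does not sum to 1")


def example_profiles(depth: int = 50_000) -> dict[str, LibraryProfile]:
    """Four library profiles mirroring a germ-cell versus somatic contrast.

    PGC-like: repeat-cluster dominated, unique tags peak at 26 nt.
    StageX-like: intermediate (nascent germ cells within the blastoderm).
    GSC/CEF-like: somatic; miRNA/rRNA dominated, total reads peak at 22 nt.
    """
    weights = {
        "PGC": {"repeat_piRNA_cluster": 0.44, "genic_piRNA": 0.02,
                "miRNA_like": 0.26, "rRNA_fragment": 0.10,
                "tRNA_fragment": 0.05, "exon_fragment": 0.04,
                "intron_fragment": 0.06, "random_background": 0.03},
        "StageX": {"repeat_piRNA_cluster": 0.22, "genic_piRNA": 0.03,
                   "miRNA_like": 0.30, "rRNA_fragment": 0.20,
                   "tRNA_fragment": 0.08, "exon_fragment": 0.05,
                   "intron_fragment": 0.07, "random_background": 0.05},
        "GSC": {"repeat_piRNA_cluster": 0.04, "genic_piRNA": 0.02,
                "miRNA_like": 0.32, "rRNA_fragment": 0.35,
                "tRNA_fragment": 0.06, "exon_fragment": 0.10,
                "intron_fragment": 0.08, "random_background": 0.03},
        "CEF": {"repeat_piRNA_cluster": 0.01, "genic_piRNA": 0.01,
                "miRNA_like": 0.47, "rRNA_fragment": 0.28,
                "tRNA_fragment": 0.10, "exon_fragment": 0.05,
                "intron_fragment": 0.05, "random_background": 0.03},
    }
    return {name: LibraryProfile(class_weights=w, depth=depth, name=name)
            for name, w in weights.items()}


@dataclass
class TruthTable:
    """Per-read class labels and planted cluster intervals."""

    reads: pd.DataFrame     # read_id, class, feature_id, chrom, start, end,
                            # strand, insert_len, low_quality, has_adapter
    clusters: pd.DataFrame  # cluster_id, chrom, start, end, main_strand, n_loci

    def to_tsv(self, reads_path: str | Path, clusters_path: str | Path) -> None:
        self.reads.to_csv(reads_path, sep="\t", index=False)
        self.clusters.to_csv(clusters_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, reads_path: str | Path, clusters_path: str | Path) -> "TruthTable":
        return cls(pd.read_csv(reads_path, sep="\t"),
                   pd.read_csv(clusters_path, sep="\t"))


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

class _Allocator:
    """Non-overlapping interval placement on one chromosome."""

    def __init__(self, length: int):
        self.length = length
        self.starts: list[int] = []
        self.ends: list[int] = []

    def try_place(self, size: int, rng: np.random.Generator,
                  attempts: int = 1000) -> int | None:
        if size > self.length:
            return None
        for _ in range(attempts):
            start = int(rng.integers(0, self.length - size + 1))
            i = bisect.bisect_right(self.starts, start)
            if i > 0 and self.ends[i - 1] > start:
                continue
            if i < len(self.starts) and self.starts[i] < start + size:
                continue
            self.starts.insert(i, start)
            self.ends.insert(i, start + size)
            return start
        return None


def _random_sequence(rng: np.random.Generator, length: int,
                     weights: tuple[float, ...]) -> np.ndarray:
    return rng.choice(4, size=length, p=np.asarray(weights) / sum(weights)).astype(np.uint8)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    hits = np.flatnonzero(rng.random(len(codes)) < rate)
    if len(hits):
        # shift by 1-3 mod 4 guarantees an actual substitution
        out[hits] = (out[hits] + rng.integers(1, 4, size=len(hits))) % 4
    return out


def build_genome(spec: GenomeSpec, outdir: str | Path | None = None) -> GenomeModel:
    """Generate chromosome sequences and plant the configured feature set.

    Features of all categories are placed without overlap (exons/introns nest
    inside their gene, repeat copies tile planted clusters).  Raises
    ``ValueError`` naming the category if a feature cannot be placed or the
    requested features exceed 80% of the genome.
    """
    rng = np.random.default_rng(spec.seed)
    total_len = spec.n_chromosomes * spec.chrom_length
    if spec.planted_length() > 0.8 * total_len:
        raise ValueError(
            f"infeasible packing: planted features span {spec.planted_length()} nt, "
            f"more than 80% of the {total_len} nt genome")

    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    chrom_codes = {name: _random_sequence(rng, spec.chrom_length, spec.base_weights)
                   for name in chrom_names}
    allocators = {name: _Allocator(spec.chrom_length) for name in chrom_names}
    features: list[Feature] = []
    # each cluster and each dispersed subtype gets its own repeat consensus:
    # old LINE/CR1-like families are diverged enough that 18-44 nt tags map
    # (near-)uniquely outside their own cluster
    consensus_pool: dict[str, np.ndarray] = {}

    def consensus_for(family: str) -> np.ndarray:
        if family not in consensus_pool:
            consensus_pool[family] = _random_sequence(rng, spec.repeat_length,
                                                      (0.25,) * 4)
        return consensus_pool[family]

    def place(size: int, category: str) -> tuple[str, int]:
        chrom = chrom_names[int(rng.integers(0, spec.n_chromosomes))]
        start = allocators[chrom].try_place(size, rng)
        if start is None:
            raise ValueError(f"infeasible packing: could not place a {category} "
                             f"feature of {size} nt")
        return chrom, start

    def plant_repeat(chrom: str, start: int, strand: str, idx: int,
                     subtype: str, family: str) -> None:
        copy = _mutate(consensus_for(family), spec.repeat_divergence, rng)
        if strand == "-":
            copy = (3 - copy)[::-1]  # reverse complement in code space
        chrom_codes[chrom][start:start + spec.repeat_length] = copy
        features.append(Feature(f"repeat_{idx}", chrom, start,
                                start + spec.repeat_length, strand, "repeat",
                                subtype=subtype))

    repeat_idx = 0
    # planted piRNA clusters: intervals tiled with same-strand repeat copies
    for ci in range(spec.n_clusters):
        chrom, start = place(spec.cluster_length, "piRNA_cluster")
        main_strand = "+" if rng.random() < 0.5 else "-"
        features.append(Feature(f"cluster_{ci}", chrom, start,
                                start + spec.cluster_length, main_strand,
                                "piRNA_cluster"))
        for off in range(0, spec.cluster_length - spec.repeat_length + 1,
                         spec.repeat_length):
            plant_repeat(chrom, start + off, main_strand, repeat_idx,
                         "LINE/CR1", family=f"cluster_{ci}")
            repeat_idx += 1

    # dispersed repeat copies
    subtypes = ["LINE/CR1", "LTR/ERVL", "SINE/MIR"]
    for _ in range(spec.repeat_copies):
        chrom, start = place(spec.repeat_length, "repeat")
        strand = "+" if rng.random() < 0.5 else "-"
        subtype = subtypes[int(rng.choice(3, p=[0.7, 0.2, 0.1]))]
        plant_repeat(chrom, start, strand, repeat_idx, subtype, family=subtype)
        repeat_idx += 1

    # gene models with alternating exons and introns
    gene_len = (spec.exons_per_gene * spec.exon_length
                + (spec.exons_per_gene - 1) * spec.intron_length)
    for gi in range(spec.gene_models):
        chrom, start = place(gene_len, "gene")
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene_{gi}"
        features.append(Feature(gene_id, chrom, start, start + gene_len,
                                strand, "gene"))
        pos = start
        for ei in range(spec.exons_per_gene):
            features.append(Feature(f"{gene_id}_exon_{ei}", chrom, pos,
                                    pos + spec.exon_length, strand, "exon",
                                    parent=gene_id))
            pos += spec.exon_length
            if ei < spec.exons_per_gene - 1:
                features.append(Feature(f"{gene_id}_intron_{ei}", chrom, pos,
                                        pos + spec.intron_length, strand,
                                        "intron", parent=gene_id))
                pos += spec.intron_length

    # structural small RNA loci
    for category in sorted(spec.structural_rna_loci):
        size = spec.STRUCTURAL_LENGTHS[category]
        for i in range(spec.structural_rna_loci[category]):
            chrom, start = place(size, category)
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(Feature(f"{category}_{i}", chrom, start,
                                    start + size, strand, category))

    sequences = {name: BASES[codes].tobytes().decode()
                 for name, codes in chrom_codes.items()}
    genome = GenomeModel(sequences, features)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genome.write(outdir / "genome.fa", outdir / "features.gff3",
                     outdir / "features.bed")
    return genome


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Locus:
    chrom: str
    start: int
    end: int
    strand: str
    feature_id: str

    def read_sequence(self, genome: GenomeModel) -> str:
        seq = genome.sequences[self.chrom][self.start:self.end]
        return revcomp(seq) if self.strand == "-" else seq


def _sample_length(dist: dict[int, float], rng: np.random.Generator) -> int:
    lengths = list(dist)
    return int(lengths[int(rng.choice(len(lengths), p=list(dist.values())))])


def _draw_signature_locus(genome: GenomeModel, interval: Feature,
                          length: int, strand: str, want_1u: bool,
                          want_10a: bool, rng: np.random.Generator,
                          feature_id: str, attempts: int = 200) -> _Locus:
    """Rejection-sample a start whose read shows the requested 1U/10A bases."""
    lo, hi = interval.start, interval.end - length
    if hi < lo:
        lo, hi = interval.start, interval.start
    seq = genome.sequences[interval.chrom]
    locus = None
    for _ in range(attempts):
        start = int(rng.integers(lo, hi + 1))
        locus = _Locus(interval.chrom, start, start + length, strand, feature_id)
        read = locus.read_sequence(genome)
        if want_1u and read[0] != "T":
            continue
        if want_10a and (len(read) < 10 or read[9] != "A"):
            continue
        return locus
    return locus  # constraint waived after `attempts` tries (bias negligible)


def _plant_cluster_loci(genome: GenomeModel, cluster: Feature,
                        profile: LibraryProfile,
                        rng: np.random.Generator) -> list[_Locus]:
    dist = profile.length_distributions["repeat_piRNA_cluster"]
    loci: list[_Locus] = []
    seen: set[tuple[int, int, str]] = set()
    attempts = 0
    while len(loci) < profile.cluster_distinct_loci:
        attempts += 1
        if attempts > 50 * profile.cluster_distinct_loci:
            raise ValueError(
                f"could not plant {profile.cluster_distinct_loci} distinct loci "
                f"in cluster {cluster.feature_id}")
        length = _sample_length(dist, rng)
        main = rng.random() < profile.strand_main_fraction
        strand = cluster.strand if main else ("-" if cluster.strand == "+" else "+")
        locus = _draw_signature_locus(
            genome, cluster, length, strand,
            want_1u=rng.random() < profile.one_u_fraction,
            want_10a=rng.random() < profile.ten_a_fraction,
            rng=rng, feature_id=cluster.feature_id)
        key = (locus.start, locus.end, locus.strand)
        if key not in seen:
            seen.add(key)
            loci.append(locus)
    return loci


def _plant_fragment_loci(genome: GenomeModel, feature: Feature, n: int,
                         dist: dict[int, float], antisense_rate: float,
                         rng: np.random.Generator) -> list[_Locus]:
    """Pre-draw a limited set of distinct degradation-fragment species."""
    loci = []
    seen: set[tuple[int, int, str]] = set()
    for _ in range(8 * n):
        if len(loci) >= n:
            break
        length = min(_sample_length(dist, rng), feature.length)
        start = int(rng.integers(feature.start, feature.end - length + 1))
        strand = feature.strand
        if rng.random() < antisense_rate:
            strand = "-" if strand == "+" else "+"
        key = (start, start + length, strand)
        if key not in seen:
            seen.add(key)
            loci.append(_Locus(feature.chrom, start, start + length, strand,
                               feature.feature_id))
    return loci


def simulate_library(genome: GenomeModel, profile: LibraryProfile,
                     seed: int) -> tuple[list[tuple[str, str, str]], TruthTable]:
    """Simulate one FASTQ library; returns (reads, truth).

    Each read is an ``(id, sequence, quality_string)`` triple (Phred+33).
    Raises ``ValueError`` if a class with nonzero weight has no source
    feature in the genome.
    """
    rng = np.random.default_rng(seed)
    active = [c for c in SIMULATED_CLASSES if profile.class_weights.get(c, 0) > 0]
    for cls in active:
        needed = CLASS_SOURCE[cls]
        if needed and not any(genome.features_by_category(cat) for cat in needed):
            raise ValueError(
                f"class {cls!r} has weight "
                f"{profile.class_weights[cls]} but the genome has no "
                f"{'/'.join(needed)} features")

    clusters = genome.features_by_category("piRNA_cluster")
    cluster_loci = {c.feature_id: _plant_cluster_loci(genome, c, profile, rng)
                    for c in (clusters if "repeat_piRNA_cluster" in active else [])}
    cluster_df = pd.DataFrame(
        [{"cluster_id": c.feature_id, "chrom": c.chrom, "start": c.start,
          "end": c.end, "main_strand": c.strand,
          "n_loci": len(cluster_loci.get(c.feature_id, []))}
         for c in clusters])

    frag_loci: dict[str, list[_Locus]] = {}
    for cls in ("rRNA_fragment", "tRNA_fragment", "exon_fragment",
                "intron_fragment"):
        if cls not in active:
            continue
        pool: list[_Locus] = []
        for feat in genome.features_by_category(CLASS_SOURCE[cls][0]):
            pool.extend(_plant_fragment_loci(
                genome, feat, profile.fragment_diversity.get(cls, 20),
                profile.length_distributions[cls],
                profile.fragment_antisense_rate, rng))
        frag_loci[cls] = pool

    mirna_feats = genome.features_by_category("miRNA")
    if "miRNA_like" in active:
        mirna_weights = rng.dirichlet(np.full(len(mirna_feats), 0.5))

    genic_feats = (genome.features_by_category("exon")
                   + genome.features_by_category("intron"))
    chrom_names = sorted(genome.sequences)
    chrom_p = np.array([len(genome.sequences[c]) for c in chrom_names], float)
    chrom_p /= chrom_p.sum()

    if profile.depth == 0:
        return [], TruthTable(reads=pd.DataFrame(
            columns=["read_id", "class", "feature_id", "chrom", "start", "end",
                     "strand", "insert_len", "low_quality", "has_adapter"]),
            clusters=cluster_df)

    weights = np.array([profile.class_weights.get(c, 0.0) for c in SIMULATED_CLASSES])
    class_idx = rng.choice(len(SIMULATED_CLASSES), size=profile.depth, p=weights)
    adapter_flags = rng.random(profile.depth) < profile.adapter_rate
    lowq_flags = rng.random(profile.depth) < profile.low_quality_rate

    def draw_locus(cls: str) -> _Locus:
        if cls == "repeat_piRNA_cluster":
            cluster = clusters[int(rng.integers(len(clusters)))]
            pool = cluster_loci[cluster.feature_id]
            return pool[int(rng.integers(len(pool)))]
        if cls == "miRNA_like":
            feat = mirna_feats[int(rng.choice(len(mirna_feats), p=mirna_weights))]
            return _Locus(feat.chrom, feat.start, feat.end, feat.strand,
                          feat.feature_id)
        if cls == "genic_piRNA":
            feat = genic_feats[int(rng.integers(len(genic_feats)))]
            length = min(_sample_length(
                profile.length_distributions[cls], rng), feat.length)
            strand = feat.strand if rng.random() < 0.5 else (
                "-" if feat.strand == "+" else "+")
            return _draw_signature_locus(
                genome, feat, length, strand,
                want_1u=rng.random() < profile.one_u_fraction,
                want_10a=rng.random() < profile.ten_a_fraction,
                rng=rng, feature_id=feat.feature_id)
        if cls in frag_loci:
            pool = frag_loci[cls]
            return pool[int(rng.integers(len(pool)))]
        # random background
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
        length = _sample_length(profile.length_distributions[cls], rng)
        start = int(rng.integers(0, len(genome.sequences[chrom]) - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        return _Locus(chrom, start, start + length, strand, ".")

    ids, seqs, truth_rows = [], [], []
    for i in range(profile.depth):
        cls = SIMULATED_CLASSES[class_idx[i]]
        locus = draw_locus(cls)
        insert = locus.read_sequence(genome)
        seq = insert + profile.adapter if adapter_flags[i] else insert
        read_id = f"{profile.name}_{i:06d}"
        ids.append(read_id)
        seqs.append(seq)
        truth_rows.append((read_id, cls, locus.feature_id, locus.chrom,
                           locus.start, locus.end, locus.strand, len(insert),
                           bool(lowq_flags[i]), bool(adapter_flags[i])))

    quals = _quality_strings(np.array([len(s) for s in seqs]), lowq_flags, rng)
    reads = list(zip(ids, seqs, quals))
    truth = TruthTable(
        reads=pd.DataFrame(truth_rows, columns=[
            "read_id", "class", "feature_id", "chrom", "start", "end",
            "strand", "insert_len", "low_quality", "has_adapter"]),
        clusters=cluster_df)
    return reads, truth


def _quality_strings(lengths: np.ndarray, lowq: np.ndarray,
                     rng: np.random.Generator) -> list[str]:
    """Two-component per-base Phred model: good reads ~Q35, bad reads ~Q8."""
    means = np.where(lowq, 8.0, 35.0)
    per_base_mean = np.repeat(means, lengths)
    q = rng.normal(per_base_mean, 2.5)
    q = np.clip(np.rint(q), 2, 41).astype(np.uint8) + 33
    blob = q.tobytes().decode("latin-1")
    out, pos = [], 0
    for n in lengths:
        out.append(blob[pos:pos + n])
        pos += n
    return out


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
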