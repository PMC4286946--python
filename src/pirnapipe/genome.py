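"""Genome container: chromosome sequences plus strand-aware feature intervals.

Coordinates are 0-based half-open internally.  GFF3 is written/read 1-based
closed; BED6 is written 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

#: Annotation categories, highest priority first.  Structural RNAs outrank
#: miRNAs, which outrank repeats, which outrank exons, then introns.
CATEGORY_PRIORITY = [
    "tRNA", "rRNA", "snRNA", "snoRNA", "scRNA",
    "miRNA", "repeat", "exon", "intron",
]

#: Feature categories that exist in the genome model but never annotate a tag
#: (truth metadata and gene scaffolding).
NON_ANNOTATING = {"gene", "piRNA_cluster"}

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """A strand-aware genomic interval with an annotation category."""

    feature_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str
    category: str
    subtype: str | None = None  # repeat subtype, e.g. "LINE/CR1"
    parent: str | None = None   # gene id for exons/introns

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r} for {self.feature_id}")
        if self.end <= self.start:
            raise ValueError(f"empty interval for {self.feature_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeModel:
    """Chromosome sequences and the feature set used for mapping/annotation."""

    def __init__(self, sequences: dict[str, str], features: Iterable[Feature] = ()):
        self.sequences = dict(sequences)
        self.features: list[Feature] = list(features)
        for f in self.features:
            if f.chrom not in self.sequences:
                raise ValueError(f"feature {f.feature_id} on unknown chromosome {f.chrom}")
            if f.end > len(self.sequences[f.chrom]):
                raise ValueError(f"feature {f.feature_id} exceeds chromosome bounds")
        self._trees: dict[str, IntervalTree] | None = None

    # -- basic accessors -------------------------------------------------
    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def features_by_category(self, category: str) -> list[Feature]:
        return [f for f in self.features if f.category == category]

    def feature_sequence(self, feature: Feature) -> str:
        seq = self.sequences[feature.chrom][feature.start:feature.end]
        return revcomp(seq) if feature.strand == "-" else seq

    def interval_tree(self, chrom: str) -> IntervalTree:
        """Interval tree over annotating features of one chromosome."""
        if self._trees is None:
            self._trees = {name: IntervalTree() for name in self.sequences}
            for f in self.features:
                if f.category not in NON_ANNOTATING:
                    self._trees[f.chrom].addi(f.start, f.end, f)
        return self._trees[chrom]

    # -- I/O -------------------------------------------------------------
    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sorted(self.sequences.items())
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in sorted(self.sequences.items()):
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for f in sorted(self.features, key=lambda f: (f.chrom, f.start, f.feature_id)):
                attrs = [f"ID={f.feature_id}", f"category={f.category}"]
                if f.subtype:
                    attrs.append(f"subtype={f.subtype}")
                if f.parent:
                    attrs.append(f"Parent={f.parent}")
                fh.write(
                    "\t".join([
                        f.chrom, "pirnapipe", f.category,
                        str(f.start + 1), str(f.end), ".", f.strand, ".",
                        ";".join(attrs),
                    ]) + "\n"
                )

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in sorted(self.features, key=lambda f: (f.chrom, f.start, f.feature_id)):
                fh.write(
                    f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\n"
                )

    def write(self, fasta: str | Path, gff3: str | Path, bed: str | Path | None = None) -> None:
        self.write_fasta(fasta)
        self.write_gff3(gff3)
        if bed is not None:
            self.write_bed(bed)

    @classmethod
    def from_files(cls, fasta: str | Path, gff3: str | Path | None = None) -> "GenomeModel":
        sequences = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
        }
        features = list(parse_gff3(gff3)) if gff3 is not None else []
        return cls(sequences, features)


def parse_gff3(path: str | Path) -> Iterator[Feature]:
    """Read features back from the 9-column GFF3 written by this package."""
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            yield Feature(
                feature_id=attrs.get("ID", "."),
                chrom=cols[0],
                start=int(cols[3]) - 1,
                end=int(cols[4]),
                strand=cols[6],
                category=attrs.get("category", cols[2]),
                subtype=attrs.get("subtype"),
                parent=attrs.get("Parent"),
            )
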