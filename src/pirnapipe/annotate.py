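"""Hierarchical single-category annotation of mapped tags.

Every mapped tag receives exactly one category via a priority rule:
structural RNAs (tRNA > rRNA > snRNA > snoRNA > scRNA) outrank miRNAs, which
outrank repeats, then exons, then introns.  Exon/intron assignments are split
into sense/antisense by comparing the locus strand with the gene strand.  A
locus overlaps a feature when at least ``min_overlap_frac`` of the locus lies
inside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .genome import CATEGORY_PRIORITY, GenomeModel
from .mapping import TagMapping

#: Final report categories in fixed order.
ANNOTATION_CATEGORIES = [
    "tRNA", "rRNA", "snRNA", "snoRNA", "scRNA", "miRNA", "repeat",
    "exon_sense", "exon_antisense", "intron_sense", "intron_antisense",
    "unannotated",
]

_RANK = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}


@dataclass(frozen=True)
class AnnotationRecord:
    tag: str
    category: str
    n_loci: int
    repeat_subtype: str | None = None


def annotate_tag(mapping: TagMapping, genome: GenomeModel,
                 min_overlap_frac: float = 0.5) -> AnnotationRecord:
    """Assign the single highest-priority category over all (locus, feature)
    overlap pairs of a mapped tag."""
    if not mapping.loci:
        raise ValueError(f"tag {mapping.tag} has no loci; unmapped tags are "
                         "reported separately")
    best_rank = len(CATEGORY_PRIORITY)
    sense_hit = antisense_hit = False
    subtypes: set[str] = set()
    for locus in mapping.loci:
        tree = genome.interval_tree(locus.chrom)
        min_overlap = min_overlap_frac * (locus.end - locus.start)
        for iv in tree.overlap(locus.start, locus.end):
            overlap = min(locus.end, iv.end) - max(locus.start, iv.begin)
            if overlap < min_overlap:
                continue
            feature = iv.data
            rank = _RANK[feature.category]
            if rank < best_rank:
                best_rank = rank
                sense_hit = antisense_hit = False
                subtypes = set()
            if rank == best_rank:
                if feature.category == "repeat" and feature.subtype:
                    subtypes.add(feature.subtype)
                if locus.strand == feature.strand:
                    sense_hit = True
                else:
                    antisense_hit = True
    if best_rank == len(CATEGORY_PRIORITY):
        return AnnotationRecord(mapping.tag, "unannotated", mapping.n_loci)
    category = CATEGORY_PRIORITY[best_rank]
    subtype = None
    if category == "repeat":
        subtype = "Ambi" if len(subtypes) > 1 else (next(iter(subtypes), None))
    elif category in ("exon", "intron"):
        # sense wins when both orientations are hit at the top category
        category += "_sense" if sense_hit else "_antisense"
    return AnnotationRecord(mapping.tag, category, mapping.n_loci, subtype)


def annotate_tags(mappings: Mapping[str, TagMapping], genome: GenomeModel,
                  min_overlap_frac: float = 0.5) -> dict[str, AnnotationRecord]:
    """Annotate every mapped tag; tags with zero loci are skipped."""
    return {
        tag: annotate_tag(m, genome, min_overlap_frac)
        for tag, m in mappings.items() if m.loci
    }


def summarize_distributions(records: Mapping[str, AnnotationRecord],
                            counts: Mapping[str, int],
                            lengths: tuple[int, int] = (18, 44),
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Category and length distributions over mapped tags for one sample.

    ``counts`` maps tag sequence -> read count in the sample; tags absent or
    at zero count are excluded.  Returns (category_table, length_table), each
    with unique- and total-read counts and percentages.
    """
    cat_unique = {c: 0 for c in ANNOTATION_CATEGORIES}
    cat_total = {c: 0 for c in ANNOTATION_CATEGORIES}
    len_unique = {n: 0 for n in range(lengths[0], lengths[1] + 1)}
    len_total = {n: 0 for n in range(lengths[0], lengths[1] + 1)}
    for tag, rec in records.items():
        c = counts.get(tag, 0)
        if c <= 0:
            continue
        cat_unique[rec.category] += 1
        cat_total[rec.category] += c
        if len(tag) in len_unique:
            len_unique[len(tag)] += 1
            len_total[len(tag)] += c
    n_unique = sum(cat_unique.values()) or 1
    n_total = sum(cat_total.values()) or 1
    cat_df = pd.DataFrame({
        "category": ANNOTATION_CATEGORIES,
        "unique_reads": [cat_unique[c] for c in ANNOTATION_CATEGORIES],
        "total_reads": [cat_total[c] for c in ANNOTATION_CATEGORIES],
    })
    cat_df["unique_pct"] = 100.0 * cat_df.unique_reads / n_unique
    cat_df["total_pct"] = 100.0 * cat_df.total_reads / n_total
    len_df = pd.DataFrame({
        "length": list(len_unique),
        "unique_reads": list(len_unique.values()),
        "total_reads": list(len_total.values()),
    })
    len_df["unique_pct"] = 100.0 * len_df.unique_reads / n_unique
    len_df["total_pct"] = 100.0 * len_df.total_reads / n_total
    return cat_df, len_df
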