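"""Per-tag RPKM, cross-sample fold change, and 2-fold upregulation tables.

RPKM normalizes a tag's read count by its own length (in kb) and the sample's
total clean reads (in millions): ``C * 1e9 / (L * N)``.  The fold change of a
focal sample is its RPKM over the mean RPKM of the other samples, with the
denominator floored at a small pseudocount so tags absent elsewhere get a
finite, large fold change.  A tag is upregulated in a sample when its fold
change there is at least the cutoff (default 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotate import ANNOTATION_CATEGORIES, AnnotationRecord
from .reads import TagSet


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Report-time rounding: 0.005 -> 0.01 (not banker's)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def rpkm(count: int, length: int, total_clean_reads: int) -> float:
    """Reads per kilobase (of the tag's own length) per million clean reads."""
    if total_clean_reads <= 0:
        raise ValueError("total clean reads must be positive")
    if length <= 0:
        raise ValueError("tag length must be positive")
    return count * 1e9 / (length * total_clean_reads)


def fold_change(rpkms: Mapping[str, float], focal: str,
                pseudocount: float = 0.01) -> float:
    """Focal-sample RPKM over the mean of the other samples, denominator
    floored at ``pseudocount``."""
    others = [v for s, v in rpkms.items() if s != focal]
    if not others:
        raise ValueError("fold change requires at least two samples")
    denom = max(sum(others) / len(others), pseudocount)
    return rpkms[focal] / denom


@dataclass(frozen=True)
class ExpressionRecord:
    tag: str
    rpkm: dict[str, float]
    fold_change: dict[str, float]
    upregulated: dict[str, bool]


def expression_table(tagset: TagSet, fc_cutoff: float = 2.0,
                     pseudocount: float = 0.01) -> pd.DataFrame:
    """Per-tag expression across all samples of a tag set.

    Columns: sequence, length, then count_/rpkm_/fc_/up_ per sample.
    """
    samples = tagset.sample_names
    rows = []
    for tag in tagset:
        rpkms = {s: rpkm(tag.count(s), tag.length, tagset.clean_totals[s])
                 for s in samples}
        row: dict[str, object] = {"sequence": tag.sequence, "length": tag.length}
        for s in samples:
            row[f"count_{s}"] = tag.count(s)
            row[f"rpkm_{s}"] = rpkms[s]
        if len(samples) > 1:
            for s in samples:
                fc = fold_change(rpkms, s, pseudocount)
                row[f"fc_{s}"] = fc
                row[f"up_{s}"] = fc >= fc_cutoff
        rows.append(row)
    return pd.DataFrame(rows)


def upregulation_table(expr: pd.DataFrame,
                       annotations: Mapping[str, AnnotationRecord],
                       samples: Sequence[str]) -> pd.DataFrame:
    """Counts and percentages of upregulated tags by annotation category,
    one count/percentage column pair per focal sample.

    Only annotated (mapped) tags are counted; percentages are per focal
    sample, of that sample's total upregulated tags, rounded half-up to two
    decimals at report time.
    """
    table: dict[str, dict[str, int]] = {
        c: {s: 0 for s in samples} for c in ANNOTATION_CATEGORIES}
    totals = {s: 0 for s in samples}
    for row in expr.itertuples(index=False):
        rec = annotations.get(row.sequence)
        if rec is None:
            continue
        for s in samples:
            if getattr(row, f"up_{s}", False) and getattr(row, f"count_{s}") > 0:
                table[rec.category][s] += 1
                totals[s] += 1
    out = pd.DataFrame({"category": ANNOTATION_CATEGORIES})
    for s in samples:
        out[f"count_{s}"] = [table[c][s] for c in ANNOTATION_CATEGORIES]
        denom = totals[s]
        out[f"pct_{s}"] = [
            round_half_up(100.0 * table[c][s] / denom) if denom else 0.0
            for c in ANNOTATION_CATEGORIES]
    return out


def category_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Percentages (half-up, 2 dp) of category counts over their total."""
    total = sum(counts.values())
    if total == 0:
        return {c: 0.0 for c in counts}
    return {c: round_half_up(100.0 * n / total) for c, n in counts.items()}


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index=False, float_format="%.6g")
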