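"""Raw FASTQ cleaning and unique-tag collapsing.

Cleaning contract: trim the 3' adapter, discard reads whose mean per-base
Phred quality is below the threshold (default 13), discard reads containing N,
and keep only inserts of 18-44 nt.  Filter order is trim -> quality -> length,
so retention is decided by the insert, not the adapter bases.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .simulate import DEFAULT_ADAPTER


@dataclass(frozen=True)
class SmallRNARead:
    id: str
    sequence: str
    qualities: str  # Phred+33

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence and quality lengths differ")

    @property
    def phred(self) -> np.ndarray:
        return np.frombuffer(self.qualities.encode("latin-1"), np.uint8) - 33

    @property
    def mean_quality(self) -> float:
        return float(self.phred.mean()) if self.sequence else 0.0


@dataclass
class CleaningConfig:
    min_mean_quality: float = 13.0
    min_length: int = 18
    max_length: int = 44
    adapter: str = DEFAULT_ADAPTER
    min_adapter_overlap: int = 6
    adapter_mismatch_frac: float = 0.10
    quality_mode: str = "mean"  # "mean" (whole-read) or "any_base"

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length exceeds max_length")
        if self.min_mean_quality < 0:
            raise ValueError("min_mean_quality must be non-negative")
        if self.quality_mode not in ("mean", "any_base"):
            raise ValueError(f"unknown quality_mode {self.quality_mode!r}")


@dataclass
class LibraryStats:
    total_reads: int = 0
    total_bases: int = 0
    clean_reads: int = 0
    clean_bases: int = 0
    min_len: int | None = None
    max_len: int | None = None
    unique_tags: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[SmallRNARead]:
    """Stream a (optionally gzipped) FASTQ file; malformed records raise
    ``ValueError`` naming the record index."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        index = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record at index {index} in {path}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ record at index {index} in {path}: "
                    f"sequence/quality length mismatch")
            yield SmallRNARead(header[1:].split()[0], seq.upper(), qual)
            index += 1


def write_fastq(reads: Iterable[SmallRNARead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.qualities}\n")


# ---------------------------------------------------------------------------
# adapter trimming
# ---------------------------------------------------------------------------

def find_adapter(seq: str, adapter: str, min_overlap: int = 6,
                 max_mismatch_frac: float = 0.10) -> int | None:
    """Best semi-global suffix(read)/prefix(adapter) match.

    Returns the read position where the adapter starts (trim point), or None.
    The leftmost start with mismatches <= floor(max_mismatch_frac * overlap)
    wins.  Fast paths cover exact matches; the tolerant scan is vectorized.
    """
    L, A = len(seq), len(adapter)
    if L < min_overlap or A < min_overlap:
        return None
    # fast path: exact occurrence of the adapter prefix
    probe = adapter[:min(A, 10)]
    pos = seq.find(probe)
    if pos != -1 and L - pos >= min_overlap:
        overlap = min(A, L - pos)
        mism = sum(a != b for a, b in zip(seq[pos:pos + overlap], adapter[:overlap]))
        if mism <= int(max_mismatch_frac * overlap):
            return pos
    # short exact suffix overlaps (overlap < len(probe))
    for ov in range(min(A, len(probe)) - 1, min_overlap - 1, -1):
        if L >= ov and seq[L - ov:] == adapter[:ov]:
            return L - ov
    # tolerant scan over all starts
    arr = np.frombuffer(seq.encode(), np.uint8)
    ad = np.frombuffer(adapter.encode(), np.uint8)
    best = None
    for start in range(0, L - min_overlap + 1):
        overlap = min(A, L - start)
        mism = int(np.count_nonzero(arr[start:start + overlap] != ad[:overlap]))
        if mism <= int(max_mismatch_frac * overlap):
            best = start
            break
    return best


def trim_adapter(read: SmallRNARead, config: CleaningConfig) -> SmallRNARead:
    pos = find_adapter(read.sequence, config.adapter,
                       config.min_adapter_overlap, config.adapter_mismatch_frac)
    if pos is None:
        return read
    return SmallRNARead(read.id, read.sequence[:pos], read.qualities[:pos])


# ---------------------------------------------------------------------------
# cleaning and collapsing
# ---------------------------------------------------------------------------

def clean_reads(reads: Iterable[SmallRNARead],
                config: CleaningConfig | None = None,
                ) -> tuple[list[SmallRNARead], LibraryStats]:
    """Apply the cleaning contract; returns clean reads (order preserved) and
    library statistics."""
    config = config or CleaningConfig()
    stats = LibraryStats()
    clean: list[SmallRNARead] = []
    for read in reads:
        stats.total_reads += 1
        stats.total_bases += len(read.sequence)
        trimmed = trim_adapter(read, config)
        if not trimmed.sequence or "N" in trimmed.sequence:
            continue
        phred = trimmed.phred
        if config.quality_mode == "mean":
            if phred.mean() < config.min_mean_quality:
                continue
        elif phred.min() < config.min_mean_quality:
            continue
        n = len(trimmed.sequence)
        if not config.min_length <= n <= config.max_length:
            continue
        clean.append(trimmed)
        stats.clean_reads += 1
        stats.clean_bases += n
        stats.min_len = n if stats.min_len is None else min(stats.min_len, n)
        stats.max_len = n if stats.max_len is None else max(stats.max_len, n)
    return clean, stats


@dataclass(frozen=True)
class UniqueTag:
    """A distinct clean-read sequence with per-sample read counts."""

    sequence: str
    counts: dict[str, int] = field(hash=False)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def count(self, sample: str) -> int:
        return self.counts.get(sample, 0)


class TagSet:
    """Collapsed unique tags over one or more samples."""

    def __init__(self, sample_names: Sequence[str], tags: list[UniqueTag],
                 clean_totals: dict[str, int]):
        self.sample_names = list(sample_names)
        self.tags = tags
        self.clean_totals = dict(clean_totals)

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self) -> Iterator[UniqueTag]:
        return iter(self.tags)

    @classmethod
    def from_samples(cls, samples: dict[str, Iterable[str | SmallRNARead]]) -> "TagSet":
        """Collapse per-sample clean reads (sequences or read objects)."""
        counts: dict[str, dict[str, int]] = {}
        totals: dict[str, int] = {}
        for sample, reads in samples.items():
            totals[sample] = 0
            for read in reads:
                seq = read if isinstance(read, str) else read.sequence
                totals[sample] += 1
                per = counts.setdefault(seq, {})
                per[sample] = per.get(sample, 0) + 1
        tags = [UniqueTag(seq, per) for seq, per in sorted(counts.items())]
        return cls(list(samples), tags, totals)

    def unique_counts(self, sample: str) -> int:
        return sum(1 for t in self.tags if t.count(sample) > 0)

    # -- I/O -------------------------------------------------------------
    def write_fasta(self, path: str | Path) -> None:
        """Collapsed-tag FASTA in the ``tag<i>_x<count>`` header dialect."""
        with open(path, "w") as fh:
            for i, tag in enumerate(self.tags):
                fh.write(f">tag{i}_x{tag.total_count}\n{tag.sequence}\n")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            cols = "\t".join(self.sample_names)
            fh.write(f"sequence\tlength\t{cols}\n")
            for tag in self.tags:
                vals = "\t".join(str(tag.count(s)) for s in self.sample_names)
                fh.write(f"{tag.sequence}\t{tag.length}\t{vals}\n")

    @classmethod
    def read_tsv(cls, path: str | Path,
                 clean_totals: dict[str, int] | None = None) -> "TagSet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        samples = [c for c in df.columns if c not in ("sequence", "length")]
        tags = [
            UniqueTag(row.sequence,
                      {s: int(getattr(row, s)) for s in samples if getattr(row, s) > 0})
            for row in df.itertuples(index=False)
        ]
        totals = clean_totals or {
            s: int(df[s].sum()) for s in samples
        }
        return cls(samples, tags, totals)
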