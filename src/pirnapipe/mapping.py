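"""Exact-seed + ungapped-extension placement of unique tags on the genome.

A tag of length L maps at a locus if some ungapped window of at least
ceil(min_coverage * L) consecutive tag bases aligns with at most
floor((1 - min_identity) * window) mismatches.  At 18-44 nt with the default
thresholds (identity >= 0.90, coverage >= 0.95) this admits at most 4
mismatches and at most 2 trimmed bases, so gapped alignment adds nothing.

Seeding is exhaustive over all tag offsets.  By the pigeonhole principle a
seed length of 6 guarantees that every qualifying alignment contains an exact
seed; 12-mer seeding (the default on genomes >= 200 kb) is a faster heuristic
complete for any alignment containing an exact 12-mer run - in particular for
every exact-substring placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomeModel

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_SENTINEL = 4  # spacer/padding code; mismatches everything, breaks seeds
_PAD = 50


def encode(seq: str) -> np.ndarray:
    codes = _ENCODE[np.frombuffer(seq.encode(), np.uint8)]
    if (codes == 255).any():
        raise ValueError(f"sequence contains non-ACGT characters: {seq!r}")
    return codes


@dataclass
class MappingParams:
    min_identity: float = 0.90
    min_coverage: float = 0.95
    seed_k: int | None = None  # None -> 6 below 200 kb genome, else 12
    max_loci: int = 500

    def resolve_k(self, genome_length: int) -> int:
        if self.seed_k is not None:
            return self.seed_k
        return 6 if genome_length < 200_000 else 12


@dataclass(frozen=True)
class MappingLocus:
    tag: str
    chrom: str
    start: int   # 0-based inclusive
    end: int     # 0-based exclusive
    strand: str
    identity: float
    coverage: float

    @property
    def mismatches(self) -> int:
        aligned = self.end - self.start
        return round(aligned * (1.0 - self.identity))


@dataclass
class TagMapping:
    tag: str
    loci: list[MappingLocus]
    n_loci: int           # total placements found (before any truncation)
    truncated: bool = False


class SeedIndex:
    """Sorted k-mer index over the concatenated, sentinel-padded genome."""

    def __init__(self, genome: GenomeModel, k: int):
        self.k = k
        self.chrom_names = sorted(genome.sequences)
        parts = [np.full(_PAD, _SENTINEL, np.uint8)]
        starts, ends = [], []
        pos = _PAD
        for name in self.chrom_names:
            codes = encode(genome.sequences[name])
            starts.append(pos)
            ends.append(pos + len(codes))
            parts.append(codes)
            parts.append(np.full(_PAD, _SENTINEL, np.uint8))
            pos += len(codes) + _PAD
        self.concat = np.concatenate(parts)
        self.chrom_starts = np.array(starts, dtype=np.int64)
        self.chrom_ends = np.array(ends, dtype=np.int64)
        # base-5 rolling codes: any window touching a sentinel contains the
        # digit 4 and can never equal a pure-ACGT tag seed
        kcodes = _rolling_codes(self.concat, k)
        self.order = np.argsort(kcodes, kind="stable").astype(np.int64)
        self.sorted_codes = kcodes[self.order]

    def candidate_positions(self, seed_codes: np.ndarray) -> list[np.ndarray]:
        lo = np.searchsorted(self.sorted_codes, seed_codes, "left")
        hi = np.searchsorted(self.sorted_codes, seed_codes, "right")
        return [self.order[l:h] for l, h in zip(lo, hi)]


def _rolling_codes(codes: np.ndarray, k: int) -> np.ndarray:
    arr = codes.astype(np.int64)
    n = len(arr) - k + 1
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out = out * 5 + arr[j:j + n]
    return out


def _best_windows(index: SeedIndex, offsets: np.ndarray, tcodes: np.ndarray,
                  min_identity: float, min_coverage: float,
                  ) -> list[tuple[int, int, int, int]]:
    """For each candidate diagonal, the best qualifying window.

    Returns (global_start, global_end, mismatches, chrom_index) tuples.
    Preference: longest window, then leftmost trim combination.
    """
    L = len(tcodes)
    max_trim = L - math.ceil(min_coverage * L)
    gathered = index.concat[offsets[:, None] + np.arange(L)]
    neq = gathered != tcodes
    cs = np.zeros((len(offsets), L + 1), dtype=np.int32)
    np.cumsum(neq, axis=1, out=cs[:, 1:])

    unresolved = np.ones(len(offsets), dtype=bool)
    results: list[tuple[int, int, int, int]] = []
    for trim in range(max_trim + 1):
        w = L - trim
        allowed = w - math.ceil(min_identity * w)
        for a in range(trim + 1):
            b = trim - a
            mism = cs[:, L - b] - cs[:, a]
            g0 = offsets + a
            g1 = offsets + (L - b)
            ci = np.searchsorted(index.chrom_ends, g0, "right")
            ci = np.clip(ci, 0, len(index.chrom_ends) - 1)
            inside = (g0 >= index.chrom_starts[ci]) & (g1 <= index.chrom_ends[ci])
            ok = unresolved & (mism <= allowed) & inside
            for i in np.flatnonzero(ok):
                results.append((int(g0[i]), int(g1[i]), int(mism[i]), int(ci[i])))
            unresolved &= ~ok
        if not unresolved.any():
            break
    return results


def map_tag(tag: str, index: SeedIndex, params: MappingParams | None = None,
            ) -> TagMapping:
    """All genomic placements of a tag on both strands under the
    identity/coverage contract, in (chrom, start, strand) order."""
    params = params or MappingParams()
    tcodes = encode(tag)
    L = len(tcodes)
    if L < index.k:
        raise ValueError(f"tag shorter than seed length {index.k}: {tag!r}")
    if L > _PAD - 5:
        raise ValueError(f"tag longer than supported maximum: {tag!r}")

    loci: list[MappingLocus] = []
    for strand, codes in (("+", tcodes), ("-", (3 - tcodes)[::-1])):
        seeds = _rolling_codes(codes, index.k)
        cands = index.candidate_positions(seeds)
        offs = np.concatenate(
            [pos - j for j, pos in enumerate(cands)]) if cands else np.array([], np.int64)
        if offs.size == 0:
            continue
        offs = np.unique(offs)
        for g0, g1, mism, ci in _best_windows(
                index, offs, codes, params.min_identity, params.min_coverage):
            w = g1 - g0
            chrom = index.chrom_names[ci]
            local = g0 - int(index.chrom_starts[ci])
            loci.append(MappingLocus(
                tag=tag, chrom=chrom, start=local, end=local + w,
                strand=strand, identity=(w - mism) / w, coverage=w / L))
    # adjacent diagonals can propose the same trimmed window: deduplicate,
    # keeping the highest identity
    best: dict[tuple[str, int, int, str], MappingLocus] = {}
    for l in loci:
        key = (l.chrom, l.start, l.end, l.strand)
        if key not in best or l.identity > best[key].identity:
            best[key] = l
    loci = sorted(best.values(), key=lambda l: (l.chrom, l.start, l.strand))
    n = len(loci)
    if n > params.max_loci:
        return TagMapping(tag, loci[:params.max_loci], n_loci=n, truncated=True)
    return TagMapping(tag, loci, n_loci=n)


def map_tags(tags: Iterable[str], genome: GenomeModel,
             params: MappingParams | None = None,
             index: SeedIndex | None = None) -> dict[str, TagMapping]:
    params = params or MappingParams()
    if index is None:
        index = SeedIndex(genome, params.resolve_k(genome.total_length))
    return {tag: map_tag(tag, index, params) for tag in tags}


# ---------------------------------------------------------------------------
# interoperability output
# ---------------------------------------------------------------------------

def write_loci_bed(mappings: Iterable[TagMapping], path: str | Path) -> None:
    """BED6 with the tag in column 4 and identity*1000 in the score column."""
    rows = [l for m in mappings for l in m.loci]
    rows.sort(key=lambda l: (l.chrom, l.start, l.strand))
    with open(path, "w") as fh:
        for l in rows:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.tag}\t"
                     f"{int(round(l.identity * 1000))}\t{l.strand}\n")


def write_eland(mappings: Iterable[TagMapping], path: str | Path) -> None:
    """ELAND3-like TSV: tag, chrom, 0-based position, strand, mismatches."""
    with open(path, "w") as fh:
        fh.write("tag\tchrom\tpos\tstrand\tmismatches\n")
        for m in mappings:
            for l in m.loci:
                fh.write(f"{l.tag}\t{l.chrom}\t{l.start}\t{l.strand}\t{l.mismatches}\n")


def read_eland(path: str | Path) -> dict[str, TagMapping]:
    """Read ELAND3-like records back into minimal TagMapping objects."""
    per_tag: dict[str, list[MappingLocus]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["tag", "chrom"]:
            raise ValueError(f"unrecognized alignment header in {path}")
        for line in fh:
            tag, chrom, pos, strand, mism = line.rstrip("\n").split("\t")
            start = int(pos)
            w = len(tag)
            per_tag.setdefault(tag, []).append(MappingLocus(
                tag=tag, chrom=chrom, start=start, end=start + w,
                strand=strand, identity=(w - int(mism)) / w, coverage=1.0))
    return {tag: TagMapping(tag, loci, n_loci=len(loci))
            for tag, loci in per_tag.items()}
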