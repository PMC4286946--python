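"""Probabilistic piRNA cluster prediction from mapped tag loci.

A sliding window is candidate-significant when the upper-tail Poisson
probability of its locus count, under a genome-wide uniform background rate,
is at most ``density_alpha``.  Overlapping significant windows are merged and
trimmed to their outermost loci.  A merged cluster is accepted only if ALL
composition criteria hold simultaneously: at least ``min_loci`` distinct
loci, density p <= alpha, main/minor strand-bias score >= 1.3, and at least
75% of (weighted) loci both in the typical piRNA length range (26-32 nt) and
showing the ping-pong 1U/10A signature (T at position 1 or A at position 10
of the tag).

Loci are weighted 1/(tag's total loci) by default, so clusters supported by
infrequently-mapped tags count fully while high-multimapping tags are
discounted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import ANNOTATION_CATEGORIES, AnnotationRecord
from .mapping import MappingLocus, TagMapping


@dataclass
class ClusterParams:
    min_loci: int = 6
    density_alpha: float = 0.05
    min_strand_bias_score: float = 1.3
    pirna_length_range: tuple[int, int] = (26, 32)
    min_length_fraction: float = 0.75
    min_1u10a_fraction: float = 0.75
    window: int = 5_000
    locus_weighting: str = "one_over_nloci"  # or "uniform"

    def __post_init__(self) -> None:
        if not 0 < self.density_alpha < 1:
            raise ValueError("density_alpha must be in (0, 1)")
        if self.min_loci < 2:
            raise ValueError("min_loci must be at least 2")
        for name in ("min_length_fraction", "min_1u10a_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.locus_weighting not in ("uniform", "one_over_nloci"):
            raise ValueError(f"unknown locus_weighting {self.locus_weighting!r}")


@dataclass
class PiRNACluster:
    cluster_id: str
    chrom: str
    start: int  # 0-based half-open, trimmed to outermost loci
    end: int
    n_loci: int
    n_tags: int
    main_strand: str
    strand_bias_score: float
    frac_1u10a: float
    frac_typical_length: float
    density_p: float
    accepted: bool


@dataclass(frozen=True)
class PiRNACall:
    tag: str
    clusters: tuple[str, ...]
    origin_category: str


def one_u_ten_a(sequence: str) -> bool:
    """Ping-pong signature: T at position 1 or A at position 10 (1-based,
    on the tag as sequenced)."""
    if len(sequence) < 10:
        warnings.warn(f"sequence shorter than 10 nt: {sequence!r}", stacklevel=2)
        return False
    return sequence[0] == "T" or sequence[9] == "A"


def strand_bias_score(plus_weight: float, minus_weight: float) -> float:
    """Main-strand over minor-strand weighted locus count, minor floored at 1
    so an all-one-strand cluster scores its own (weighted) size."""
    main, minor = max(plus_weight, minus_weight), min(plus_weight, minus_weight)
    return main / max(minor, 1.0)


def _loci_frame(mappings: Mapping[str, TagMapping],
                weighting: str,
                restrict_tags: set[str] | None = None) -> pd.DataFrame:
    rows = []
    for tag, m in mappings.items():
        if restrict_tags is not None and tag not in restrict_tags:
            continue
        w = 1.0 / m.n_loci if (weighting == "one_over_nloci" and m.n_loci) else 1.0
        sig = one_u_ten_a(tag) if len(tag) >= 10 else False
        for l in m.loci:
            rows.append((tag, l.chrom, l.start, l.end, l.strand, w, sig, len(tag)))
    return pd.DataFrame(rows, columns=[
        "tag", "chrom", "start", "end", "strand", "weight", "sig_1u10a", "length"])


def scan_clusters(mappings: Mapping[str, TagMapping],
                  chrom_lengths: Mapping[str, int],
                  params: ClusterParams | None = None,
                  restrict_tags: Iterable[str] | None = None,
                  ) -> list[PiRNACluster]:
    """Slide half-overlapping windows, merge significant ones, trim to
    outermost loci, and score every merged candidate.

    ``restrict_tags`` limits the scan to tags present in one sample.
    Output is independent of input order (loci are sorted internally).
    """
    params = params or ClusterParams()
    total_len = sum(chrom_lengths.values())
    if total_len <= 0:
        raise ValueError("genome length must be positive")
    loci = _loci_frame(mappings, params.locus_weighting,
                       set(restrict_tags) if restrict_tags is not None else None)
    if loci.empty:
        return []
    lam = len(loci) / total_len  # genome-wide uniform background rate
    mu = lam * params.window
    # smallest locus count that is window-significant at alpha
    min_count = int(stats.poisson.isf(params.density_alpha, mu)) + 1

    clusters: list[PiRNACluster] = []
    cluster_no = 0
    step = max(params.window // 2, 1)
    for chrom in sorted(chrom_lengths):
        sub = loci[loci.chrom == chrom].sort_values(["start", "end", "strand"])
        if sub.empty:
            continue
        starts = sub.start.to_numpy()
        n_windows = max((chrom_lengths[chrom] - 1) // step, 0) + 1
        w_starts = np.arange(n_windows) * step
        counts = (np.searchsorted(starts, w_starts + params.window, "left")
                  - np.searchsorted(starts, w_starts, "left"))
        sig = counts >= min_count
        # merge overlapping/adjacent significant windows
        intervals: list[list[int]] = []
        for ws in w_starts[sig]:
            we = ws + params.window
            if intervals and ws <= intervals[-1][1]:
                intervals[-1][1] = max(intervals[-1][1], we)
            else:
                intervals.append([int(ws), int(we)])
        for ws, we in intervals:
            lo = np.searchsorted(starts, ws, "left")
            hi = np.searchsorted(starts, we, "left")
            members = sub.iloc[lo:hi]
            if members.empty:
                continue
            cluster = _score_cluster(members, f"cluster_{cluster_no}", chrom,
                                     mu, params)
            clusters.append(cluster)
            cluster_no += 1
    return clusters


def _score_cluster(members: pd.DataFrame, cluster_id: str, chrom: str,
                   mu: float, params: ClusterParams) -> PiRNACluster:
    n_loci = len(members)
    w = members.weight.to_numpy()
    plus_w = float(w[(members.strand == "+").to_numpy()].sum())
    minus_w = float(w[(members.strand == "-").to_numpy()].sum())
    wsum = float(w.sum()) or 1.0
    lo_len, hi_len = params.pirna_length_range
    typical = ((members.length >= lo_len) & (members.length <= hi_len)).to_numpy()
    frac_typical = float(w[typical].sum()) / wsum
    frac_sig = float(w[members.sig_1u10a.to_numpy()].sum()) / wsum
    score = strand_bias_score(plus_w, minus_w)
    density_p = float(stats.poisson.sf(n_loci - 1, mu))
    accepted = (n_loci >= params.min_loci
                and density_p <= params.density_alpha
                and score >= params.min_strand_bias_score
                and frac_sig >= params.min_1u10a_fraction
                and frac_typical >= params.min_length_fraction)
    return PiRNACluster(
        cluster_id=cluster_id, chrom=chrom,
        start=int(members.start.min()), end=int(members.end.max()),
        n_loci=n_loci, n_tags=members.tag.nunique(),
        main_strand="+" if plus_w >= minus_w else "-",
        strand_bias_score=score, frac_1u10a=frac_sig,
        frac_typical_length=frac_typical, density_p=density_p,
        accepted=accepted)


def call_pirnas(clusters: Sequence[PiRNACluster],
                mappings: Mapping[str, TagMapping],
                annotations: Mapping[str, AnnotationRecord],
                restrict_tags: Iterable[str] | None = None,
                ) -> tuple[list[PiRNACall], pd.DataFrame]:
    """Tags with at least one locus inside an accepted cluster, plus their
    origin-category distribution (each tag counted once)."""
    accepted = [c for c in clusters if c.accepted]
    by_chrom: dict[str, list[PiRNACluster]] = {}
    for c in accepted:
        by_chrom.setdefault(c.chrom, []).append(c)
    restrict = set(restrict_tags) if restrict_tags is not None else None

    calls: list[PiRNACall] = []
    origin_counts = {c: 0 for c in ANNOTATION_CATEGORIES}
    for tag, m in mappings.items():
        if restrict is not None and tag not in restrict:
            continue
        hits = []
        for l in m.loci:
            for c in by_chrom.get(l.chrom, []):
                if l.start < c.end and c.start < l.end:
                    hits.append(c.cluster_id)
        if hits:
            rec = annotations.get(tag)
            category = rec.category if rec else "unannotated"
            calls.append(PiRNACall(tag, tuple(sorted(set(hits))), category))
            origin_counts[category] += 1
    origin = pd.DataFrame({
        "category": ANNOTATION_CATEGORIES,
        "n_pirnas": [origin_counts[c] for c in ANNOTATION_CATEGORIES]})
    return calls, origin


def write_clusters_bed(clusters: Sequence[PiRNACluster], path: str | Path) -> None:
    """BED6+ with extra columns: n_loci, density_p, strand_bias_score,
    frac_1u10a, frac_typical_length, accepted."""
    with open(path, "w") as fh:
        for c in sorted(clusters, key=lambda c: (c.chrom, c.start)):
            fh.write("\t".join(map(str, [
                c.chrom, c.start, c.end, c.cluster_id, 0, c.main_strand,
                c.n_loci, f"{c.density_p:.3g}", f"{c.strand_bias_score:.3f}",
                f"{c.frac_1u10a:.3f}", f"{c.frac_typical_length:.3f}",
                int(c.accepted)])) + "\n")
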