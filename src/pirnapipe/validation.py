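"""Slow reference implementations used as independent oracles in validation.

These re-derive the mapping, annotation and cluster contracts by direct
enumeration, sharing no code with the production paths (no seed index, no
interval trees, no vectorized scan bookkeeping).  They are quadratic-ish and
meant for small genomes only.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .clusters import ClusterParams, PiRNACluster, one_u_ten_a
from .genome import CATEGORY_PRIORITY, NON_ANNOTATING, GenomeModel, revcomp
from .mapping import TagMapping


def brute_force_map(tag: str, genome: GenomeModel,
                    min_identity: float = 0.90, min_coverage: float = 0.95,
                    ) -> dict[tuple[str, int, int, str], float]:
    """All qualifying placements of a tag by scanning every offset of every
    chromosome on both strands; returns {(chrom, start, end, strand): identity}.

    Per diagonal the longest qualifying window wins (leftmost trim on ties),
    matching the mapping contract's reporting rule.
    """
    L = len(tag)
    max_trim = L - math.ceil(min_coverage * L)
    results: dict[tuple[str, int, int, str], float] = {}
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        n = len(seq)
        arr = np.full(n + 2 * max_trim, 255, np.uint8)  # 255 never matches
        arr[max_trim:max_trim + n] = np.frombuffer(seq.encode(), np.uint8)
        if len(arr) < L:
            continue
        # trim combinations in preference order: longest window first, then
        # leftmost trim
        combos = [(a, t - a) for t in range(max_trim + 1) for a in range(t + 1)]
        for strand in "+-":
            q = tag if strand == "+" else revcomp(tag)
            qa = np.frombuffer(q.encode(), np.uint8)
            neq = sliding_window_view(arr, L) != qa
            cs = np.zeros((neq.shape[0], L + 1), np.int32)
            np.cumsum(neq, axis=1, out=cs[:, 1:])
            mism_by_combo = np.stack(
                [cs[:, L - b] - cs[:, a] for a, b in combos], axis=1)
            allowed = np.array([
                (L - a - b) - math.ceil(min_identity * (L - a - b))
                for a, b in combos])
            offs = np.arange(neq.shape[0]) - max_trim
            a_arr = np.array([a for a, _ in combos])
            b_arr = np.array([b for _, b in combos])
            in_bounds = ((offs[:, None] + a_arr >= 0)
                         & (offs[:, None] + L - b_arr <= n))
            valid = (mism_by_combo <= allowed) & in_bounds
            first = np.argmax(valid, axis=1)
            for off in np.flatnonzero(valid.any(axis=1)):
                a, b = combos[first[off]]
                w = L - a - b
                start = off - max_trim + a
                end = off - max_trim + L - b
                identity = (w - int(mism_by_combo[off, first[off]])) / w
                key = (chrom, start, end, strand)
                if key not in results or identity > results[key]:
                    results[key] = identity
    return results


def annotation_oracle(mapping: TagMapping, genome: GenomeModel,
                      min_overlap_frac: float = 0.5) -> str:
    """Category of a mapped tag by enumerating every (locus, feature) pair."""
    pairs = []
    for locus in mapping.loci:
        for f in genome.features:
            if f.category in NON_ANNOTATING or f.chrom != locus.chrom:
                continue
            overlap = min(f.end, locus.end) - max(f.start, locus.start)
            if overlap > 0 and overlap >= min_overlap_frac * (locus.end - locus.start):
                pairs.append((locus, f))
    if not pairs:
        return "unannotated"
    best = min(CATEGORY_PRIORITY.index(f.category) for _, f in pairs)
    category = CATEGORY_PRIORITY[best]
    if category in ("exon", "intron"):
        top = [(l, f) for l, f in pairs if f.category == category]
        sense = any(l.strand == f.strand for l, f in top)
        category += "_sense" if sense else "_antisense"
    return category


def cluster_scan_oracle(mappings: Mapping[str, TagMapping],
                        chrom_lengths: Mapping[str, int],
                        params: ClusterParams | None = None,
                        ) -> list[tuple[str, int, int, bool]]:
    """Window enumeration + direct Poisson tail evaluation + plain-python
    scoring; returns (chrom, start, end, accepted) per merged candidate."""
    params = params or ClusterParams()
    loci = []
    for tag, m in mappings.items():
        w = 1.0 / m.n_loci if (params.locus_weighting == "one_over_nloci"
                               and m.n_loci) else 1.0
        for l in m.loci:
            loci.append((l.chrom, l.start, l.end, l.strand, w, tag))
    if not loci:
        return []
    lam = len(loci) / sum(chrom_lengths.values())
    mu = lam * params.window
    step = max(params.window // 2, 1)
    out = []
    for chrom in sorted(chrom_lengths):
        sub = sorted([l for l in loci if l[0] == chrom], key=lambda l: (l[1], l[2]))
        sig_windows = []
        ws = 0
        while ws < chrom_lengths[chrom]:
            count = sum(1 for l in sub if ws <= l[1] < ws + params.window)
            if count and float(stats.poisson.sf(count - 1, mu)) <= params.density_alpha:
                sig_windows.append((ws, ws + params.window))
            ws += step
        merged: list[list[int]] = []
        for s, e in sig_windows:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            members = [l for l in sub if s <= l[1] < e]
            if not members:
                continue
            n = len(members)
            wsum = sum(m[4] for m in members)
            plus = sum(m[4] for m in members if m[3] == "+")
            minus = wsum - plus
            main, minor = max(plus, minus), min(plus, minus)
            score = main / max(minor, 1.0)
            lo, hi = params.pirna_length_range
            f_typ = sum(m[4] for m in members
                        if lo <= (m[2] - m[1]) <= hi) / (wsum or 1.0)
            f_sig = sum(m[4] for m in members
                        if len(m[5]) >= 10 and one_u_ten_a(m[5])) / (wsum or 1.0)
            p = float(stats.poisson.sf(n - 1, mu))
            accepted = (n >= params.min_loci and p <= params.density_alpha
                        and score >= params.min_strand_bias_score
                        and f_sig >= params.min_1u10a_fraction
                        and f_typ >= params.min_length_fraction)
            out.append((chrom, min(m[1] for m in members),
                        max(m[2] for m in members), accepted))
    return out


def cluster_recovery(accepted: Sequence[PiRNACluster],
                     truth_clusters, min_cover: float = 0.5,
                     ) -> tuple[int, int, int]:
    """(recovered, planted, false_positives): a planted cluster is recovered
    when an accepted cluster covers >= ``min_cover`` of its interval; an
    accepted cluster overlapping no planted interval is a false positive."""
    planted = [(r.chrom, int(r.start), int(r.end))
               for r in truth_clusters.itertuples(index=False)]
    recovered = 0
    for chrom, ps, pe in planted:
        cover = max((min(c.end, pe) - max(c.start, ps)
                     for c in accepted if c.chrom == chrom), default=0)
        if cover >= min_cover * (pe - ps):
            recovered += 1
    false = sum(
        1 for c in accepted
        if not any(c.chrom == chrom and min(c.end, pe) > max(c.start, ps)
                   for chrom, ps, pe in planted))
    return recovered, len(planted), false
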