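"""Genomic interval sets: annotation derivation and the uncovered-region census.

All coordinates are BED-style 0-based half-open.  A base counts as "not
covered" when fewer than ``min_reads`` (default 3) filtered reads support
it: three reads are the minimum to call a heterozygous variant — two
carrying the non-reference base and one the reference.  N runs terminate
uncovered regions rather than bridging them, and excluded contigs never
contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .depth_core import DepthTracks
from .genome_sim import GenomeModel


@dataclass
class RegionSet:
    """A named list of (contig, start, end) intervals."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for contig, s, e in self.intervals:
            if s >= e:
                raise ValueError(f"empty/inverted interval [{s},{e}) on {contig}")
            if s < 0:
                raise ValueError("interval start must be >= 0")

    def __len__(self) -> int:
        return len(self.intervals)

    def total_bases(self) -> int:
        """Base count of the merged footprint (overlaps counted once)."""
        return sum(e - s for _, s, e in merge_intervals(self).intervals)

    def sorted(self) -> "RegionSet":
        return RegionSet(self.name, sorted(self.intervals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["contig", "start", "end"])


def uncovered_regions(
    tracks: DepthTracks,
    genome: GenomeModel,
    min_reads: int = 3,
) -> RegionSet:
    """Maximal runs of informative bases with depth < min_reads.

    min_reads=1 gives the strict zero-coverage variant.  N bases split runs
    and never appear inside a region; excluded contigs are skipped.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    intervals: list[tuple[str, int, int]] = []
    for contig in genome.analysis_contigs():
        mask = genome.informative_mask(contig) & (tracks[contig] < min_reads)
        edges = np.diff(mask.astype(np.int8), prepend=0, append=0)
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        intervals.extend((contig, int(s), int(e)) for s, e in zip(starts, ends))
    return RegionSet(f"uncovered_lt{min_reads}", intervals)


def size_distribution(regions: RegionSet, bin_edges: list[float]) -> pd.DataFrame:
    """Counts of regions per length bin [e_i, e_{i+1}), final bin open-ended."""
    edges = list(bin_edges)
    if len(edges) < 1 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing")
    if not np.isinf(edges[-1]):
        edges = edges + [np.inf]
    lengths = np.array([e - s for _, s, e in regions.intervals], dtype=float)
    counts, _ = np.histogram(lengths, bins=edges)
    labels = [
        f"[{int(a)},{int(b)})" if np.isfinite(b) else f"[{int(a)},inf)"
        for a, b in zip(edges, edges[1:])
    ]
    return pd.DataFrame({"size_bin": labels, "count": counts})


def derive_shores(cpg_islands: RegionSet, genome: GenomeModel, flank: int = 2000) -> RegionSet:
    """Shores: the ``flank`` bp immediately up- and downstream of each island.

    Island bases are excluded by construction; shores of different islands
    may overlap each other or other islands — merging is left explicit.
    Flanks are clipped to contig bounds.
    """
    shores: list[tuple[str, int, int]] = []
    for contig, s, e in cpg_islands.intervals:
        L = genome.contig_length(contig)
        up_s, up_e = max(0, s - flank), s
        dn_s, dn_e = e, min(L, e + flank)
        if up_s < up_e:
            shores.append((contig, up_s, up_e))
        if dn_s < dn_e:
            shores.append((contig, dn_s, dn_e))
    return RegionSet("cpg_shores", shores)


def derive_promoters(
    tss_list: list[tuple[str, int, str]],
    genome: GenomeModel,
    up: int = 2000,
    down: int = 500,
) -> RegionSet:
    """Promoters: ``up`` bp upstream and ``down`` bp downstream of each TSS.

    Upstream follows the strand: [tss-up, tss+down) on +, [tss-down, tss+up)
    on -, clipped to contig bounds.
    """
    promoters: list[tuple[str, int, int]] = []
    for contig, tss, strand in tss_list:
        L = genome.contig_length(contig)
        if strand == "+":
            s, e = tss - up, tss + down
        elif strand == "-":
            s, e = tss - down, tss + up
        else:
            raise ValueError(f"unknown strand {strand!r}")
        s, e = max(0, s), min(L, e)
        if s < e:
            promoters.append((contig, s, e))
    return RegionSet("promoters", promoters)


def derive_introns(transcripts: list[tuple[tuple[str, int, int], RegionSet]]) -> RegionSet:
    """Introns: per transcript, gaps between consecutive exons.

    The complement of the exons within [first exon start, last exon end);
    zero-length gaps (abutting exons) are omitted.  Overlapping exons within
    one transcript are an error.
    """
    introns: list[tuple[str, int, int]] = []
    for _, exons in transcripts:
        ivs = sorted(exons.intervals)
        for (c1, _, e1), (c2, s2, _) in zip(ivs, ivs[1:]):
            if c1 != c2:
                raise ValueError("exons of one transcript must share a contig")
            if s2 < e1:
                raise ValueError("overlapping exons within one transcript")
            if s2 > e1:
                introns.append((c1, e1, s2))
    return RegionSet("introns", introns)


def merge_intervals(regions: RegionSet) -> RegionSet:
    """Minimal sorted disjoint interval set with the same base footprint."""
    merged: list[tuple[str, int, int]] = []
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, s, e in regions.intervals:
        by_contig.setdefault(contig, []).append((s, e))
    for contig in sorted(by_contig):
        cur_s = cur_e = None
        for s, e in sorted(by_contig[contig]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((contig, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((contig, cur_s, cur_e))
    return RegionSet(regions.name, merged)


def overlap_bases(a: RegionSet, b: RegionSet) -> int:
    """Base count of the intersection of the merged footprints."""
    am = merge_intervals(a).intervals
    bm = merge_intervals(b).intervals
    by_contig: dict[str, tuple[list, list]] = {}
    for contig, s, e in am:
        by_contig.setdefault(contig, ([], []))[0].append((s, e))
    for contig, s, e in bm:
        by_contig.setdefault(contig, ([], []))[1].append((s, e))
    total = 0
    for xs, ys in by_contig.values():
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i][0], ys[j][0])
            e = min(xs[i][1], ys[j][1])
            if s < e:
                total += e - s
            if xs[i][1] < ys[j][1]:
                i += 1
            else:
                j += 1
    return total


def fraction_uncovered(uncovered: RegionSet, element: RegionSet) -> float:
    """Fraction of an element's merged bases that fall in uncovered regions."""
    denom = element.total_bases()
    if denom == 0:
        raise ValueError("element set has zero bases")
    return overlap_bases(uncovered, element) / denom


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    informative: bool


def compare_fractions_ttest(fractions_a, fractions_b) -> TTestResult:
    """Two-sided equal-variance two-sample t-test on per-sample fractions.

    Groups of fewer than two samples are refused.  When both groups have zero
    variance and equal means the test carries no information and is flagged
    as such (statistic 0, p 1).
    """
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return TTestResult(0.0, 1.0, informative=False)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), float(p), informative=True)
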