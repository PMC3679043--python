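"""Per-base depth tracks, coverage summaries, downsampling and merging.

Depth is counted pileup-style: every filtered read contributes one unit to
each base its interval covers, so overlapping mates of one pair count twice
at overlapped bases.  All summaries (mean coverage, histograms, cumulative
curves) run over informative bases of non-excluded contigs only; N bases and
excluded contigs keep their raw counts in the tracks but are masked out of
every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_sim import GenomeModel, ReadSet

DepthTracks = dict[str, np.ndarray]


@dataclass
class CoverageHistogram:
    """Counts of informative bases per depth value."""

    counts: dict[int, int]
    total_informative_bases: int

    def __post_init__(self) -> None:
        if any(d < 0 or c < 0 for d, c in self.counts.items()):
            raise ValueError("histogram keys and counts must be non-negative")
        if sum(self.counts.values()) != self.total_informative_bases:
            raise ValueError("histogram counts must sum to total_informative_bases")


def filter_reads(reads: ReadSet) -> ReadSet:
    """Keep uniquely mapping, non-duplicate reads; order preserved."""
    df = reads.df
    keep = df["is_unique"].to_numpy() & ~df["is_duplicate"].to_numpy()
    return ReadSet(df.loc[keep].reset_index(drop=True))


def compute_depth(reads: ReadSet, genome: GenomeModel) -> DepthTracks:
    """Per-base read depth for every contig, via interval difference arrays."""
    reads.validate_against(genome)
    tracks: DepthTracks = {
        name: np.zeros(genome.contig_length(name), dtype=np.int32) for name in genome.contigs
    }
    for contig, sub in reads.df.groupby("contig", sort=False):
        L = genome.contig_length(contig)
        diff = np.zeros(L + 1, dtype=np.int64)
        np.add.at(diff, sub["start"].to_numpy(), 1)
        np.add.at(diff, sub["end"].to_numpy(), -1)
        tracks[contig] = np.cumsum(diff[:-1]).astype(np.int32)
    return tracks


def _informative_depths(tracks: DepthTracks, genome: GenomeModel) -> np.ndarray:
    parts = []
    for contig in genome.analysis_contigs():
        if contig not in tracks:
            raise ValueError(f"no depth track for contig {contig!r}")
        parts.append(tracks[contig][genome.informative_mask(contig)])
    return np.concatenate(parts) if parts else np.zeros(0, dtype=np.int32)


def mean_coverage(tracks: DepthTracks, genome: GenomeModel) -> float:
    """Mean depth over informative bases of non-excluded contigs."""
    depths = _informative_depths(tracks, genome)
    if depths.size == 0:
        raise ValueError("genome has zero informative bases on analysis contigs")
    return float(depths.mean())


def downsample(
    reads: ReadSet,
    current_mean: float,
    target_mean: float,
    seed: int = 0,
    exact: bool = False,
) -> ReadSet:
    """Randomly thin read pairs/singletons to a target mean coverage.

    Each pair (mates share a pair_id) and each singleton is retained
    independently with probability target_mean / current_mean; mates are kept
    or dropped together.  ``exact=True`` instead retains exactly
    round(ratio * n_units) units, for reproducibility studies.
    """
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")
    if target_mean > current_mean:
        raise ValueError("target_mean may not exceed current_mean")
    ratio = target_mean / current_mean
    if ratio == 1.0:
        return ReadSet(reads.df.copy())

    df = reads.df
    pair_ids = df["pair_id"]
    # sampling unit: pair_id where present, else the row itself
    unit = np.where(pair_ids.isna(), -1 - np.arange(len(df)), pair_ids.fillna(0).to_numpy())
    units, inverse = np.unique(unit, return_inverse=True)
    rng = np.random.default_rng(seed)
    if exact:
        n_keep = int(round(ratio * len(units)))
        kept_units = np.zeros(len(units), dtype=bool)
        kept_units[rng.choice(len(units), size=n_keep, replace=False)] = True
    else:
        kept_units = rng.random(len(units)) < ratio
    keep = kept_units[inverse]
    return ReadSet(df.loc[keep].reset_index(drop=True))


def merge_readsets(readsets: list[ReadSet], genome: GenomeModel | None = None) -> ReadSet:
    """Multiset union of read sets from one genome; platform tags preserved.

    pair_ids are re-keyed per source so pairs from different platforms never
    collide.  When ``genome`` is given, every set is validated against it and
    a read on a foreign contig raises.
    """
    if not readsets:
        raise ValueError("need at least one ReadSet")
    parts = []
    offset = 0
    for rs in readsets:
        if genome is not None:
            rs.validate_against(genome)
        df = rs.df.copy()
        if len(df):
            df["pair_id"] = df["pair_id"] + offset
            mx = df["pair_id"].max()
            offset = int(mx) + 1 if pd.notna(mx) else offset
        parts.append(df)
    merged = pd.concat(parts, ignore_index=True)
    merged = merged.sort_values(["contig", "start", "end"], kind="stable").reset_index(drop=True)
    return ReadSet(merged)


def depth_histogram(tracks: DepthTracks, genome: GenomeModel) -> CoverageHistogram:
    """Histogram of depth over informative bases of analysis contigs."""
    depths = _informative_depths(tracks, genome)
    if depths.size == 0:
        return CoverageHistogram({}, 0)
    counts = np.bincount(depths)
    return CoverageHistogram(
        {int(d): int(c) for d, c in enumerate(counts) if c > 0}, int(depths.size)
    )


def cumulative_coverage(hist: CoverageHistogram) -> pd.DataFrame:
    """Fraction of informative bases with depth >= d, for d = 0 .. max depth."""
    if hist.total_informative_bases == 0:
        raise ValueError("empty histogram")
    max_d = max(hist.counts) if hist.counts else 0
    counts = np.zeros(max_d + 1, dtype=np.int64)
    for d, c in hist.counts.items():
        counts[d] = c
    ge = counts[::-1].cumsum()[::-1] / hist.total_informative_bases
    return pd.DataFrame({"depth": np.arange(max_d + 1), "fraction_ge": ge})


def bases_below(hist: CoverageHistogram, k: int) -> int:
    """Number of informative bases covered by fewer than k reads."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return sum(c for d, c in hist.counts.items() if d < k)
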