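"""Synthetic genomes, annotations, truth genotypes and platform-profiled reads.

The study design this package evaluates needs a genome with a wide,
block-structured GC spectrum, annotation tracks planted at known coordinates,
a gold-standard genotype set, and read sets whose depth carries the
platform-specific statistical structure the downstream metrics are meant to
detect: a fragment-GC sampling response, per-locus overdispersion,
mappability dropout in repeats, and duplicate reads.  Everything here is a
pure function of its arguments and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype="S1")
READ_COLUMNS = ["contig", "start", "end", "pair_id", "mate", "is_duplicate", "is_unique", "platform"]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GenomeModel:
    """A small multi-contig genome over {A,C,G,T,N}.

    ``contigs`` maps name -> numpy byte array (dtype S1).  ``informative_mask``
    is True where the base is defined (not N).  Contigs listed in
    ``excluded_contigs`` are carried along but masked out of every summary,
    the way a sex chromosome is dropped from an autosomal analysis.
    ``planted_blocks`` records the (start, end, target_gc) composition blocks
    the generator used, so annotation rules can address them by GC class.
    """

    contigs: dict[str, np.ndarray]
    excluded_contigs: set[str] = field(default_factory=set)
    planted_blocks: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = self.excluded_contigs - set(self.contigs)
        if unknown:
            raise ValueError(f"excluded contigs not in genome: {sorted(unknown)}")
        if self.informative_length() == 0:
            raise ValueError("genome has no informative (non-N) bases")

    @property
    def contig_names(self) -> list[str]:
        return list(self.contigs)

    def contig_length(self, name: str) -> int:
        return len(self.contigs[name])

    def informative_mask(self, name: str) -> np.ndarray:
        return self.contigs[name] != b"N"

    def analysis_contigs(self) -> list[str]:
        """Contigs that enter summaries (not excluded)."""
        return [c for c in self.contigs if c not in self.excluded_contigs]

    def informative_length(self) -> int:
        return int(sum(self.informative_mask(c).sum() for c in self.analysis_contigs()))

    def gc_mask(self, name: str) -> np.ndarray:
        seq = self.contigs[name]
        return (seq == b"G") | (seq == b"C")


@dataclass(frozen=True)
class PlatformProfile:
    """Sampling behaviour of one sequencing platform.

    ``gc_response`` is a piecewise-linear non-negative weight function w(g) on
    GC fraction g in [0, 1], given as (gc_knots, weights); a fragment whose GC
    fraction is g is sampled proportionally to w(g).  ``dispersion`` is the
    overdispersion of per-locus fragment counts: counts are negative-binomial
    with variance mu * (1 + dispersion * mu), collapsing to Poisson at 0.
    ``repeat_mappability`` is the probability that a read starting inside a
    low-mappability region keeps a unique alignment.
    """

    name: str
    gc_knots: tuple[float, ...]
    gc_weights: tuple[float, ...]
    fragment_length_mean: float
    fragment_length_sd: float
    read_length: int
    duplicate_rate: float = 0.0
    dispersion: float = 0.0
    repeat_mappability: float = 1.0

    def __post_init__(self) -> None:
        if len(self.gc_knots) != len(self.gc_weights) or len(self.gc_knots) < 2:
            raise ValueError("gc_response needs >= 2 (knot, weight) pairs")
        if any(w < 0 for w in self.gc_weights):
            raise ValueError("gc_response weights must be non-negative")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValueError("duplicate_rate must be in [0, 1]")
        if not 0.0 <= self.repeat_mappability <= 1.0:
            raise ValueError("repeat_mappability must be in [0, 1]")
        if self.fragment_length_mean <= self.read_length:
            raise ValueError("fragment_length_mean must exceed read_length")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def gc_response(self, gc: np.ndarray) -> np.ndarray:
        """Evaluate w(g) by linear interpolation between knots."""
        return np.interp(gc, self.gc_knots, self.gc_weights)


def new_read_frame(n: int = 0) -> pd.DataFrame:
    """Empty/preallocated ReadSet frame with the canonical columns."""
    return pd.DataFrame(
        {
            "contig": pd.Series([""] * n, dtype=object),
            "start": np.zeros(n, dtype=np.int64),
            "end": np.zeros(n, dtype=np.int64),
            "pair_id": pd.array([pd.NA] * n, dtype="Int64"),
            "mate": np.zeros(n, dtype=np.int64),
            "is_duplicate": np.zeros(n, dtype=bool),
            "is_unique": np.ones(n, dtype=bool),
            "platform": pd.Series([""] * n, dtype=object),
        }
    )


@dataclass
class ReadSet:
    """Aligned read placements: paired/singleton intervals with flags.

    Backed by a DataFrame with columns contig, start, end (0-based half-open),
    pair_id (nullable int; shared by mates), mate (0/1), is_duplicate,
    is_unique, platform (source tag, preserved through merging).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in READ_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"ReadSet frame missing columns: {missing}")
        if len(self.df) and not (self.df["start"] < self.df["end"]).all():
            raise ValueError("every read must satisfy start < end")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records, platform: str = "") -> "ReadSet":
        """Build from (contig, start, end, pair_id, mate, dup, unique) tuples."""
        if not records:
            return cls(new_read_frame(0))
        df = pd.DataFrame(records, columns=READ_COLUMNS[:7])
        df["pair_id"] = df["pair_id"].astype("Int64")
        df["platform"] = platform
        return cls(df)

    def validate_against(self, genome: GenomeModel) -> None:
        for contig, sub in self.df.groupby("contig", sort=False):
            if contig not in genome.contigs:
                raise ValueError(f"read on unknown contig {contig!r}")
            if len(sub) and int(sub["end"].max()) > genome.contig_length(contig):
                raise ValueError(f"read beyond end of contig {contig!r}")


@dataclass
class TruthGenotypes:
    """Gold-standard diploid genotypes at known positions.

    A DataFrame of contig, pos (0-based), ref, a1, a2.  Zygosity is derived:
    hom-ref (a1 == a2 == ref), het (a1 != a2), hom-alt (a1 == a2 != ref).
    Stands in for an external array-genotyped truth set.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["contig", "pos", "ref", "a1", "a2"]
        missing = [c for c in req if c not in self.df.columns]
        if missing:
            raise ValueError(f"TruthGenotypes frame missing columns: {missing}")
        if len(self.df) and self.df.duplicated(["contig", "pos"]).any():
            raise ValueError("truth positions must be unique per contig")
        for col in ("ref", "a1", "a2"):
            if len(self.df) and not self.df[col].isin(list("ACGT")).all():
                raise ValueError(f"alleles in column {col} must be in A/C/G/T")

    def __len__(self) -> int:
        return len(self.df)

    def zygosity(self) -> pd.Series:
        het = self.df["a1"] != self.df["a2"]
        hom_ref = (~het) & (self.df["a1"] == self.df["ref"])
        out = pd.Series("hom_alt", index=self.df.index)
        out[het] = "het"
        out[hom_ref] = "hom_ref"
        return out


# ---------------------------------------------------------------------------
# generators


def generate_reference(
    n_contigs: int,
    contig_length: int,
    gc_block_spec: list[tuple[int, float]],
    n_gap_spec: list[tuple[int, int]] | None = None,
    seed: int = 0,
    excluded_contigs: set[str] | None = None,
) -> GenomeModel:
    """Generate a block-structured random genome.

    ``gc_block_spec`` is a list of (block_length, target_gc) pairs, cycled to
    fill each contig; within a block each base is G/C with probability
    target_gc (split evenly between G and C) and A/T otherwise.  ``n_gap_spec``
    lists (start, length) N runs stamped onto every contig.  Contigs are named
    ``chr1`` .. ``chrN``.
    """
    if n_contigs < 1:
        raise ValueError("need at least one contig")
    if contig_length <= 0:
        raise ValueError("contig_length must be positive")
    if not gc_block_spec:
        raise ValueError("gc_block_spec must list at least one block")
    for length, gc in gc_block_spec:
        if length <= 0:
            raise ValueError("block lengths must be positive")
        if not 0.0 <= gc <= 1.0:
            raise ValueError(f"target_gc {gc} outside [0, 1]")

    rng = np.random.default_rng(seed)
    contigs: dict[str, np.ndarray] = {}
    blocks: dict[str, list[tuple[int, int, float]]] = {}
    for i in range(n_contigs):
        name = f"chr{i + 1}"
        seq = np.empty(contig_length, dtype="S1")
        contig_blocks: list[tuple[int, int, float]] = []
        pos = 0
        j = 0
        while pos < contig_length:
            length, gc = gc_block_spec[j % len(gc_block_spec)]
            end = min(pos + length, contig_length)
            n = end - pos
            is_gc = rng.random(n) < gc
            strong = rng.integers(0, 2, n)  # 0 -> G, 1 -> C
            weak = rng.integers(0, 2, n)  # 0 -> A, 1 -> T
            block = np.where(is_gc, np.where(strong == 0, b"G", b"C"), np.where(weak == 0, b"A", b"T"))
            seq[pos:end] = block
            contig_blocks.append((pos, end, gc))
            pos = end
            j += 1
        for gap_start, gap_len in n_gap_spec or []:
            if gap_start < 0 or gap_start + gap_len > contig_length:
                raise ValueError("N gap outside contig bounds")
            seq[gap_start : gap_start + gap_len] = b"N"
        contigs[name] = seq
        blocks[name] = contig_blocks
    return GenomeModel(contigs, set(excluded_contigs or ()), blocks)


def plant_regions(genome: GenomeModel, catalog_spec: dict) -> dict[str, "RegionSet"]:
    """Materialize a named annotation catalog on a synthetic genome.

    Each catalog entry is either an explicit interval list
    ``[(contig, start, end), ...]`` or a GC-class rule
    ``{"rule": "gc_blocks", "min_gc": x, "max_gc": y}`` selecting the planted
    composition blocks whose target GC lies in [min_gc, max_gc].  Overlapping
    intervals are retained verbatim; merging is a downstream operation.
    """
    from .regions import RegionSet  # local import to avoid a cycle

    catalog: dict[str, RegionSet] = {}
    for name, spec in catalog_spec.items():
        if isinstance(spec, dict):
            if spec.get("rule") != "gc_blocks":
                raise ValueError(f"unknown region rule {spec.get('rule')!r}")
            lo, hi = spec.get("min_gc", 0.0), spec.get("max_gc", 1.0)
            intervals = [
                (contig, s, e)
                for contig, blocks in genome.planted_blocks.items()
                for (s, e, gc) in blocks
                if lo <= gc <= hi
            ]
        else:
            intervals = [tuple(iv) for iv in spec]
        for contig, s, e in intervals:
            if contig not in genome.contigs:
                raise ValueError(f"region on unknown contig {contig!r}")
            if s < 0 or e > genome.contig_length(contig):
                raise ValueError(f"region [{s},{e}) outside contig {contig!r}")
        catalog[name] = RegionSet(name, intervals)
    return catalog


def plant_variants(
    genome: GenomeModel,
    density_per_bp: float,
    het_fraction: float,
    seed: int = 0,
    hom_ref_density: float = 0.0,
) -> TruthGenotypes:
    """Plant SNVs (and optionally genotyped hom-ref sites) on informative bases.

    Each informative base carries a variant with probability ``density_per_bp``;
    ``het_fraction`` of variants are heterozygous (ref/alt), the rest
    homozygous alt/alt.  ``hom_ref_density`` additionally plants ref/ref
    records, emulating the reference-genotype positions an array reports,
    which the ROC uses as its false-positive denominator.
    """
    if not 0.0 <= density_per_bp <= 1.0:
        raise ValueError("density_per_bp must be in [0, 1]")
    if not 0.0 <= het_fraction <= 1.0:
        raise ValueError("het_fraction must be in [0, 1]")
    if not 0.0 <= hom_ref_density <= 1.0 - density_per_bp:
        raise ValueError("hom_ref_density must be in [0, 1 - density_per_bp]")

    rng = np.random.default_rng(seed)
    frames = []
    for contig in genome.analysis_contigs():
        mask = genome.informative_mask(contig)
        positions = np.flatnonzero(mask)
        if positions.size == 0:
            continue
        u = rng.random(positions.size)
        var_pos = positions[u < density_per_bp]
        ref_pos = positions[(u >= density_per_bp) & (u < density_per_bp + hom_ref_density)]
        seq = genome.contigs[contig]

        ref = seq[var_pos].astype("U1")
        # alt drawn uniformly from the three non-reference bases
        offset = rng.integers(1, 4, var_pos.size)
        ref_idx = np.searchsorted(BASES, seq[var_pos])
        alt = BASES[(ref_idx + offset) % 4].astype("U1")
        is_het = rng.random(var_pos.size) < het_fraction
        a1 = np.where(is_het, ref, alt)
        a2 = alt
        frames.append(
            pd.DataFrame({"contig": contig, "pos": var_pos, "ref": ref, "a1": a1, "a2": a2})
        )
        if ref_pos.size:
            rr = seq[ref_pos].astype("U1")
            frames.append(
                pd.DataFrame({"contig": contig, "pos": ref_pos, "ref": rr, "a1": rr, "a2": rr})
            )
    if not frames:
        return TruthGenotypes(pd.DataFrame(columns=["contig", "pos", "ref", "a1", "a2"]))
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)
    return TruthGenotypes(df)


def _start_weights(
    genome: GenomeModel,
    contig: str,
    profile: PlatformProfile,
    gamma: np.ndarray,
    tile: int,
) -> np.ndarray:
    """Per-start sampling weight for fragments of the profile's mean length.

    The fragment GC used for weighting is computed over the window
    [start, start + fragment_length_mean); starts whose window overlaps an N
    run or the contig end get weight zero, so fragments never touch undefined
    sequence.
    """
    L = genome.contig_length(contig)
    flen = int(round(profile.fragment_length_mean))
    if L < flen:
        return np.zeros(0)
    gc = genome.gc_mask(contig).astype(np.float64)
    defined = genome.informative_mask(contig).astype(np.int64)
    gc_cum = np.concatenate([[0.0], np.cumsum(gc)])
    def_cum = np.concatenate([[0], np.cumsum(defined)])
    n_starts = L - flen + 1
    window_gc = (gc_cum[flen:] - gc_cum[:-flen])[:n_starts] / flen
    window_def = (def_cum[flen:] - def_cum[:-flen])[:n_starts]
    w = profile.gc_response(window_gc)
    w[window_def < flen] = 0.0
    w *= gamma[(np.arange(n_starts) // tile)]
    return w


def simulate_reads(
    genome: GenomeModel,
    profile: PlatformProfile,
    target_mean_coverage: float,
    low_mappability: "RegionSet | None" = None,
    seed: int = 0,
    locus_tile: int = 1000,
) -> ReadSet:
    """Simulate paired-end read placements for one platform.

    Fragments are drawn with probability proportional to w(fragment GC) times
    a per-tile gamma factor (shape 1/dispersion), which makes per-locus
    fragment counts negative-binomial; paired reads of ``read_length`` sit at
    the two fragment ends.  Fragments never overlap N runs.  Reads whose
    fragment starts in ``low_mappability`` lose their unique-mapping status
    with probability 1 - repeat_mappability; a ``duplicate_rate`` fraction of
    extra fragments is emitted as flagged duplicates.  Sampling continues
    until the analysis-ready reads (unique, non-duplicate) supply
    ``target_mean_coverage`` times the informative genome length in bases, so
    the realized post-filter mean coverage tracks the target to within read
    granularity.
    """
    if target_mean_coverage <= 0:
        raise ValueError("target_mean_coverage must be positive")
    rng = np.random.default_rng(seed)
    rlen = profile.read_length
    flen_mean = profile.fragment_length_mean

    contig_names = list(genome.contigs)
    weights = []
    for contig in contig_names:
        L = genome.contig_length(contig)
        n_tiles = max(1, -(-L // locus_tile))
        if profile.dispersion > 0:
            shape = 1.0 / profile.dispersion
            gamma = rng.gamma(shape, profile.dispersion, n_tiles)
        else:
            gamma = np.ones(n_tiles)
        weights.append(_start_weights(genome, contig, profile, gamma, locus_tile))
    total_w = np.array([w.sum() for w in weights])
    analysis_w = sum(w for c, w in zip(contig_names, total_w) if c not in genome.excluded_contigs)
    if total_w.sum() <= 0 or analysis_w <= 0:
        raise ValueError("no sampleable fragments: gc_response is zero over the genome's GC range")
    contig_prob = total_w / total_w.sum()

    # map low-mappability intervals to fast per-contig lookups
    lowmap: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if low_mappability is not None and len(low_mappability.intervals):
        from .regions import merge_intervals

        merged = merge_intervals(low_mappability)
        for contig, s, e in merged.intervals:
            starts, ends = lowmap.setdefault(contig, ([], []))  # type: ignore[arg-type]
            starts.append(s)  # type: ignore[union-attr]
            ends.append(e)  # type: ignore[union-attr]
        lowmap = {c: (np.asarray(s), np.asarray(e)) for c, (s, e) in lowmap.items()}

    budget = target_mean_coverage * genome.informative_length()
    analysis = set(genome.analysis_contigs())

    kept_parts: list[pd.DataFrame] = []
    kept_bases = 0.0
    next_pair = 0
    # draw in batches until the filtered reads meet the coverage budget
    while kept_bases < budget:
        deficit = budget - kept_bases
        n_batch = max(256, int(deficit / (2 * rlen) * 1.1))
        c_idx = rng.choice(len(contig_names), size=n_batch, p=contig_prob)
        starts = np.empty(n_batch, dtype=np.int64)
        for ci in np.unique(c_idx):
            sel = c_idx == ci
            w = weights[ci]
            starts[sel] = rng.choice(len(w), size=int(sel.sum()), p=w / w.sum())
        lengths = rng.normal(flen_mean, profile.fragment_length_sd, n_batch)
        lengths = np.maximum(np.round(lengths).astype(np.int64), rlen + 1)

        batch_frames = []
        for ci in np.unique(c_idx):
            contig = contig_names[ci]
            sel = c_idx == ci
            s = starts[sel]
            ln = lengths[sel]
            # clamp the fragment to the defined run it started in
            mask = genome.informative_mask(contig)
            L = len(mask)
            run_end = _run_ends(mask)
            e = np.minimum(s + ln, run_end[s])
            e = np.maximum(e, s + rlen + 1)
            e = np.minimum(e, L)

            unique = np.ones(s.size, dtype=bool)
            if contig in lowmap:
                ls, le = lowmap[contig]
                idx = np.searchsorted(ls, s, side="right") - 1
                inside = (idx >= 0) & (s < le[np.clip(idx, 0, len(le) - 1)])
                dropped = inside & (rng.random(s.size) >= profile.repeat_mappability)
                unique = ~dropped
            pid = np.arange(next_pair, next_pair + s.size, dtype=np.int64)
            next_pair += s.size
            frame = pd.DataFrame(
                {
                    "contig": contig,
                    "frag_start": s,
                    "frag_end": e,
                    "pair_id": pid,
                    "is_unique": unique,
                }
            )
            batch_frames.append(frame)
        batch = pd.concat(batch_frames, ignore_index=True)
        contributes = batch["is_unique"].to_numpy() & batch["contig"].isin(analysis).to_numpy()
        read_bases = np.where(contributes, 2 * rlen, 0)
        cum = kept_bases + np.cumsum(read_bases)
        cut = int(np.searchsorted(cum, budget)) + 1
        batch = batch.iloc[:cut]
        kept_bases = float(cum[min(cut, len(cum)) - 1]) if len(cum) else kept_bases
        kept_parts.append(batch)

    frags = pd.concat(kept_parts, ignore_index=True)

    # duplicates: copies of sampled fragments, flagged, beyond the budget
    n_dup = int(round(profile.duplicate_rate / (1 - profile.duplicate_rate) * len(frags))) if profile.duplicate_rate > 0 else 0
    if n_dup:
        src = rng.integers(0, len(frags), n_dup)
        dups = frags.iloc[src].copy()
        dups["pair_id"] = np.arange(next_pair, next_pair + n_dup, dtype=np.int64)
        dups["is_duplicate"] = True
        frags["is_duplicate"] = False
        frags = pd.concat([frags, dups], ignore_index=True)
    else:
        frags["is_duplicate"] = False

    # expand fragments to read pairs at the fragment ends
    m1 = frags.copy()
    m1["start"] = m1["frag_start"]
    m1["end"] = m1["frag_start"] + rlen
    m1["mate"] = 0
    m2 = frags.copy()
    m2["start"] = m2["frag_end"] - rlen
    m2["end"] = m2["frag_end"]
    m2["mate"] = 1
    reads = pd.concat([m1, m2], ignore_index=True)
    reads["platform"] = profile.name
    reads = reads[READ_COLUMNS].copy()
    reads["pair_id"] = reads["pair_id"].astype("Int64")
    reads = reads.sort_values(["contig", "start", "end", "pair_id", "mate"], kind="stable").reset_index(drop=True)
    return ReadSet(reads)


def _run_ends(mask: np.ndarray) -> np.ndarray:
    """run_ends[i] = end of the N-free run containing position i.

    For an N base the value is i itself; start weights are zero there anyway.
    """
    L = len(mask)
    n_pos = np.flatnonzero(~mask)
    bounds = np.concatenate([n_pos, [L]])
    idx = np.searchsorted(n_pos, np.arange(L), side="left")
    run_end = bounds[np.clip(idx, 0, len(bounds) - 1)]
    run_end[~mask] = n_pos
    return run_end
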