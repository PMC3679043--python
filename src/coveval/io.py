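"""Readers and writers for the standard formats the pipeline exchanges.

FASTA for genomes, BED (0-based half-open) for region sets, SAM (via pysam)
and a simplified TSV dialect for read placements, bedGraph and
samtools-depth-style TSV for depth tracks, TSV (1-based positions, matching
VCF convention) for truth genotypes and calls, and minimal VCF (GT/DP) for
call sets.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .concordance import CALL_COLUMNS, CallSet
from .depth_core import DepthTracks
from .genome_sim import GenomeModel, PlatformProfile, ReadSet, TruthGenotypes, new_read_frame
from .regions import RegionSet

DUP_FLAG = 0x400
PAIRED_FLAG = 0x1


# -- FASTA ------------------------------------------------------------------


def write_fasta(genome: GenomeModel, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            s = seq.tobytes().decode("ascii")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path: str | Path, excluded_contigs: set[str] | None = None) -> GenomeModel:
    contigs: dict[str, np.ndarray] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    contigs[name] = np.frombuffer("".join(chunks).upper().encode(), dtype="S1").copy()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        contigs[name] = np.frombuffer("".join(chunks).upper().encode(), dtype="S1").copy()
    return GenomeModel(contigs, set(excluded_contigs or ()))


# -- BED --------------------------------------------------------------------


def write_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, s, e in sorted(regions.intervals):
            fh.write(f"{contig}\t{s}\t{e}\n")


def read_bed(path: str | Path, name: str | None = None) -> RegionSet:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return RegionSet(name or Path(path).stem, intervals)


# -- reads: SAM and simplified TSV -----------------------------------------


def write_sam(reads: ReadSet, genome: GenomeModel, path: str | Path) -> None:
    """Coordinate-sorted SAM; duplicate -> flag 0x400, non-unique -> MAPQ 0."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": genome.contig_length(c)} for c in genome.contigs],
    }
    df = reads.df.sort_values(["contig", "start"], kind="stable")
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {c: i for i, c in enumerate(genome.contigs)}
        for row in df.itertuples(index=False):
            a = pysam.AlignedSegment(out.header)
            pid = row.pair_id
            a.query_name = f"p{pid}" if pd.notna(pid) else "s"
            a.reference_id = tid[row.contig]
            a.reference_start = int(row.start)
            length = int(row.end - row.start)
            a.query_sequence = "N" * length
            a.cigarstring = f"{length}M"
            flag = 0
            if pd.notna(pid):
                flag |= PAIRED_FLAG | (0x40 if row.mate == 0 else 0x80)
            if row.is_duplicate:
                flag |= DUP_FLAG
            a.flag = flag
            a.mapping_quality = 60 if row.is_unique else 0
            a.set_tag("PL", row.platform or "NA")
            out.write(a)


def read_sam(path: str | Path) -> ReadSet:
    rows = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            pid = int(a.query_name[1:]) if a.query_name.startswith("p") else None
            rows.append(
                (
                    a.reference_name,
                    a.reference_start,
                    a.reference_end,
                    pid,
                    1 if a.is_read2 else 0,
                    a.is_duplicate,
                    a.mapping_quality > 0,
                    a.get_tag("PL") if a.has_tag("PL") else "",
                )
            )
    if not rows:
        return ReadSet(new_read_frame(0))
    df = pd.DataFrame(rows, columns=list(new_read_frame(0).columns))
    df["pair_id"] = df["pair_id"].astype("Int64")
    return ReadSet(df)


def write_reads_tsv(reads: ReadSet, path: str | Path) -> None:
    """Simplified dialect: contig, start, end, pair_id, mate, dup, unique."""
    df = reads.df.copy()
    df["dup"] = df.pop("is_duplicate").astype(int)
    df["unique"] = df.pop("is_unique").astype(int)
    df[["contig", "start", "end", "pair_id", "mate", "dup", "unique"]].to_csv(
        path, sep="\t", index=False
    )


def read_reads_tsv(path: str | Path, platform: str = "") -> ReadSet:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    df["pair_id"] = df["pair_id"].astype("Int64")
    df["is_duplicate"] = df.pop("dup").astype(bool)
    df["is_unique"] = df.pop("unique").astype(bool)
    df["platform"] = platform
    return ReadSet(df[list(new_read_frame(0).columns)])


# -- depth tracks -----------------------------------------------------------


def write_bedgraph(tracks: DepthTracks, path: str | Path) -> None:
    """Depth track with equal-depth runs collapsed to single rows."""
    with open(path, "w") as fh:
        for contig in tracks:
            depth = tracks[contig]
            if depth.size == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [depth.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{contig}\t{s}\t{e}\t{depth[s]}\n")


def read_bedgraph(path: str | Path, contig_lengths: dict[str, int]) -> DepthTracks:
    tracks = {c: np.zeros(L, dtype=np.int32) for c, L in contig_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, s, e, d = line.split("\t")
            tracks[contig][int(s) : int(e)] = int(d)
    return tracks


def write_depth_tsv(tracks: DepthTracks, path: str | Path) -> None:
    """samtools-depth style: contig, 1-based position, depth."""
    with open(path, "w") as fh:
        for contig, depth in tracks.items():
            for i, d in enumerate(depth, start=1):
                fh.write(f"{contig}\t{i}\t{d}\n")


# -- genotypes and calls ----------------------------------------------------


def write_truth_tsv(truth: TruthGenotypes, path: str | Path) -> None:
    df = truth.df.copy()
    df["pos_1based"] = df.pop("pos") + 1
    df[["contig", "pos_1based", "ref", "a1", "a2"]].to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> TruthGenotypes:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    df["pos"] = df.pop("pos_1based") - 1
    return TruthGenotypes(df[["contig", "pos", "ref", "a1", "a2"]])


def write_calls_tsv(calls: CallSet, path: str | Path) -> None:
    df = calls.df.copy()
    df["pos_1based"] = df.pop("pos") + 1
    df[["contig", "pos_1based", "a1", "a2", "depth"]].to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> CallSet:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    df["pos"] = df.pop("pos_1based") - 1
    return CallSet(df[CALL_COLUMNS])


def read_calls_vcf(path: str | Path) -> CallSet:
    """Minimal VCF reader: one sample, GT and DP format fields."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            sample = rec.samples[next(iter(rec.samples))]
            gt = sample.get("GT")
            if gt is None or any(g is None for g in gt):
                continue
            alleles = [rec.alleles[g] for g in gt]
            rows.append(
                (
                    rec.chrom,
                    rec.pos - 1,
                    alleles[0],
                    alleles[1] if len(alleles) > 1 else alleles[0],
                    sample.get("DP") or 0,
                )
            )
    return CallSet(pd.DataFrame(rows, columns=CALL_COLUMNS))


# -- profiles ---------------------------------------------------------------


def load_profiles(path: str | Path) -> dict[str, PlatformProfile]:
    """Platform profiles from a YAML mapping name -> parameters."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {name: profile_from_dict(name, spec) for name, spec in raw.items()}


def profile_from_dict(name: str, spec: dict) -> PlatformProfile:
    gc = spec.get("gc_response", {"knots": [0.0, 1.0], "weights": [1.0, 1.0]})
    return PlatformProfile(
        name=name,
        gc_knots=tuple(float(k) for k in gc["knots"]),
        gc_weights=tuple(float(w) for w in gc["weights"]),
        fragment_length_mean=float(spec.get("fragment_length_mean", 400)),
        fragment_length_sd=float(spec.get("fragment_length_sd", 40)),
        read_length=int(spec.get("read_length", 100)),
        duplicate_rate=float(spec.get("duplicate_rate", 0.0)),
        dispersion=float(spec.get("dispersion", 0.0)),
        repeat_mappability=float(spec.get("repeat_mappability", 1.0)),
    )


def builtin_profiles() -> dict[str, PlatformProfile]:
    """The shipped platform presets."""
    from importlib.resources import files

    path = files("coveval").joinpath("profiles/platforms.yaml")
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    return {name: profile_from_dict(name, spec) for name, spec in raw.items()}
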