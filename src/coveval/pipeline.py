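"""End-to-end orchestration: simulate, measure, compare, report.

A single config dict (usually loaded from YAML) drives the full evaluation:
genome and annotation simulation, per-platform read simulation at a target
mean coverage, filtering and depth computation, GC-bias trend fitting with
pairwise KS comparisons, the uncovered-region census with per-element
fractions, coverage-thresholded ROC/concordance against the planted truth
set, downsampling experiments, and platform-combination experiments.  Every
stochastic stage draws its own seed from the master seed by stable hashing
of the stage name, so adding a stage never perturbs the random streams of
earlier ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import depth_core, gc_bias, genome_sim, regions
from . import concordance as conc
from . import io as cio

log = logging.getLogger("coveval")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (zlib.crc32(stage.encode()) ^ (master_seed * 2654435761)) % (2**31)


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "genome": {
        "n_contigs": 2,
        "contig_length": 1_000_000,
        # 1 kb blocks cycling GC 0.15 -> 0.75, giving both regimes support
        "gc_block_spec": [[1000, round(0.15 + 0.025 * i, 3)] for i in range(25)],
        "n_gap_spec": [[500_000, 2_000]],
        "excluded_contigs": [],
    },
    "platforms": ["illumina_like", "solid_like", "cg_like"],
    "mean_coverage": 30.0,
    "downsample_targets": [15.0],
    "annotations": {
        "cpg_island": {"rule": "gc_blocks", "min_gc": 0.70},
        "exon": {"rule": "gc_blocks", "min_gc": 0.45, "max_gc": 0.55},
        "low_gc": {"rule": "gc_blocks", "max_gc": 0.20},
    },
    "low_mappability": None,
    "variants": {"density_per_bp": 5e-4, "het_fraction": 0.6, "hom_ref_density": 5e-4},
    "call_model": {"alt_read_min": 2, "depth_min": 3, "fp_rate": 1e-3},
    "gc": {"window_size": 1000, "span": 0.3, "gc_low": 0.25, "gc_high": 0.60, "grid_step": 0.005},
    "min_reads": 3,
    "merge_pairs": [["illumina_like", "solid_like", 15.0, 15.0]],
}


def _merged_config(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


@dataclass
class ReportBundle:
    """All report tables plus a provenance block with table checksums."""

    tables: dict[str, pd.DataFrame]
    provenance: dict = field(default_factory=dict)

    def checksums(self) -> dict[str, str]:
        return {
            name: hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()
            for name, df in sorted(self.tables.items())
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump({**self.provenance, "checksums": self.checksums()}, fh, indent=2, default=str)


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None) -> ReportBundle:
    """Run the full evaluation described by ``config``; see DEFAULT_CONFIG."""
    cfg = _merged_config(config)
    seed = int(cfg["seed"])
    gcfg = cfg["genome"]

    log.info("generating reference genome")
    genome = genome_sim.generate_reference(
        n_contigs=int(gcfg["n_contigs"]),
        contig_length=int(gcfg["contig_length"]),
        gc_block_spec=[tuple(b) for b in gcfg["gc_block_spec"]],
        n_gap_spec=[tuple(g) for g in gcfg.get("n_gap_spec") or []],
        seed=stage_seed(seed, "genome"),
        excluded_contigs=set(gcfg.get("excluded_contigs") or []),
    )
    catalog = genome_sim.plant_regions(genome, cfg["annotations"])
    lowmap_name = cfg.get("low_mappability")
    lowmap = catalog.get(lowmap_name) if lowmap_name else None

    vcfg = cfg["variants"]
    truth = genome_sim.plant_variants(
        genome,
        density_per_bp=float(vcfg["density_per_bp"]),
        het_fraction=float(vcfg["het_fraction"]),
        seed=stage_seed(seed, "variants"),
        hom_ref_density=float(vcfg.get("hom_ref_density", 0.0)),
    )

    profiles = cio.builtin_profiles()
    platform_cfg = cfg["platforms"]
    if isinstance(platform_cfg, dict):
        selected = {n: cio.profile_from_dict(n, s) for n, s in platform_cfg.items()}
    else:
        selected = {n: profiles[n] for n in platform_cfg}

    target = float(cfg["mean_coverage"])
    ccfg = cfg["call_model"]
    gcc = cfg["gc"]
    min_reads = int(cfg["min_reads"])

    readsets: dict[str, genome_sim.ReadSet] = {}
    depths: dict[str, depth_core.DepthTracks] = {}
    curves: dict[str, gc_bias.LoessCurve] = {}
    metric_rows = []
    roc_rows = []
    fraction_rows = []
    size_rows = []

    def evaluate(label: str, tracks: depth_core.DepthTracks, call_seed: str) -> None:
        mean = depth_core.mean_coverage(tracks, genome)
        hist = depth_core.depth_histogram(tracks, genome)
        below5 = depth_core.bases_below(hist, 5)
        uncov = regions.uncovered_regions(tracks, genome, min_reads=min_reads)
        frac_genome = sum(e - s for _, s, e in uncov.intervals) / hist.total_informative_bases
        metric_rows.extend(
            [
                {"platform": label, "metric": "mean_coverage", "value": mean},
                {"platform": label, "metric": "bases_below_5", "value": below5},
                {"platform": label, "metric": "fraction_genome_uncovered", "value": frac_genome},
                {"platform": label, "metric": "n_uncovered_regions", "value": len(uncov)},
            ]
        )
        for elem_name, elem in catalog.items():
            if len(elem) == 0:
                continue
            fraction_rows.append(
                {
                    "platform": label,
                    "element": elem_name,
                    "fraction_uncovered": regions.fraction_uncovered(uncov, elem),
                }
            )
        dist = regions.size_distribution(uncov, [1, 3, 10, 50, 150, 500])
        for row in dist.itertuples(index=False):
            size_rows.append({"platform": label, "size_bin": row.size_bin, "count": row.count})

        calls = conc.simulate_calls(
            tracks,
            truth,
            alt_read_min=int(ccfg["alt_read_min"]),
            depth_min=int(ccfg["depth_min"]),
            fp_rate=float(ccfg["fp_rate"]),
            seed=stage_seed(seed, call_seed),
        )
        roc = conc.roc_curve(truth, calls)
        table = conc.classify_genotypes(truth, calls)
        roc_rows.append(
            {
                "platform": label,
                "sensitivity_t0": conc.sensitivity_at(roc, 0),
                "fpr_t0": float(roc.fpr[0]),
                "auc": roc.auc,
                "het_identical": int(table.loc["het", "identical"]),
                "hom_identical": int(table.loc["hom", "identical"]),
            }
        )

    for name, profile in selected.items():
        log.info("simulating %s at %.0fx", name, target)
        reads = genome_sim.simulate_reads(
            genome, profile, target, lowmap, seed=stage_seed(seed, f"reads:{name}")
        )
        filtered = depth_core.filter_reads(reads)
        tracks = depth_core.compute_depth(filtered, genome)
        readsets[name] = filtered
        depths[name] = tracks
        evaluate(name, tracks, f"calls:{name}")
        table = gc_bias.window_table(tracks, genome, window_size=int(gcc["window_size"]))
        curves[name] = gc_bias.fit_loess(table, span=float(gcc["span"]))

        current = depth_core.mean_coverage(tracks, genome)
        for ds_target in cfg.get("downsample_targets") or []:
            ds_target = float(ds_target)
            if ds_target >= current:
                continue
            label = f"{name}_{ds_target:g}x"
            ds = depth_core.downsample(
                readsets[name], current, ds_target, seed=stage_seed(seed, f"ds:{label}")
            )
            evaluate(label, depth_core.compute_depth(ds, genome), f"calls:{label}")

    gc_table = gc_bias.compare_platforms(
        curves,
        gc_low=float(gcc["gc_low"]),
        gc_high=float(gcc["gc_high"]),
        step=float(gcc["grid_step"]),
        seed=stage_seed(seed, "gc_compare"),
    )

    for pair in cfg.get("merge_pairs") or []:
        name_a, name_b, cov_a, cov_b = pair
        label = f"{name_a}_{cov_a:g}x+{name_b}_{cov_b:g}x"
        parts = []
        for name, cov in ((name_a, float(cov_a)), (name_b, float(cov_b))):
            current = depth_core.mean_coverage(depths[name], genome)
            rs = readsets[name]
            if cov < current:
                rs = depth_core.downsample(rs, current, cov, seed=stage_seed(seed, f"mds:{label}:{name}"))
            parts.append(rs)
        merged = depth_core.merge_readsets(parts, genome)
        evaluate(label, depth_core.compute_depth(merged, genome), f"calls:{label}")

    bundle = ReportBundle(
        tables={
            "coverage_metrics": pd.DataFrame(metric_rows),
            "uncovered_fractions": pd.DataFrame(fraction_rows),
            "uncovered_size_distribution": pd.DataFrame(size_rows),
            "gc_bias_comparisons": gc_table,
            "roc_summary": pd.DataFrame(roc_rows),
        },
        provenance={
            "seed": seed,
            "config": cfg,
            "loess_span": gcc["span"],
            "curve_sampling": "deterministic grid on the fitted loess support",
        },
    )
    if out_dir is not None:
        bundle.write(out_dir)
        log.info("report written to %s", out_dir)
    return bundle
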