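"""Calibration and parameter-recovery experiments on synthetic data.

These are the standard self-checks of the evaluation pipeline: KS regime-test
calibration (replicates of one platform should rarely differ; a planted
high-GC dropout should almost always be detected), het-variant detection
against the analytic binomial tail, sensitivity as a function of mean
coverage, and the platform-combination gain.  They are used both by the
acceptance checks and as a template for users validating configuration
changes.
"""

from __future__ import annotations

import numpy as np

from . import concordance as conc
from .depth_core import compute_depth, filter_reads, mean_coverage, merge_readsets
from .gc_bias import fit_loess, ks_compare, sample_curve_noisy, window_table
from .genome_sim import GenomeModel, PlatformProfile, generate_reference, plant_variants, simulate_reads
from .pipeline import stage_seed

FLAT_PROFILE = PlatformProfile(
    "flat", (0.0, 1.0), (1.0, 1.0), fragment_length_mean=400, fragment_length_sd=40, read_length=100
)
# sampling weight halved for fragments with GC >= 0.6
HIGH_GC_DROP_PROFILE = PlatformProfile(
    "high_gc_drop",
    (0.0, 0.6, 0.6001, 1.0),
    (1.0, 1.0, 0.5, 0.5),
    fragment_length_mean=400,
    fragment_length_sd=40,
    read_length=100,
)


def calibration_genome(total_length: int = 2_000_000, seed: int = 0) -> GenomeModel:
    """Two-contig genome with 1 kb blocks cycling GC 0.15 -> 0.75."""
    spec = [(1000, round(0.15 + 0.025 * i, 3)) for i in range(25)]
    return generate_reference(2, total_length // 2, spec, seed=seed)


def _trend_curve(genome: GenomeModel, profile: PlatformProfile, coverage: float, seed: int):
    reads = simulate_reads(genome, profile, coverage, seed=seed)
    tracks = compute_depth(filter_reads(reads), genome)
    return fit_loess(window_table(tracks, genome), span=0.3)


def gc_regime_pvalues(
    genome: GenomeModel,
    profile_a: PlatformProfile,
    profile_b: PlatformProfile,
    n_pairs: int,
    seed: int,
    coverage: float = 30.0,
    gc_low: float = 0.25,
    gc_high: float = 0.60,
    step: float = 0.005,
) -> list[tuple[float, float]]:
    """KS p-values (low-GC regime, high-GC regime) over independent seed pairs.

    Each pair simulates both platforms independently, fits the loess trend,
    samples both regimes with residual noise, and tests the two samples.
    """
    out = []
    rng = np.random.default_rng(stage_seed(seed, "gc_regime_noise"))
    for i in range(n_pairs):
        ca = _trend_curve(genome, profile_a, coverage, stage_seed(seed, f"a{i}"))
        cb = _trend_curve(genome, profile_b, coverage, stage_seed(seed, f"b{i}"))
        ps = []
        for lo, hi in ((0.0, gc_low), (gc_high, 1.0)):
            va = sample_curve_noisy(ca, lo, hi, step, rng)
            vb = sample_curve_noisy(cb, lo, hi, step, rng)
            ps.append(ks_compare(va, vb)[1])
        out.append((ps[0], ps[1]))
    return out


def het_detection_rates(
    depths: list[int], n_variants: int = 12_000, seed: int = 0
) -> dict[int, tuple[float, float]]:
    """Measured vs analytic het detection rate at fixed depths.

    Detection requires >= 2 alt reads (Binomial(d, 0.5)) and depth >= 3, so
    the analytic rate at depth d >= 3 is P(Bin(d, 0.5) >= 2).
    """
    from scipy.stats import binom
    import pandas as pd
    from .genome_sim import TruthGenotypes

    rows = [("chr1", p, "A", "A", "G") for p in range(n_variants)]
    truth = TruthGenotypes(pd.DataFrame(rows, columns=["contig", "pos", "ref", "a1", "a2"]))
    out = {}
    for d in depths:
        tracks = {"chr1": np.full(n_variants, d, dtype=np.int32)}
        calls = conc.simulate_calls(tracks, truth, seed=stage_seed(seed, f"het{d}"))
        measured = len(calls) / n_variants
        analytic = float(1 - binom.cdf(1, d, 0.5)) if d >= 3 else 0.0
        out[d] = (measured, analytic)
    return out


def coverage_sensitivity(
    genome: GenomeModel,
    profile: PlatformProfile,
    coverages: list[float],
    seed: int,
    fp_rate: float = 1e-3,
) -> dict[float, float]:
    """Sensitivity at threshold 0 as a function of simulated mean coverage."""
    truth = plant_variants(
        genome, 5e-4, 0.6, seed=stage_seed(seed, "truth"), hom_ref_density=5e-4
    )
    out = {}
    for cov in coverages:
        reads = simulate_reads(genome, profile, cov, seed=stage_seed(seed, f"cov{cov}"))
        tracks = compute_depth(filter_reads(reads), genome)
        calls = conc.simulate_calls(
            tracks, truth, fp_rate=fp_rate, seed=stage_seed(seed, f"calls{cov}")
        )
        roc = conc.roc_curve(truth, calls)
        out[cov] = conc.sensitivity_at(roc, 0)
    return out


def merge_gain(
    genome: GenomeModel,
    profile_a: PlatformProfile,
    profile_b: PlatformProfile,
    coverage: float,
    seed: int,
    fp_rate: float = 1e-3,
) -> tuple[float, float, float]:
    """Sensitivity at t=0 of (merged A+B, A alone, B alone) at equal coverage."""
    truth = plant_variants(
        genome, 5e-4, 0.6, seed=stage_seed(seed, "mtruth"), hom_ref_density=5e-4
    )
    sets = {}
    for tag, prof in (("a", profile_a), ("b", profile_b)):
        reads = simulate_reads(genome, prof, coverage, seed=stage_seed(seed, f"m{tag}"))
        sets[tag] = filter_reads(reads)

    def sens(reads_list, tag):
        tracks = compute_depth(
            reads_list[0] if len(reads_list) == 1 else merge_readsets(reads_list, genome), genome
        )
        calls = conc.simulate_calls(
            tracks, truth, fp_rate=fp_rate, seed=stage_seed(seed, f"mc{tag}")
        )
        return conc.sensitivity_at(conc.roc_curve(truth, calls), 0)

    return (
        sens([sets["a"], sets["b"]], "ab"),
        sens([sets["a"]], "a"),
        sens([sets["b"]], "b"),
    )
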