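"""Call-set evaluation against truth genotypes.

The evaluation is anchored to an externally genotyped truth set: sensitivity
is the fraction of truth variant positions at which the platform made any
non-reference call, the false-positive rate is the fraction of truth
homozygous-reference positions with a spurious non-reference call, and the
ROC traces both as the required depth at the position increases.  Genotype
agreement is reported separately as a concordance table (identical /
one_identical / no_identical by truth zygosity), where a position without a
sequencing call is assumed homozygous reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .depth_core import DepthTracks
from .genome_sim import GenomeModel, TruthGenotypes

CALL_COLUMNS = ["contig", "pos", "a1", "a2", "depth"]


@dataclass
class CallSet:
    """Diploid calls at genomic positions, with the depth at each position.

    Positions absent from the frame are no-calls.  ``a2`` may be None for a
    half-call; depth is the filtered read depth the caller saw.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CALL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"CallSet frame missing columns: {missing}")
        if len(self.df) and self.df.duplicated(["contig", "pos"]).any():
            raise ValueError("call positions must be unique per contig")
        if len(self.df) and (self.df["depth"] < 0).any():
            raise ValueError("depth must be non-negative")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class RocCurve:
    """Sensitivity and false-positive rate as the depth threshold varies."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    fpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        for arr in (self.sensitivity, self.fpr):
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValueError("rates must lie in [0, 1]")
            if np.any(np.diff(arr) > 1e-12):
                raise ValueError("rates must be non-increasing in the threshold")


def simulate_calls(
    tracks: DepthTracks,
    truth: TruthGenotypes,
    alt_read_min: int = 2,
    depth_min: int = 3,
    fp_rate: float = 0.0,
    seed: int = 0,
    het_allele_fraction: float = 0.5,
    hom_allele_fraction: float = 0.98,
) -> CallSet:
    """Coverage-dependent caller emulation at truth positions.

    At a truth variant position with filtered depth d, the number of
    alt-supporting reads is Binomial(d, f) with f the het or hom-alt allele
    fraction; a variant is called iff alt reads >= alt_read_min and
    d >= depth_min (two non-reference reads plus one reference read being the
    minimum evidence for a het call).  The genotype is het when at least one
    reference read remains, else hom-alt.  At truth hom-ref positions a
    spurious het call is emitted with probability ``fp_rate``.  A lower
    ``het_allele_fraction`` emulates tumor samples with sub-50% mutant allele
    fractions.
    """
    if not 0.0 <= fp_rate <= 1.0:
        raise ValueError("fp_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    zyg = truth.zygosity()
    for contig, sub in truth.df.groupby("contig", sort=False):
        if contig not in tracks:
            raise ValueError(f"no depth track for contig {contig!r}")
        depth = tracks[contig][sub["pos"].to_numpy()]
        z = zyg.loc[sub.index].to_numpy()
        is_het = z == "het"
        is_hom_alt = z == "hom_alt"
        is_variant = is_het | is_hom_alt
        af = np.where(is_het, het_allele_fraction, hom_allele_fraction)
        alt_reads = rng.binomial(depth, af)
        called = is_variant & (alt_reads >= alt_read_min) & (depth >= depth_min)
        ref_reads = depth - alt_reads
        called_het = called & (ref_reads >= 1)

        # the alt allele of a truth record is a2 (het) or a1==a2 (hom-alt)
        ref = sub["ref"].to_numpy()
        alt = sub["a2"].to_numpy()
        fp = (~is_variant) & (rng.random(len(sub)) < fp_rate) & (depth > 0)
        fp_alt = _random_alt(rng, ref)

        for take, a1, a2 in (
            (called & called_het, ref, alt),
            (called & ~called_het, alt, alt),
            (fp, ref, fp_alt),
        ):
            if take.any():
                rows.append(
                    pd.DataFrame(
                        {
                            "contig": contig,
                            "pos": sub["pos"].to_numpy()[take],
                            "a1": a1[take],
                            "a2": a2[take],
                            "depth": depth[take],
                        }
                    )
                )
    if not rows:
        return CallSet(pd.DataFrame(columns=CALL_COLUMNS))
    df = pd.concat(rows, ignore_index=True).sort_values(["contig", "pos"], kind="stable")
    return CallSet(df.reset_index(drop=True))


def _random_alt(rng: np.random.Generator, ref: np.ndarray) -> np.ndarray:
    bases = np.array(list("ACGT"))
    idx = np.searchsorted(bases, ref)
    return bases[(idx + rng.integers(1, 4, ref.size)) % 4]


def roc_curve(truth: TruthGenotypes, calls: CallSet) -> RocCurve:
    """Depth-thresholded ROC of non-reference calls against the truth set.

    Thresholds enumerate the observed depths at called truth positions plus
    zero.  At threshold t, sensitivity counts truth variant positions with a
    non-reference call of depth >= t; FPR counts truth hom-ref positions
    with a non-reference call of depth >= t.  The AUC integrates the curve by
    trapezoid, anchored at (0, 0) and extended horizontally to FPR = 1 (a
    caller accepts everything below its last threshold).
    """
    zyg = truth.zygosity()
    is_variant = (zyg != "hom_ref").to_numpy()
    n_var = int(is_variant.sum())
    n_ref = int((~is_variant).sum())
    if n_var == 0 or n_ref == 0:
        raise ValueError("truth must contain both variant and hom-ref positions")

    merged = truth.df[["contig", "pos", "ref"]].copy()
    merged["is_variant"] = is_variant
    calls_nonref = calls.df.merge(merged, on=["contig", "pos"], how="inner")
    nonref = (calls_nonref["a1"] != calls_nonref["ref"]) | (
        calls_nonref["a2"] != calls_nonref["ref"]
    )
    calls_nonref = calls_nonref[nonref]

    var_depths = calls_nonref.loc[calls_nonref["is_variant"], "depth"].to_numpy()
    ref_depths = calls_nonref.loc[~calls_nonref["is_variant"], "depth"].to_numpy()

    thresholds = np.unique(np.concatenate([[0], var_depths, ref_depths]))
    sens = np.array([(var_depths >= t).sum() / n_var for t in thresholds])
    fpr = np.array([(ref_depths >= t).sum() / n_ref for t in thresholds])

    order = np.argsort(thresholds)[::-1]  # ascending FPR
    fx = np.concatenate([[0.0], fpr[order], [1.0]])
    fy = np.concatenate([[0.0], sens[order], [sens.max(initial=0.0)]])
    auc = float(np.trapezoid(fy, fx))
    return RocCurve(thresholds, sens, fpr, auc)


def sensitivity_at(roc: RocCurve, t: float) -> float:
    """Sensitivity at threshold t: fraction of truth variants called with depth >= t.

    Between observed depths the step function holds the value of the next
    threshold up (no call has a depth in the gap); above the largest observed
    depth it is zero.
    """
    if t < roc.thresholds.min():
        raise ValueError("t below the smallest threshold")
    idx = int(np.searchsorted(roc.thresholds, t, side="left"))
    if idx == len(roc.thresholds):
        return 0.0
    return float(roc.sensitivity[idx])


def auc(roc: RocCurve) -> float:
    return roc.auc


def classify_genotypes(truth: TruthGenotypes, calls: CallSet) -> pd.DataFrame:
    """Concordance of called genotypes with truth, by truth zygosity.

    Truth and call allele multisets are compared; a position without a call
    is assumed homozygous reference.  Classes: identical (both alleles
    match), one_identical (exactly one), no_identical (none).  Rows: hom,
    het; the NA column (missing truth genotype) is carried for table
    compatibility and is zero for fully genotyped truth sets.
    """
    for col in ("a1", "a2"):
        if len(calls.df) and not calls.df[col].isin(list("ACGT")).all():
            raise ValueError(f"call allele column {col} must be A/C/G/T")
    t = truth.df.merge(
        calls.df[["contig", "pos", "a1", "a2"]].rename(columns={"a1": "c1", "a2": "c2"}),
        on=["contig", "pos"],
        how="left",
    )
    no_call = t["c1"].isna()
    t.loc[no_call, "c1"] = t.loc[no_call, "ref"]
    t.loc[no_call, "c2"] = t.loc[no_call, "ref"]

    def match_count(row) -> int:
        truth_ms = [row["a1"], row["a2"]]
        n = 0
        for allele in (row["c1"], row["c2"]):
            if allele in truth_ms:
                truth_ms.remove(allele)
                n += 1
        return n

    matches = t.apply(match_count, axis=1) if len(t) else pd.Series(dtype=int)
    zyg = truth.zygosity().to_numpy()
    is_het = zyg == "het"
    table = pd.DataFrame(
        0,
        index=["hom", "het"],
        columns=["identical", "one_identical", "no_identical", "NA"],
        dtype=int,
    )
    class_of = {2: "identical", 1: "one_identical", 0: "no_identical"}
    for i in range(len(t)):
        row = "het" if is_het[i] else "hom"
        table.loc[row, class_of[int(matches.iloc[i])]] += 1
    return table


def paired_sensitivity_test(sens_a, sens_b) -> "PairedTTestResult":
    """Two-sided paired t-test on per-sample sensitivities."""
    a = np.asarray(sens_a, dtype=float)
    b = np.asarray(sens_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need >= 2 paired samples")
    diff = a - b
    if diff.std() == 0:
        # constant difference: the t statistic is undefined
        return PairedTTestResult(0.0, 1.0, informative=False)
    t, p = stats.ttest_rel(a, b)
    return PairedTTestResult(float(t), float(p), informative=True)


@dataclass(frozen=True)
class PairedTTestResult:
    statistic: float
    p_value: float
    informative: bool


def allele_nocall_binomial(one_allele_missing: int, both_alleles_missing: int) -> float:
    """Exact two-sided binomial test of the no-call asymmetry.

    Tests whether SNPs missing calls on both alleles are as frequent as SNPs
    missing a call on one allele, under a fair 0.5 split.
    """
    if one_allele_missing < 0 or both_alleles_missing < 0:
        raise ValueError("counts must be non-negative")
    n = one_allele_missing + both_alleles_missing
    if n == 0:
        raise ValueError("at least one count must be positive")
    return float(stats.binomtest(both_alleles_missing, n, 0.5, alternative="two-sided").pvalue)
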