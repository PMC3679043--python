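"""Interval derivation, the uncovered census, and fraction comparisons."""

import numpy as np
import pytest

from coveval.genome_sim import GenomeModel, generate_reference, plant_regions, simulate_reads
from coveval.depth_core import compute_depth, filter_reads
from coveval.regions import (
    RegionSet,
    compare_fractions_ttest,
    derive_introns,
    derive_promoters,
    derive_shores,
    fraction_uncovered,
    merge_intervals,
    size_distribution,
    uncovered_regions,
)


def genome_of_length(n, name="chr1"):
    return GenomeModel({name: np.frombuffer(b"ACGT" * (n // 4 + 1), dtype="S1")[:n].copy()})


class TestUncoveredRegions:
    def test_runs_below_threshold(self):
        g = genome_of_length(6)
        regions = uncovered_regions({"chr1": np.array([0, 1, 2, 3, 3, 2])}, g, min_reads=3)
        assert regions.intervals == [("chr1", 0, 3), ("chr1", 5, 6)]

    def test_all_covered_gives_empty_set(self):
        g = genome_of_length(5)
        assert len(uncovered_regions({"chr1": np.full(5, 3)}, g)) == 0

    def test_zero_read_variant(self):
        g = genome_of_length(3)
        regions = uncovered_regions({"chr1": np.array([0, 0, 5])}, g, min_reads=1)
        assert regions.intervals == [("chr1", 0, 2)]

    def test_n_runs_split_regions(self):
        g = GenomeModel({"chr1": np.frombuffer(b"AANNAA", dtype="S1").copy()})
        regions = uncovered_regions({"chr1": np.zeros(6, int)}, g, min_reads=3)
        assert regions.intervals == [("chr1", 0, 2), ("chr1", 4, 6)]

    @pytest.mark.parametrize("min_reads", [1, 3, 5])
    def test_matches_brute_force_scan(self, min_reads):
        rng = np.random.default_rng(min_reads)
        g = generate_reference(1, 10_000, [(1000, 0.5)], n_gap_spec=[(3000, 100)], seed=2)
        track = rng.integers(0, 6, 10_000)
        regions = uncovered_regions({"chr1": track}, g, min_reads=min_reads)
        mask = g.informative_mask("chr1") & (track < min_reads)
        covered_by_regions = np.zeros(10_000, dtype=bool)
        for _, s, e in regions.intervals:
            assert mask[s:e].all()
            covered_by_regions[s:e] = True
        assert (covered_by_regions == mask).all()
        # maximality: flanks of every region are not below-threshold informative bases
        for _, s, e in regions.intervals:
            if s > 0:
                assert not mask[s - 1]
            if e < 10_000:
                assert not mask[e]

    def test_uncovered_bases_monotone_in_min_reads(self):
        rng = np.random.default_rng(9)
        g = generate_reference(1, 5000, [(1000, 0.5)], seed=3)
        track = rng.integers(0, 8, 5000)
        sizes = []
        for k in (1, 3, 5):
            regs = uncovered_regions({"chr1": track}, g, min_reads=k)
            sizes.append(sum(e - s for _, s, e in regs.intervals))
        assert sizes == sorted(sizes)


class TestSizeDistribution:
    def test_counts_per_bin(self):
        regs = RegionSet("u", [("chr1", 0, 1), ("chr1", 5, 7), ("chr1", 100, 250)])
        dist = size_distribution(regs, [1, 3, 150])
        assert dist["count"].tolist() == [2, 0, 1]

    def test_empty_set_all_zero(self):
        dist = size_distribution(RegionSet("u", []), [1, 10])
        assert dist["count"].sum() == 0

    def test_total_count_conserved(self):
        rng = np.random.default_rng(1)
        regs = RegionSet(
            "u", [("chr1", int(s), int(s) + int(l)) for s, l in
                  zip(rng.integers(0, 10_000, 200) * 100, rng.integers(1, 500, 200))]
        )
        dist = size_distribution(regs, [1, 10, 100])
        assert dist["count"].sum() == 200


class TestDerivations:
    def test_shores_flank_the_island(self):
        g = genome_of_length(20_000)
        shores = derive_shores(RegionSet("cpg", [("chr1", 5000, 5600)]), g)
        assert sorted(shores.intervals) == [("chr1", 3000, 5000), ("chr1", 5600, 7600)]

    def test_upstream_shore_clipped_at_contig_start(self):
        g = genome_of_length(20_000)
        shores = derive_shores(RegionSet("cpg", [("chr1", 500, 900)]), g)
        assert ("chr1", 0, 500) in shores.intervals

    def test_empty_islands_empty_shores(self, tiny_genome):
        assert len(derive_shores(RegionSet("cpg", []), tiny_genome)) == 0

    def test_shores_never_intersect_their_islands(self):
        g = genome_of_length(50_000)
        islands = RegionSet("cpg", [("chr1", 4000, 4500), ("chr1", 9000, 9800)])
        from coveval.regions import overlap_bases

        for _, s, e in islands.intervals:
            own = RegionSet("island", [("chr1", s, e)])
            # a shore may touch another island, but never the island it flanks
            flanks = derive_shores(RegionSet("i", [("chr1", s, e)]), g)
            assert overlap_bases(flanks, own) == 0

    def test_promoter_strand_arithmetic(self):
        g = genome_of_length(20_000)
        plus = derive_promoters([("chr1", 10_000, "+")], g)
        minus = derive_promoters([("chr1", 10_000, "-")], g)
        assert plus.intervals == [("chr1", 8000, 10_500)]
        assert minus.intervals == [("chr1", 9500, 12_000)]

    def test_promoter_clipping_and_length(self):
        g = genome_of_length(20_000)
        clipped = derive_promoters([("chr1", 100, "+")], g)
        assert clipped.intervals == [("chr1", 0, 600)]
        unclipped = derive_promoters([("chr1", 10_000, "+")], g, up=2000, down=500)
        _, s, e = unclipped.intervals[0]
        assert e - s == 2500

    def test_unknown_strand_raises(self, tiny_genome):
        with pytest.raises(ValueError):
            derive_promoters([("chr1", 10, ".")], tiny_genome)

    def test_intron_between_exons(self):
        exons = RegionSet("e", [("chr1", 0, 200), ("chr1", 800, 1000)])
        introns = derive_introns([(("chr1", 0, 1000), exons)])
        assert introns.intervals == [("chr1", 200, 800)]

    def test_single_and_abutting_exons_give_no_introns(self):
        single = derive_introns([(("chr1", 0, 100), RegionSet("e", [("chr1", 0, 100)]))])
        assert len(single) == 0
        abutting = derive_introns(
            [(("chr1", 0, 400), RegionSet("e", [("chr1", 0, 200), ("chr1", 200, 400)]))]
        )
        assert len(abutting) == 0

    def test_overlapping_exons_raise(self):
        exons = RegionSet("e", [("chr1", 0, 250), ("chr1", 200, 400)])
        with pytest.raises(ValueError):
            derive_introns([(("chr1", 0, 400), exons)])


class TestMergeAndFractions:
    def test_merge_overlapping(self):
        merged = merge_intervals(RegionSet("r", [("chr1", 0, 10), ("chr1", 5, 20)]))
        assert merged.intervals == [("chr1", 0, 20)]

    def test_merge_disjoint_unchanged(self):
        ivs = [("chr1", 0, 5), ("chr1", 10, 15)]
        assert merge_intervals(RegionSet("r", ivs)).intervals == ivs

    def test_merge_idempotent(self):
        rng = np.random.default_rng(4)
        ivs = [("chr1", int(s), int(s + l)) for s, l in
               zip(rng.integers(0, 1000, 50), rng.integers(1, 100, 50))]
        once = merge_intervals(RegionSet("r", ivs))
        twice = merge_intervals(once)
        assert once.intervals == twice.intervals

    def test_fraction_simple_overlap(self):
        uncov = RegionSet("u", [("chr1", 0, 58)])
        elem = RegionSet("e", [("chr1", 0, 100)])
        assert fraction_uncovered(uncov, elem) == 0.58

    def test_disjoint_fraction_zero(self):
        assert fraction_uncovered(
            RegionSet("u", [("chr1", 0, 10)]), RegionSet("e", [("chr1", 50, 60)])
        ) == 0.0

    def test_duplicated_element_same_fraction(self):
        uncov = RegionSet("u", [("chr1", 0, 30)])
        single = RegionSet("e", [("chr1", 0, 100)])
        doubled = RegionSet("e", [("chr1", 0, 100), ("chr1", 0, 100)])
        assert fraction_uncovered(uncov, single) == fraction_uncovered(uncov, doubled)

    def test_empty_element_raises(self):
        with pytest.raises(ValueError):
            fraction_uncovered(RegionSet("u", []), RegionSet("e", []))


class TestAgainstPyranges:
    def test_merge_and_overlap_agree_with_pyranges(self):
        pyranges = pytest.importorskip("pyranges")
        import pandas as pd

        rng = np.random.default_rng(17)
        for rep in range(10):
            ivs_a = [("chr1", int(s), int(s + l)) for s, l in
                     zip(rng.integers(0, 5000, 40), rng.integers(1, 300, 40))]
            ivs_b = [("chr1", int(s), int(s + l)) for s, l in
                     zip(rng.integers(0, 5000, 40), rng.integers(1, 300, 40))]
            merged = merge_intervals(RegionSet("a", ivs_a))
            pr = pyranges.PyRanges(
                pd.DataFrame(ivs_a, columns=["Chromosome", "Start", "End"])
            ).merge()
            expected = list(zip(pr.df["Chromosome"], pr.df["Start"], pr.df["End"]))
            assert [(c, s, e) for c, s, e in merged.intervals] == expected

            from coveval.regions import overlap_bases

            ours = overlap_bases(RegionSet("a", ivs_a), RegionSet("b", ivs_b))
            pa = pyranges.PyRanges(pd.DataFrame(ivs_a, columns=["Chromosome", "Start", "End"]))
            pb = pyranges.PyRanges(pd.DataFrame(ivs_b, columns=["Chromosome", "Start", "End"]))
            inter = pa.merge().intersect(pb.merge())
            theirs = int((inter.df["End"] - inter.df["Start"]).sum()) if len(inter) else 0
            assert ours == theirs


class TestFractionTTest:
    def test_degenerate_groups_flagged_noninformative(self):
        res = compare_fractions_ttest([0.1, 0.1], [0.1, 0.1])
        assert not res.informative

    def test_identical_groups_give_p_one(self):
        res = compare_fractions_ttest([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_t_distribution_oracle(self):
        # expected values computed by numerical integration of the t density, df = 6
        res = compare_fractions_ttest([0.0, 0.1, 0.0, 0.1], [0.5, 0.6, 0.5, 0.6])
        assert res.statistic == pytest.approx(-12.247448713915892, rel=1e-9)
        assert res.p_value == pytest.approx(1.8042449044220354e-05, rel=1e-6)

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            compare_fractions_ttest([0.1], [0.2, 0.3])


class TestHighGcDropoutRecovery:
    def test_planted_cpg_islands_lose_more_coverage_than_exons(self, gc_dropout_profile):
        spec = [(1000, 0.45), (1000, 0.75), (1000, 0.5), (1000, 0.45)]
        g = generate_reference(1, 200_000, spec, seed=31)
        catalog = plant_regions(
            g,
            {
                "cpg_island": {"rule": "gc_blocks", "min_gc": 0.7},
                "exon": {"rule": "gc_blocks", "min_gc": 0.45, "max_gc": 0.55},
            },
        )
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            reads = simulate_reads(g, gc_dropout_profile, 8.0, seed=seed)
            tracks = compute_depth(filter_reads(reads), g)
            uncov = uncovered_regions(tracks, g, min_reads=3)
            cpg = fraction_uncovered(uncov, catalog["cpg_island"])
            exon = fraction_uncovered(uncov, catalog["exon"])
            wins += cpg > exon
        assert wins >= 0.95 * n_seeds
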