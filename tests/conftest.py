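import numpy as np
import pytest

from coveval.genome_sim import GenomeModel, PlatformProfile, ReadSet, generate_reference


@pytest.fixture(scope="session")
def flat_profile():
    """GC-indifferent platform: every fragment equally sampleable."""
    return PlatformProfile(
        name="flat",
        gc_knots=(0.0, 1.0),
        gc_weights=(1.0, 1.0),
        fragment_length_mean=400,
        fragment_length_sd=40,
        read_length=100,
    )


@pytest.fixture(scope="session")
def gc_dropout_profile():
    """Platform whose sampling weight vanishes for fragments with GC >= 0.6."""
    return PlatformProfile(
        name="dropout",
        gc_knots=(0.0, 0.55, 0.6, 1.0),
        gc_weights=(1.0, 1.0, 0.0, 0.0),
        fragment_length_mean=400,
        fragment_length_sd=40,
        read_length=100,
    )


@pytest.fixture(scope="session")
def wide_gc_genome():
    """200 kb genome whose 1 kb blocks cycle GC 0.15 -> 0.75."""
    spec = [(1000, round(0.15 + 0.025 * i, 3)) for i in range(25)]
    return generate_reference(1, 200_000, spec, seed=42)


@pytest.fixture
def tiny_genome():
    """Two 60 bp contigs, one with an N gap, plus an excluded contig."""
    seqs = {
        "chr1": np.frombuffer(b"ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"[:60], dtype="S1").copy(),
        "chr2": np.frombuffer((b"ACGT" * 10 + b"N" * 10 + b"GGCC" * 2 + b"AT").ljust(60, b"A"), dtype="S1").copy(),
        "chrY": np.frombuffer(b"A" * 60, dtype="S1").copy(),
    }
    return GenomeModel(seqs, excluded_contigs={"chrY"})


def make_reads(records, platform=""):
    """records: (contig, start, end, pair_id, mate, dup, unique) tuples."""
    return ReadSet.from_records(records, platform=platform)


@pytest.fixture
def simple_reads():
    return make_reads(
        [
            ("chr1", 0, 4, 0, 0, False, True),
            ("chr1", 2, 6, 0, 1, False, True),
        ]
    )
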