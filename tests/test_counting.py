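"""Soft-clip removal, read assignment, counting conservation, length profiles."""

from __future__ import annotations

import random

import numpy as np
import pytest

from mitoribo import counting, synthetic_data as sd
from mitoribo.counting import AMBIGUOUS, UNASSIGNED, LibraryMeta
from mitoribo.io_formats import AlignmentRecord, Annotation, Feature


def _rec(pos, cigar, lib="lib", ref="mito_toy", qid="r"):
    from mitoribo.io_formats import decode_cigar

    return AlignmentRecord(qid, ref, pos, decode_cigar(cigar), lib)


@pytest.fixture(scope="module")
def toy_annotation():
    return Annotation(
        (
            Feature("A", "target", "heavy", 0, 500),
            Feature("B", "target", "heavy", 500, 900),
            Feature("S", "spikein", "spikein", 1000, 1400),
        ),
        reference_name="mito_toy",
    )


# ---------------------------------------------------------------------------
# strip_soft_clips
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pos,cigar,span,alen",
    [
        (10, "2S10M3S", (9, 19), 10),
        (1, "5M2D5M", (0, 12), 10),
        (1, "4M1I4M", (0, 8), 9),
        (100, "30M", (99, 129), 30),
    ],
)
def test_strip_soft_clips_arithmetic(pos, cigar, span, alen):
    got_span, got_len = counting.strip_soft_clips(_rec(pos, cigar))
    assert got_span == span
    assert got_len == alen


def test_soft_clip_invariance_property():
    """Adding S ops never changes span, length or assignment."""
    rng = random.Random(0)
    ann = Annotation(
        (Feature("A", "target", "heavy", 0, 500), Feature("S", "spikein", "spikein", 600, 900)),
        reference_name="mito_toy",
    )
    for _ in range(200):
        pos = rng.randint(1, 460)
        core = f"{rng.randint(20, 40)}M"
        bare = _rec(pos, core)
        clipped = _rec(pos, f"{rng.randint(1,5)}S{core}{rng.randint(1,5)}S")
        assert counting.strip_soft_clips(bare) == counting.strip_soft_clips(clipped)
        assert counting.assign_read(bare, ann) == counting.assign_read(clipped, ann)


# ---------------------------------------------------------------------------
# assign_read
# ---------------------------------------------------------------------------


def test_assign_inside_feature(toy_annotation):
    assert counting.assign_read(_rec(10, "10M"), toy_annotation) == "A"


def test_assign_straddling_is_ambiguous(toy_annotation):
    assert counting.assign_read(_rec(495, "10M"), toy_annotation) == AMBIGUOUS


def test_assign_intergenic_is_unassigned(toy_annotation):
    assert counting.assign_read(_rec(930, "20M"), toy_annotation) == UNASSIGNED


def test_assign_single_base_overlap(toy_annotation):
    # span [499, 509) touches A by exactly 1 nt and B by 9 -> ambiguous
    assert counting.assign_read(_rec(500, "10M"), toy_annotation) == AMBIGUOUS
    # span [899, 929) touches only B by 1 nt
    assert counting.assign_read(_rec(900, "30M"), toy_annotation) == "B"


# ---------------------------------------------------------------------------
# count_features
# ---------------------------------------------------------------------------


def test_count_features_hand_fixture(toy_annotation):
    reads = [
        _rec(10, "10M", qid="a1"),
        _rec(100, "2S20M", qid="a2"),
        _rec(400, "30M", qid="a3"),
        _rec(495, "10M", qid="amb"),
        _rec(930, "20M", qid="un"),
    ]
    table = counting.count_features(reads, toy_annotation, {"lib": LibraryMeta("RPF", "KO")})
    assert table.counts.loc["A", "lib"] == 3
    assert table.counts.loc["B", "lib"] == 0
    assert table.qc.loc["lib", "ambiguous"] == 1
    assert table.qc.loc["lib", "unassigned"] == 1
    assert table.qc.loc["lib"].sum() == len(reads)


def test_count_features_empty_stream(toy_annotation):
    table = counting.count_features([], toy_annotation, {"lib": LibraryMeta("RNA", "rescue")})
    assert (table.counts.values == 0).all()


def test_count_features_unknown_library(toy_annotation):
    with pytest.raises(ValueError, match="unknown library"):
        counting.count_features(
            [_rec(10, "10M", lib="ghost")], toy_annotation, {"lib": LibraryMeta("RPF", "KO")}
        )


def test_count_additivity_and_permutation(toy_annotation):
    rng = random.Random(1)
    reads = [
        _rec(rng.randint(1, 1300), "25M", qid=f"r{i}")
        for i in range(300)
    ]
    libs = {"lib": LibraryMeta("RPF", "KO")}
    once = counting.count_features(reads, toy_annotation, libs)
    twice = counting.count_features(reads + reads, toy_annotation, libs)
    assert (twice.counts.values == 2 * once.counts.values).all()
    shuffled = reads[:]
    rng.shuffle(shuffled)
    perm = counting.count_features(shuffled, toy_annotation, libs)
    assert perm.counts.equals(once.counts)
    assert perm.qc.equals(once.qc)


def test_conservation_invariant(annotation, preset, contrast_libraries):
    """assigned + ambiguous + unassigned == stream size for every library."""
    specs, meta = contrast_libraries(5_000, seed=4)
    from itertools import chain

    stream = chain.from_iterable(sd.sample_library(s, annotation, preset) for s in specs)
    table = counting.count_features(stream, annotation, meta)
    for lib in meta:
        assert table.qc.loc[lib].sum() == 5_000


# ---------------------------------------------------------------------------
# length distributions
# ---------------------------------------------------------------------------


def test_length_distribution_counts_and_fractions(toy_annotation):
    reads = [_rec(10, "30M"), _rec(50, "30M"), _rec(100, "34M"), _rec(200, "34M")]
    dist = counting.length_distribution(reads, toy_annotation)
    assert dist.counts.loc[30, "lib"] == 2
    assert dist.counts.loc[34, "lib"] == 2
    frac = dist.fractions()
    assert frac.loc[30, "lib"] == pytest.approx(0.5)
    assert counting.mean_protected_length(dist, "lib") == pytest.approx(32.0)


def test_length_distribution_excludes_non_target(toy_annotation):
    reads = [_rec(10, "30M"), _rec(1100, "30M")]  # second maps to spike-in
    dist = counting.length_distribution(reads, toy_annotation, target_only=True)
    assert dist.counts["lib"].sum() == 1
    both = counting.length_distribution(reads, toy_annotation, target_only=False)
    assert both.counts["lib"].sum() == 2


def test_empty_library_flagged_not_nan(toy_annotation):
    dist = counting.length_distribution(
        [_rec(10, "30M")], toy_annotation, libraries=["lib", "empty"]
    )
    assert dist.empty_libraries == ["empty"]
    with pytest.raises(ValueError, match="empty"):
        dist.fractions()
    with pytest.raises(ValueError):
        counting.mean_protected_length(dist, "empty")


def test_singleton_mean_length(toy_annotation):
    dist = counting.length_distribution([_rec(10, "31M")], toy_annotation)
    assert counting.mean_protected_length(dist, "lib") == 31.0


def test_ko_fragments_shorter_than_rescue(annotation, preset):
    """Simulated KO libraries show the shortened protected fragments."""
    from itertools import chain

    n = 100_000
    rescue = sd.LibrarySpec("rpf_rescue", "RPF", "rescue", n, seed=6, rpf_length_mean=33.0)
    ko = sd.LibrarySpec("rpf_KO", "RPF", "KO", n, seed=7, rpf_length_mean=31.0)
    dist = counting.length_distribution(
        chain(sd.sample_library(rescue, annotation, preset),
              sd.sample_library(ko, annotation, preset)),
        annotation,
    )
    m_res = counting.mean_protected_length(dist, "rpf_rescue")
    m_ko = counting.mean_protected_length(dist, "rpf_KO")
    assert m_ko < m_res
    assert abs((m_res - m_ko) - 2.0) < 0.1
    frac = dist.fractions()
    assert np.allclose(frac.sum(axis=0), 1.0)
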