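"""Read classification, category conservation, and tag collapsing."""

import numpy as np
import pytest

from srnamir.preprocess import (
    FastqFormatError,
    Read,
    UniqueTag,
    classify_and_trim,
    length_distribution,
    merge_libraries,
    read_collapsed_fasta,
    write_collapsed_fasta,
)

A3 = "TCGTATGCCGTCTTCTGCTTG"
A5 = "GTTCAGAGTTCTACAGTCCGACGATC"
Q = [38]


def make(seq):
    return Read(seq, [38] * len(seq))


def run(reads, **kw):
    return classify_and_trim(reads, A3, A5, **kw)


def test_hand_built_fixture_classifies_each_category():
    insert16 = "ACGTACGTACGTACGT"
    clean = ["ACGTACGTACGTACGTACGTA", "GGGCATCGATCGTAGCTAGCT",
             "TTGCATCGGATCGGATCGGAT", "CCGATCGATCGATTGCATGCA"]
    reads = (
        [make(A3), make(A3 + "AAAA")]                       # adapter-only
        + [make("ACGT" * 9)]                                # no adapter, 36 nt
        + [make(A5 + "ACGTACGTAC" + A3)]                    # 5' contaminant
        + [make(insert16 + A3)]                             # trims to 16 nt
        + [make("A" * 24 + A3)]                             # poly(A)
        + [make(s + A3) for s in clean]
    )
    tags, stats = run(reads)
    assert stats.insert_null == 2
    assert stats.adapter3_null == 1
    assert stats.adapter5_contaminant == 1
    assert stats.smaller_than_min == 1
    assert stats.polyA == 1
    assert stats.clean == 4
    assert stats.conserved()
    assert sorted(t.sequence for t in tags) == sorted(clean)


def test_adapter_only_read_is_insert_null():
    _, stats = run([make(A3)])
    assert stats.insert_null == 1


def test_raw_read_without_adapter_is_adapter3_null():
    _, stats = run([make("ACGT" * 10)])
    assert stats.adapter3_null == 1


def test_empty_input_gives_zero_stats():
    tags, stats = run([])
    assert tags == [] and stats.raw == 0 and stats.conserved()


def test_malformed_record_raises_with_index():
    reads = [make("ACGT" + A3), make("ACNGT" + A3)]
    with pytest.raises(FastqFormatError, match="record 1"):
        run(reads)


def test_quality_floor_filters_reads():
    low = Read("ACGTACGTACGTACGTACGTA" + A3, [5] * 42)
    _, stats = run([low], quality_floor=20.0)
    assert stats.raw == 1 and stats.high_quality == 0 and stats.conserved()


def test_trimming_is_idempotent_on_clean_tags():
    clean = ["ACGTACGTACGTACGTACGTA", "GGGCATCGATCGTAGCTAGCT"]
    tags, _ = run([make(s + A3) for s in clean])
    retags, restats = run([Read(t.sequence) for t in tags])
    assert restats.clean == len(clean)
    assert sorted(t.sequence for t in retags) == sorted(clean)


def test_category_conservation_on_random_reads(rng):
    reads = []
    for _ in range(300):
        n = int(rng.integers(5, 40))
        reads.append(make("".join(rng.choice(list("ACGT"), n))))
    _, stats = run(reads)
    assert stats.conserved()


def test_adapter_detection_tolerates_one_mismatch_in_extension():
    mutated = A3[:8] + "A" + A3[9:]  # seed intact, one extension mismatch
    tags, stats = run([make("ACGTACGTACGTACGTACGTA" + mutated)])
    assert stats.clean == 1
    assert tags[0].sequence == "ACGTACGTACGTACGTACGTA"


def test_length_distribution_single_and_fractions():
    t24 = UniqueTag("A" * 24, 10, 0)
    assert length_distribution([t24]) == {24: (10, 1.0)}
    t21 = UniqueTag("C" * 21, 20, 10)
    dist = length_distribution([t21, UniqueTag("G" * 24, 30, 40)])
    assert dist[21] == (30, pytest.approx(0.3))
    assert dist[24] == (70, pytest.approx(0.7))
    assert sum(f for _, f in dist.values()) == pytest.approx(1.0, abs=1e-9)


def test_length_distribution_empty_raises():
    with pytest.raises(ValueError):
        length_distribution([])


def test_simulated_library_mode_is_24nt(small_bundle):
    tags_br, _ = classify_and_trim(
        small_bundle.reads_BR, small_bundle.config.adapter3,
        small_bundle.config.adapter5, library="BR")
    dist = length_distribution(tags_br)
    mode = max(dist, key=lambda L: dist[L][0])
    assert mode == 24


def test_merge_and_collapsed_fasta_roundtrip(tmp_path):
    br = [UniqueTag("ACGTACGTACGTACGTAA", count_BR=3)]
    bs = [UniqueTag("ACGTACGTACGTACGTAA", count_BS=5),
          UniqueTag("GGGTACGTACGTACGTAA", count_BS=1)]
    merged = merge_libraries(br, bs)
    assert {(t.sequence, t.count_BR, t.count_BS) for t in merged} == {
        ("ACGTACGTACGTACGTAA", 3, 5), ("GGGTACGTACGTACGTAA", 0, 1)}
    path = tmp_path / "tags.fasta"
    write_collapsed_fasta(merged, path)
    assert merged == read_collapsed_fasta(path)
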