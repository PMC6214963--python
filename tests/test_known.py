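"""Known-miRNA matching and the family expression table.

The published family table (counts, totals, and two-decimal BS/BR ratios)
ships with the package as a fixture; every row must be reproducible from its
own count pair.
"""

from importlib import resources

import pytest

from srnamir._seq import SequenceError
from srnamir.known import (
    FamilyExpressionRow,
    MatureRecord,
    assign_tags,
    build_family_table,
    match_known,
    round_ratio,
)
from srnamir.preprocess import UniqueTag

DB = [
    MatureRecord("miR1a", "miR1", True, "ACGTACGTACGTACGTACGTA"),
    MatureRecord("miR1b", "miR1", True, "ACGTACGTACGTACGTACCCA"),
    MatureRecord("miR2a", "miR2", False, "GGGTTTCCCAAAGGGTTTCCC"),
]


def load_family_fixture():
    text = (resources.files("srnamir.data") / "known_family_counts.tsv").read_text()
    rows = []
    for line in text.strip().splitlines()[1:]:
        f, members, br, bs, total, ratio, cons = line.split("\t")
        rows.append((f, int(members), int(br), int(bs), int(total), ratio,
                     bool(int(cons))))
    return rows


def test_identical_tag_matches_with_zero_mismatches():
    hits = match_known("ACGTACGTACGTACGTACGTA", DB)
    assert [h.mature_id for h in hits if h.mismatches == 0] == ["miR1a"]
    assert all(h.best for h in hits if h.mismatches == 0)


def test_distance_two_matches_distance_three_does_not():
    two_off = "TTGTACGTACGTACGTACGTA"
    assert any(h.mismatches == 2 for h in match_known(two_off, DB))
    three_off = "TTTTACGTACGTACGTACGTA"
    assert match_known(three_off, DB) == []


def test_length_mismatch_never_matches():
    assert match_known("ACGTACGTACGTACGTACGT", DB) == []


def test_invalid_tag_raises():
    with pytest.raises(SequenceError):
        match_known("ACGTNACGTACGTACGTACGT", DB)


def test_multi_family_tie_breaks_lexicographically():
    db = [
        MatureRecord("miRBa", "miRB", True, "AAAACCCCGGGGTTTTAAAAC"),
        MatureRecord("miRAa", "miRA", True, "AAAACCCCGGGGTTTTAAAAC"),
    ]
    tags = [UniqueTag("AAAACCCCGGGGTTTTAAAAC", 5, 5)]
    best = assign_tags(tags, db)
    assert best["AAAACCCCGGGGTTTTAAAAC"].family == "miRA"


@pytest.mark.parametrize("br,bs,total,ratio", [
    (2305, 1840, 4145, "0.80"),   # miR159
    (8218, 9997, 18215, "1.22"),  # miR396
    (1984, 883, 2867, "0.45"),    # miR399
    (156, 18, 174, "0.12"),       # miR858
    (3, 5, 8, "1.67"),            # miR502
    (4, 0, 4, "0.00"),            # miR408: BS=0 prints 0.00
    (0, 1, 1, "—"),               # miR173: BR=0 prints an em dash
])
def test_family_row_totals_and_ratios(br, bs, total, ratio):
    row = FamilyExpressionRow("f", 1, br, bs)
    assert row.total == total
    assert row.ratio_str == ratio


def test_every_published_family_row_is_reproduced():
    for fam, members, br, bs, total, ratio, _ in load_family_fixture():
        row = FamilyExpressionRow(fam, members, br, bs)
        assert row.total == total, fam
        assert row.ratio_str == ratio, fam


def test_ratio_rounds_half_away_from_zero():
    assert round_ratio(1, 8) == 0.13  # 0.125 rounds up, not to even


def test_swapping_libraries_inverts_the_ratio():
    for _, _, br, bs, _, _, _ in load_family_fixture():
        if br == 0 or bs == 0:
            continue
        r = FamilyExpressionRow("f", 1, br, bs).ratio
        r_swapped = FamilyExpressionRow("f", 1, bs, br).ratio
        assert r_swapped == pytest.approx(1.0 / r, rel=0.05)


def test_build_family_table_aggregates_best_matches():
    tags = [
        UniqueTag("ACGTACGTACGTACGTACGTA", 10, 20),  # = miR1a
        UniqueTag("ACGTACGTACGTACGTACCCA", 5, 0),    # = miR1b
        UniqueTag("GGGTTTCCCAAAGGGTTTCCC", 0, 7),    # = miR2a
    ]
    rows = build_family_table(assign_tags(tags, DB), tags)
    by_family = {r.family: r for r in rows}
    assert by_family["miR1"].members == 2
    assert by_family["miR1"].reads_BR == 15
    assert by_family["miR1"].reads_BS == 20
    assert by_family["miR1"].total == 35
    assert by_family["miR2"].reads_BS == 7
    assert not by_family["miR2"].conserved


def test_family_table_referential_integrity():
    from srnamir.known import KnownMatch

    with pytest.raises(ValueError):
        build_family_table(
            {"ACGTACGTACGTACGTACGTA": KnownMatch(
                "ACGTACGTACGTACGTACGTA", "miR1a", "miR1", 0, True)}, [])


def test_no_tag_counted_twice_across_families(small_bundle):
    db = [MatureRecord(i, f, c, s) for i, f, c, s in small_bundle.mature_db]
    tags = [UniqueTag(s, 3, 4) for _, _, _, s in small_bundle.mature_db]
    rows = build_family_table(assign_tags(tags, db), tags)
    assert sum(r.reads_BR for r in rows) <= sum(t.count_BR for t in tags)
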