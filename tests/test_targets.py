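"""Target-site scoring and scanning against explicit enumeration."""

import numpy as np
import pytest

from srnamir._seq import revcomp
from srnamir.targets import (
    Column,
    best_expectation,
    scan_transcripts,
    score_columns,
    score_duplex,
)


def identity_alignment(L):
    """miRNA position i pairs site position L-i (site written 5'->3')."""
    return [(i, L - i) for i in range(1, L + 1)]


def naive_best_expectation(mirna, transcript, max_gap=1):
    """Enumerate every <=1-gap alignment explicitly; independent of the DP."""
    L = len(mirna)
    best = float("inf")

    def score(cols):
        return score_columns(mirna, cols)

    for end in range(len(transcript)):
        if end - L + 1 >= 0:  # ungapped
            cols = [Column(i + 1, transcript[end - i], i + 1) for i in range(L)]
            best = min(best, score(cols))
        if max_gap < 1:
            continue
        if end - L + 2 >= 0:  # one miRNA-side gap at position k
            for k in range(1, L + 1):
                cols, j = [], end
                for i in range(1, L + 1):
                    if i == k:
                        cols.append(Column(i, None, i))
                    else:
                        cols.append(Column(i, transcript[j], i))
                        j -= 1
                best = min(best, score(cols))
        if end - L >= 0:  # one transcript-side bulge before position k
            for k in range(1, L + 2):
                cols, j = [], end
                for i in range(1, L + 1):
                    if i == k:
                        cols.append(Column(None, transcript[j], min(i, L)))
                        j -= 1
                    cols.append(Column(i, transcript[j], i))
                    j -= 1
                if k == L + 1:
                    cols.append(Column(None, transcript[j], L))
                best = min(best, score(cols))
    return best


MIRNA = "ACGTACGTACGTACGTACGTA"


def test_exact_complement_scores_zero():
    site = revcomp(MIRNA)
    assert score_duplex(MIRNA, site, identity_alignment(len(MIRNA))) == 0.0


def test_seed_mismatch_is_doubled():
    site = list(revcomp(MIRNA))
    # miRNA position 5 pairs site position L-5 (0-based L-5 in 5'->3' site)
    pos = len(MIRNA) - 5
    site[pos] = {"A": "C", "C": "A", "G": "A", "T": "C"}[site[pos]]
    e = score_duplex(MIRNA, "".join(site), identity_alignment(len(MIRNA)))
    assert e == pytest.approx(2.0)


def test_wobble_outside_seed_scores_half():
    m = "ACGTACGTACGTACGGACGTA"  # position 15 is G
    site = list(revcomp(m))
    site[len(m) - 15] = "T"  # G:U wobble at miRNA position 15
    e = score_duplex(m, "".join(site), identity_alignment(len(m)))
    assert e == pytest.approx(0.5)


def test_score_duplex_requires_full_coverage():
    with pytest.raises(ValueError):
        score_duplex(MIRNA, revcomp(MIRNA), identity_alignment(len(MIRNA))[:-1])


def test_perfect_site_is_found_with_cleavage_call():
    t = "TTTGGATTACCA" + revcomp(MIRNA) + "GGCATTA"
    sites = scan_transcripts(MIRNA, {"tr": t})
    assert len(sites) == 1
    s = sites[0]
    assert (s.start, s.end) == (13, 33)
    assert s.expectation == 0.0
    assert s.inhibition == "cleavage"


def test_central_mismatch_gives_translation_call():
    site = list(revcomp(MIRNA))
    pos = len(MIRNA) - 10  # pairs miRNA position 10
    site[pos] = {"A": "C", "C": "A", "G": "A", "T": "C"}[site[pos]]
    t = "GAGTGTTAAT" + "".join(site) + "CCGGTAAGTG"
    sites = scan_transcripts(MIRNA, {"tr": t}, cutoff=3.0)
    assert sites and sites[0].inhibition == "translation"


def test_two_planted_sites_both_reported():
    good = revcomp(MIRNA)
    weak = list(good)
    weak[2] = {"A": "C", "C": "A", "G": "A", "T": "C"}[weak[2]]  # outside seed
    t = "ACCTGA" + good + "TGTCAGTCAGTA" + "".join(weak) + "GGA"
    sites = scan_transcripts(MIRNA, {"tr": t}, cutoff=3.0)
    assert len(sites) == 2
    assert [s.expectation for s in sites] == [0.0, pytest.approx(1.0)]


def test_scanner_matches_enumeration_on_random_sequence(rng):
    for trial in range(25):
        L = int(rng.integers(19, 23))
        m = "".join(rng.choice(list("ACGT"), L))
        t = "".join(rng.choice(list("ACGT"), int(rng.integers(40, 120))))
        if trial % 3 == 0:  # plant a near-complement
            site = list(revcomp(m))
            site[5] = "ACGT"[int(rng.integers(0, 4))]
            pos = int(rng.integers(0, len(t) - len(site)))
            t = t[:pos] + "".join(site) + t[pos + len(site):]
        assert best_expectation(m, t) == pytest.approx(
            naive_best_expectation(m, t), abs=1e-9)


def test_raising_cutoff_never_removes_sites(rng):
    m = "".join(rng.choice(list("ACGT"), 21))
    t = "".join(rng.choice(list("ACGT"), 300))
    t = t[:50] + revcomp(m) + t[50 + len(m):]
    lo = scan_transcripts(m, {"tr": t}, cutoff=2.0)
    hi = scan_transcripts(m, {"tr": t}, cutoff=5.0)
    lo_keys = {(s.start, s.end) for s in lo}
    hi_keys = {(s.start, s.end) for s in hi}
    assert lo_keys <= hi_keys


def test_empty_transcripts_yield_empty_list():
    assert scan_transcripts(MIRNA, {}) == []
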