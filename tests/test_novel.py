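"""Candidate excision and the stem-loop acceptance screen."""

import numpy as np
import pytest

from srnamir._seq import revcomp
from srnamir.novel import (
    Criteria,
    MiRNAAnnotation,
    PrecursorCandidate,
    Rejection,
    discover,
    evaluate_candidate,
    excise_candidates,
    map_tags,
)
from srnamir.preprocess import UniqueTag
from srnamir.simulate import plant_hairpin


def embed(hp, rng, flank=150):
    left = "".join(rng.choice(list("ACGT"), flank))
    right = "".join(rng.choice(list("ACGT"), flank))
    return left + hp.sequence + right, flank + hp.mature_start


def evaluate_at(hp, rng, criteria=Criteria(), counts=(50, 50)):
    ref, pos = embed(hp, rng)
    tag = UniqueTag(hp.mature, *counts)
    cands = excise_candidates(tag, [("r", pos, "+")], {"r": ref})
    results = [evaluate_candidate(c, (), criteria) for c in cands]
    accepted = [r for r in results if isinstance(r, MiRNAAnnotation)]
    return accepted, results


def test_excision_window_arithmetic():
    ref = {"r": "A" * 1000}
    tag = UniqueTag("G" * 21, 5, 5)
    cands = excise_candidates(tag, [("r", 100, "+")], ref)
    spans = {(c.arm, c.start, c.end) for c in cands}
    assert ("5p", 90, 281) in spans
    assert ("3p", 0, 131) in spans  # 100-160 clips to 0


def test_no_hits_yield_no_candidates():
    assert excise_candidates(UniqueTag("G" * 21, 1, 1), [], {"r": "A" * 100}) == []


def test_map_tags_reports_both_strands():
    core = "GGCATCGATTCAGGATACGCA"
    ref = {"r": "TTTT" + core + "GGGG"}
    fwd = UniqueTag(core, 1, 1)
    rev = UniqueTag(revcomp(core), 1, 1)
    hits = map_tags([fwd, rev], ref)
    assert hits[fwd.sequence] == [("r", 4, "+")]
    assert hits[rev.sequence] == [("r", 4, "-")]


def test_planted_hairpin_is_accepted(rng):
    hp = plant_hairpin("GCTAGCATCGGATCCGTAGCA", 1, 6, rng)
    accepted, _ = evaluate_at(hp, rng)
    assert accepted
    best = min(accepted, key=lambda a: a.MFE)
    assert best.mature_sequence == hp.mature
    assert best.MFE <= -18.0
    assert best.LP >= 39


def test_published_novel_mature_builds_an_accepted_hairpin(rng):
    hp = plant_hairpin("TCGGACCAGGCTTCATTCCCC", 1, 6, rng)
    accepted, _ = evaluate_at(hp, rng)
    assert accepted


def test_truncated_duplex_rejected_for_min_overlap():
    # star complements only the first 12 mature bases: <16 bp can ever pair
    # (the loop and pad are poly(A) so no incidental helices form)
    m = "GCTAGCATCGGATCCGTAGCA"
    seq = m + "AAACAA" + revcomp(m[:12]) + "A" * 12
    cand = PrecursorCandidate("r", 0, len(seq), "+", seq,
                              UniqueTag(m, 9, 9), 0, "5p")
    res = evaluate_candidate(cand)
    assert isinstance(res, Rejection)
    assert res.reason == "min_overlap"


def test_overlong_mature_rejected_before_folding():
    m = "G" * 26
    cand = PrecursorCandidate("r", 0, 60, "+", "A" * 60,
                              UniqueTag(m, 9, 9), 0, "5p")
    res = evaluate_candidate(cand)
    assert isinstance(res, Rejection) and res.reason == "mature_length"


def test_star_requirement_rejects_without_star_reads(rng):
    hp = plant_hairpin("GCTAGCATCGGATCCGTAGCA", 0, 6, rng)
    accepted, results = evaluate_at(hp, rng, Criteria(require_star=True))
    assert not accepted
    assert any(isinstance(r, Rejection) and r.reason == "no_star"
               for r in results)


def test_star_evidence_detected_from_window_tags(rng):
    hp = plant_hairpin("GCTAGCATCGGATCCGTAGCA", 0, 6, rng)
    ref, pos = embed(hp, rng)
    mature = UniqueTag(hp.mature, 50, 50)
    star_tag = UniqueTag(hp.star, 4, 3)
    cands = excise_candidates(mature, [("r", pos, "+")], {"r": ref})
    hits = [evaluate_candidate(c, [star_tag], Criteria(require_star=True))
            for c in cands]
    assert any(isinstance(r, MiRNAAnnotation) and r.star_detected for r in hits)


def test_loosening_a_threshold_never_shrinks_the_accepted_set(rng):
    strict = Criteria()
    loose = Criteria(min_overlap=14, max_bulges=5, max_energy=-12.0,
                     max_asymmetry=6, min_mfei=0.6)
    n_strict = n_loose = 0
    for i in range(6):
        hp = plant_hairpin("GCTAGCATCGGATCCGTAGCA", i % 3, 5 + i % 4, rng)
        a1, _ = evaluate_at(hp, rng, strict)
        a2, _ = evaluate_at(hp, rng, loose)
        n_strict += bool(a1)
        n_loose += bool(a2)
        assert bool(a1) <= bool(a2)
    assert n_loose >= n_strict


def test_discover_names_and_collapses(small_bundle):
    truth_novel = {t.sequence for t in small_bundle.truth if t.kind == "novel"}
    tags = [UniqueTag(s, 40, 40) for s in truth_novel]
    annotations, _ = discover(tags, small_bundle.references)
    assert {a.mature_sequence for a in annotations} == truth_novel
    assert all(a.name.startswith("Lc-miRn") for a in annotations)
    assert len({a.name for a in annotations}) == len(annotations)
    for a in annotations:
        assert a.length == len(a.mature_sequence)
        assert 18 <= a.length <= 25
        assert a.MFE <= -18.0
        assert a.LP == len(a.precursor_sequence)


def test_low_count_tags_are_not_considered(small_bundle):
    truth_novel = sorted(t.sequence for t in small_bundle.truth
                         if t.kind == "novel")
    tags = [UniqueTag(truth_novel[0], 1, 1)]
    annotations, _ = discover(tags, small_bundle.references,
                              Criteria(min_count=5))
    assert annotations == []
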