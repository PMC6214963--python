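"""Novel-miRNA discovery from unannotated tags mapped to reference sequence.

For every perfect-match hit of an unannotated tag, two candidate precursor
windows are excised — one treating the tag as the 5p arm (short 5′ flank,
long 3′ flank) and one as the 3p arm — folded with the built-in folder, and
screened against stem-loop criteria: mature length 18–25 nt, mature on a stem
arm (not the terminal loop), at least 16 bp pairing between mature and star,
at most four bulges in the duplex, and precursor MFE at or below
−18 kcal/mol. Read-level evidence for the star sequence (a tag sitting on the
computed star interval within a ±2 nt shift) is recorded and raises
confidence, but is not required by default: star reads are usually degraded
away, so requiring them would discard most genuine candidates.

Reported precursors are trimmed to the hairpin extent (the span of the mature
and star intervals in the excised window) and re-folded, so the precursor
length LP and MFE describe the hairpin itself, not the arbitrary excision
window.
"""

from __future__ import annotations

import numpy as np

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

from ._seq import revcomp
from .fold import FoldResult, duplex_stats, fold
from .preprocess import UniqueTag

DEFAULT_FLANK = 160
_ARM_NEAR_FLANK = 10
_MIN_WINDOW = 50
# geometric floor: two 18-nt arms around a 3-nt terminal loop
_MIN_PRECURSOR = 39


@dataclass(frozen=True)
class Criteria:
    """Thresholds of the stem-loop screen (all configurable)."""

    mature_len_min: int = 18
    mature_len_max: int = 25
    min_overlap: int = 16
    max_bulges: int = 4
    max_asymmetry: int = 4
    max_loop: int = 35
    max_energy: float = -18.0
    min_mfei: float = 0.85
    min_precursor: int = _MIN_PRECURSOR
    require_star: bool = False
    star_shift: int = 2
    min_count: int = 5


@dataclass(frozen=True)
class PrecursorCandidate:
    """An excised window with the mature tag placed on one arm."""

    ref_id: str
    start: int            # 0-based half-open on the reference, plus strand
    end: int
    strand: str
    sequence: str
    mature: UniqueTag
    mature_offset: int    # position of the mature inside ``sequence``
    arm: str              # "5p" | "3p" hypothesis
    fold: FoldResult | None = None


@dataclass(frozen=True)
class MiRNAAnnotation:
    """An accepted novel miRNA (one table row of the report)."""

    name: str
    arm: str
    mature_sequence: str
    length: int
    LP: int
    MFE: float
    reads_BR: int
    reads_BS: int
    star_detected: bool
    location: str
    precursor_sequence: str
    precursor_start: int   # 0-based on the reference, plus strand
    mature_start: int      # 0-based on the reference, plus strand
    strand: str
    dot_bracket: str


@dataclass(frozen=True)
class Rejection:
    """A machine-readable reason why a candidate failed the screen."""

    candidate: PrecursorCandidate
    reason: str


def map_tags(
    tags: Sequence[UniqueTag], refs: Mapping[str, str], both_strands: bool = True
) -> dict[str, list[tuple[str, int, str]]]:
    """Perfect-match positions of each tag: seq -> [(ref, pos, strand)].

    Minus-strand positions are reported on the plus strand of the reference
    (position of the reverse-complemented tag). Tags hitting nowhere are
    absent from the result.
    """
    hits: dict[str, list[tuple[str, int, str]]] = {}
    for tag in tags:
        found: list[tuple[str, int, str]] = []
        rc = revcomp(tag.sequence)
        for rid in sorted(refs):
            seq = refs[rid]
            for query, strand in ((tag.sequence, "+"), (rc, "-")):
                if strand == "-" and not both_strands:
                    continue
                p = seq.find(query)
                while p >= 0:
                    found.append((rid, p, strand))
                    p = seq.find(query, p + 1)
        if found:
            hits[tag.sequence] = found
    return hits


def excise_candidates(
    tag: UniqueTag,
    hits: Iterable[tuple[str, int, str]],
    refs: Mapping[str, str],
    flank5: int = DEFAULT_FLANK,
    flank3: int = DEFAULT_FLANK,
) -> list[PrecursorCandidate]:
    """Excise the 5p- and 3p-arm windows around every hit.

    Windows are clipped to reference bounds; a window shorter than 50 nt
    after clipping is discarded. Zero hits yield an empty list.
    """
    out: list[PrecursorCandidate] = []
    L = len(tag.sequence)
    for rid, pos, strand in hits:
        ref = refs[rid]
        tag_end = pos + L
        for arm, w0, w1 in (
            ("5p", pos - _ARM_NEAR_FLANK, tag_end + flank3),
            ("3p", pos - flank5, tag_end + _ARM_NEAR_FLANK),
        ):
            w0c, w1c = max(0, w0), min(len(ref), w1)
            if w1c - w0c < _MIN_WINDOW:
                continue
            window = ref[w0c:w1c]
            offset = pos - w0c
            if strand == "-":
                window = revcomp(window)
                offset = (w1c - w0c) - (offset + L)
                arm_oriented = {"5p": "3p", "3p": "5p"}[arm]
            else:
                arm_oriented = arm
            out.append(PrecursorCandidate(
                rid, w0c, w1c, strand, window, tag, offset, arm_oriented,
            ))
    return out


def _star_evidence(
    precursor: str,
    star0: int,
    star1: int,
    window_tags: Iterable[UniqueTag],
    mature_seq: str,
    shift: int,
) -> bool:
    """True iff some other tag sits on the star interval within ±shift nt."""
    for t in window_tags:
        if t.sequence == mature_seq:
            continue
        p = precursor.find(t.sequence)
        while p >= 0:
            if abs(p - star0) <= shift and abs(p + len(t.sequence) - star1) <= shift:
                return True
            p = precursor.find(t.sequence, p + 1)
    return False


_MIN_LOOP_SEP = 3
_N_STAR_TRIALS = 3

_REASON_ORDER = ("no_hairpin", "precursor_too_short", "mature_in_loop",
                 "star_overlap", "loop_too_long", "min_overlap",
                 "max_bulges", "asymmetry", "mfe", "mfei", "no_star")


def _trial_extents(cand: PrecursorCandidate,
                   criteria: Criteria) -> list[tuple[int, int]]:
    """Candidate precursor extents inside the window, star-anchored.

    The star arm is located by a gapped complementarity scan of the flank on
    the hypothesised star side (the same alignment DP the target scanner
    uses, without seed weighting, allowing up to ``max_bulges`` gaps); the
    best few anchors each define one trial precursor spanning mature and
    star.
    """
    from . import targets as tg

    w = cand.sequence
    mature = cand.mature.sequence
    m0, L = cand.mature_offset, len(mature)
    max_gap = criteria.max_bulges
    extents: list[tuple[int, int]] = []
    reach = criteria.max_loop + L + max_gap
    if cand.arm == "5p":
        off = m0 + L + _MIN_LOOP_SEP
        region = w[off: m0 + L + reach]
        if len(region) >= L - max_gap:
            scores = tg._best_scores(mature, region, max_gap,
                                     seed_double=False)
            for e in np.argsort(scores, kind="stable")[:_N_STAR_TRIALS]:
                if not np.isfinite(scores[e]):
                    continue
                # anchor = star pairing 3' end; +2 nt 3' overhang past it
                extents.append((m0, min(len(w), off + int(e) + 1 + 2)))
    else:
        roff = max(0, m0 - reach)
        region = w[roff: max(0, m0 - _MIN_LOOP_SEP)]
        if len(region) >= L - max_gap:
            scores = tg._best_scores(mature, region, max_gap,
                                     seed_double=False)
            for e in np.argsort(scores, kind="stable")[:_N_STAR_TRIALS]:
                if not np.isfinite(scores[e]):
                    continue
                res = tg._align_end(mature, region, int(e), max_gap,
                                    seed_double=False)
                if res is None or res[1] < 0:
                    continue
                extents.append((roff + res[1], m0 + L))
    seen: set[tuple[int, int]] = set()
    return [x for x in extents if not (x in seen or seen.add(x))]


def evaluate_candidate(
    cand: PrecursorCandidate,
    window_tags: Sequence[UniqueTag] = (),
    criteria: Criteria = Criteria(),
    folder: Callable[[str], FoldResult] = fold,
) -> MiRNAAnnotation | Rejection:
    """Screen one candidate; return an annotation or a reasoned rejection.

    Several star-anchored precursor extents are folded; the lowest-MFE
    extent passing every criterion wins. On rejection, the reason of the
    trial that got furthest through the screen is reported.
    """
    L = len(cand.mature.sequence)
    if not criteria.mature_len_min <= L <= criteria.mature_len_max:
        return Rejection(cand, "mature_length")
    best: MiRNAAnnotation | None = None
    deepest = 0

    def _fail(reason: str) -> None:
        nonlocal deepest
        deepest = max(deepest, _REASON_ORDER.index(reason))

    for p0, p1 in _trial_extents(cand, criteria):
        precursor = cand.sequence[p0:p1]
        if len(precursor) < criteria.min_precursor:
            # below the geometric floor of two arms around a terminal loop
            _fail("precursor_too_short")
            continue
        pf = folder(precursor)
        m_off = cand.mature_offset - p0
        pds = duplex_stats(pf, m_off, L)
        if pds.in_loop:
            _fail("mature_in_loop")
            continue
        star_pair0 = pds.star_start
        star_pair1 = pds.star_start + pds.star_span
        if not (star_pair0 >= m_off + L + _MIN_LOOP_SEP
                or star_pair1 + _MIN_LOOP_SEP <= m_off):
            # partners fall inside or against the mature itself: the fold is
            # self-pairing, not a two-arm duplex across a terminal loop
            _fail("star_overlap")
            continue
        loop_gap = (star_pair0 - (m_off + L) if star_pair0 > m_off
                    else m_off - star_pair1)
        if loop_gap > criteria.max_loop:
            # space between mature and star capped, as in stem-loop
            # predictors: a distant pseudo-star across a folded spacer is
            # not a miRNA/miRNA* duplex
            _fail("loop_too_long")
            continue
        if pds.overlap_bp < criteria.min_overlap:
            _fail("min_overlap")
            continue
        if pds.n_bulges > criteria.max_bulges:
            _fail("max_bulges")
            continue
        if pds.asymmetry > criteria.max_asymmetry:
            # the paired star span must mirror the mature span: a genuine
            # miRNA/miRNA* duplex tolerates only small asymmetries
            _fail("asymmetry")
            continue
        if pf.energy > criteria.max_energy:
            _fail("mfe")
            continue
        gc = sum(precursor.count(b) for b in "GC") / len(precursor)
        mfei = (100.0 * pf.energy / len(precursor)) / (100.0 * gc) if gc else 0.0
        if mfei > -criteria.min_mfei:
            # energy density screen (MFE index): genuine pre-miRNAs fold
            # much more stably per nucleotide than other sequence
            _fail("mfei")
            continue
        star = _star_evidence(precursor, pds.star_start, pds.star_end,
                              window_tags, cand.mature.sequence,
                              criteria.star_shift)
        if criteria.require_star and not star:
            _fail("no_star")
            continue
        arm = "5p" if cand.mature_offset - p0 < pds.star_start else "3p"
        if cand.strand == "+":
            prec_start = cand.start + p0
            mat_start = cand.start + cand.mature_offset
        else:  # offsets are in the reverse-complemented window
            prec_start = cand.end - p1
            mat_start = cand.end - cand.mature_offset - L
        ann = MiRNAAnnotation(
            name="",
            arm=arm,
            mature_sequence=cand.mature.sequence,
            length=L,
            LP=len(precursor),
            MFE=pf.energy,
            reads_BR=cand.mature.count_BR,
            reads_BS=cand.mature.count_BS,
            star_detected=star,
            location=cand.ref_id,
            precursor_sequence=precursor,
            precursor_start=prec_start,
            mature_start=mat_start,
            strand=cand.strand,
            dot_bracket=pf.dot_bracket,
        )
        if best is None or ann.MFE < best.MFE:
            best = ann
    if best is not None:
        return best
    return Rejection(cand, _REASON_ORDER[deepest])


def discover(
    tags: Sequence[UniqueTag],
    refs: Mapping[str, str],
    criteria: Criteria = Criteria(),
    flank5: int = DEFAULT_FLANK,
    flank3: int = DEFAULT_FLANK,
    folder: Callable[[str], FoldResult] = fold,
) -> tuple[list[MiRNAAnnotation], list[Rejection]]:
    """Run the full screen over all unannotated tags.

    Tags below the read-support floor are not considered. Among a tag's
    accepted candidates only the best (lowest-MFE) one is kept; accepted
    miRNAs are named Lc-miRn{i}-{arm} in order of reference location.
    """
    supported = [t for t in tags if t.total >= criteria.min_count]
    hits = map_tags(supported, refs)
    accepted: list[MiRNAAnnotation] = []
    rejections: list[Rejection] = []
    for tag in supported:
        tag_hits = hits.get(tag.sequence)
        if not tag_hits:
            continue
        cands = excise_candidates(tag, tag_hits, refs, flank5, flank3)
        best: MiRNAAnnotation | None = None
        for cand in cands:
            window_tags = [
                t for t in supported
                if t.sequence != tag.sequence and t.sequence in cand.sequence
            ]
            res = evaluate_candidate(cand, window_tags, criteria, folder)
            if isinstance(res, Rejection):
                rejections.append(res)
            elif best is None or res.MFE < best.MFE:
                best = res
        if best is not None:
            accepted.append(best)
    accepted = _collapse_loci(accepted)
    accepted.sort(key=lambda a: (a.location, a.precursor_start, a.mature_sequence))
    named = []
    for i, a in enumerate(accepted, start=1):
        named.append(replace(a, name=f"Lc-miRn{i}-{a.arm}"))
    return named, rejections


def _collapse_loci(accepted: list[MiRNAAnnotation]) -> list[MiRNAAnnotation]:
    """Keep one mature per locus: the dominant (highest-read) product.

    Accepted matures whose intervals overlap on the same reference strand
    are ragged variants of one processing product; the 5p and 3p arms of a
    hairpin do not overlap and are kept as separate records.
    """
    by_strand: dict[tuple[str, str], list[MiRNAAnnotation]] = {}
    for a in accepted:
        by_strand.setdefault((a.location, a.strand), []).append(a)
    kept: list[MiRNAAnnotation] = []
    for group in by_strand.values():
        group.sort(key=lambda a: a.mature_start)
        cluster: list[MiRNAAnnotation] = []
        hi = -1
        for a in group:
            if cluster and a.mature_start >= hi:
                kept.append(max(cluster,
                                key=lambda x: (x.reads_BR + x.reads_BS, -x.MFE)))
                cluster = []
            cluster.append(a)
            hi = max(hi, a.mature_start + a.length)
        if cluster:
            kept.append(max(cluster,
                            key=lambda x: (x.reads_BR + x.reads_BS, -x.MFE)))
    return kept


def novel_tsv(annotations: Iterable[MiRNAAnnotation]) -> str:
    lines = ["miRNA\tmature_5p_to_3p\tlength\tLP\tMFE\treads_BR\treads_BS"
             "\tarm\tlocation\tstar_detected"]
    for a in annotations:
        lines.append(
            f"{a.name}\t{a.mature_sequence}\t{a.length}\t{a.LP}\t{a.MFE:.1f}\t"
            f"{a.reads_BR}\t{a.reads_BS}\t{a.arm}\t{a.location}\t"
            f"{int(a.star_detected)}"
        )
    return "\n".join(lines) + "\n"
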