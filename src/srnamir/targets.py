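"""Plant miRNA target prediction by complementarity expectation score.

A miRNA is aligned antiparallel against transcript windows; each alignment
column is penalized — mismatch 1.0, G:U wobble 0.5, gap/bulge 2.0 — and
penalties are doubled at miRNA positions 2–13 counted from the miRNA 5′ end
(the seed-weighted scheme canonical in plant target prediction). The
expectation E of a site is the summed penalty of its best alignment; sites
with E at or below the cutoff (default 3.0) are reported. A site whose best
alignment has a mismatch or gap touching miRNA positions 9–11 (the slicing
region) is called translational inhibition, otherwise cleavage.

Alignment columns are anchored at the site's 3′-most transcript base (which
faces miRNA position 1) and proceed toward the site 5′ end; at most
``max_gap`` gap columns (miRNA-side or transcript-side) are allowed, so the
site length is within |miRNA| ± max_gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import normalize

GAP_PENALTY = 2.0
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
SEED_RANGE = (2, 13)      # 1-based miRNA positions with doubled penalties
CENTRAL_RANGE = (9, 11)   # disruption here flags translational inhibition

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class Column:
    """One alignment column: miRNA position (1-based) and/or site base.

    ``mirna_pos`` is None for a transcript-side bulge; ``site_base`` is None
    for a miRNA-side gap. ``weight_pos`` is the miRNA position whose seed
    weighting applies to this column.
    """

    mirna_pos: int | None
    site_base: str | None
    weight_pos: int


@dataclass(frozen=True)
class TargetSite:
    """One reported miRNA target location on a transcript."""

    mirna_id: str
    transcript_id: str
    start: int            # 1-based inclusive on the transcript
    end: int              # 1-based inclusive
    expectation: float
    inhibition: str       # "cleavage" | "translation"
    duplex: str


def _weight(pos: int, seed_double: bool = True) -> float:
    if not seed_double:
        return 1.0
    return 2.0 if SEED_RANGE[0] <= pos <= SEED_RANGE[1] else 1.0


def _base_cost(m: str, s: str) -> float:
    """Penalty of pairing miRNA base ``m`` against site base ``s``."""
    if s == _COMP[m]:
        return 0.0
    if (m, s) in (("G", "T"), ("T", "G")):
        return WOBBLE_PENALTY
    return MISMATCH_PENALTY


def score_columns(mirna: str, columns: Sequence[Column]) -> float:
    """Expectation score of an explicit column sequence."""
    e = 0.0
    for col in columns:
        w = _weight(col.weight_pos)
        if col.mirna_pos is None or col.site_base is None:
            e += GAP_PENALTY * w
        else:
            e += _base_cost(mirna[col.mirna_pos - 1], col.site_base) * w
    return e


def score_duplex(mirna: str, site: str,
                 alignment: Sequence[tuple[int | None, int | None]]) -> float:
    """Score an explicit miRNA/site alignment.

    ``alignment`` lists columns as (miRNA position 1-based | None,
    site position 0-based from the site 5′ end | None); every miRNA position
    must appear exactly once and site positions must be consumed from the
    site's 3′ end toward its 5′ end.
    """
    m = normalize(mirna)
    s = normalize(site)
    seen = [a for a, _ in alignment if a is not None]
    if sorted(seen) != list(range(1, len(m) + 1)):
        raise ValueError("alignment must cover all miRNA positions exactly once")
    cols = []
    last_mirna = 0
    for mp, sp in alignment:
        wpos = mp if mp is not None else min(last_mirna + 1, len(m))
        cols.append(Column(mp, None if sp is None else s[sp], wpos))
        if mp is not None:
            last_mirna = mp
    return score_columns(m, cols)


def _align_end(mirna: str, transcript: str, end: int, max_gap: int,
               seed_double: bool = True):
    """Best alignment with the site's 3′ base at transcript index ``end``.

    Returns (E, site_start, columns) or None if the transcript is too short.
    DP over states (i miRNA positions consumed, g_m miRNA gaps, g_s site
    bulges); ties break toward fewer gaps, then fewer site bulges.
    """
    L = len(mirna)
    INF = float("inf")
    # D[(i, gm, gs)] = (cost, parent_state, column)
    D: dict[tuple[int, int, int], tuple[float, tuple | None, Column | None]] = {
        (0, 0, 0): (0.0, None, None)
    }
    for i in range(0, L + 1):
        for gm in range(0, max_gap + 1):
            for gs in range(0, max_gap - gm + 1):
                state = (i, gm, gs)
                if state not in D:
                    continue
                cost = D[state][0]
                consumed = (i - gm) + gs
                j = end - consumed  # next site base (moving 5′-ward)
                if i < L:
                    wpos = i + 1
                    if j >= 0:  # pair column
                        c = cost + _base_cost(mirna[i], transcript[j]) \
                            * _weight(wpos, seed_double)
                        col = Column(wpos, transcript[j], wpos)
                        _relax(D, (i + 1, gm, gs), c, state, col)
                    if gm + gs < max_gap:  # miRNA-side gap
                        c = cost + GAP_PENALTY * _weight(wpos, seed_double)
                        col = Column(wpos, None, wpos)
                        _relax(D, (i + 1, gm + 1, gs), c, state, col)
                if gm + gs < max_gap and j >= 0:  # transcript-side bulge
                    wpos = min(i + 1, L)
                    c = cost + GAP_PENALTY * _weight(wpos, seed_double)
                    col = Column(None, transcript[j], wpos)
                    _relax(D, (i, gm, gs + 1), c, state, col)
    best = None
    for gm in range(0, max_gap + 1):
        for gs in range(0, max_gap - gm + 1):
            state = (L, gm, gs)
            if state not in D:
                continue
            consumed = (L - gm) + gs
            if end - consumed + 1 < 0:
                continue
            key = (D[state][0], gm + gs, gs)
            if best is None or key < best[0]:
                best = (key, state)
    if best is None:
        return None
    _, state = best
    cols: list[Column] = []
    while state is not None:
        cost, parent, col = D[state]
        if col is not None:
            cols.append(col)
        state = parent
    cols.reverse()
    consumed = sum(1 for c in cols if c.site_base is not None)
    return D[best[1]][0], end - consumed + 1, cols


def _relax(D, state, cost, parent, col):
    cur = D.get(state)
    if cur is None or cost < cur[0] - 1e-12:
        D[state] = (cost, parent, col)


_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COST_TABLE = np.full((4, 4), MISMATCH_PENALTY)
for _m in "ACGT":
    _COST_TABLE[_IDX[_m], _IDX[_COMP[_m]]] = 0.0
_COST_TABLE[_IDX["G"], _IDX["T"]] = WOBBLE_PENALTY
_COST_TABLE[_IDX["T"], _IDX["G"]] = WOBBLE_PENALTY


def _best_scores(mirna: str, transcript: str, max_gap: int,
                 seed_double: bool = True) -> np.ndarray:
    """Best alignment E for every site 3′-anchor position, vectorized.

    Same recurrences as :func:`_align_end`, evaluated for all anchor
    positions at once; used to locate candidate sites cheaply before the
    per-anchor traceback DP reconstructs the alignment.
    """
    L, n = len(mirna), len(transcript)
    tenc = np.fromiter((_IDX[c] for c in transcript), dtype=np.int64, count=n)
    costrows = [
        _weight(i + 1, seed_double) * _COST_TABLE[_IDX[mirna[i]]][tenc]
        for i in range(L)
    ]
    INF = np.inf
    D: dict[tuple[int, int, int], np.ndarray] = {(0, 0, 0): np.zeros(n)}

    def _merge(key, arr):
        D[key] = arr if key not in D else np.minimum(D[key], arr)

    for i in range(L + 1):
        for gm in range(max_gap + 1):
            for gs in range(max_gap - gm):  # transcript-side bulge at this i
                src = D.get((i, gm, gs))
                if src is None:
                    continue
                consumed = (i - gm) + gs
                if consumed >= n:
                    continue
                dst = np.full(n, INF)
                dst[consumed:] = src[consumed:] \
                    + GAP_PENALTY * _weight(min(i + 1, L), seed_double)
                _merge((i, gm, gs + 1), dst)
        if i == L:
            break
        for gm in range(max_gap + 1):
            for gs in range(max_gap - gm + 1):
                src = D.get((i, gm, gs))
                if src is None:
                    continue
                consumed = (i - gm) + gs
                dst = np.full(n, INF)
                if consumed < n:
                    dst[consumed:] = src[consumed:] + costrows[i][: n - consumed]
                _merge((i + 1, gm, gs), dst)
                if gm + gs < max_gap:  # miRNA-side gap
                    _merge((i + 1, gm + 1, gs),
                           src + GAP_PENALTY * _weight(i + 1, seed_double))
    best = np.full(n, INF)
    for gm in range(max_gap + 1):
        for gs in range(max_gap - gm + 1):
            arr = D.get((L, gm, gs))
            if arr is not None:
                best = np.minimum(best, arr)
    return best


def _inhibition(cols: Sequence[Column], mirna: str) -> str:
    for col in cols:
        if col.mirna_pos is None or col.site_base is None:
            disrupted = True
        else:
            disrupted = _base_cost(mirna[col.mirna_pos - 1], col.site_base) > 0
        if disrupted and CENTRAL_RANGE[0] <= col.weight_pos <= CENTRAL_RANGE[1]:
            return "translation"
    return "cleavage"


def _render_duplex(cols: Sequence[Column], mirna: str) -> str:
    """Three-line rendering: miRNA 5′→3′, bond symbols, site 3′→5′."""
    top, mid, bot = [], [], []
    for col in cols:
        m = mirna[col.mirna_pos - 1] if col.mirna_pos else "-"
        s = col.site_base if col.site_base else "-"
        if col.mirna_pos and col.site_base:
            cost = _base_cost(m, s)
            mid.append("|" if cost == 0 else ("o" if cost == WOBBLE_PENALTY else " "))
        else:
            mid.append(" ")
        top.append(m)
        bot.append(s)
    return "".join(top) + "\n" + "".join(mid) + "\n" + "".join(bot)


def scan_transcripts(
    mirna: str,
    transcripts: Mapping[str, str],
    cutoff: float = 3.0,
    max_gap: int = 1,
    mirna_id: str = "miRNA",
) -> list[TargetSite]:
    """Report all non-overlapping target sites with E ≤ cutoff.

    Every site 3′-anchor position is evaluated; overlapping candidate sites
    for the same miRNA/transcript are resolved greedily by (E, position).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    m = normalize(mirna)
    out: list[TargetSite] = []
    for tid in sorted(transcripts):
        t = normalize(transcripts[tid])
        if len(t) < len(m) - max_gap:
            continue
        scores = _best_scores(m, t, max_gap)
        cands = []
        for end in np.nonzero(scores <= cutoff + 1e-12)[0]:
            res = _align_end(m, t, int(end), max_gap)
            if res is None:
                continue
            e, start, cols = res
            if e <= cutoff + 1e-12 and start >= 0:
                cands.append((e, start, int(end), cols))
        cands.sort(key=lambda c: (c[0], c[1]))
        chosen: list[tuple[float, int, int, list[Column]]] = []
        for cand in cands:
            if all(cand[2] < c[1] or cand[1] > c[2] for c in chosen):
                chosen.append(cand)
        for e, start, end, cols in sorted(chosen, key=lambda c: c[1]):
            out.append(TargetSite(
                mirna_id, tid, start + 1, end + 1, e,
                _inhibition(cols, m), _render_duplex(cols, m),
            ))
    return out


def best_expectation(mirna: str, transcript: str, max_gap: int = 1) -> float:
    """Best (lowest) E of the miRNA anywhere on one transcript."""
    m = normalize(mirna)
    t = normalize(transcript)
    if len(t) < len(m) - max_gap:
        return float("inf")
    return float(_best_scores(m, t, max_gap).min())


def target_tsv(sites: Iterable[TargetSite]) -> str:
    lines = ["miRNA\ttranscript\tstart\tend\texpectation\tinhibition\tduplex"]
    for s in sites:
        lines.append(
            f"{s.mirna_id}\t{s.transcript_id}\t{s.start}\t{s.end}\t"
            f"{s.expectation:.2f}\t{s.inhibition}\t{s.duplex.replace(chr(10), ';')}"
        )
    return "\n".join(lines) + "\n"
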