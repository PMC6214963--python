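"""Secondary-structure folding for hairpin-precursor screening.

The built-in folder computes the minimum-free-energy *nested* structure under a
simplified stacking-energy model: every base pair whose immediately interior
neighbour is also paired ("stacked pair") contributes an energy that depends on
its own identity — GC/CG −3.0, AT(AU)/TA −2.0, GT(GU)/TG −1.0 kcal/mol — while
every pair that is *not* stacked (each helix's innermost, loop-closing pair)
pays a +4.0 kcal/mol destabilization, the coarse analogue of thermodynamic
loop/bulge initiation penalties.  Unpaired bases contribute 0 and hairpin loops must
enclose at least 3 unpaired bases.  The energy of the open chain is 0, so every
MFE is ≤ 0.  Without the closure term a structure stitched from many short
helices scores as well as one long helix, which would make energy thresholds
meaningless as a hairpin screen.

This is deliberately not a full Turner nearest-neighbour model: the pipeline
only uses MFE as an acceptance threshold for candidate precursors, and the
simplified model is exactly reproducible and independently checkable by
exhaustive enumeration.  A thermodynamic folder (e.g. RNAfold) can be plugged
in through :class:`ExternalFolder`, in which case its energies are used
verbatim.

Dynamic program
---------------
Three matrices over spans ``[i, j]``:

* ``C[i,j]``  — best energy given that ``(i, j)`` is a pair,
* ``Fh[i,j]`` — best energy over structures of ``[i, j]`` in which ``i`` and
  ``j`` are *not* paired with each other,
* ``F[i,j]``  — best energy overall, ``min(C, Fh)``.

``C`` chooses between stacking on ``(i+1, j-1)`` (adding the stack term) and
closing any structure in which ``(i+1, j-1)`` is not a pair.  Ties in energy
are broken toward more pairs, then toward 5′-most pairing during traceback, so
output is deterministic.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from numba import njit

from ._seq import SequenceError, encode, normalize, to_rna

MAX_FOLD_LEN = 1000
_MIN_LOOP = 3
_EPS = 1e-9

# stack energy by pair type, indexed by encoded (base5, base3):
# GC/CG -3.0, AT/TA -2.0, GT/TG -1.0, everything else not pairable.
_PAIR_ENERGY = np.full((4, 4), 1.0)
_PAIR_ENERGY[2, 1] = _PAIR_ENERGY[1, 2] = -3.0
_PAIR_ENERGY[0, 3] = _PAIR_ENERGY[3, 0] = -2.0
_PAIR_ENERGY[2, 3] = _PAIR_ENERGY[3, 2] = -1.0
_PAIRABLE = _PAIR_ENERGY < 0.0
#: destabilization paid by each helix-closing (non-stacked) pair, kcal/mol
LOOP_PENALTY = 4.0


@dataclass(frozen=True)
class FoldResult:
    """Optimal nested structure of one sequence.

    ``pair_table[i]`` is the partner of position ``i`` or −1 if unpaired; the
    table is an involution without crossing pairs. ``energy`` is in kcal/mol.
    """

    sequence: str
    pair_table: np.ndarray
    energy: float

    @property
    def dot_bracket(self) -> str:
        out = []
        for i, p in enumerate(self.pair_table):
            out.append("." if p < 0 else ("(" if p > i else ")"))
        return "".join(out)

    @property
    def n_pairs(self) -> int:
        return int((self.pair_table >= 0).sum()) // 2


@dataclass(frozen=True)
class DuplexStats:
    """Pairing statistics of a mature interval inside a folded precursor.

    ``mature_span``/``star_span`` are the extents of the paired region on
    each strand (first to last paired position); their difference is the
    duplex asymmetry — near zero for a genuine miRNA/miRNA* duplex, large
    when the mature's partners are scattered.
    """

    overlap_bp: int
    n_bulges: int
    star_start: int
    star_end: int
    overhang3: int
    in_loop: bool
    mature_span: int = 0
    star_span: int = 0

    @property
    def asymmetry(self) -> int:
        return abs(self.star_span - self.mature_span)


@njit(cache=True)
def _fill(enc, pair_e, pairable, loop_pen):  # pragma: no cover - exercised via fold()
    n = enc.shape[0]
    INF = 1e18
    F = np.zeros((n, n))
    Fh = np.zeros((n, n))
    C = np.full((n, n), INF)
    PF = np.zeros((n, n), np.int32)
    PFh = np.zeros((n, n), np.int32)
    PC = np.zeros((n, n), np.int32)
    for span in range(_MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            # C[i,j]: (i,j) paired
            if pairable[enc[i], enc[j]]:
                best_e = Fh[i + 1, j - 1] + loop_pen
                best_p = PFh[i + 1, j - 1] + 1
                if C[i + 1, j - 1] < INF:
                    e = C[i + 1, j - 1] + pair_e[enc[i], enc[j]]
                    p = PC[i + 1, j - 1] + 1
                    if e < best_e - _EPS or (e < best_e + _EPS and p > best_p):
                        best_e, best_p = e, p
                C[i, j] = best_e
                PC[i, j] = best_p
            # Fh[i,j]: i,j not paired to each other
            best_e = F[i, j - 1]
            best_p = PF[i, j - 1]
            for k in range(i + 1, j - _MIN_LOOP):
                if C[k, j] < INF:
                    left_e = F[i, k - 1] if k > i else 0.0
                    left_p = PF[i, k - 1] if k > i else 0
                    e = left_e + C[k, j]
                    p = left_p + PC[k, j]
                    if e < best_e - _EPS or (e < best_e + _EPS and p > best_p):
                        best_e, best_p = e, p
            Fh[i, j] = best_e
            PFh[i, j] = best_p
            # F[i,j]
            if C[i, j] < best_e - _EPS or (
                C[i, j] < best_e + _EPS and PC[i, j] > best_p
            ):
                F[i, j] = C[i, j]
                PF[i, j] = PC[i, j]
            else:
                F[i, j] = best_e
                PF[i, j] = best_p
    return F, Fh, C, PF, PFh, PC


def _close(e1, p1, e2, p2) -> bool:
    return abs(e1 - e2) < _EPS and p1 == p2


def _traceback(enc, F, Fh, C, PF, PFh, PC):
    n = enc.shape[0]
    table = np.full(n, -1, dtype=np.int64)
    # stack of (i, j, mode); mode 0 = F, 1 = Fh (exclude k=i), 2 = C
    stack = [(0, n - 1, 0)]
    while stack:
        i, j, mode = stack.pop()
        if j - i < _MIN_LOOP + 1:
            continue
        if mode == 2:
            table[i], table[j] = j, i
            if (
                C[i + 1, j - 1] < 1e17
                and _close(
                    C[i, j],
                    PC[i, j],
                    C[i + 1, j - 1] + _PAIR_ENERGY[enc[i], enc[j]],
                    PC[i + 1, j - 1] + 1,
                )
            ):
                stack.append((i + 1, j - 1, 2))
            else:
                stack.append((i + 1, j - 1, 1))  # closes a loop (+penalty)
            continue
        e, p = (F[i, j], PF[i, j]) if mode == 0 else (Fh[i, j], PFh[i, j])
        kmin = i if mode == 0 else i + 1
        done = False
        for k in range(kmin, j - _MIN_LOOP):
            if C[k, j] >= 1e17:
                continue
            left_e = F[i, k - 1] if k > i else 0.0
            left_p = PF[i, k - 1] if k > i else 0
            if _close(e, p, left_e + C[k, j], left_p + PC[k, j]):
                if k > i:
                    stack.append((i, k - 1, 0))
                stack.append((k, j, 2))
                done = True
                break
        if not done:
            stack.append((i, j - 1, 0))
    return table


def fold(seq: str) -> FoldResult:
    """Fold ``seq`` and return its minimum-energy nested structure.

    Raises :class:`~srnamir._seq.SequenceError` on invalid characters and
    ``ValueError`` on sequences outside 1..1000 nt.
    """
    s = normalize(seq)
    if not 1 <= len(s) <= MAX_FOLD_LEN:
        raise ValueError(f"sequence length {len(s)} outside [1, {MAX_FOLD_LEN}]")
    enc = encode(s)
    n = len(s)
    if n < _MIN_LOOP + 2:
        return FoldResult(s, np.full(n, -1, dtype=np.int64), 0.0)
    F, Fh, C, PF, PFh, PC = _fill(enc, _PAIR_ENERGY, _PAIRABLE, LOOP_PENALTY)
    table = _traceback(enc, F, Fh, C, PF, PFh, PC)
    energy = float(F[0, n - 1])
    return FoldResult(s, table, 0.0 if energy == 0 else energy)


def enumerate_structures(seq: str):
    """Yield every nested structure of ``seq`` as (pair_table, energy).

    Exhaustive-search oracle for :func:`fold`; only usable for short
    sequences (exponential in length).
    """
    s = normalize(seq)
    enc = encode(s)
    n = len(s)

    def structures(i: int, j: int):
        # all nested pair-lists on span [i, j]
        if j - i < _MIN_LOOP + 1:
            yield []
            return
        # j unpaired
        for st in structures(i, j - 1):
            yield st
        for k in range(i, j - _MIN_LOOP):
            if not _PAIRABLE[enc[k], enc[j]]:
                continue
            for left in structures(i, k - 1) if k > i else [[]]:
                for inner in structures(k + 1, j - 1):
                    yield left + inner + [(k, j)]

    for pairs in structures(0, n - 1):
        table = np.full(n, -1, dtype=np.int64)
        for a, b in pairs:
            table[a], table[b] = b, a
        yield table, score_structure(s, table)


def score_structure(seq: str, pair_table: np.ndarray) -> float:
    """Energy of an explicit structure under the built-in model."""
    enc = encode(normalize(seq))
    e = 0.0
    for i, p in enumerate(pair_table):
        if p <= i:
            continue
        if pair_table[i + 1] == p - 1 and p - 1 > i + 1:
            # pair (i,p) stacks on (i+1,p-1); outer pair contributes its term
            e += _PAIR_ENERGY[enc[i], enc[p]]
        else:
            e += LOOP_PENALTY
    return e


def duplex_stats(fr: FoldResult, mature_start: int, mature_len: int,
                 overhang3: int = 2) -> DuplexStats:
    """Pairing statistics of the mature/star duplex inside a fold.

    ``overlap_bp`` counts mature positions with a partner; the star interval
    is the minimal interval covering those partners, extended by ``overhang3``
    nt at its 3′ (higher-coordinate) end and clipped to the sequence. A bulge
    is a maximal run of unpaired positions strictly inside the mature or star
    interval (flanked by paired positions on both sides within the interval);
    internal loops therefore count once per strand.  A mature interval with no
    partners at all (sitting in the terminal loop) is flagged, not an error.
    """
    n = len(fr.sequence)
    if not (0 <= mature_start and mature_start + mature_len <= n):
        raise ValueError("mature interval outside sequence")
    m0, m1 = mature_start, mature_start + mature_len
    paired_idx = [i for i in range(m0, m1) if fr.pair_table[i] >= 0]
    partners = [int(fr.pair_table[i]) for i in paired_idx]
    overlap = len(partners)
    if overlap == 0:
        return DuplexStats(0, 0, -1, -1, overhang3, True)
    star0, star1 = min(partners), max(partners) + 1
    star_span = star1 - star0
    mature_span = paired_idx[-1] - paired_idx[0] + 1
    star1 = min(n, star1 + overhang3)

    def _runs(lo: int, hi: int) -> int:
        runs, in_run, seen_paired, pending = 0, False, False, 0
        for i in range(lo, hi):
            if fr.pair_table[i] >= 0:
                if seen_paired and pending:
                    runs += 1
                seen_paired, pending = True, 0
            else:
                pending += 1
        return runs

    n_bulges = _runs(m0, m1) + _runs(star0, star1)
    return DuplexStats(overlap, n_bulges, star0, star1, overhang3, False,
                       mature_span, star_span)


class Folder(Protocol):
    """Adapter contract for pluggable folding engines."""

    def __call__(self, seq: str) -> FoldResult: ...


@dataclass
class ExternalFolder:
    """Wrap an external command that maps sequence -> (dot-bracket, energy).

    ``runner`` takes an RNA sequence and returns ``(dot_bracket, energy)``;
    the default shells out to ``RNAfold --noPS`` when available.
    """

    runner: Callable[[str], tuple[str, float]] = field(default=None)  # type: ignore[assignment]

    def __call__(self, seq: str) -> FoldResult:
        s = normalize(seq)
        run = self.runner or _rnafold_runner
        db, energy = run(to_rna(s))
        return FoldResult(s, dot_bracket_to_pair_table(db), float(energy))


def _rnafold_runner(rna: str) -> tuple[str, float]:
    out = subprocess.run(
        ["RNAfold", "--noPS"], input=rna + "\n", text=True,
        capture_output=True, check=True,
    ).stdout.splitlines()
    struct, _, tail = out[1].partition(" ")
    return struct, float(tail.strip().strip("()"))


def dot_bracket_to_pair_table(db: str) -> np.ndarray:
    table = np.full(len(db), -1, dtype=np.int64)
    stack: list[int] = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            table[i], table[j] = j, i
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return table
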