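"""Known-miRNA identification and the family expression table.

Tags are compared to a mature-miRNA database by equal-length ungapped Hamming
distance with a mismatch budget (default 2). Each tag is assigned to the
family of its minimum-mismatch match; ties across families break
lexicographically by family name, so assignment is deterministic. The family
table carries, per family: distinct matched database members, per-library read
sums, their total, and the BS/BR ratio rounded half-away-from-zero to two
decimals — with ``reads_BR = 0`` the ratio is undefined and rendered "—",
while ``reads_BS = 0`` gives 0.00.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from Bio import SeqIO

from ._seq import SequenceError, normalize
from .preprocess import UniqueTag


@dataclass(frozen=True)
class MatureRecord:
    """One known mature miRNA: id, family name, conserved flag."""

    mature_id: str
    family: str
    conserved: bool
    sequence: str


@dataclass(frozen=True)
class KnownMatch:
    """A tag/database hit within the mismatch budget."""

    tag_sequence: str
    mature_id: str
    family: str
    mismatches: int
    conserved: bool
    best: bool = False


@dataclass(frozen=True)
class FamilyExpressionRow:
    """One family row of the expression table."""

    family: str
    members: int
    reads_BR: int
    reads_BS: int
    conserved: bool = True

    @property
    def total(self) -> int:
        return self.reads_BR + self.reads_BS

    @property
    def ratio(self) -> float | None:
        """BS/BR to 2 decimals (half-away-from-zero); None when BR = 0."""
        if self.reads_BR == 0:
            return None
        return round_ratio(self.reads_BS, self.reads_BR)

    @property
    def ratio_str(self) -> str:
        r = self.ratio
        return "—" if r is None else f"{r:.2f}"


def round_ratio(numerator: int, denominator: int) -> float:
    """numerator/denominator rounded half-away-from-zero to 2 decimals."""
    q = Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def match_known(
    tag: str, mature_db: Sequence[MatureRecord], max_mismatch: int = 2
) -> list[KnownMatch]:
    """All equal-length database hits of ``tag`` within ``max_mismatch``.

    Minimum-distance hits are flagged ``best``. Non-ACGTU characters in the
    tag raise a validation error.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    try:
        seq = normalize(tag)
    except SequenceError as exc:
        raise SequenceError(f"invalid tag sequence: {exc}") from exc
    hits = []
    for rec in mature_db:
        if len(rec.sequence) != len(seq):
            continue
        mm = hamming(seq, rec.sequence)
        if mm <= max_mismatch:
            hits.append(KnownMatch(seq, rec.mature_id, rec.family, mm,
                                   rec.conserved))
    if hits:
        best_mm = min(h.mismatches for h in hits)
        hits = [
            KnownMatch(h.tag_sequence, h.mature_id, h.family, h.mismatches,
                       h.conserved, best=h.mismatches == best_mm)
            for h in hits
        ]
    return hits


def assign_tags(
    tags: Sequence[UniqueTag],
    mature_db: Sequence[MatureRecord],
    max_mismatch: int = 2,
) -> dict[str, KnownMatch]:
    """Map tag sequence -> its single best match (unmatched tags absent).

    The best match is the minimum-mismatch hit; among equally good hits the
    lexicographically smallest (family, mature_id) wins.
    """
    out: dict[str, KnownMatch] = {}
    for tag in tags:
        hits = [h for h in match_known(tag.sequence, mature_db, max_mismatch)
                if h.best]
        if hits:
            out[tag.sequence] = min(hits, key=lambda h: (h.family, h.mature_id))
    return out


def build_family_table(
    matches: dict[str, KnownMatch], tags: Sequence[UniqueTag]
) -> list[FamilyExpressionRow]:
    """Aggregate best matches into family rows (each tag counted once)."""
    by_seq = {t.sequence: t for t in tags}
    for seq in matches:
        if seq not in by_seq:
            raise ValueError(f"match references unknown tag {seq!r}")
    fam: dict[str, dict] = {}
    for seq, m in matches.items():
        t = by_seq[seq]
        d = fam.setdefault(m.family, {"members": set(), "BR": 0, "BS": 0,
                                      "conserved": m.conserved})
        d["members"].add(m.mature_id)
        d["BR"] += t.count_BR
        d["BS"] += t.count_BS
    return [
        FamilyExpressionRow(f, len(d["members"]), d["BR"], d["BS"],
                            d["conserved"])
        for f, d in sorted(fam.items())
    ]


def read_mature_db(path) -> list[MatureRecord]:
    """Load a mature-miRNA FASTA whose headers are ``id|family|flag``."""
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 3:
            raise ValueError(f"header {rec.id!r} is not 'id|family|flag'")
        records.append(
            MatureRecord(parts[0], parts[1], parts[2] in ("1", "conserved"),
                         normalize(str(rec.seq)))
        )
    return records


def family_table_tsv(rows: Iterable[FamilyExpressionRow]) -> str:
    lines = ["family\tmembers\treads_BR\treads_BS\ttotal\tratio_BS_BR\tconserved"]
    for r in rows:
        lines.append(
            f"{r.family}\t{r.members}\t{r.reads_BR}\t{r.reads_BS}\t"
            f"{r.total}\t{r.ratio_str}\t{int(r.conserved)}"
        )
    return "\n".join(lines) + "\n"
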