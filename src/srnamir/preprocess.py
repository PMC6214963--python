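"""Raw-read cleanup: quality filter, adapter classification, tag collapsing.

Every high-quality read is assigned to exactly one removal category or kept as
a clean tag, so the category counts always sum back to the high-quality total
(the accounting shape of a standard sRNA-library summary table).

Category precedence when several could apply:
5′-adapter contaminant > insert-null > 3′-adapter-null > poly(A) > too-short.
Adapter detection is seed-and-extend: exact match of the adapter's first 8 nt
anywhere in the read, extended outward allowing at most one mismatch.  Inserts
trimming to more than ``max_len`` are counted under 3′-adapter-null (a genuine
size-selected sRNA insert must terminate in adapter within the clean window;
an adapter that far out is treated as absent).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from ._seq import SequenceError, normalize

LIBRARIES = ("BR", "BS")

_SEED_LEN = 8
_EXT_MAX_MM = 1
_POLYA_FRAC = 0.8


class FastqFormatError(ValueError):
    """Malformed read record; carries the 0-based record index."""

    def __init__(self, index: int, message: str):
        super().__init__(f"record {index}: {message}")
        self.index = index


@dataclass(frozen=True)
class Read:
    """One raw sequencing read (quality may be None for FASTA input)."""

    sequence: str
    quality: Sequence[int] | None = None
    name: str = ""


@dataclass
class PreprocessStats:
    """Per-library read accounting (the published summary-table shape)."""

    raw: int = 0
    high_quality: int = 0
    clean: int = 0
    adapter3_null: int = 0
    insert_null: int = 0
    adapter5_contaminant: int = 0
    smaller_than_min: int = 0
    polyA: int = 0

    _CATEGORIES = (
        "clean", "adapter3_null", "insert_null", "adapter5_contaminant",
        "smaller_than_min", "polyA",
    )

    def percentages(self) -> dict[str, float]:
        """Each category as a percentage of high-quality reads."""
        denom = self.high_quality or 1
        return {c: 100.0 * getattr(self, c) / denom for c in self._CATEGORIES}

    def conserved(self) -> bool:
        return sum(getattr(self, c) for c in self._CATEGORIES) == self.high_quality


@dataclass
class UniqueTag:
    """A distinct trimmed sRNA sequence with per-library read counts."""

    sequence: str
    count_BR: int = 0
    count_BS: int = 0

    @property
    def total(self) -> int:
        return self.count_BR + self.count_BS

    def count(self, library: str) -> int:
        return getattr(self, f"count_{library}")


def _find_adapter(read: str, adapter: str) -> int:
    """Return the start of the adapter occurrence in ``read``, or -1.

    Seed: exact match of adapter[:8]; extension of the remainder tolerates up
    to one mismatch (truncated adapters at the read end are accepted).
    """
    seed = adapter[: _SEED_LEN]
    start = 0
    while True:
        pos = read.find(seed, start)
        if pos < 0:
            return -1
        rest = adapter[_SEED_LEN:]
        avail = read[pos + _SEED_LEN: pos + len(adapter)]
        mm = sum(a != b for a, b in zip(avail, rest))
        if mm <= _EXT_MAX_MM:
            return pos
        start = pos + 1


def classify_read(
    seq: str,
    adapter3: str,
    adapter5: str,
    min_len: int = 18,
    max_len: int = 30,
) -> tuple[str, str | None]:
    """Classify one high-quality read; return (category, trimmed-insert)."""
    if _find_adapter(seq, adapter5) >= 0:
        return "adapter5_contaminant", None
    pos = _find_adapter(seq, adapter3)
    if pos < 0:
        # no adapter: raw reads (longer than the clean window) are
        # adapter-null; an already-trimmed in-window sequence re-classifies
        # as clean, which makes trimming idempotent.
        if len(seq) > max_len:
            return "adapter3_null", None
        insert = seq
    else:
        insert = seq[:pos]
    if not insert:
        return "insert_null", None
    if insert.count("A") >= _POLYA_FRAC * len(insert):
        return "polyA", None
    if len(insert) < min_len:
        return "smaller_than_min", None
    if len(insert) > max_len:
        return "adapter3_null", None
    return "clean", insert


def classify_and_trim(
    reads: Iterable[Read],
    adapter3: str,
    adapter5: str,
    min_len: int = 18,
    max_len: int = 30,
    quality_floor: float = 20.0,
    library: str = "BR",
) -> tuple[list[UniqueTag], PreprocessStats]:
    """Classify one library's raw reads and collapse clean inserts to tags.

    Empty input yields all-zero stats. A read with non-ACGTU characters raises
    :class:`FastqFormatError` naming the offending record index.
    """
    if not adapter3 or not adapter5:
        raise ValueError("adapters must be non-empty")
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    if library not in LIBRARIES:
        raise ValueError(f"library must be one of {LIBRARIES}")
    stats = PreprocessStats()
    counts: Counter[str] = Counter()
    for idx, read in enumerate(reads):
        stats.raw += 1
        try:
            seq = normalize(read.sequence)
        except SequenceError as exc:
            raise FastqFormatError(idx, str(exc)) from exc
        if read.quality is not None:
            if len(read.quality) != len(seq):
                raise FastqFormatError(idx, "quality length != sequence length")
            if seq and sum(read.quality) / len(seq) < quality_floor:
                continue
        stats.high_quality += 1
        category, insert = classify_read(seq, normalize(adapter3),
                                         normalize(adapter5), min_len, max_len)
        setattr(stats, category, getattr(stats, category) + 1)
        if insert is not None:
            counts[insert] += 1
    tags = [
        UniqueTag(s, **{f"count_{library}": n})
        for s, n in sorted(counts.items())
    ]
    return tags, stats


def merge_libraries(tags_br: Iterable[UniqueTag],
                    tags_bs: Iterable[UniqueTag]) -> list[UniqueTag]:
    """Merge per-library tag sets into tags carrying both counts."""
    merged: dict[str, UniqueTag] = {}
    for src in (tags_br, tags_bs):
        for t in src:
            m = merged.setdefault(t.sequence, UniqueTag(t.sequence))
            m.count_BR += t.count_BR
            m.count_BS += t.count_BS
    return [merged[s] for s in sorted(merged)]


def length_distribution(tags: Sequence[UniqueTag]) -> dict[int, tuple[int, float]]:
    """Read-weighted length distribution: length -> (reads, fraction)."""
    if not tags:
        raise ValueError("length_distribution requires a non-empty tag set")
    counts: Counter[int] = Counter()
    for t in tags:
        counts[len(t.sequence)] += t.total
    total = sum(counts.values())
    return {L: (n, n / total) for L, n in sorted(counts.items())}


def read_fastq(path) -> Iterator[Read]:
    """Yield reads from a FASTQ (or FASTA, qualities None) file."""
    fmt = "fastq"
    with open(path) as fh:
        head = fh.read(1)
        if head == ">":
            fmt = "fasta"
    for rec in SeqIO.parse(path, fmt):
        qual = rec.letter_annotations.get("phred_quality")
        yield Read(str(rec.seq), qual, rec.id)


def write_collapsed_fasta(tags: Sequence[UniqueTag], path) -> None:
    """Write tags as ``>tag{i}|{count_BR}|{count_BS}`` FASTA records."""
    with open(path, "w") as fh:
        for i, t in enumerate(tags):
            fh.write(f">tag{i}|{t.count_BR}|{t.count_BS}\n{t.sequence}\n")


def read_collapsed_fasta(path) -> list[UniqueTag]:
    tags = []
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.id.split("|")
        tags.append(UniqueTag(str(rec.seq), int(parts[1]), int(parts[2])))
    return tags
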