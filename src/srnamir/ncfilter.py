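"""Removal of tags matching structural non-coding RNA classes.

A tag is removed iff it is a perfect substring of a database record on either
strand. Exact matching is the conservative, reproducible stand-in for a
BLASTn screen with unstated thresholds. A tag hitting records of several
classes is annotated with the highest-precedence class:
rRNA > tRNA > snRNA > snoRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO

from ._seq import normalize, revcomp
from .preprocess import UniqueTag

NC_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")
_PRECEDENCE = {c: i for i, c in enumerate(NC_CLASSES)}


class NcConfigError(ValueError):
    """Database record with an unknown class label."""


@dataclass(frozen=True)
class NcRecord:
    """One contaminant-database entry with its class label."""

    record_id: str
    nc_class: str
    sequence: str

    def __post_init__(self):
        if self.nc_class not in NC_CLASSES:
            raise NcConfigError(
                f"unknown ncRNA class {self.nc_class!r} for record "
                f"{self.record_id!r}; expected one of {NC_CLASSES}"
            )


@dataclass(frozen=True)
class NcAnnotation:
    """Why a tag was removed: matched record, class, and strand."""

    tag_sequence: str
    nc_class: str
    record_id: str
    strand: str  # '+' or '-'


def read_ncdb(path) -> list[NcRecord]:
    """Load a contaminant FASTA whose headers are ``id|class``."""
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 2:
            raise NcConfigError(f"header {rec.id!r} lacks a '|class' suffix")
        records.append(NcRecord(parts[0], parts[1], normalize(str(rec.seq))))
    return records


def filter_ncrna(
    tags: Sequence[UniqueTag], ncdb: Iterable[NcRecord]
) -> tuple[list[NcAnnotation], list[UniqueTag]]:
    """Partition tags into (removed annotations, kept tags)."""
    db = list(ncdb)
    removed: list[NcAnnotation] = []
    kept: list[UniqueTag] = []
    for tag in tags:
        hit: NcAnnotation | None = None
        for rec in db:
            strand = None
            if tag.sequence in rec.sequence:
                strand = "+"
            elif tag.sequence in revcomp(rec.sequence):
                strand = "-"
            if strand is None:
                continue
            cand = NcAnnotation(tag.sequence, rec.nc_class, rec.record_id, strand)
            if hit is None or _PRECEDENCE[cand.nc_class] < _PRECEDENCE[hit.nc_class]:
                hit = cand
        if hit is None:
            kept.append(tag)
        else:
            removed.append(hit)
    return removed, kept
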