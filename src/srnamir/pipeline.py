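"""End-to-end orchestration: raw reads to report tables.

Stages run in the published order — preprocess, length distribution, ncRNA
filter, known-miRNA identification, novel-miRNA discovery, differential
expression, target prediction — each emitting a plain TSV shaped like the
corresponding published table, plus a YAML run manifest recording every
effective parameter. Stages are plain functions over files, so any stage can
be re-run from the previous stage's outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import yaml

from . import diffexpr as de
from . import known as kn
from . import ncfilter as nc
from . import novel as nv
from . import preprocess as pp
from . import targets as tg
from .novel import Criteria


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input paths and every stage parameter (defaults per stage docs)."""

    reads_BR: str = ""
    reads_BS: str = ""
    references: str = ""
    mature_db: str = ""
    ncdb: str = ""
    transcripts: str = ""      # defaults to `references` when empty
    outdir: str = "srnamir_out"
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    min_len: int = 18
    max_len: int = 30
    quality_floor: float = 20.0
    max_mismatch: int = 2
    criteria: Criteria = field(default_factory=Criteria)
    flank5: int = nv.DEFAULT_FLANK
    flank3: int = nv.DEFAULT_FLANK
    fc_cut: float = 1.0
    p_cut: float = 0.05
    two_sided: bool = True
    target_cutoff: float = 3.0
    target_max_gap: int = 1
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("reads_BR", "reads_BS", "references", "mature_db", "ncdb"):
            path = getattr(self, name)
            if not path or not os.path.exists(path):
                raise PipelineError("config", f"missing input {name}: {path!r}")


@dataclass
class PipelineResult:
    """In-memory results of a full run plus the output-path map."""

    stats_BR: pp.PreprocessStats
    stats_BS: pp.PreprocessStats
    tags: list[pp.UniqueTag]
    kept_tags: list[pp.UniqueTag]
    family_rows: list[kn.FamilyExpressionRow]
    novel_annotations: list[nv.MiRNAAnnotation]
    de_records: list[de.DiffExprRecord]
    target_sites: list[tg.TargetSite]
    paths: dict[str, str]


def _stats_tsv(sbr: pp.PreprocessStats, sbs: pp.PreprocessStats) -> str:
    rows = ["raw", "high_quality", "clean", "adapter3_null", "insert_null",
            "adapter5_contaminant", "smaller_than_min", "polyA"]
    pct_br, pct_bs = sbr.percentages(), sbs.percentages()
    lines = ["category\tBR_count\tBR_percent\tBS_count\tBS_percent"]
    for r in rows:
        pb = 100.0 if r == "high_quality" else pct_br.get(r, float("nan"))
        ps = 100.0 if r == "high_quality" else pct_bs.get(r, float("nan"))
        if r == "raw":
            lines.append(f"raw\t{sbr.raw}\t\t{sbs.raw}\t")
        else:
            lines.append(f"{r}\t{getattr(sbr, r)}\t{pb:.2f}\t"
                         f"{getattr(sbs, r)}\t{ps:.2f}")
    return "\n".join(lines) + "\n"


def _lengths_tsv(tags) -> str:
    dist = pp.length_distribution(tags)
    lines = ["length\treads\tfraction"]
    for L, (n, frac) in dist.items():
        lines.append(f"{L}\t{n}\t{frac:.6f}")
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage and write the six report TSVs plus a manifest."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    paths = {name: os.path.join(cfg.outdir, fname) for name, fname in (
        ("stats", "preprocess_stats.tsv"),
        ("lengths", "length_distribution.tsv"),
        ("ncremoved", "ncrna_removed.tsv"),
        ("families", "family_expression.tsv"),
        ("novel", "novel_mirnas.tsv"),
        ("diffexpr", "differential_expression.tsv"),
        ("targets", "target_sites.tsv"),
        ("manifest", "manifest.yaml"),
    )}

    try:
        tags_br, stats_br = pp.classify_and_trim(
            pp.read_fastq(cfg.reads_BR), cfg.adapter3, cfg.adapter5,
            cfg.min_len, cfg.max_len, cfg.quality_floor, library="BR")
        tags_bs, stats_bs = pp.classify_and_trim(
            pp.read_fastq(cfg.reads_BS), cfg.adapter3, cfg.adapter5,
            cfg.min_len, cfg.max_len, cfg.quality_floor, library="BS")
        tags = pp.merge_libraries(tags_br, tags_bs)
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc
    with open(paths["stats"], "w") as fh:
        fh.write(_stats_tsv(stats_br, stats_bs))
    if tags:
        with open(paths["lengths"], "w") as fh:
            fh.write(_lengths_tsv(tags))

    try:
        ncdb = nc.read_ncdb(cfg.ncdb)
        removed, kept = nc.filter_ncrna(tags, ncdb)
    except Exception as exc:
        raise PipelineError("ncfilter", str(exc)) from exc
    with open(paths["ncremoved"], "w") as fh:
        fh.write("tag_sequence\tclass\trecord\tstrand\n")
        for ann in removed:
            fh.write(f"{ann.tag_sequence}\t{ann.nc_class}\t"
                     f"{ann.record_id}\t{ann.strand}\n")

    try:
        mature_db = kn.read_mature_db(cfg.mature_db)
        matches = kn.assign_tags(kept, mature_db, cfg.max_mismatch)
        family_rows = kn.build_family_table(matches, kept)
    except Exception as exc:
        raise PipelineError("known", str(exc)) from exc
    with open(paths["families"], "w") as fh:
        fh.write(kn.family_table_tsv(family_rows))

    try:
        from Bio import SeqIO

        refs = {r.id.split("|")[0]: str(r.seq).upper()
                for r in SeqIO.parse(cfg.references, "fasta")}
        unannotated = [t for t in kept if t.sequence not in matches]
        annotations, _ = nv.discover(unannotated, refs, cfg.criteria,
                                     cfg.flank5, cfg.flank3)
    except Exception as exc:
        raise PipelineError("novel", str(exc)) from exc
    with open(paths["novel"], "w") as fh:
        fh.write(nv.novel_tsv(annotations))

    try:
        counts: dict[str, tuple[int, int]] = {}
        per_mature: dict[str, tuple[int, int]] = {}
        for seq, m in matches.items():
            tag = next(t for t in kept if t.sequence == seq)
            br, bs = per_mature.get(m.mature_id, (0, 0))
            per_mature[m.mature_id] = (br + tag.count_BR, bs + tag.count_BS)
        counts.update(per_mature)
        for a in annotations:
            counts[a.name] = (a.reads_BR, a.reads_BS)
        n1, n2 = stats_br.clean, stats_bs.clean
        de_records = de.call_differential(counts, n1, n2, cfg.fc_cut,
                                          cfg.p_cut, cfg.two_sided)
    except Exception as exc:
        raise PipelineError("diffexpr", str(exc)) from exc
    with open(paths["diffexpr"], "w") as fh:
        fh.write(de.diffexpr_tsv(de_records))

    try:
        trans_path = cfg.transcripts or cfg.references
        transcripts = {r.id.split("|")[0]: str(r.seq).upper()
                       for r in SeqIO.parse(trans_path, "fasta")}
        sequences: dict[str, str] = {}
        for a in annotations:
            sequences[a.name] = a.mature_sequence
        for rec in mature_db:
            sequences[rec.mature_id] = rec.sequence
        called = {r.mirna_id for r in de_records if r.call in ("up", "down")}
        sites: list[tg.TargetSite] = []
        for mid in sorted(called):
            if mid in sequences:
                sites.extend(tg.scan_transcripts(
                    sequences[mid], transcripts, cfg.target_cutoff,
                    cfg.target_max_gap, mirna_id=mid))
    except Exception as exc:
        raise PipelineError("targets", str(exc)) from exc
    with open(paths["targets"], "w") as fh:
        fh.write(tg.target_tsv(sites))

    manifest = asdict(cfg)
    manifest["criteria"] = asdict(cfg.criteria)
    manifest["stage_counts"] = {
        "raw_BR": stats_br.raw, "raw_BS": stats_bs.raw,
        "clean_BR": stats_br.clean, "clean_BS": stats_bs.clean,
        "unique_tags": len(tags), "ncrna_removed": len(removed),
        "tags_kept": len(kept), "known_families": len(family_rows),
        "novel_mirnas": len(annotations),
        "de_called": sum(r.call in ("up", "down") for r in de_records),
        "target_sites": len(sites),
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return PipelineResult(stats_br, stats_bs, tags, kept, family_rows,
                          annotations, de_records, sites, paths)
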