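"""Synthetic two-library sRNA study with known ground truth.

The generator emulates the design of a two-condition (browning-resistant BR
vs browning-sensitive BS) small-RNA sequencing study: reference contigs with
planted novel-miRNA hairpins, a known mature-miRNA database with family
structure, an ncRNA contaminant database, and two read libraries containing
clean sRNA tags (known-family matches, novel hairpin arms, a heavy-tailed
background of degradation fragments dominated by the 24-nt class), plus the
removal categories a library summary table accounts for: adapter-less reads,
adapter-only reads, 5′-adapter contaminants, sub-18-nt inserts, poly(A)
reads, ncRNA fragments, and low-quality reads.

Per-library read counts are multinomial at the configured depth over expected
proportions; a planted log2 fold-change plan biases the two libraries'
proportions so that expected counts have ratio 2^fc. The truth table records
the *realized* expected counts and their exact log2 ratio (the estimand the
pipeline is later judged against), alongside the planned value. Identical
seeds give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml

from ._seq import normalize, revcomp
from .fold import FoldResult, duplex_stats, fold
from .preprocess import Read

# length distribution of background degradation fragments (24-nt dominant,
# 21-nt the secondary class, mirroring a typical plant sRNA library)
_BG_LENGTH_DIST = {
    18: 0.01, 19: 0.01, 20: 0.02, 21: 0.06, 22: 0.03, 23: 0.03, 24: 0.78,
    25: 0.02, 26: 0.01, 27: 0.01, 28: 0.01, 29: 0.005, 30: 0.005,
}
_MATURE_LENGTH_DIST = {20: 0.10, 21: 0.55, 22: 0.20, 23: 0.15}

#: planned log2 fold changes cycled over planted miRNAs: mostly null, a few
#: moderate and strong effects in both directions, balanced so the two
#: libraries keep comparable clean totals
_FC_CYCLE = (0.0, 1.0, -1.0, 0.0, 2.0, 0.0, -1.0, 1.0, 0.0, -2.0)

DEFAULT_CONTAMINANTS = {
    "adapter3_null": 0.0096,
    "insert_null": 0.0014,
    "adapter5_contaminant": 0.0005,
    "smaller_than_min": 0.027,
    "polyA": 0.0003,
    "low_quality": 0.010,
    "ncrna": 0.150,
}

HIGH_Q = 38
LOW_Q = 8


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    rng_seed: int = 0
    n_background_refs: int = 20
    ref_length: int = 2000
    n_known_families: int = 30
    members_per_family: int = 2
    n_conserved_families: int = 24
    n_novel_hairpins: int = 10
    n_star_detectable: int = 5
    library_depth: int = 100_000
    planted_fc_plan: dict[str, float] | None = None
    contaminant_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTAMINANTS))
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    read_length: int = 42
    error_rate: float = 0.001
    n_background_tags: int = 500
    mirna_clean_fraction: float = 0.42
    star_weight: float = 0.08
    shuffle_reads: bool = True

    def validate(self) -> None:
        fr = self.contaminant_fractions
        if any(not 0 <= v <= 1 for v in fr.values()):
            raise ValueError("contaminant fractions must lie in [0, 1]")
        if sum(fr.values()) >= 1:
            raise ValueError("contaminant fractions must sum to < 1")
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if self.n_star_detectable > self.n_novel_hairpins:
            raise ValueError("n_star_detectable must be <= n_novel_hairpins")
        if self.n_background_refs <= 0 or self.ref_length < 300:
            raise ValueError("need at least one reference of >= 300 nt")


@dataclass(frozen=True)
class PlantedHairpin:
    """A constructed stem-loop with its intended duplex geometry."""

    sequence: str
    mature_start: int
    mature_len: int
    star_start: int
    star_len: int
    arm: str
    n_bulges: int
    fold: FoldResult

    @property
    def mature(self) -> str:
        return self.sequence[self.mature_start:self.mature_start + self.mature_len]

    @property
    def star(self) -> str:
        return self.sequence[self.star_start:self.star_start + self.star_len]


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one planted sRNA entity."""

    entity_id: str
    kind: str               # "known" | "novel" | "star"
    sequence: str
    family: str
    arm: str
    ref_id: str             # "" for known matures (database-only)
    precursor_start: int    # -1 when not placed on a reference
    precursor_end: int
    expected_BR: float
    expected_BS: float
    true_fc: float          # log2 of expected-count ratio (equal depths)
    planned_fc: float
    star_planted: bool


@dataclass
class SimulatedBundle:
    """Everything one simulation run produces, in memory."""

    config: SimulationConfig
    reads_BR: list[Read]
    reads_BS: list[Read]
    truth: list[TruthRow]
    references: dict[str, str]
    mature_db: list[tuple[str, str, bool, str]]   # id, family, conserved, seq
    hairpin_db: dict[str, str]
    ncdb: list[tuple[str, str, str]]              # id, class, seq
    category_expected: dict[str, float]           # per-library expected reads


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _noncomplementary(rng: np.random.Generator, base: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[base]
    choices = [b for b in "ACGT" if b != comp]
    return choices[rng.integers(0, len(choices))]


def plant_hairpin(
    mature: str,
    n_bulges: int,
    loop_len: int,
    rng: np.random.Generator,
    arm: str = "5p",
    overhang3: int = 2,
    folder: Callable[[str], FoldResult] = fold,
    max_attempts: int = 100,
    energy_bound: float | None = -20.0,
    mfei_bound: float | None = -0.90,
) -> PlantedHairpin:
    """Construct a stem-loop around ``mature`` and verify it folds back.

    The star strand is the reverse complement of the mature (minus the
    ``overhang3``-nt 3′ overhang) with ``n_bulges`` single-base asymmetries
    inserted; construction is retried with fresh random choices until the
    built-in folder confirms at least 16 paired mature positions and exactly
    the requested bulge count, or raises after ``max_attempts``.
    """
    m = normalize(mature)
    if not 18 <= len(m) <= 25:
        raise ValueError("mature length must be within 18-25 nt")
    if n_bulges > 4:
        raise ValueError("n_bulges must be <= 4")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be '5p' or '3p'")
    L = len(m)
    core = revcomp(m[: L - overhang3] if overhang3 else m)
    for _ in range(max_attempts):
        star = list(core)
        if n_bulges:
            slots = rng.choice(np.arange(2, len(core) - 2), size=n_bulges,
                               replace=False)
            for pos in sorted(slots, reverse=True):
                star.insert(int(pos), _random_seq(rng, 1))
        tail = "".join(
            _noncomplementary(rng, m[L - overhang3 + k]) for k in range(overhang3)
        )
        star_seq = "".join(star) + tail
        loop = _random_seq(rng, loop_len)
        if arm == "5p":
            seq = m + loop + star_seq
            mstart, sstart = 0, L + loop_len
        else:
            seq = star_seq + loop + m
            mstart, sstart = len(star_seq) + loop_len, 0
        fr = folder(seq)
        ds = duplex_stats(fr, mstart, L)
        if ds.in_loop or ds.overlap_bp < min(16, L - overhang3):
            continue
        if ds.n_bulges != n_bulges:
            continue
        if energy_bound is not None and fr.energy > energy_bound:
            continue  # generator stays self-consistent with the screen
        if mfei_bound is not None:
            gc = sum(seq.count(b) for b in "GC") / len(seq)
            if gc == 0 or fr.energy / len(seq) / gc > mfei_bound:
                continue  # hairpin must clear the MFE-index screen too
        # self-consistency by construction: the precursor must pass the
        # very screen the discovery stage applies
        from .novel import Criteria, PrecursorCandidate, Rejection, \
            evaluate_candidate
        from .preprocess import UniqueTag

        cand = PrecursorCandidate("synthetic", 0, len(seq), "+", seq,
                                  UniqueTag(m, 1, 1), mstart, arm)
        if isinstance(evaluate_candidate(cand, (), Criteria(min_count=0),
                                         folder), Rejection):
            continue
        return PlantedHairpin(seq, mstart, L, sstart, len(star_seq), arm,
                              n_bulges, fr)
    raise RuntimeError(
        f"could not construct a verifiable hairpin for {mature!r} "
        f"after {max_attempts} attempts"
    )


def _hamming_min(seq: str, others: Sequence[str]) -> int:
    best = len(seq) + 1
    for o in others:
        if len(o) == len(seq):
            best = min(best, sum(a != b for a, b in zip(seq, o)))
    return best


def _contains_adapter_seed(config: SimulationConfig, seq: str) -> bool:
    # keep generated inserts free of adapter seeds so category accounting
    # stays exact
    return config.adapter3[:8] in seq or config.adapter5[:8] in seq


def _sample_len(rng: np.random.Generator, dist: dict[int, float]) -> int:
    lens = sorted(dist)
    probs = np.array([dist[L] for L in lens], dtype=float)
    return int(rng.choice(lens, p=probs / probs.sum()))


def _make_read(insert: str, cfg: SimulationConfig, name: str,
               quality: int = HIGH_Q) -> Read:
    seq = (insert + cfg.adapter3 + "A" * cfg.read_length)[: cfg.read_length]
    return Read(seq, [quality] * len(seq), name)


def simulate_libraries(config: SimulationConfig) -> SimulatedBundle:
    """Generate the full synthetic study (references, databases, two
    libraries, truth table). Deterministic for a fixed config."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    refs = {
        f"TR{i + 1}": _random_seq(rng, config.ref_length)
        for i in range(config.n_background_refs)
    }

    # --- known mature database with family structure -----------------------
    mature_db: list[tuple[str, str, bool, str]] = []
    known_seqs: list[str] = []
    hairpin_db: dict[str, str] = {}
    for f in range(config.n_known_families):
        family = f"miR{1001 + f}"
        conserved = f < config.n_conserved_families
        for mbr in range(config.members_per_family):
            while True:
                seq = _random_seq(rng, _sample_len(rng, _MATURE_LENGTH_DIST))
                if _hamming_min(seq, known_seqs) <= 4 \
                        or _contains_adapter_seed(config, seq):
                    continue
                try:
                    hp = plant_hairpin(seq, int(rng.integers(0, 3)),
                                       int(rng.integers(4, 9)), rng,
                                       arm="5p" if mbr % 2 == 0 else "3p")
                except RuntimeError:
                    continue  # redraw a mature that folds into a hairpin
                break
            mid = f"{family}{chr(97 + mbr)}"
            mature_db.append((mid, family, conserved, seq))
            known_seqs.append(seq)
            hairpin_db[f"{mid}-precursor"] = hp.sequence

    # --- novel hairpins embedded in the references --------------------------
    novel: list[tuple[str, PlantedHairpin, str, int]] = []  # id, hp, ref, at
    ref_ids = sorted(refs)
    for i in range(config.n_novel_hairpins):
        while True:
            seq = _random_seq(rng, _sample_len(rng, _MATURE_LENGTH_DIST))
            if _hamming_min(seq, known_seqs) <= 4 \
                    or _contains_adapter_seed(config, seq):
                continue
            try:
                hp = plant_hairpin(seq, int(rng.integers(0, 4)),
                                   int(rng.integers(4, 9)), rng,
                                   arm="5p" if i % 2 == 0 else "3p")
            except RuntimeError:
                continue  # redraw a mature that folds into a hairpin
            break
        rid = ref_ids[i % len(ref_ids)]
        margin = 200
        at = int(rng.integers(margin, config.ref_length - margin - len(hp.sequence)))
        refs[rid] = refs[rid][:at] + hp.sequence + refs[rid][at + len(hp.sequence):]
        novel.append((f"novel{i + 1}", hp, rid, at))
        known_seqs.append(seq)

    # --- ncRNA contaminant database -----------------------------------------
    ncdb = []
    for cls in ("rRNA", "tRNA", "snRNA", "snoRNA"):
        for k in range(2):
            ncdb.append((f"{cls}{k + 1}", cls, _random_seq(rng, 240)))

    # --- expression plan -----------------------------------------------------
    entities: list[dict] = []
    for mid, family, conserved, seq in mature_db:
        entities.append({"id": mid, "kind": "known", "seq": seq,
                         "family": family, "arm": "", "ref": "",
                         "p0": -1, "p1": -1, "star": False})
    for nid, hp, rid, at in novel:
        entities.append({"id": nid, "kind": "novel", "seq": hp.mature,
                         "family": "", "arm": hp.arm, "ref": rid,
                         "p0": at, "p1": at + len(hp.sequence),
                         "star": False})
    for j, (nid, hp, rid, at) in enumerate(novel):
        if j < config.n_star_detectable:
            entities.append({"id": f"{nid}*", "kind": "star",
                             "seq": hp.star, "family": "", "arm": "",
                             "ref": rid, "p0": at,
                             "p1": at + len(hp.sequence), "star": True})

    plan = dict(config.planted_fc_plan or {})
    if config.planted_fc_plan is None:
        k = 0
        for e in entities:
            if e["kind"] in ("known", "novel"):
                plan[e["id"]] = _FC_CYCLE[k % len(_FC_CYCLE)]
                k += 1
    base = np.clip(rng.lognormal(0.3, 0.6, len(entities)), 1.0, 4.0)
    w_br = np.empty(len(entities))
    w_bs = np.empty(len(entities))
    for i, e in enumerate(entities):
        b = config.star_weight if e["kind"] == "star" else base[i]
        fc = float(plan.get(e["id"], 0.0))
        e["fc_planned"] = fc
        w_br[i] = b * 2.0 ** fc if fc >= 0 else b
        w_bs[i] = b if fc >= 0 else b * 2.0 ** (-fc)

    # --- background degradation tag pool ------------------------------------
    # drawn outside planted hairpin loci: shifted fragments of a genuine
    # precursor are arm isomiRs, not background
    planted_at: dict[str, list[tuple[int, int]]] = {}
    for _, hp, rid, at in novel:
        planted_at.setdefault(rid, []).append((at, at + len(hp.sequence)))
    bg: list[tuple[str, float]] = []
    seen = set(e["seq"] for e in entities)
    while len(bg) < config.n_background_tags:
        rid = ref_ids[int(rng.integers(0, len(ref_ids)))]
        L = _sample_len(rng, _BG_LENGTH_DIST)
        at = int(rng.integers(0, config.ref_length - L))
        if any(at < hi and at + L > lo for lo, hi in planted_at.get(rid, ())):
            continue
        frag = refs[rid][at:at + L]
        if frag in seen or _contains_adapter_seed(config, frag):
            continue
        seen.add(frag)
        bg.append((frag, float(rng.lognormal(0.0, 1.2))))

    # --- ncRNA fragment pool -------------------------------------------------
    ncfrag: list[tuple[str, float]] = []
    while len(ncfrag) < 60:
        _, _, seq = ncdb[int(rng.integers(0, len(ncdb)))]
        L = _sample_len(rng, _BG_LENGTH_DIST)
        at = int(rng.integers(0, len(seq) - L))
        frag = seq[at:at + L]
        if frag in seen or _contains_adapter_seed(config, frag):
            continue
        seen.add(frag)
        ncfrag.append((frag, float(rng.lognormal(0.0, 1.0))))

    # --- assemble per-library probability vectors ----------------------------
    fr = config.contaminant_fractions
    contaminant_names = list(fr)
    clean_frac = 1.0 - sum(fr.values())
    mir_frac = clean_frac * config.mirna_clean_fraction
    bg_frac = clean_frac - mir_frac

    bg_w = np.array([w for _, w in bg])
    bg_p = bg_w / bg_w.sum() * bg_frac
    nc_w = np.array([w for _, w in ncfrag])

    items: list[tuple[str, object]] = []       # (kind, payload)
    probs_br: list[float] = []
    probs_bs: list[float] = []
    for i, e in enumerate(entities):
        items.append(("entity", e))
        probs_br.append(w_br[i] / w_br.sum() * mir_frac)
        probs_bs.append(w_bs[i] / w_bs.sum() * mir_frac)
    for (fragseq, _), p in zip(bg, bg_p):
        items.append(("bg", fragseq))
        probs_br.append(p)
        probs_bs.append(p)
    for fragseq, w in ncfrag:
        items.append(("ncrna", fragseq))
        probs_br.append(w / nc_w.sum() * fr["ncrna"])
        probs_bs.append(w / nc_w.sum() * fr["ncrna"])
    for name in contaminant_names:
        if name == "ncrna":
            continue
        items.append(("category", name))
        probs_br.append(fr[name])
        probs_bs.append(fr[name])

    pv_br = np.array(probs_br)
    pv_bs = np.array(probs_bs)
    pv_br /= pv_br.sum()
    pv_bs /= pv_bs.sum()

    counts_br = rng.multinomial(config.library_depth, pv_br)
    counts_bs = rng.multinomial(config.library_depth, pv_bs)

    # --- truth table ----------------------------------------------------------
    truth: list[TruthRow] = []
    for i, e in enumerate(entities):
        exp_br = float(pv_br[i] * config.library_depth)
        exp_bs = float(pv_bs[i] * config.library_depth)
        truth.append(TruthRow(
            e["id"], e["kind"], e["seq"], e["family"], e["arm"], e["ref"],
            e["p0"], e["p1"], exp_br, exp_bs,
            float(np.log2(exp_br / exp_bs)), e["fc_planned"],
            bool(e["star"] or (e["kind"] == "novel" and any(
                t["id"] == e["id"] + "*" for t in entities))),
        ))

    # --- materialize reads ----------------------------------------------------
    def build_reads(counts: np.ndarray, lib: str) -> list[Read]:
        reads: list[Read] = []
        serial = 0
        for (kind, payload), c in zip(items, counts):
            if c == 0:
                continue
            if kind in ("entity", "bg", "ncrna"):
                insert = payload["seq"] if kind == "entity" else payload
                n_err = int(rng.binomial(
                    c, min(1.0, config.error_rate * len(insert))))
                for r in range(int(c)):
                    serial += 1
                    ins = insert
                    if r < n_err:
                        pos = int(rng.integers(0, len(insert)))
                        sub = "ACGT"[int(rng.integers(0, 4))]
                        ins = insert[:pos] + sub + insert[pos + 1:]
                    reads.append(_make_read(ins, config, f"{lib}_{serial}"))
            else:
                for _ in range(int(c)):
                    serial += 1
                    name = f"{lib}_{serial}"
                    if payload == "adapter3_null":
                        while True:
                            s = _random_seq(rng, config.read_length)
                            if config.adapter3[:8] not in s \
                                    and config.adapter5[:8] not in s:
                                break
                        reads.append(Read(s, [HIGH_Q] * len(s), name))
                    elif payload == "insert_null":
                        reads.append(_make_read("", config, name))
                    elif payload == "adapter5_contaminant":
                        ins = config.adapter5 + _random_seq(rng, 8)
                        reads.append(_make_read(ins, config, name))
                    elif payload == "smaller_than_min":
                        reads.append(_make_read(
                            _random_seq(rng, int(rng.integers(10, 18))),
                            config, name))
                    elif payload == "polyA":
                        reads.append(_make_read(
                            "A" * int(rng.integers(20, 27)), config, name))
                    elif payload == "low_quality":
                        reads.append(_make_read(
                            _random_seq(rng, 24), config, name, quality=LOW_Q))
        if config.shuffle_reads:
            order = rng.permutation(len(reads))
            reads = [reads[int(i)] for i in order]
        return reads

    reads_br = build_reads(counts_br, "BR")
    reads_bs = build_reads(counts_bs, "BS")

    cat_exp = {name: float(fr[name] * config.library_depth)
               for name in contaminant_names}
    return SimulatedBundle(config, reads_br, reads_bs, truth, refs,
                           mature_db, hairpin_db, ncdb, cat_exp)


# --------------------------------------------------------------------------
# file output
# --------------------------------------------------------------------------

def _write_fastq(reads: Sequence[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in (r.quality or []))
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{qual}\n")


def _write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def truth_tsv(truth: Sequence[TruthRow]) -> str:
    lines = ["entity_id\tkind\tsequence\tfamily\tarm\tref_id\tprecursor_start"
             "\tprecursor_end\texpected_BR\texpected_BS\ttrue_fc\tplanned_fc"
             "\tstar_planted"]
    for t in truth:
        lines.append(
            f"{t.entity_id}\t{t.kind}\t{t.sequence}\t{t.family}\t{t.arm}\t"
            f"{t.ref_id}\t{t.precursor_start}\t{t.precursor_end}\t"
            f"{t.expected_BR:.3f}\t{t.expected_BS:.3f}\t{t.true_fc:.4f}\t"
            f"{t.planned_fc:.1f}\t{int(t.star_planted)}"
        )
    return "\n".join(lines) + "\n"


def write_bundle(bundle: SimulatedBundle, outdir) -> dict[str, str]:
    """Write the bundle to ``outdir``; returns the path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "reads_BR": os.path.join(outdir, "reads_BR.fastq"),
        "reads_BS": os.path.join(outdir, "reads_BS.fastq"),
        "references": os.path.join(outdir, "references.fasta"),
        "mature_db": os.path.join(outdir, "mature_db.fasta"),
        "hairpin_db": os.path.join(outdir, "hairpin_db.fasta"),
        "ncdb": os.path.join(outdir, "ncdb.fasta"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "config": os.path.join(outdir, "config.yaml"),
    }
    _write_fastq(bundle.reads_BR, paths["reads_BR"])
    _write_fastq(bundle.reads_BS, paths["reads_BS"])
    _write_fasta(sorted(bundle.references.items()), paths["references"])
    _write_fasta(
        [(f"{mid}|{family}|{int(cons)}", seq)
         for mid, family, cons, seq in bundle.mature_db],
        paths["mature_db"])
    _write_fasta(sorted(bundle.hairpin_db.items()), paths["hairpin_db"])
    _write_fasta([(f"{rid}|{cls}", seq) for rid, cls, seq in bundle.ncdb],
                 paths["ncdb"])
    with open(paths["truth"], "w") as fh:
        fh.write(truth_tsv(bundle.truth))
    cfg = dict(bundle.config.__dict__)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
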