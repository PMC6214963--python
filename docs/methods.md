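# Methods

This note documents the models, parameter choices, and numerical decisions
behind `srnamir`, and what the synthetic-data experiments do and do not
demonstrate.

## Read classification

A raw read is first quality-filtered (mean Phred ≥ `quality_floor`,
default 20). Adapter detection is seed-and-extend: an exact match of the
adapter's first 8 nt anywhere in the read, extended over the remaining
adapter bases tolerating one mismatch (truncated adapters at the read end
are accepted). The removal categories are assigned with a fixed precedence —
5′-adapter contaminant > insert-null > 3′-adapter-null > poly(A) >
shorter-than-minimum — so each read lands in exactly one category and the
counts sum to the high-quality total on every input; that conservation
identity is asserted in tests and in the acceptance run.

Choices worth noting:

* The clean window defaults to 18–30 nt. Descriptions of such experiments
  variously quote 15–30 nt, an 18-nt lower bound, and read lengths up to
  45 nt; 18–30 is the self-consistent reading of a size-selected plant sRNA
  library, and both ends are configurable.
* A read with no 3′ adapter is adapter-null when it is longer than the clean
  window (the raw-read case). An in-window sequence with no adapter
  re-classifies as clean, which makes trimming idempotent — already-trimmed
  tags can be re-fed to the classifier unchanged.
* An insert trimming to more than `max_len` is counted under adapter-null: a
  genuine size-selected insert must terminate in adapter within the window,
  so an adapter that far out is treated as absent. The published accounting
  shape has no long-insert category.
* Poly(A) means ≥ 80 % A after trimming; "low quality" and "poly(A)" carry
  no standard definitions, so both cutoffs are explicit parameters.

## ncRNA filtering and known-miRNA assignment

Structural-ncRNA filtering uses exact substring matching against a classed
database on both strands — the conservative, fully reproducible stand-in
for a BLASTn screen whose thresholds are rarely reported. Class precedence
for multi-class hits is rRNA > tRNA > snRNA > snoRNA.

Known-miRNA assignment is equal-length ungapped Hamming comparison with at
most `max_mismatch` (default 2) mismatches; no isomiR length variants are
matched. A tag matching several database entries is assigned to its
minimum-distance hit, with ties broken lexicographically by family then
mature id, so assignment is deterministic. Family-table ratios are BS/BR
rounded half-away-from-zero to two decimals; a family absent from the BR
library has an undefined ratio rendered "—", while one absent from BS
prints 0.00 — both conventions read directly from the published table this
report format mirrors.

## The built-in folder

The folder computes the optimal *nested* structure under a simplified
energy model: a base pair stacked directly on another pair contributes
GC/CG −3.0, AU/UA −2.0, or GU/UG −1.0 kcal/mol, and every pair that is not
stacked — each helix's innermost, loop-closing pair — pays +4.0 kcal/mol,
the coarse analogue of thermodynamic loop/bulge initiation. Unpaired bases
are free and hairpin loops enclose at least 3 nt. The dynamic program keeps
three matrices (paired / unpaired-ends / overall) with deterministic
tie-breaking (more pairs, then 5′-most pairing), and is verified against an
exhaustive enumeration oracle for all structures of short sequences.

The loop-closure term matters: with stack bonuses alone, a structure
stitched from many 3–4-bp helices scores as well as one long helix, random
sequence folds almost as "stably" as a real hairpin, and an absolute-energy
screen separates nothing. +4.0 kcal/mol sits in the range of thermodynamic
bulge/interior-loop initiation penalties and restores the screening power
the energy criterion is meant to have. The model is still deliberately far
from a full nearest-neighbour parameterization — no loop-size dependence,
no dangles, no AU-end terms — and its absolute energies are not comparable
to RNAfold's; a thermodynamic folder can be plugged in via the
`ExternalFolder` adapter, in which case its energies are used verbatim.

## Novel-miRNA screening

For each unannotated tag with at least `min_count` (default 5) reads and a
perfect-match genomic hit, two windows are excised (tag as 5p arm: 10 nt
upstream to 160 nt downstream; tag as 3p arm mirrored; both clipped to the
reference). Rather than folding the whole window — whose flanks entangle
with the hairpin — the star arm is *located*: the mature is aligned against
the flank on the hypothesised star side with the same gapped alignment DP
the target scanner uses (unweighted, up to 4 gaps), and the best few anchors
each define a tight trial precursor spanning mature and star. Each trial is
folded and screened; the lowest-MFE passing trial wins, and every rejection
carries a machine-readable reason code.

Acceptance criteria (all configurable, defaults follow the conventions of
stem-loop predictors in the MIREAP tradition):

| criterion | default | reason code |
|---|---|---|
| mature length | 18–25 nt | `mature_length` |
| precursor length | ≥ 39 nt (two 18-nt arms + 3-nt loop) | `precursor_too_short` |
| mature on a stem arm | — | `mature_in_loop` |
| star pairing disjoint from mature | — | `star_overlap` |
| loop separation mature↔star | ≤ 35 nt | `loop_too_long` |
| paired mature positions | ≥ 16 bp | `min_overlap` |
| bulges in the duplex (either strand) | ≤ 4 | `max_bulges` |
| duplex asymmetry (star span − mature span) | ≤ 4 nt | `asymmetry` |
| precursor MFE | ≤ −18 kcal/mol | `mfe` |
| MFE index (100·MFE/LP/GC%) | ≤ −0.85 | `mfei` |
| star reads present (±2 nt) | recorded, optional | `no_star` |

A "bulge" is a maximal run of unpaired positions strictly inside the
mature or star interval; internal loops count once per strand. Star-read
presence raises confidence but is not required by default — passenger
strands are usually degraded away, and requiring them would discard most
genuine candidates; `require_star=True` enforces it. Accepted matures whose
intervals overlap on the same reference strand are collapsed to the
dominant (highest-read) product; the 5p and 3p arms of one hairpin do not
overlap and are reported as separate records, named `Lc-miRn{i}-{arm}` in
order of genomic location. Reported coordinates are 0-based half-open
internally and 1-based inclusive in reports.

Residual false discoveries exist by construction: random 40-kb references
contain a few loci that satisfy *every* criterion above — including under a
full thermodynamic folder — so precision against planted truth saturates
around 0.85–1.0 depending on the seed (≈ 0–3 such loci per run at the
default study scale). They are indistinguishable from real miRNA loci by
structure alone; real surveys prune them with cross-species conservation or
degradome evidence, both out of scope here.

## Differential expression

Counts are normalized per million clean reads of their own library
(post-preprocess totals; whether to exclude ncRNA-filtered reads from the
denominator is configurable). A normalized zero becomes 0.01 so fold
changes stay finite. The significance test is the exact conditional
(Audic–Claverie) test; the implementation uses the identity that
P(y | x) is negative binomial with r = x+1 and p = N1/(N1+N2), evaluated by
scipy in log space, and the test suite checks it against direct log-space
summation. The default p-value is two-sided by tail doubling. Note the
statistic conditions on the first library's count, so swapping the
libraries is only *approximately* symmetric in p (exactly antisymmetric in
fold change and in the up/down call); the approximation is excellent for
moderate counts. No multiple-testing correction enters the calls (the
published rule is raw p ≤ 0.05 with |log₂ FC| ≥ 1); a Benjamini–Hochberg
column is emitted for reference.

## Target prediction

The expectation score E follows the canonical plant-target scheme:
mismatch 1.0, G:U wobble 0.5, gap/bulge 2.0 per position, doubled at miRNA
positions 2–13 from the 5′ end, cutoff 3.0, at most one gap by default.
Alignments are anchored at the site's 3′-most base (facing miRNA position
1); a vectorized DP scores every anchor position and a per-anchor traceback
DP reconstructs the best alignment for reporting. Sites whose best
alignment disrupts (mismatch or gap) miRNA positions 9–11 are called
translational inhibition, otherwise cleavage. Overlapping candidate sites
for one miRNA/transcript pair are resolved greedily by (E, position). The
scanner is validated against explicit enumeration of all ≤ 1-gap
alignments.

## The synthetic study

The generator emulates a two-condition plant sRNA experiment: 20 random
2-kb reference contigs; 30 known families × 2 members with stem-loop
precursors; 10 novel hairpins embedded in the references, 5 of them with
expressed star reads; two libraries of 100 000 reads each. Removal
categories follow the accounting shape of such studies (≈ 1 %
adapter-null, 0.14 % insert-null, 0.05 % 5′-contaminant, 2.7 % short,
trace poly(A), 1 % low-quality, 15 % ncRNA fragments). Clean reads split
42 % miRNA-derived and 58 % background degradation fragments whose length
distribution is dominated by the 24-nt class with 21 nt second, mirroring
the length profile such libraries report. Abundances are log-normal
(heavy-tailed, like published family tables); per-library counts are
multinomial at the configured depth; substitution noise is uniform at
10⁻³ per base.

Planted log₂ fold changes cycle through {0, +1, −1, 0, +2, 0, −1, +1, 0,
−2} over the planted miRNAs — balanced so both libraries keep comparable
clean totals — and the truth table records the *realized* expected counts
and their exact log ratio (the estimand), alongside the planned value.
Hairpin construction places the star (reverse complement of the mature
minus a 2-nt 3′ overhang, with the requested bulge insertions) across a
4–8-nt loop and retries random choices until the construct passes the very
screen the discovery stage applies, so generator and caller are
self-consistent by construction; matures that cannot support such a hairpin
are redrawn. Background fragments avoid planted loci (a shifted fragment of
a real precursor is an arm isomiR, not background) and all generated
inserts avoid adapter seeds so the category accounting stays exact.

What passing these simulations does *not* show: performance on real
libraries with sequencing-error structure, isomiR raggedness, repetitive
genomes, or non-uniform background composition; the generator's
distributions are stand-ins chosen for plausibility, not estimates fitted
to any dataset. Dataset-level figures from real studies (total miRNA
counts, average precursor MFE under a thermodynamic model, target counts
on a real transcriptome) are intentionally out of reach at this scale.

## Problem sizes and runtime

Default experiments are sized for a single CPU: the full two-library study
(2 × 10⁵ reads) simulates in ~4 s and the complete pipeline runs in ~10 s;
the folding oracle checks 200 sequences of ≤ 14 nt against exhaustive
enumeration in well under a second; null calibration uses 2 000 simulated
tag pairs at depth 10⁶. The folding DP is O(n³) with numba-compiled inner
loops (~5 ms at 190 nt, ~2 s at the 1 000-nt cap).
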