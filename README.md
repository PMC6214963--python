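# srnamir

Small-RNA sequencing analysis for two-condition miRNA studies in plants:
read cleanup and classification, structural-ncRNA filtering, known-miRNA
family expression tables, stem-loop screening for novel miRNAs, exact
two-library differential expression, and miRNA target prediction by
complementarity scoring. A synthetic-data generator with full ground truth
makes every stage testable end to end.

The package is aimed at analysts working with paired sRNA libraries from
contrasting genotypes or treatments (for example browning-resistant vs
browning-sensitive fruit lines) who want a transparent, reproducible
re-implementation of the classic sRNA-seq miRNA-discovery workflow rather
than a chain of web servers and legacy binaries.

## What it computes

**Read accounting.** Raw reads are quality-filtered (mean Phred ≥ 20 by
default) and each high-quality read is assigned to exactly one category —
clean, 3′-adapter-null, insert-null, 5′-adapter contaminant, shorter than
18 nt, or poly(A) — so category counts always sum to the high-quality total.
Clean inserts (18–30 nt) are collapsed to unique tags with per-library
counts; tags matching rRNA/tRNA/snRNA/snoRNA records exactly (either strand)
are removed.

**Known miRNAs.** Tags are compared to a mature-miRNA database by
equal-length Hamming distance with at most 2 mismatches; the family table
reports members, per-library reads, totals, and the BS/BR ratio rounded to
two decimals.

**Novel miRNAs.** Unannotated tags that map perfectly to the reference are
screened as stem-loop candidates. The star arm is located by a gapped
complementarity scan of the flanking sequence, trial precursors are folded
with a built-in minimum-free-energy folder, and a candidate is accepted iff
its mature is 18–25 nt on a stem arm, pairs the star over ≥ 16 bp with ≤ 4
bulges and ≤ 4 nt duplex asymmetry within ≤ 35 nt of loop separation, and
the precursor reaches MFE ≤ −18 kcal/mol with an MFE index ≤ −0.85.
Detection of star reads (±2 nt) is recorded as supporting evidence.

**Differential expression.** Counts are normalized to reads per million
(zeros become 0.01), the fold change is log₂(RPM_BR / RPM_BS), and
significance uses the exact Audic–Claverie conditional test

    P(Y = y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

two-sided by tail doubling. Calls require |log₂ FC| ≥ 1 and p ≤ 0.05;
miRNAs with RPM < 1 in both libraries are skipped.

**Targets.** A miRNA is aligned antiparallel against transcript windows;
mismatches cost 1.0, G:U wobbles 0.5, gaps 2.0, all doubled at miRNA
positions 2–13, and sites with expectation E ≤ 3.0 are reported with a
cleavage/translation call based on positions 9–11.

## Worked example

Simulate a two-library study and run every stage:

```
srnamir simulate --seed 7 --depth 50000 --outdir sim
srnamir all --config pipeline.yaml     # paths to the sim/ files + outdir
```

The run writes seven TSV reports plus a YAML manifest. Excerpts from an
actual run with the commands above:

```
category       BR_count  BR_percent  BS_count  BS_percent
raw            50000               50000
high_quality   49515     100.00    49508     100.00
clean          47530      95.99    47599      96.14

family   members  reads_BR  reads_BS  total  ratio_BS_BR  conserved
miR1001  2        424       274       698    0.65         1
miR1002  2        372       477       849    1.28         1

miRNA        mature_5p_to_3p           length  LP  MFE    reads_BR  reads_BS  arm  location  star_detected
Lc-miRn1-3p  TTCACTTGCTAAGCTGTACGCGT   23      54  -35.0  13        5         3p   TR1       1
Lc-miRn2-5p  GCGTACACTTACAAGTGAATG     21      52  -32.0  312       263       5p   TR1       1

Lc-miRn11-5p  623  131  13107.51  2752.16  2.2518  7.0e-78  up
Lc-miRn16-3p  301  1125  6332.84  23634.95 -1.9000  1.0e-111 down
```

Reading the excerpts: 95–96 % of reads survive as clean inserts and the
category counts sum to the high-quality totals; family miR1001 was seen with
424 reads in the BR library and 274 in BS (ratio 0.65); `Lc-miRn1-3p` is a
novel miRNA on contig TR1 whose 54-nt precursor folds at −35 kcal/mol with
star reads detected; `Lc-miRn11-5p` is called up-regulated in the BR library
with an estimated log₂ fold change of 2.25. Because the data were simulated,
every one of these numbers can be checked against the written ground-truth
table (`sim/truth.tsv`).

Each stage is also exposed as its own subcommand (`preprocess`, `ncfilter`,
`known`, `novel`, `diffexpr`, `targets`) over plain FASTA/FASTQ/TSV files,
and as an ordinary Python API (`srnamir.classify_and_trim`, `srnamir.fold`,
`srnamir.discover`, `srnamir.call_differential`, ...).

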