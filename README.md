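# tsscan

Detection and quantification of clustered A-to-I RNA editing in aligned
RNA-seq data.

ADAR deaminases convert adenosine to inosine within double-stranded RNA
structures; sequencers read inosine as guanosine, so editing appears in
alignments as A>G mismatches on the sense strand or T>C on the antisense
strand. Because ADAR tends to edit many adenosines within one duplex
("hyperediting"), the signal is spatially clustered — and clusters of
moderate-frequency mismatches are exactly what single-site variant callers
discard as noise. `tsscan` targets the cluster signal directly: it is for
transcriptomicists who want to find editing regions de novo in bulk or
single-cell RNA-seq BAMs, quantify them across samples, and isolate
ADAR-dependent regions by comparing wild-type against ADAR-deficient data.

## Method

For each transition type (TsType) in {AG, CT, GA, TC} — AG and TC are the
ADAR-indicative *target* types, CT and GA serve as internal controls — the
scan slides a window of length `wSize` (default 100 nt) one nucleotide at a
time over per-position read counts and accumulates a 2×2 contingency table
over the positions with depth ≥ `minCov` (default 4):

|                      | transition reads | other reads |
|----------------------|------------------|-------------|
| query-source base    | q-Ts             | q-nTs       |
| other reference bases| nq-Ts            | nq-nTs      |

where *q-Ts* counts reads carrying the query transition (e.g. G reads at
reference-A positions for AG) and *nq-Ts* counts each other base's own
transition partner. A one-sided Fisher's exact test gives
p = P(X ≥ q-Ts) under the hypergeometric null; a window is significant if
p < α (default 0.05, **no multiple-testing correction** — false positives
are handled downstream), it contains at least `minTsSitesWindow` TsSites,
and its relative transition frequency RTF = q-Ts / (q-Ts + q-nTs) passes
`minWindowRTF`. Overlapping significant windows are merged into
**TsRegions**: `rtf_mean`/`p_mean` average the member windows, while
`rtf_exact`/`p_exact` are recomputed treating the merged span as one
window, together with the TsSite count and positions (`TsSiteCount`,
`TsPos`). *Regio* mode applies the same exact quantification to a fixed
region list (default `minCov` 8).

Downstream, candidate regions from a wild-type (WT) sample are merged
within 100 nt, removed if ≥ 50% covered by matching knockout (KO) regions,
filtered to TsSiteCount ≥ 5, and scored with the confidence indicator

    CI = (RTF_exact(WT) − RTF_exact(KO)) / RTF_exact(WT),

keeping CI ≥ 0.85. Gene-level editing is summarized as

    Δ(∑RTF) = (∑_AG RTF + ∑_TC RTF)_WT − (∑_AG RTF + ∑_TC RTF)_KO

over all target regions overlapping a gene (KO term omitted without KO
data), and analogously for TsSiteCounts.

A deterministic simulator generates reference FASTA plus pre-aligned
SAM/BAM with planted editing clusters, SNP-like variants, sequencing error
and spliced reads, together with machine-readable ground truth — every
detection claim in the test suite is checked against planted truth.

## Worked example

`python examples/01_simulate_and_scan.py` simulates a 100 kb contig at 30×
coverage (sequencing error 10⁻³) with one planted AG and one planted TC
cluster (10 sites each, editing frequency 0.3), and scans de novo:

```
planted clusters:
  c1:20000-20150 AG (10 sites at freq 0.3)
  c1:60000-60150 TC (10 sites at freq 0.3)

detected TsRegions with >= 5 TsSites (type, span, RTF_exact, p_exact, TsSiteCount):
  AG c1:19906-20225 rtf=0.0391 p=2.09e-51 sites=10
  TC c1:59901-60246 rtf=0.0310 p=6.38e-49 sites=10

33 additional low-TsSite regions from sequencing error (removed by the
TsSiteCount >= 5 downstream filter).
```

Both planted clusters are recovered with all 10 sites; the region spans
extend up to one window beyond the outermost edited site, by construction.
An RTF of 0.039 means 3.9% of all read bases at reference-A positions in
the region carry G — a 10-site cluster at editing frequency 0.3 diluted by
the region's unedited A positions. The 33 error-driven regions carry 2–4
TsSites each and vanish at the TsSiteCount ≥ 5 filter, which is why the
scan itself applies no multiple-testing correction.

`examples/02_differential_editing.py` runs the full WT/KO pipeline
(survivors come out with CI = 1.00) and `examples/03_gene_scores_and_annotation.py`
classifies regions against a gene annotation and ranks genes by Δ(∑RTF).

The same workflow is available from the shell:

```sh
tsscan simulate sim.yaml simdir
tsscan denovo simdir/sim.bam simdir/sim.fa out/ -wSize 100 -minCov 4 -tsType AG -tsType TC
tsscan regio simdir/sim.bam simdir/sim.fa out/sample.c1.AG.tsregions.gff3 regio.gff3
tsscan merge / subtract / confidence / genes / classify ...
```

deNovo writes one GFF3 per contig and TsType with the attribute schema
`type, rtf_mean, rtf_exact, p_mean, p_exact, TsSiteCount, TsPos`; Regio
writes a single GFF3 per sample and flags uncovered regions with
`not analyzed: no position has min. coverage`.

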