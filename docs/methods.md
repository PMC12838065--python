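# Methods

## Model and procedure

`tsscan` models clustered A-to-I editing as a local enrichment of one
transition type over all other mismatches. The unit of evidence is the
read base, not the site: within a window, every read base at a position
with depth ≥ `minCov` falls into one cell of a 2×2 table — rows split
positions into query-source-base vs other reference bases, columns split
reads into "carries that base's transition partner" vs "anything else"
(reference matches and transversions together). The one-sided Fisher's
exact test then asks whether transition reads concentrate on the query
rows. Pooling read bases across a window is what gives the method power on
clusters whose individual sites would not reach significance, and using
the three non-query bases as the in-window background makes the test
robust to locally elevated error or mapping noise, which inflates all
mismatch classes together.

The scan is not strand-specific: a cluster on a sense transcript appears
as AG, on an antisense transcript as TC, and both are reported as target
types. CT and GA are scanned with identical machinery as negative
controls. The implementation is exactly symmetric under
reverse-complement (AG↔TC, CT↔GA with mirrored coordinates and identical
statistics), which the test suite asserts.

Raw p-values are gated by `alpha` with **no multiple-testing correction**.
A genome-wide correction at ~10⁸ windows would suppress true moderate
clusters; instead false positives are controlled by the per-window TsSite
count / RTF thresholds and the downstream filters, all of which operate on
interpretable quantities. The practical consequence — visible in the
worked example — is a steady trickle of 2–4-site "regions" from sequencing
error that the TsSiteCount ≥ 5 filter removes.

### Windows, merging, exact statistics

Windows of `wSize` advance 1 nt over the covered span (first to last
covered position of the contig or chunk); uncovered positions contribute
nothing, and windows are anchored on genomic coordinates, which keeps
results chunk-stable. Runs of *overlapping* (≥ 1 shared position)
significant windows merge into a TsRegion; adjacency alone does not merge
at this stage — the deliberate 100-nt distance merge is a separate
downstream step. Mean statistics average member windows; exact statistics
re-analyze the merged span as a single window, which is also precisely
what Regio mode computes, so de novo output re-quantified with the same
`minCov` reproduces `rtf_exact`, `p_exact`, `TsSiteCount` and `TsPos`
bit-for-bit (asserted exactly in the tests).

A TsSite is a minCov-passing source-base position with at least
`minTsCount` (default 1) transition-partner reads; an optional per-site
minimum frequency (default 0) tightens this for noisy data. RTF is
q-Ts / (q-Ts + q-nTs): the fraction of read bases at query-source
positions carrying the transition. It is a per-base, coverage-weighted
quantity — diluted by unedited source positions in the span — and should
be read as a relative, not absolute, measure of editing.

### Contingency alternatives

Whether reference-matching reads belong in the "non-transition" cells is a
genuine design fork. They are included by default: the mismatch-only
alternative degenerates on clean data (a perfect cluster with zero
background mismatches would have empty non-transition columns and p = 1).
The alternative remains available as `mismatch_only_test` for
exploration.

## Parameters

| name | default | meaning |
|------|---------|---------|
| `w_size` | 100 nt | rolling window length; also the chunk overlap |
| `min_cov` | 4 (de novo), 8 (Regio) | per-site depth for a position to count |
| `alpha` | 0.05 | raw one-sided p-value gate per window |
| `min_ts_sites_window` | 1 | TsSites required per significant window |
| `min_window_rtf` | 0.0 | RTF floor per window |
| `min_ts_count` / `min_ts_freq` | 1 / 0.0 | per-site evidence for a TsSite |
| `chunk_size` | 50,000,000 nt | traversal chunk; chunks overlap by `w_size` |
| `primary_only` | on | drop `_random/_alt/chrUn/scaffold/_decoy/EBV` contigs |
| merge gap | 100 nt | downstream same-type distance merge |
| subtract fraction | 0.5 | KO-coverage fraction that removes a WT region |
| TsSite filter / CI | ≥ 5 / ≥ 0.85 | differential confidence thresholds |

The downstream defaults (100 nt, 50%, ≥5 sites, CI ≥ 0.85) are the
pipeline's standard operating point for isolating hyperediting clusters;
CI = 1 means editing fully abolished in the knockout, and regions with
RTF_exact(WT) = 0 are treated as not analyzable since CI divides by it.

Duplicate-marked, secondary and supplementary alignments are excluded
from the pileup; base quality and MAPQ filters default to 0/off, on the
assumption that an upstream alignment pipeline has already curated the
BAM — both are exposed as flags for other inputs. Reference-N positions
are skipped (no transition partner is defined). "Primary assembly"
selection is a name-pattern heuristic mirroring UCSC/GENCODE naming and is
user-overridable.

## Numerical choices

p-values come from the hypergeometric survival function
(`scipy.stats.hypergeom.sf`), vectorized over all windows via cumulative
sums of per-position cell contributions; any zero table margin defines
p = 1 (a single admissible table). The implementation is compared in the
tests against exhaustive enumeration in exact integer arithmetic (and
against `scipy.stats.fisher_exact`) to 1e-9 on all tables with total ≤ 60,
and agreement is at machine precision. Window significance is strict
(p < α). Coordinates are 0-based half-open internally; GFF3 I/O converts
to 1-based inclusive in one module, prints RTF/CI with 6 decimals and
p-values with 3 significant digits, and is a formatting fixpoint
(write∘read∘write is byte-identical). Windows with no minCov-passing
position yield an all-zero table flagged as empty, not an exception;
Regio regions without any covered position are reported with the error
marker `not analyzed: no position has min. coverage`.

Chunked traversal overlaps consecutive chunks by exactly `w_size`, the
minimum that places every window wholly inside some chunk; windows seen
twice in an overlap are deduplicated by start position, and chunked runs
are asserted identical to whole-contig runs. In chunked runs the exact
statistics of merged regions are recomputed from a fresh pileup of each
region span.

## What the simulator emulates — and what it does not

The generator emulates the data regime the scan targets: uniform read
starts at a configurable mean coverage (default 30×), read length 100,
per-base substitution error 10⁻³ (uniform over the three other bases),
editing clusters of 5–40 sites planted on forced source bases within a
span (default 10 sites in 150 nt, the scale of an Alu-duplex hyperediting
target, edited per-read-independently at frequency 0.05–0.8, default
0.3), SNP-like single positions at alt fraction ~0.5/1.0, and spliced
reads that skip configured intronic gaps via N CIGAR operations (no read
starts inside a gap). Reads are emitted pre-aligned at their sampled
positions, because planted-truth evaluation requires alignment-free
ground truth and read alignment is out of scope.

It does **not** model: alignment artifacts (soft-clip pileups, multimapper
ambiguity, the low-coverage gaps heavily edited reads cause by failing to
align), indels, PCR duplicates, quality-score structure, expression-level
heterogeneity, or read-level correlation of edits (real hyperediting
concentrates many edits on single molecules; a correlation knob exists but
is off by default, since per-site frequencies are what the scan consumes).
Passing tests therefore demonstrate the statistical machinery — counting,
testing, merging, quantification, differential filtering — under a clean
alignment model, not robustness to alignment pathology.

A knockout counterpart (`knockout_config`) keeps every cluster's site
placement (so the simulated genome is identical between the pair) and
zeros the editing frequency of knocked-out clusters; since random draws
are consumed independently of the frequencies, the WT and KO samples share
read placement and error realization and differ only at edited bases. The
differential-pipeline fixtures use error rate 0 in both samples: the
pipeline's exactness contract (survivors with CI exactly 1.0) is only
defined in the noise-free regime, because any nonzero KO error makes a
strictly positive KO RTF almost sure over a multi-hundred-base region.

## Problem sizes in the tests and acceptance script

The standard recovery benchmark uses two 1-Mb contigs with 20 planted
clusters (10 sites, frequency 0.3, 30×, error 10⁻³); the null benchmark a
200-kb contig; the differential benchmark two 300-kb contigs with 12
clusters, 6 of them shared between WT and KO. These sizes give every
statistic hundreds of thousands of windows while keeping the whole suite
fast on a single core. The acceptance script re-simulates everything from
its `--seed` and reports recovery above 95%, TsSiteCount calibration
(8–12 sites for ≥ 90% of recovered 10-site clusters — sequencing error
adds roughly one spurious single-read TsSite per recovered region at
these settings), exact deNovo/Regio agreement, and an error-only
false-positive rate well under the α·n budget.

## Known limitations

- Not strand-aware; AG and TC must jointly be read as ADAR activity.
- No SNP-database masking; isolated transition SNPs are removed only by
  the downstream TsSiteCount filter, and residual SNPs inside regions
  bias RTF upward.
- RTF depends on region extent and coverage; compare it across samples
  quantified over the *same* region list (Regio), not across differently
  delimited regions.
- Single-site editing is out of scope by design; the window test has no
  power at one site unless its frequency is high.
- Gene association is strand-agnostic 1-bp overlap; a region in a
  sense/antisense gene pair credits both genes.
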