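# Methods

This note documents the models, parameter choices and numerical
conventions behind `evtx`, and what the synthetic-data experiments do and
do not demonstrate about real data.

## Pipeline model and assumptions

The pipeline assumes a fragmented total-RNA library: reads are short
(most 20–40 nt), every RNA class is represented in proportion to its
fragment count, and alignments are produced externally (the package
consumes SAM; it does not align). Stage order is fixed — trim → screen →
route → miRNA match → MAPQ filter → tRNA overlap → Ensembl overlap → mcv
filter → quantify → backsplice detection — and annotation is hierarchical:
a read matched to a mature miRNA is never re-annotated against tRNA or
Ensembl features, and a tRNA overlap pre-empts any Ensembl overlap. Every
input read terminates in exactly one accounting category; this
conservation identity is asserted on every run.

### Quality trimming

A read is cut to the longest prefix in which every 30-base window (or the
whole prefix, when shorter) has mean quality strictly greater than
Phred 15. The "strictly greater" reading and prefix-only (3′) trimming
follow the convention of single-pass semiconductor sequencing, where
quality decays toward the 3′ end. Trimming is idempotent; reads trimmed to
zero length are counted as removed-by-trim. Reads shorter than 12 nt after
trimming are discarded at the routing stage (configurable) — the fate of
sub-12-nt reads is otherwise unspecified by the protocol.

### Contaminant screen

A deterministic k-mer majority rule (k = 18, both strands indexed,
removal at ≥ 50% k-mer hits) stands in for a multi-genome mapping screen.
This is an accounting-grade simplification: it is exact on the synthetic
data (whose contaminants are k-mer disjoint from the genome by
construction) but would be more permissive than a real aligner on
diverged rRNA fragments. Reads shorter than k contribute no k-mers and
are kept.

### miRNA matching

Reads of 12–25 nt are compared against mature sequences anchored at the
5′ end, allowing ≤ 1 substitution and ≤ 2 untemplated or trimmed 3′
bases — a conservative approximation of isomiR tolerance. Ties break by
fewest mismatches then lexicographic id, making the matcher deterministic.
Each mature sequence is treated independently (5p/3p arms are not
collapsed).

### Overlap annotation

Overlap is computed on exon unions via an interval tree with a 1-bp
minimum (BEDTools-intersect default), strand-agnostic by default
(`stranded` flag available) because the library chemistry's strandedness
is not relied upon. Within a tier, the winning feature has the largest
overlap, then the smallest spliced length (the most specific model), then
the lexicographically first id. How reads overlapping several Ensembl
features should be resolved is genuinely open; this rule is chosen for
determinism and specificity.

### mcv (coverage-uniformity) filter

The spliced length of each transcript is divided into 10 near-equal bins
(the first `L mod 10` bins one base longer); each alignment increments
the bin containing the midpoint of its spliced projection (midpoint rule:
a read straddling a bin edge counts once, unambiguously). The mcv-score
is the uncorrected population Gini coefficient of the bin counts,
computed with the sorted-rank identity and verified in tests against the
O(n²) pairwise-difference definition to 1e-12. Bounds: 0 ≤ G ≤ (n−1)/n,
the upper bound attained exactly for single-bin mass. Transcripts with
G < cutoff are retained; the default cutoff is 0.7, with 0.6 exposed as
`MCV_CUTOFF_STRICT` — both operating points are in use for this statistic
and neither is privileged beyond the default. The filter applies only to
features annotated from the Ensembl tier; miRBase and GtRNAdb assignments
are exempt by pipeline order. Transcripts with spliced length < 10 are
skipped with a warning; zero-coverage profiles have an undefined score
and are rejected rather than silently retained.

### Quantification conventions

* Transcript inventories use a ≥ 2-read threshold; the high-coverage view
  uses ≥ 10 reads.
* RPM = count × 10⁶ / total. The "total" is ambiguous in practice;
  the default denominator is post-filter reads, configurable to raw or
  mapped.
* Per-100k normalization divides by total mapped Ensembl counts and sums
  to 100,000 on a complete table.
* "Present" for the core transcriptome means a feature survives the
  ≥ 2-read rule with positive normalized count; the core is the
  intersection across samples, reported with its fraction of the union.
* Percentages are printed to one decimal with half-up rounding. In
  summary tables, the Average row averages per-sample percentages (not
  ratios of averaged counts) and rounds count means half-up to whole
  reads. The removal percentage is 100·(raw − post-filter)/raw — the only
  reading consistent with all rows of the shipped five-donor table.

### circRNA detection

Terminal anchors (20 nt) are located in the genome by exact match on both
strands; a read whose anchors hit multiple loci is skipped and counted
(no rescue scoring). A junction requires (i) anchors on one chromosome in
reversed genomic order, (ii) a breakpoint split that reconstructs the
entire read as (suffix of circle end) + (prefix of circle start), and
(iii) a canonical strand-aware GT/AG signal at the circle flanks. When
repeated bases around the two junction sides make several splits
sequence-identical, the breakpoint slides across all of them and keeps
the one with the canonical signal — without this, junction coordinates
would be off by the repeat length. Non-canonical chimeras are rejected
outright; if both strands' signals match (palindromic flanks) the strand
defaults to '+' with an `ambiguous_strand` flag. Support counts distinct
reads and the ≥ 2-read filter is applied before classification.
Classification against the reference is chromosome-restricted and
strand-agnostic, exact by default with an optional ±k bp slop. This
exact-anchor detector trades the sensitivity of aligner-based anchor
extension for byte-deterministic, desk-scale behaviour.

### qPCR arithmetic

All quantities assume perfect doubling per cycle (no efficiency
correction). Undetermined reactions are imputed at Ct = 35, which caps
any protection ratio at 2^(35 − min observed Ct). ΔCt direction is
explicit in each signature: `fold_change_qpcr(ct_low, ct_high)` =
2^(ct_low − ct_high); `protection_ratio(ct_intact, ct_treated)` =
2^(ct_treated − ct_intact), > 1 meaning template loss.

## Synthetic-data generator

The generator's defaults are the package's study conditions and are not
tuned per experiment:

| parameter | default | rationale |
|---|---|---|
| contaminant fraction | 0.73 | rRNA-dominated plasma-EV libraries |
| fragment length | 12 + NB(size 4, p 0.15), clipped to ≤ 200 nt | mode ≈ 29–30 nt, bulk in 20–40 nt |
| biotype mixture | 73.25% short noncoding (tRNA 42.0%, Mt_rRNA 10.9%, miRNA 9.4%, misc_RNA 9.7% split 57/39/3/0.1 across Y/SRP-7SL/Vault/7SK, plus minor rRNA/snoRNA/snRNA), 24.5% protein coding, 2.2% long noncoding, 0.1% pseudogene | the observed plasma-EV read-share landscape; sums exactly to 1 |
| coverage Gini target | 0.15 | well-behaved mapping |
| circRNA read fraction | 0.001 | tens of junction reads per 10⁵ reads |
| substitution error rate | 0 | lets screen/annotation exactness be provable |

One synthetic chromosome carries transcript models per biotype (e.g.
protein coding: 1800 nt spliced over 3 exons; tRNA: 72 nt; mature miRNA
loci: 18–24 nt), circle loci flanked by planted AG…GT signals, and
intergenic spacers. Contaminant sequences are regenerated until they share
no 18-mer with the genome (either strand), so screen exactness holds by
construction. Coverage concentration places a read's target bin on one
"hot" bin with probability w = g·n/(n−1) — a mixture whose population
Gini equals the target g exactly. Reads are kept inside single exons (a
fragment crossing an exon boundary is clipped), so truth alignments are
ungapped; this slightly narrows realized fragment lengths for multi-exon
models and is invisible to the 10-bin profiles at the feature sizes used.
Backsplice reads are 50 nt with a random junction split of ≥ 20 nt per
side. Everything derives from one `numpy` Generator seeded by
`SimConfig.seed`; identical configurations produce byte-identical
FASTQ/SAM/truth files.

**What passing tests do not show about real data:** the generator has no
sequencing-error model beyond optional uniform substitutions, no
platform-specific quality decay, no multi-mapping (all truth alignments
have MAPQ 60), no expression heterogeneity within a biotype, and
contaminants are exact substrings. Exact screen/annotation recovery and
zero circRNA false positives are therefore properties of the error-free
regime, not expected field performance.

## Problem sizes in tests and the acceptance script

The shared test fixture uses 20,000 reads; mixture recovery runs the full
pipeline at 100,000 reads; mcv discrimination uses 100 transcripts at
1,000 reads each; the Gini oracle suite uses 1,000 random vectors; circRNA
round-trips use 8 circles at 3 reads each plus a 500-read linear control.
These sizes make every statistical criterion comfortably decidable (e.g.
binomial error on a 42% mixture share at ~27,000 annotated reads is
±0.3%, against a ±3% acceptance band) while keeping a full run in
seconds.

## Known limitations

* The contaminant screen and miRNA matcher are deliberate stand-ins for
  aligner-based tools; their exactness guarantees hold only on the
  synthetic regime above.
* The circRNA detector requires exact anchors and canonical GT/AG; real
  non-canonical or mismatch-bearing junctions would be missed.
* Multi-mapper rescue, spliced alignment, novel-miRNA prediction and
  differential expression are out of scope.
* The five-donor accounting table ships as data for the summary
  arithmetic; the underlying raw sequencing data are not public, so
  biotype percentages and circRNA counts of that study are not
  reproduced here.
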