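# Methods

## Scope and model

`exmeth` re-implements, as a tested library, the computational core of a
methylome comparison between embryonic and extraembryonic mouse gut
lineages: extraembryonic endoderm carries a non-canonical methylome —
intermediate genome-wide methylation with hypermethylation at a select
set of CpG islands (CGIs) — whereas embryonic tissue shows the somatic
pattern of high global methylation and unmethylated CGIs. The package
quantifies that contrast from per-CpG bisulfite calls, links promoter
methylation to differential expression, and classifies the lineage
origin of single cells from a two-marker co-expression rule.

## Per-CpG calls and feature aggregation

Calls are (chrom, pos, methylated count, total count, rate) records in a
6-column bedGraph dialect, one record per CpG (plus-strand C position,
strand-collapsed upstream). Replicates are merged at the raw count
level: counts are summed per position over the union of covered
positions and the merged rate is recomputed from the sums; with equal
per-replicate depth this equals the per-CpG average of replicate rates.
Depth filters are inclusive on both sides (defaults 5–150 for single
replicates, 10–150 for merged tables or WGBS).

Feature methylation is the **unweighted mean of per-CpG rates** inside
the interval — coverage adequacy is already enforced by the depth
filter, so no read-count weighting is applied. Summaries keep features
with at least 3 covered CpGs, and (by default) only autosomal features:
X inactivation in female samples inflates X-linked methylation, which
the package surfaces as a warning whenever the autosome restriction is
disabled. Tiling uses fixed windows (default 1 kb, step 1 kb) with the
trailing partial tile retained.

## Promoters and CpG-density classes

Promoters span 500 bp on either side of the TSS (the gene's 5′ end by
strand), clamped to the chromosome. A CGI is assigned to a promoter if
the overlap covers ≥ 20 % of the CGI *or* ≥ 20 % of the promoter. For
the methylation level, an assigned CGI is *used* only if it has ≥ 3
covered CpGs in every sample of the pair under analysis; the promoter
level is then the unweighted mean of the used CGIs' mean rates,
otherwise the mean per-CpG rate over the promoter region. Density
classing is coupled to that decision: region-sourced promoters are LCP
by definition; CGI-sourced promoters are HCP when the maximum O/E CpG
ratio among used CGIs exceeds 0.8 (strict), else ICP. When several CGIs
overlap one promoter the maximum O/E is used — the conservative "is
there a high-density island" reading. O/E ratios come from the CGI
annotation when present, or from sequence as `n_CG · L / (n_C · n_G)`.
Promoters are hyper-/hypomethylated at a strict ±0.1 on the
test-minus-reference delta.

## Hyper-CGI classification

A CGI is *hyper* in the test tissue when all of:

1. mean methylation difference (test − reference) > 0.1 (strict);
2. more than half (strict) of the CpGs covered in both samples gain
   ≥ 0.1, **or** the CGI contains a DMR with higher methylation in the
   test tissue;
3. the reference (epiblast) CGI mean is < 0.15 (≥ 0.15 excludes,
   inclusive).

Deltas are computed only for CGIs with ≥ 3 covered CpGs in both
samples; the per-CpG majority fraction uses only CpGs covered in both
and is reported missing when fewer than 3 are shared — such CGIs can
still be hyper through the DMR clause.

### DMR caller

DMRs are called on CpGs inside CGIs only. Replicates are merged per
group; candidate regions are maximal runs of CpGs covered in both
groups with inter-CpG gaps ≤ 80 bp. Within a run, the contiguous
segment of ≥ 10 CpGs maximizing the absolute mean group difference is
found by **exact search** (all windows scored via prefix sums, ties to
the longer then leftmost window), recursing on the flanks for further
non-overlapping segments. Segments with |mean difference| ≥ 0.1 are
tested by a two-sided Mann–Whitney rank-sum comparison of the two
groups' per-CpG rates over the segment; Benjamini–Hochberg correction
is pooled across all candidate segments of the run and DMRs with
q < 0.05 are reported. The CpG-count / effect / gap parameters mirror a
common DMR tool's `-m/-d/-M` switches, but the statistic and the exact
segment search are this package's own ("metilene-like", not a
reimplementation); that tool's `-c/-f/-v` switches have no counterpart
here. Exact search was chosen over greedy binary splitting because it
is provably identical to exhaustive segment enumeration, which the test
suite verifies directly.

## Expression integration

The differential-expression engine is deliberately **not**
re-implemented: an external per-gene (log2FC, adjusted P) table is
first-class input, and for synthetic runs `simple_de_test` provides a
plain Welch t test on log2(TPM+1) with BH correction — documented as a
location test, not a count model. Around it sit the bespoke rules, all
with strict inequalities as printed in the protocol: expressed genes
need TPM > 1 in ≥ 4 of 16 samples (Y-chromosome genes removed,
protein-coding only); high/low classes need |log2FC| > 1 and adjusted
P < 0.05. Methylation-sensitive genes are the union of two
knockout-derived criteria (upregulation plus exon–DMR overlap;
upregulation plus a highly methylated CpG-rich promoter class).
Enrichment of a per-gene flag (e.g. chrX location) in a hit set is a
two-sided Fisher exact test; gene-set overrepresentation is one-sided
hypergeometric with set-size limits 10–500 and top-5 reporting; k-means
clustering operates on row z-scores with 100 restarts and 1000
iterations (k is not fixed by the protocol; the package default is 4).
The methylation–expression integration joins promoter deltas with
log2FC over the high∪low genes and reports their Spearman rank
correlation — a package-defined summary of an association the source
analysis shows graphically.

## Cell origin

QC removes cells with ≥ 15 % mitochondrial reads (inclusive) or
< 2,000 detected genes (strict). "Detected expression" of a marker is a
raw count ≥ 1 (configurable). Cells with both markers detected are
extraembryonic, with neither embryonic, with exactly one discarded; the
three classes partition the QC-passing cells. Per-group extraembryonic
fractions use classified (non-discarded) cells as the denominator —
the protocol does not state how single-marker cells enter reported
percentages; exclusion was chosen and is documented here — with a
Wilson score 95 % interval.

## Synthetic data

The generator plants ground truth with the qualitative structure the
analysis assumes; the distributions themselves are package choices:

- **Genome**: 3 autosome-like chromosomes + 1 X-like, 2 Mb each;
  background CpGs at geometric spacing (mean 100 bp); 300
  non-overlapping CGIs of 200–1,500 bp with ≥ 15 CpGs at mean 12 bp
  spacing; 400 genes, 60 % with TSS at a CGI midpoint, the rest placed
  with CGI-free promoters (LCP genes).
- **Methylomes**: per-CpG true rates from Beta components — embryonic
  background mean 0.80, CGIs mean 0.05; extraembryonic background mean
  0.55, planted hyper CGIs (30 % of CGIs, autosomal) mean 0.45, other
  CGIs mean 0.05. Replicate jitter is a high-concentration Beta around
  the true rate; coverage is 1 + negative binomial (mean 15); methylated
  counts are Binomial(total, rate). Hyper CGIs are planted on autosomes
  because that is where the CGI classification operates.
- **Expression**: 16 samples (4 tissues × 4 replicates). Planted low
  genes sit on planted hyper CGIs (promoter gains methylation,
  expression falls); planted high genes are LCP genes (promoter follows
  the lower extraembryonic background, expression rises), 20 % of them
  X-linked; planted fold changes are 4–16×, noise is log-normal. This
  builds the negative methylation–expression coupling directly into the
  truth.
- **Cells**: exactly `round(0.04 · 2000)` extraembryonic cells; their
  marker counts are **zero-truncated** Poisson (mean 3) so a planted
  cell is always detectable and fraction recovery is unbiased;
  embryonic cells have structural zeros, with a 1 % ambient
  single-marker fraction creating discarded cells; QC failures (5 %)
  are drawn independently of origin. The count matrix is a small gene
  panel carrying full-experiment QC metadata (n_genes_detected,
  mito_frac) as per-cell columns rather than recomputing them from the
  panel.

What passing tests show — and what they do not: the synthetic methylome
has independent per-CpG rates within a compartment, no positional
autocorrelation beyond the CGI/background split, no partially
methylated domains, no SNPs or mapping artefacts; the expression model
has no library-size or dispersion structure; the cell matrix has no
doublets or batch effects. Recovery results therefore validate the
*rules and their boundary conventions*, not performance on real
sequencing data.

## Numerical choices and scale

Deterministic seeding throughout (`numpy` Generator seeded per stage
from the run seed); identical seeds give byte-identical output files
and manifests. Ties in the DMR search break toward longer, then
leftmost segments. Degenerate inputs (zero-variance segments, empty
groups, uncovered features) return defined results or typed errors
rather than NaNs. Default problem sizes (2 Mb × 4 chromosomes, ≈ 100k
CpGs per sample, 300 CGIs, 2,000 cells) were chosen so the full demo
pipeline completes in a few seconds on one CPU while keeping ≥ 15 CpGs
per CGI and ≥ 10 expected CpGs per promoter.

## Known limitations

- The DMR caller is a stand-in: results are comparable in intent, not
  numerically, to metilene output.
- `simple_de_test` is not a negative-binomial model; real count data
  should be analysed externally and supplied as a (log2FC, padj) table.
- No smoothing, imputation, or beta-binomial modelling of methylation.
- CGIs are an input annotation; there is no de-novo CGI prediction.
- The X-bias of promoter methylation in female samples is warned about,
  not modelled.
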