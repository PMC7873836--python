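# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Single-cell QC and sex inference

Cells are filtered on two metadata fields: `mapped_read_count`
(default minimum 10⁶ reads mapped to gene transcripts) and `mito_fraction`
(removed at ≥ 0.5, a standard proxy for broken cells).  Visual outlier
removal (e.g. from an embedding) is not a reproducible computation, so
outliers are taken as an explicit exclude list and flagged in the QC
report.  Gene detection uses TPM > `min_tpm` (1) in at least
`min_cells_expressing` (3) cells.  `filter_cells` is idempotent and leaves
the gene set untouched.

Sex inference is a two-pass rule.  Pass 1: a cell is provisionally male iff
the summed TPM of annotated *single-copy* chrY genes reaches
`chry_male_tpm` (10).  Single-copy status is an annotation flag supplied
with the gene table, keeping the rule species-portable.  Pass 2 computes
per cell the ratio ∑TPM(chrY)/∑TPM(chrX) and reclassifies as female any
provisional male whose ratio falls below the maximum ratio among
provisional females.  The rationale: ambient or cross-contaminating chrY
transcripts can push a female cell over the pass-1 threshold, but such
cells still sit inside the female ratio range, whereas a genuine male's
chrY output is orders of magnitude higher.  Two open choices are fixed and
configurable: the ratio numerator uses **all** chrY genes by default
(`yx_ratio_genes: all`; single-copy-only is selectable), and pass 2 is
applied **once** — the female pool is not re-grown iteratively after
reclassification.  A cell with zero chrX expression has an undefined ratio
and raises; with no provisional females, pass 2 is skipped with a warning.

## Dosage evidence for X reactivation

Chromosome-level summaries use geometric means of TPM + 1 (the pseudocount
`geomean_pseudocount` keeps zeros finite; with expressed-gene TPMs in the
hundreds-to-thousands its bias is negligible).  The female:male ratio per
chromosome is the ratio of geometric means over (genes × cells) of each
sex, restricted to *shared expressed* genes — genes with TPM > 1 in at
least one cell of each sex, matching the global detection threshold; a
total-TPM variant is available (`method="total"`).  Windowed ratios bin
genes by TSS into consecutive right-open `fm_window` (1 Mb) windows; the
per-gene ratio is (mean TPM over females + 1)/(mean TPM over males + 1)
(the pseudocount prevents division by zero); windows with fewer than
`fm_window_min_genes` (3) genes report a missing median rather than zero.

The per-cell X:allA ratio is a bootstrap: each replicate draws `boot_genes`
expressed X-linked and `boot_genes` expressed autosomal genes without
replacement and forms the ratio of summed TPMs; the cell's value is the
median of `boot_reps` (1,000) replicates.  Defaults (`boot_genes` 100) suit
genomes with hundreds of expressed X genes; on the toy genome (33 X genes)
a smaller draw (25) is used.  The expressed-gene pool is evaluated per
stage (a per-cell variant only changes the pool, not the estimator).  Note
a small upward bias of the ratio median when the denominator pool is
right-skewed (the median of a skewed sum sits below its mean); this is a
property of the estimator itself and is left as is — group comparisons are
rank-based and unaffected.

Group comparisons are thin wrappers over scipy: pairwise Wilcoxon rank-sum
(Mann-Whitney) with Holm correction, a single two-group Mann-Whitney test
(exact for small tie-free samples), and Kruskal-Wallis followed by Dunn's
post hoc z-test.  Dunn's test is implemented directly from its rank-mean
formula with the standard tie correction `T = Σ(t³−t)/(12(N−1))`, as no
installed library provides it.

## Allelic evidence

SNV records pass three filters, in a fixed order: dbSNP-validated sites
only (a boolean input column; no live lookup), per-(cell, site) coverage
≥ `snv_min_reads` (3), and recurrence — the site must survive the coverage
filter in ≥ `snv_min_cells` (2) cells *of the same stage*.  Recurrence is
deliberately computed after coverage (the two filters do not commute);
every dropped record is annotated with its reason.

A filtered record is called biallelic iff the minor allele has
≥ `allele_detect_min_reads` reads **and** ≥ `allele_detect_min_frac` (10%)
of the site's reads; otherwise it is monoallelic toward the majority allele
(ties toward reference).  The read floor defaults to 3: under a 0.1%
per-read error rate at depth ~20, a 2-read floor admits false biallelic
calls at ~2·10⁻⁴ per (cell, site) — enough to fabricate an occasional
"escaper" gene across a somatic compartment — while a 3-read floor drives
the false rate to ~10⁻⁶ at essentially no cost in sensitivity to a true
50/50 allelic signal (the fraction rule, not the floor, governs high-depth
sites).  Both knobs are configurable.

Escapers — X-linked genes that escape X inactivation — are defined
operationally as genes with ≥ 1 biallelic SNV in ≥ 1 somatic female cell.
Per-cell biallelic gene counts exclude the escaper set, so a nonzero count
in a germ cell is evidence of reactivation, not of constitutive escape.
SNVs are assigned to genes by strict overlap with exon intervals
(first match); unassigned SNVs are dropped with a logged count.

## Methylome

Region methylation is coverage-weighted: ∑meth / ∑total over the CpGs of a
region (matching the weighted mean of standard region-methylation tools);
a mean-of-sites variant exists for sensitivity analysis.  Regions with no
covered CpG are missing, never zero.  Tiling uses left-closed non-overlapping
tiles (1 kb globally, 800 nt for escapee detection), keeping the last
partial tile.  Imprinted-region methylation is ordinary region methylation
over a supplied interval BED — no special casing.

Promoters are −1,000/+500 around the TSS (strand-aware).  Classification
slides 500-bp windows at a 5-bp step; the CpG ratio is the observed/expected
convention `n_CpG · L / (n_C · n_G)`.  HCP: some window with ratio > 0.75
and GC > 0.55; LCP: no window with ratio > 0.48; ICP otherwise.  The
partition is total over callable promoters; sequences shorter than the
window are uncallable with a warning.

Gene metaprofiles aggregate coverage-weighted levels into fixed-width flank
bins (5 kb, 50 bins) and a body scaled to 100 bins, orientation-corrected
for minus-strand genes; genes shorter than the body bin count are skipped
and logged.

Escapee (demethylation-resistant) tiles: within each 800-nt tile, only CpGs
covered ≥ `escapee_min_cov` (5×) count; the tile is meth+ iff **more than**
`escapee_cpg_frac` (20%, strict) of those CpGs have a pooled methylation
level ≥ `escapee_meth_level` (inclusive; 0.15 for pig/mouse, 0.30 for
human — the species preset).  The ambiguous natural-language rule is read
as "share of ≥5× CpGs that are individually methylated", with both
inequalities configurable.  Tiles with fewer than
`escapee_min_callable_cpgs` callable CpGs are reported as uncallable so
totals reconcile.  That minimum defaults to 10: at Poisson-10 coverage a
5–6×-covered CpG crosses the 15% level with a single methylated read even
under a 1% background (probability ~5%), so tiles judged on fewer than ~10
informative CpGs flip to meth+ on just two such events; requiring ≥ 10
callable CpGs makes a false call need three independent low-probability
events and keeps the tile-level false discovery rate well under 5% while
leaving CpG-dense escapee loci fully detectable.  Escapee calls are
monotone in `escapee_meth_level` by construction (raising the threshold
can only shrink the qualifying CpG set).

TE classification and enrichment: a tile's repeat overlap is the union of
overlapping repeat bases divided by tile length; TE-rich means ≥ 10%.  For
each repeat family the 2×2 table is (escapee vs background tiles) ×
(overlaps the family vs not), with background = all callable 800-nt tiles
genome-wide (a meth−-only background is selectable); `ES` is the ratio of
overlap fractions and p comes from a two-sided Fisher's exact test; a
family is enriched at ES > 2 and p < 0.001.  The odds ratio is a noted
alternative to the fraction ratio but is not the default.

Repeat expression is normalised per million mapped reads (RPM); the
counting itself (minimum mapping quality 20) happens upstream and is out of
scope.  Because the unit's name is sometimes conflated with RPKM, an
`rpkm=True` variant divides additionally by region length in kb; reads-per-
million is the default.

## Synthetic data: what is emulated

The toy genome has three autosomes plus X and Y (1 Mb each at `tiny`
scale, 10 Mb at `default`), 200 genes per autosome, 32 X genes plus XIST,
and 12 Y genes of which 6 are single-copy; genes are non-overlapping within
a chromosome with 1–3 exons.  CpG sites follow ~70-bp mean spacing
(denser inside CpG islands, placed at 15% of promoters); four repeat
families are placed as Poisson processes, with the SINE family `Pre0_SS`
designated "young".  Every non-XIST X gene carries 1–3 exonic SNVs with a
fixed phase; 90% are dbSNP-validated, and planted escaper genes are drawn
from X genes with at least one validated SNV (otherwise exact recovery
would be structurally impossible).

Expression: per-gene baseline weights are log-normal (σ = 1); counts are
negative-binomial (dispersion 0.2, configurable; no dropout modelling by
default) with mean proportional to weight × gene length, then TPM-
normalised.  The autosomal gene count is chosen so chrX carries ~5% of the
transcriptome, as in real genomes — important because TPM renormalisation
otherwise visibly deflates autosomal F:M ratios when X output doubles.
Baseline X-gene weights are rescaled so their mean equals the autosomal
mean: with only ~32 X genes the log-normal sample mean would drift by tens
of percent between genomes, and the planted condition is an X:allA
baseline of exactly 1 in inactive-X cells.  Males express Y genes
(single-copy well above the 10-TPM rule); females have zero single-copy Y
but an ambient multi-copy chrY background (~9–15 TPM per gene, emulating
cross-mapping), which gives pass 2 a genuine female ratio range.
Contaminant cells are true females with ~30 TPM of single-copy chrY
signal — above the pass-1 threshold, below the female ratio range.
XCR doubles non-escaper X genes exactly (the cleanest recoverable dosage
signal); escaper genes are doubled in *every* female cell, since biallelic
expression is independent of XCI state; XIST is high in XCI females
(~10× reduced upon XCR, low in males).  QC failures are planted directly
in the metadata.

Allelic counts: per (cell, SNV), total reads ~ Poisson(depth 20); XCI cells
and males draw from one haplotype with a 0.1%-per-read error toward the
other allele; XCR cells and escaper-gene sites draw Binomial(n, 0.5).

Methylomes: per-CpG coverage ~ Poisson(10); methylated reads ~
Binomial(coverage, site rate).  PGC samples sit at 1% except in 50 planted
800-nt escapee tiles at 40%; somatic samples at 75% with CpG islands at
10%.  Escapee tiles are grid-aligned candidates with ≥ 12 CpGs; a fraction
equal to 5× the young family's background tile-overlap frequency is drawn
from young-overlapping candidates and the rest from repeat-free
candidates, so the young-family 2×2 table is exact by construction and no
other family is incidentally enriched in the TE-rich escapee class.

What is **not** emulated: read-level data (FASTQ), alignment and bisulfite
conversion artefacts, PCR duplicates, single-cell dropout, doublets, cell
cycle, batch structure, linkage between expression level and allelic
coverage, non-CpG methylation, and hydroxymethylation (which bisulfite
data cannot distinguish from methylation anyway).  Passing recovery tests
on this generator therefore demonstrates that the estimators and rules
recover the signals they target under their stated statistical
assumptions — not that those assumptions hold in any particular real
dataset.

## Numerical choices and degenerate inputs

All internal coordinates are 0-based half-open (BED convention); CpG sites
are stored by the 0-based position of the C on the plus strand, assuming
strand-merged counts upstream (bismark-coverage granularity).  Chromosome
names are taken verbatim; a validator warns when two inputs have disjoint
naming.  TSS-at-boundary genes fall in the right-open window containing
the TSS.  Ties in allelic calls break toward reference.  Fisher tests on
families absent from the annotation are skipped with a log entry; an
overlap fraction with an empty background yields a missing ES.  All
randomness flows from explicit seeds (numpy `SeedSequence` children per
cell/sample); outputs are written with a fixed float format and manifests
avoid timestamps, so identical (config, seed) reruns are byte-identical.

## Problem sizes

The shipped tests and the acceptance script run the generator at `tiny`
scale (~60–90 k CpGs, 100–200 cells per cohort) for cohort analyses and at
`default` scale (~5.7 × 10⁵ CpGs) for the methylome rate-recovery check,
with 10-seed replication where a claim is about error rates — sizes chosen
as the smallest at which the planted effects are statistically
unambiguous.

## Known limitations

- The bootstrapped X:allA median carries a small positive skew bias on
  small gene pools (see above).
- Escaper identification inherits any residual false biallelic calls; at
  the default thresholds the expected count is ≪ 1 per somatic compartment
  but not exactly zero.
- The TE enrichment score conditions its foreground on TE-rich tiles;
  with a foreground enriched by construction for one family, other
  families' scores hover near 1 but are not variance-controlled — the
  p-value threshold, not the ES alone, is the guard.
- HCP/ICP/LCP classification needs promoter sequence (or per-window
  composition); it is not derivable from coverage files alone.
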