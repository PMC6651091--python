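# Methods

## Differential methylation model

Each 500-bp bin is summarised, per condition, by pooled MeDIP and MRE read
counts. Libraries are first scaled to the smallest library of their assay
(counts × min(total)/total, then rounded after pooling), so the 2×2 table
`[[MeDIP₁, MRE₁], [MeDIP₂, MRE₂]]` compares like with like. Under the null
hypothesis that the two conditions share the same methylation level, the
MeDIP fraction MeDIP/(MeDIP+MRE) is exchangeable between conditions, and the
table is tested with a two-sided Fisher's exact test. The exact conditional
test was chosen over a count-regression test because it requires no fitted
dispersion, is valid at a single library per condition (small-animal designs
often sequence one representative animal per group), and is exact at low
counts. Benjamini–Hochberg is applied across tested bins only; bins whose
total scaled count is below `min_count = 10` are reported untested — exact
tests at such totals have essentially no power and would only dilute the FDR
correction. Direction is the condition with the larger MeDIP fraction; tied
fractions fall back to the smaller pooled MRE sum (less unmethylated
signal); a fully symmetric table has no direction and cannot be emitted.
Adjacent significant bins are reported individually, matching bin-level DMR
accounting; `merge_adjacent` (gap 0, same direction) is available but off by
default.

Two implementations of the two-sided Fisher p-value exist deliberately: the
scalar path delegates to `scipy.stats.fisher_exact`, while the genome-wide
path is a log-gamma vectorised batch that sums hypergeometric probabilities
no larger than the observed one (relative tie tolerance 1 + 1e-7). The test
suite pins the two to each other and to an exhaustive enumeration oracle.

**Calibration regime.** The pooled exact test conditions on table margins
and is calibrated when within-group counts are Poisson-like. Under
extra-Poisson noise (biological replicate variability) the pooled table's
margins understate the variance of the group fractions and the test becomes
anti-conservative — a known property of pooled conditional tests, shared by
any method that ignores replicate dispersion. Null-calibration studies in
this package therefore run at dispersion 0; the generator's default
dispersion (0.05) is kept for realism everywhere else, and analyses of
overdispersed designs should treat bin-level q-values as optimistic. This is
the main known limitation of the caller.

## CpG islands and zoning

An island satisfies three criteria jointly: length ≥ 200 bp, GC content
≥ 0.5, and observed/expected CpG ratio ≥ 0.6 with
obs/exp = #CpG · L / (#C · #G). N bases are excluded from all tallies and
from the effective length. The caller slides a 200-bp window at step 1
(prefix sums make this linear-time), takes the union of qualifying windows,
merges overlapping windows into maximal segments, and trims each merged
segment one base off both ends per round until the whole segment satisfies
all three criteria (discarding segments that shrink below 200 bp). Step 1
and the symmetric trim make the procedure deterministic and
oracle-checkable; the suite verifies exact agreement with an independent
brute-force implementation over every window offset on hundreds of random
sequences.

**Edge resolution.** A fixed 200-bp qualifying window cannot localise a
composition step more sharply than the window itself: a boundary window
qualifies as soon as its island content x satisfies
(gc_isl·x + gc_bg·(200−x))/200 ≥ 0.5, i.e. x ≈ 200·(0.5−gc_bg)/(gc_isl−gc_bg)
(≈ 80 bp of systematic outward extension for a 0.40→0.70 GC step), plus
window-GC sampling noise (σ ≈ 0.034 for 200 bp, another ±50 bp at the
threshold crossing). Island-recovery tests against planted truth therefore
use an edge slop of 150 bp; the comparison helper's slop is configurable.

Shores are the 2000-bp flanks on either side of an island; zone precedence
is island > shore > open sea, so a query overlapping both an island and a
neighbouring shore counts as island and the three zones partition any query
set exactly. Distance to the nearest island is base-to-base: a query whose
first base is the base after an island's last base is 1 bp away, which makes
`zone = shore ⇔ 0 < distance ≤ 2000` an identity. Islands may be called from
the genome FASTA or supplied as a BED file — both entry points are
first-class because annotation-source islands are common in practice.

## Gene-feature partition

Promoter and downstream windows are the 1500-bp flanks upstream of the TSS
and downstream of the TES, strand-aware; overlap is ≥ 1 shared bp. Each DMR
receives exactly one label. Within a gene the precedence is
gene body > promoter > downstream — single-label assignment is what makes
the three feature counts partition the gene-associated total exactly. Across
genes, the DMR goes to the gene with the largest bp overlap against the
gene's full footprint (extent plus both flanks); ties go to the
lexicographically smallest gene_id and are logged for audit. The relative
intragenic position is 100·|midpoint − TSS|/L measured along transcription,
clipped to [0, 100]; the strand anchors are the interval's half-open
endpoints, which makes the quantity exactly invariant under translation and
strand reflection. Intron/exon placement is containment-based: a DMR inside
one exon is exonic, inside one intron intronic, anything crossing a boundary
spans. Printed percentages round half-up at the granularity of the published
summaries: whole percents for direction and feature shares, one decimal for
zone shares.

## Expression association

The expression t-score is the per-gene z-standardisation across animals
(sample SD, n−1); zero-variance genes are flagged and excluded. Selection
keeps entries with |t| ≥ k_sd (default 4). Note the algebraic bound
max|z| ≤ (n−1)/√n for a per-gene z-score over n animals: a 4-SD selection
can only fire with ≥ 18 animals, so small designs must lower `--k-sd` (the
simulation-based tests select at 2 SD) or use `--pooled`, which
re-standardises the t-matrix against its pooled mean/SD before
thresholding. A gene is labelled higher-in-MHF/higher-in-PHF by the group of
its extreme-high entries (an extreme low in one contrast group implies
higher expression in the other); genes extreme-high in both contrast groups
are excluded and logged; extremes in CON set no contrast label.

Density curves of intragenic DMR relative positions are Gaussian KDEs on a
512-point grid over [0, 100] with boundary reflection at both ends (plain
KDE would leak mass outside the bounded range; reflection keeps the
trapezoidal integral at 1 within 1e-3). The default bandwidth is Silverman's
rule 0.9·min(σ, IQR/1.34)·n^(−1/5), falling back to 5 position-percent when
the spread is degenerate (a single position still yields a proper unimodal
curve). Promoter DMRs are excluded from the curves and counted separately.
Within each expression group the Spearman correlation between relative
position and a PHF-higher direction indicator is reported.

## Enrichment

One-sided (over-representation) Fisher's exact test per gene set on
`[[k, n−k], [K−k, N−n−K+k]]`, fold enrichment (k/n)/(K/N), BH across tested
sets. Gene sets are intersected with the background before testing; the
background defaults to all genes in the gene-model annotation and is
exposed as `--background`. External annotation-clustering services
(similarity-threshold 0.85, enrichment score > 2.0 style workflows) and
annotation-similarity networks are out of scope; their internal statistics
are not reproducible from published parameters, which is a known source of
p-value differences versus service-generated tables.

## Percent methylation

Standard curves are least-squares lines of Ct on log10(quantity) (≥ 3
points), inverted as quantity = 10^((Ct − intercept)/slope); non-negative
slopes are flagged as invalid amplification, and quantification below the
lowest standard is extrapolated but flagged. Percent methylation is
100·M/(M+U); M = U = 0 raises rather than silently reporting 0. Group
comparisons use a two-tailed t-test.

## The synthetic generator

`SimulationConfig` defaults describe the emulated study: three diet groups
(MHF, PHF, CON) with three animals each, two assays, a compact 1-Mb
two-chromosome genome, 40 islands of 300–1500 bp planted at GC 0.70 in a
GC 0.40 background whose CpG dinucleotides are 80% depleted (mutating the G
of a CG to A/T — the vertebrate-like depletion that separates island from
background obs/exp), 60 non-overlapping genes of 2–15 kb with 2–8 exons, 50
planted differential bins at effect 0.6 (levels 0.8 vs 0.2; CON held at
0.5), mean bin coverage 30 and negative-binomial dispersion 0.05
(variance μ + 0.05μ²; exactly Poisson at 0). MeDIP bin means are
coverage·level·CpG/⟨CpG⟩ and MRE means coverage·(1−level)·sites/⟨sites⟩, so
an average bin at full signal draws `mean_coverage` reads. DMRs are planted
only in bins with ≥ 3 CpGs, ≥ 1 MRE site and full width — bins where a
methylation difference is observable at all. Expression is log2-normal per
gene; a gene linked to an intragenic DMR shifts the more-methylated group by
effect·(r−50)/50 at relative position r, so TSS-proximal methylation
represses and TES-proximal methylation activates — the association the
report stage is designed to recover. All stages derive their RNG streams
from the single config seed; identical seeds give byte-identical outputs.

A bins-only path (`simulate_bin_dataset`) draws per-bin CpG and MRE-site
counts from Poisson(8)/Poisson(3) instead of reading them off a sequence;
large calibration and power studies use it because the sequence layer adds
nothing there.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: read-level artefacts (no FASTQ, alignment,
mappability or GC bias), fragment-length effects, copy-number variation,
batch effects, correlated methylation along the genome (bins are
independent), isoform-specific TSSs, and realistic inter-animal biological
variability beyond the NB dispersion knob.

## Problem sizes and runtime choices

The test suite runs its null-calibration study at 50 seeds × 20,000 bins,
recovery at 3 seeds × 20,000 bins, island/oracle equivalence on 200 random
sequences up to 2 kb, and the end-to-end run on a 5-Mb, four-chromosome
genome — sizes at which every study-level property is measurable with
comfortable Monte-Carlo margins while the whole suite stays in the
low minutes on one CPU.
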