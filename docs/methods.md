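# Methods

This note documents the models and procedures implemented in `methcompare`,
the parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic validation does and does not show.

## Coordinates, units and containers

All internal coordinates are 0-based half-open; conversion happens only at
I/O boundaries (coverage tables and GTF are 1-based inclusive on disk, BED is
0-based half-open).  Methylation is carried as percent (0–100) in tables,
matching bisulfite extraction output; segmentation converts explicitly to
fractions.  Per-CpG data live in a pandas DataFrame
(`chrom, pos, n_meth, n_total, percent`), read-level calls in a
`ReadCallSet` (one row per CpG call plus a per-read summary), gene models as
lightweight `GeneModel` records with isoform-merged bodies.

Strand combination assigns minus-strand C calls at position p+1 to the
plus-strand C at p.  With a genome available the plus-strand C is identified
from sequence; without one, adjacent records (p, p+1) are paired greedily,
which is exact whenever both strands of a CpG are reported (plus-strand CpG
Cs are never adjacent, so the operation is idempotent).  Read-level calls are
collapsed the same way; a switch disables the collapse.

## Per-CpG and per-region statistics

CpGs enter an analysis at a minimum depth of 5 calls (10 for
reduced-representation data).  Reads enter the allelic caller only if they
cover ≥ 3 CpGs.  All per-region means are **unweighted across covered CpGs**
(not coverage-weighted): this matches percent-based extraction and makes
region means independent of local depth fluctuations; a coverage-weighted
variant was considered and rejected because it couples region scores to
library composition.  CGIs and promoters are scored only when ≥ 35 % of
their sequence CpGs are covered, otherwise class = NA.

The CG observed/expected ratio of a sequence is
`(n_CpG · length) / (n_C · n_G)` with N bases excluded from every count and
a declared convention of 0 when the denominator vanishes.  Windows with more
than 50 % N are dropped.

Promoters are `[TSS−1000, TSS+500)`, strand-oriented, one per gene by the
highest-CpG-ratio isoform TSS.  LCP/ICP/HCP cutoffs are species-specific
config inputs (HCP: ratio above the upper cutoff *and* GC > 55 %; LCP:
ratio below the lower cutoff; ICP otherwise).  Defaults (0.35/0.55) suit the
synthetic genomes; `suggest_promoter_cutoffs` proposes values from the
antimodes of the promoter-ratio density but never applies them silently.

## Segmentation

UMR detection scans each chromosome's depth-filtered CpGs: fractions are
smoothed with a centred running mean over k = 3 CpGs (truncated at ends),
and maximal runs of ≥ 5 consecutive CpGs with smoothed fraction < 0.5
become UMRs spanning their first-to-last CpG.  Smoothed values are rounded
to 12 decimals before the strict comparison so that window means that tie
the cutoff exactly are excluded regardless of summation order.  DMVs are
UMRs ≥ 5000 bp (inclusive).

PMD detection is deliberately **not** a hidden-Markov segmentation but a
documented approximation: a CpG votes PMD when more than half of the 101
CpGs in its surrounding window have methylation inside (0.3, 0.7); voting
runs become intervals snapped to their first/last CpG.  Externally produced
PMD intervals can be supplied instead.  PMD-masked CpGs cannot belong to a
UMR *and break UMR runs* — merely removing them from the scan would let
"consecutive" CpGs span a masked domain and produce artifactual multi-kb
valleys bridging PMDs.  The approximation is validated only against
synthetic truth (implanted-domain Jaccard > 0.8 at 20X); its genome-wide
PMD fractions are not comparable to HMM-based segmentations, and a
hypomethylated inactive X with binomial sampling noise at 12X legitimately
acquires large PMD-like calls.

Cross-species conservation of DMV gene sets is `100·n/min(x, y)` over
ortholog-mapped sets; unmapped genes are dropped.

## Allelic (imprinted) DMR caller

Imprinted DMRs show ~50 % aggregate methylation with a read-level mixture
of fully methylated and fully unmethylated molecules; random partial
methylation yields mosaic reads.  The caller:

1. scans 50-bp windows sliding by 10 bp; a read overlaps a window iff at
   least one of its CpG calls lies inside; its fully-methylated/unmethylated
   status is judged over **all** of its calls (per-window re-evaluation
   would let sparsely covered reads count as "fully" called by accident);
2. keeps windows with mean methylation in [30, 60], > 90 % full reads,
   |%fully-M − %fully-U| < 40, and ≥ 5 overlapping reads (the read floor is
   this package's choice; 1 restores a literal reading of the gates);
3. merges passing windows that overlap **or touch** (the merge convention of
   standard interval tools, and a superset of merging scan-adjacent
   windows);
4. removes candidates on chromosome X (possible XCI) and those overlapping
   an exclusion track (developmental genes with variable allelic
   methylation; the generator emits valley genes named after such families);
5. applies stringent (≥ 20 distinct covered CpGs and > 350 bp) or lenient
   (≥ 10 CpGs) thresholds, then assigns the nearest gene body within 50 kb
   (distance unspecified in the field; configurable).

**Window mean methylation** defaults to the methylated-call fraction over
*all calls of the window's overlapping reads* — the same molecule cohort the
full-read percentages are computed on.  Two alternatives remain switchable:
the unweighted mean of coverage-table CpGs inside the window, and the
in-window call fraction.  The cohort-consistent default matters at ~12X:
per-window means computed from the handful of CpGs inside a 50-bp window
share a single set of ~12–18 molecules, so their allele-sampling noise
(s.d. ≈ 14 percentage points) is perfectly correlated within a window yet
decorrelates every ~150 bp, fragmenting runs of passing windows into pieces
capped near the 350-bp stringent size gate.  Scoring the mean on the same
read cohort as the other gates makes gate failures coincide, and the caller
then recovers essentially every adequately covered implanted DMR, which is
the behaviour reported for this class of pipeline on real data.

## X inactivation

Promoter CGIs are CGIs overlapping a TSS.  Escapees are X-linked genes whose
promoter CGI is < 10 % methylated (strict); subject genes sit near 30 %
(one methylated allele).  Contrasts use two-sided Mann–Whitney tests with
tie-corrected normal approximation.  Non-CGI background tiles are
non-overlapping 1-kb tiles fully inside chromosome bounds, removed on ≥ 1 bp
CGI overlap, contributing with ≥ 1 covered CpG.  Escape calls use X data
only and are annotation-limited: genes without an annotated promoter CGI are
not callable.

## Enrichment

Upper-tail hypergeometric p = P(X ≥ k) via `scipy.stats.hypergeom.sf`
(validated against full enumeration), BH adjustment via statsmodels
(validated against a hand-rolled step-up).  "Methylated CG-rich promoter"
is operationalised as an ICP/HCP promoter with mean methylation > 50 %.
Differential-expression tables are consumed, never computed; the
upregulation gates are strict (fold change > 3, adjusted p < 0.01).

## Synthetic data generator

Each species is one autosome (1.2 Mb) plus one X chromosome (0.8 Mb), with
CpG-depleted background sequence (CG o/e ≈ 0.25), GC-rich CGIs (o/e ≈ 1,
GC 65 %), and feature slots placed without overlap: 10 imprinted loci
(4-kb "weak" islands, o/e ≈ 0.8, GC 60 % — the density and size regime of
the well-characterised mammalian germline DMRs), 3 valleys of 8 kb over
developmental genes, one 80-kb PMD, 30 ordinary genes with unmethylated
promoter CGIs, 8 germline + 12 other genes whose promoters are CG-rich in
sequence but deliberately absent from the CGI annotation (annotated islands
are predominantly unmethylated in real genomes), 10 CpG-poor promoters,
intergenic/gene-body/intronic CGIs and transposon annotations; the X carries
45 XCI-subject genes (promoter CGI alleles at 0.55/0.05 → ~30 % aggregate)
and 8 escapees (0.02/0.02) over a hypomethylated non-CGI background (0.60 vs
0.80 on autosomes).  The X gene counts are sized so the X-vs-autosome
rank-sum contrast has adequate power at the region counts a small simulated
chromosome can host.

Every CpG has two allele methylation probabilities; imprinted loci use
(1.0, 0.0) — epigenetic states are clonal per molecule, and the observed
per-call error is supplied by the conversion-noise flip — valleys and
escapee promoter CGIs 0.02, the inactive-X promoter allele 0.55/0.05.
Sequencing draws molecules with Poisson placement at per-base coverage
λ = 12 (the post-deduplication depth typical of the WGBS data this pipeline
targets); each molecule picks an allele uniformly and contributes one
contiguous string of CpG calls over 100 bp (a paired-end 2×`read_len`
fragment geometry is available via `fragment_len`); molecules inside the PMD
instead draw a per-molecule level uniform on [0.2, 0.8].  Every call flips
with probability ε = 0.005 (bisulfite conversion error scale).  The
coverage table is the exact aggregation of the emitted calls, and all
randomness flows from one integer seed through `numpy.random.default_rng`,
so outputs are byte-identical for a fixed seed.

**What the generator does not model** — and hence what passing tests do not
show about real data: sequence-level reads (no FASTQ, no mapper or caller
biases), PCR duplicates and GC coverage bias, cell-type heterogeneity and
partial somatic erosion of imprinted methylation, non-CpG methylation,
annotation errors, and chromosome-scale structure beyond the implanted
regimes.  Recovery statistics on this substrate demonstrate algorithmic
correctness and discriminative power under idealised noise, not expected
field performance.

## Problem sizes and runtime

The default study is three species × 2 Mb at 12X (~34,000 covered CpGs and
~240,000 read-level calls per species), which the full pipeline processes in
a few seconds per species; the test suite and the acceptance script each
complete in well under a minute on one CPU.  An integration run on real
mouse fibroblast WGBS (to compare against the known mouse germline DMR
catalogue) is possible through the same file-based inputs but is outside the
scope of the shipped validation.

## Known limitations

* The PMD approximation is not calibrated against HMM segmentations; its
  genome fractions are not comparable across methods.
* LCP/ICP/HCP cutoffs must be chosen per species; the density-antimode
  helper is advisory.
* Gene association of DMRs uses nearest gene-body distance with a 50-kb
  cap; imprinted control regions can regulate genes megabases away.
* Escapee calling is bounded by promoter-CGI annotation quality.
* The Wilcoxon tie handling follows the tie-corrected normal approximation;
  exact small-sample p-values are not used.
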