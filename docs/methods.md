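# Methods

## Scope and data model

The package analyses mRNA 3′-end formation from four kinds of evidence:
3′-seq read-end positions (BED6), genome sequence (FASTA), gene models
(GFF3 with gene/exon/three_prime_UTR rows), coverage tracks (bedGraph)
and protein log2-intensity tables (TSV). All internal coordinates are
0-based half-open; GFF3 is converted at the boundary. "Downstream" always
means the transcript 3′ direction (higher coordinates on `+`, lower on
`-`); every window computation routes through a single helper
(`genes.transcript_interval`) so the strand convention cannot drift
between modules.

## CPA-site calling

Read 3′ ends are clustered per (chromosome, strand) by single linkage:
consecutive positions ≤ `max_gap` apart (default 24 nt, a common polyA
cluster width that sits below typical inter-site spacing) join one
cluster. The cluster's cleavage site is its *modal* position — the base
with the largest summed count — not the midpoint, because downstream
windows for internal-priming filtering and cis-element scanning must
anchor on the most-used cleavage base; ties break toward the
transcript-downstream position. A cluster is flagged as a likely
internal-priming artifact when the 10 genomic bases immediately
downstream contain ≥ 7 adenosines or a run of ≥ 6 consecutive A
(oligo-dT priming on genomic A tracts); flagged clusters are kept in the
output but excluded from APA calling. Clusters map to a gene when the
representative lies in the gene span or ≤ 500 nt past the annotated
3′ end on the same strand; among several matching genes the nearest
annotated 3′ end wins, with exact ties broken lexicographically. These
clustering and filter parameters are declared, configurable defaults,
not estimates of any particular instrument's behaviour.

## APA events

Per gene only the two most abundant unfiltered sites (total count over
all samples, ties resolved toward the transcript-proximal pair) are
considered; a pair is testable when both sites have ≥ 10 reads. Whether
abundance should be ranked on reference-only or all-sample totals is
genuinely open; all-sample totals are used so the ranking is symmetric
in the conditions. Replicates are pooled within condition and the 2×2
table [[prox_ref, dist_ref], [prox_alt, dist_alt]] is tested two-sided
by Fisher's exact test — the standard small-replicate 3′-seq practice.
Pooling ignores biological replicate variance, so a replicate-aware
beta-binomial likelihood-ratio test (shared precision, per-condition
mean, χ²₁ reference) is available behind `method="betabinom"`.
Benjamini–Hochberg correction is applied jointly across all tested
events of all categories (the multiple-testing universe is a design
choice; a single joint universe is the least surprising one). Direction
requires `q < α` **and** `|Δ| ≥ 0.1`; the minimum effect guards against
significant-but-tiny shifts at high depth. Contexts are assigned from
the gene model (intron, terminal exon, internal exon, ≤ 500 nt 3′
extension, intergenic) and map onto the three biological categories
described in the README; proximal/distal is defined in transcript
direction, never by genomic coordinate.

## Cis-elements

Motif matching operates on DNA with T ≡ U. The two hexamer rules accept
any window at Hamming distance ≤ 1 from the consensus except the fully
degenerate word (AAAAAA, UUUUUU); each therefore accepts exactly 18 of
the 4096 hexamers, a fact the tests re-derive by brute force rather than
assume. UGUA is matched exactly — the mismatch allowance attaches only
to the hexamers. Scan windows are transcript-relative offsets from the
cleavage base and are configuration, reported in output headers:
defaults UGUA [−200, 0), PAS [−60, 0), U-rich [−60, +60). Upstream
placement of the UGUA/USE and PAS follows the canonical plant
architecture; the U-rich CstF-class element may sit on either side, so
its window straddles the site. Windows truncate at chromosome ends and
never raise. Co-occurrence tables report per-class single-element and
all-three fractions; empty classes appear with n = 0 rather than being
dropped. Base-composition profiles are transcript-oriented per-position
frequencies that sum to 1 wherever data exist.

## Overlap statistics

The one-sided overlap test is the exact hypergeometric upper tail
P[X ≥ k], summed in log space (`scipy.stats.hypergeom.logpmf` +
`logsumexp`) so universes of 10⁵ items do not underflow; probabilities
below the smallest positive float are clamped to it and the log value is
exposed separately. The universe is a required caller argument — overlap
p-values are meaningless without one, so there is no default.

## IP–MS enrichment

Missing quantifications are imputed per sample from a down-shifted
normal N(μ − 1.8σ, (0.3σ)²) of the observed values — the standard
treatment when control pulldowns show structural missingness — with the
shift and width exposed. Each protein gets a two-sided Welch *t*-test on
log2 intensities with a small variance floor so zero-variance degenerate
rows yield p ≈ 1 instead of NaN. Significance combines fold change and
p-value through the SAM-style hyperbola `−log10 p > c / (log2FC − x₀)`
for `log2FC > x₀`, strict inequalities, enrichment side only (the
repression arm is deliberately not called). Default c = 0.75, x₀ = 0; a
stricter preset c = 2.5 is provided, and stronger curvature provably
calls a subset of weaker curvature on identical data. Curve FDR is
estimated by label permutation on the once-imputed matrix: estimated
FDR = mean permuted significant count / observed significant count,
undefined (NaN) when nothing is observed significant. Note that
down-shift imputation biases proteins with many missing *control*
values toward apparent enrichment; permutation calibration cannot see
this bias, so tables with heavy uniform missingness should be
interpreted through the curve's observed/permuted counts, not as exact
FDRs.

## Coverage profiles and the 3′ shift

Anchored profiles extract a fixed window (default [−500, 2000)) around
each gene's annotated 3′ end in transcript orientation; scaled mode
resamples the gene body into 100 bins with 500-nt flanks in 50 bins
each. Per-gene normalization divides by the mean coverage of the gene's
own extracted window ("gene-mean"; also "none" and "library-size"), and
the mode is recorded on the profile object. The downstream-shift
statistic is the difference of the centre of mass of the two mean
profiles over a region near the anchor (default [−100, 1000)) —
a quantitative, configurable stand-in for "RNAPII piles up further
downstream"; a peak-position difference can be obtained from the
profiles directly. Centre of mass is translation-equivariant and
invariant to multiplicative rescaling of a track; it is *not* invariant
to adding a constant offset to both tracks (the flat component does not
translate), which is why the simulated tracks below are peak-shaped.
All-zero regions yield a missing (NaN) shift rather than an error.

## Synthetic data

The generator emulates the study's conditions, not any particular
instrument:

* **Genome and genes.** One chromosome of i.i.d. background sequence
  (default GC 0.5) carries non-overlapping genes in equal numbers on
  both strands (forcing strand-aware code paths), with 2–6 exons,
  introns of 150–500 nt, 3′ UTRs of 180–320 nt and 0.7–1.4 kb intergenic
  gaps. Draws are split per gene from the master seed
  (`SeedSequence.spawn`), so enlarging a cohort never perturbs earlier
  genes — a reproducibility property the tests assert.
* **Sites.** Every gene has its constitutive/distal site at the
  annotated 3′ end; a tandem proximal site 80–150 nt upstream in the
  terminal exon (per-gene probability configurable); and one designated
  candidate position per intron.
* **Cassettes.** `cassette_fraction_introns` (default 0.27) and
  `cassette_fraction_terminal` (default 0.65) are defined as the
  *realised* fraction of sites carrying all three cis-elements under the
  default scan windows. Random background already co-locates the three
  elements at a few percent of sites, so the generator scans first and
  tops up only as many sites as needed, inserting TGTA at −35, AATAAA at
  −25 and TTGTTT at +8 (transcript offsets, reverse-complemented on the
  minus strand) by substitution — coordinates never change. Naive
  planting on top of background would silently overshoot the nominal
  rate.
* **Usage and counts.** Baseline usage is 0.10 for the candidate intron
  site and 0.30 for the tandem site, remainder to the distal site.
  Affected genes (drawn without replacement; intronic effects only from
  cassette-bearing candidates) shift usage by `delta_usage` (default
  0.4): intronic pCPA rises in the knockdown (a *repressed* event),
  tandem usage moves 0.7 → 0.3 (an *enhanced* event). Per replicate,
  gene totals are Poisson (negative-binomial when overdispersion > 0)
  around the design depth, allocated multinomially by usage, and each
  read end is jittered uniformly within ±5 nt — enough to exercise
  clustering without splitting clusters at the default gap. The jitter
  model is a stand-in; no claim is made about any real protocol's
  positional error.
* **Coverage.** Each gene contributes a Gaussian 3′-end occupancy peak
  (height 10, sd 30 nt, no flat gene-body component); the alternate
  track displaces the peak downstream by the requested shift. The
  narrow peak keeps >99.9% of its mass inside the default shift region,
  so the planted displacement equals the centre-of-mass shift. The
  coverage cohort uses 3–4 kb intergenic gaps so neighbouring genes'
  peaks cannot leak into a gene's metaplot window.
* **Intensities.** Protein baselines N(25, 2²) on the log2 scale with
  0.3-sd replicate noise; enriched proteins are elevated by the effect
  size in bait samples; missingness is injected preferentially in
  control samples (bait rate = 0.25× control rate).

What the generator does **not** emulate: alignment artifacts, UMI
duplication, sequencing error, spliced-isoform structure, chromatin
input bias, or correlated protein abundances. Passing tests therefore
demonstrate that the implementations compute what they claim under the
stated model — not that the defaults are optimal for any real dataset.

## Validation cohorts and problem sizes

The recovery cohort uses 450 genes at depth 50 with 3 replicates per
condition and Δ = 0.4; the transcript-first cassette intron qualifies a
gene for the planted effect, giving ≈ 240 affected genes, and tandem
sites are disabled so the top-two selection isolates the intron/distal
pair. The matched null cohort (250 genes, tandem sites at 0.3, no
effect) supplies the false-positive check, the unaffected-intron
co-occurrence class (cassette rate 0.27 with pure binomial sampling
noise, since nothing is premature-cleaved) and the constitutive-site
class (rate 0.65). Coverage uses 50 genes at shift 200; enrichment uses
1500-protein null tables and an 800-protein table with 60 planted
proteins at log2FC 2.5. These sizes make the whole validation suite run
in seconds while keeping every Monte-Carlo margin (3 SE) far from its
threshold.

## Numerical choices and edge cases

Fisher p-values come from `scipy.stats.fisher_exact`; a pinned 2×2 table
is checked against an independent full-enumeration oracle computed with
exact rational arithmetic. Zero totals in a condition skip the event
with a logged reason. The beta-binomial fit uses Nelder–Mead on the
(logit mean, log precision) scale with the LRT clipped at 0. Hexamer
rule enumeration, hypergeometric tails for all universes ≤ 12, and the
clustering idempotence, count-conservation, antisymmetry and strand
involution invariants are all property-tested. Degenerate inputs (empty
cohorts, zero depth, all-missing proteins, windows past chromosome ends,
all-zero coverage regions) return empty/missing results rather than
raising, except where the input is contradictory (genes that do not fit
the chromosome, overlaps exceeding set sizes, unknown condition labels),
which raise with the violated bound named.
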