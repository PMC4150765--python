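# Methods

## The question the pipeline addresses

A transcription factor (TF) binding event at a promoter can coincide with a
local change in chromatin: a nucleosome that occupied the site in one
cellular state is found elsewhere after the TF is induced. The pipeline
quantifies this coupling genome-wide from four inputs per condition pair
(before/after TF induction): nucleosome footprint maps, TF peak sets, a TSS
annotation, and replicate expression. Its core outputs are (i) per-nucleosome
repositioning calls between the states, (ii) a classification of every
binding site unique to the induced state by its nucleosome context in both
states, (iii) the cross of those site categories with differential
expression, and (iv) the binding motif recovered from peak sequences.

## Coordinate and record model

All arithmetic is 0-based half-open (BED native). A nucleosome is reduced to
its dyad center plus a fixed 147-bp footprint: positioned-nucleosome calls
locate a particle, and a single-center abstraction makes every distance rule
unambiguous. A peak is anchored at its summit (interval midpoint unless a
summit column is given); classification is therefore invariant to peak
width. Strand is carried only by TSS records — signed positions are measured
in the transcription direction of the anchoring gene, so upstream is
negative for both strands.

## Promoter windows, phasing labels, NFR

Promoters span −7.5 kb to +2.5 kb of the TSS in transcription direction,
clipped at the chromosome start. A nucleosome belongs to a window iff its
center lies inside it; with overlapping real annotations a nucleosome is
assigned to every containing window, matching the multi-assignment rule used
for gene categories. Within a gene, nucleosomes are labeled outward from the
TSS: −1 is the greatest negative TSS-relative position, +1 the smallest
non-negative one (a dyad exactly on the TSS is +1; the tie must break one
way and this is it). The nucleosome-free region (NFR) is measured
edge-to-edge: `max(0, rel(+1) − rel(−1) − 147)`. Center-to-center would be
equally defensible; the edge-based form is used because it is zero for
abutting footprints.

## Repositioning calls (the 300-bp rule)

Each before-state promoter nucleosome is paired with the nearest after-state
dyad in the same window (many-to-one; an optional greedy one-to-one
assignment was considered and rejected as an interpretation the simple
nearest-neighbor reading does not require). The displacement ΔN is the
center-to-center distance; a call is *repositioned* when ΔN > 300 bp —
i.e. no after-state placement within ±150 bp of a position able to cover
the same linker — and an empty after-window yields a censored (infinite) ΔN
counted as repositioned. Displacements are summarized in bins {0}, (0,100],
(100,200], (200,300], >300 (censored in the last), and two displacement
distributions are compared with the two-sided Wilcoxon rank-sum test:
exact permutation enumeration with midranks when both samples have n ≤ 10,
tie-corrected normal approximation otherwise. Censored displacements cannot
be ranked and are excluded from the test (their counts are reported).

## Site classification

A peak is *unique to the induced state* iff its interval shares no base pair
with any before-state peak. For each unique site, d_before and d_after are
the distances from the summit to the nearest dyad in each map (0 inside a
footprint, infinite on an empty chromosome). The 300-bp rule then gives four
quadrants: repositioning_coupled (≤300 → >300), co_occupied (≤300 → ≤300),
nucleosome_independent (>300 → >300) and nucleosome_gained (>300 → ≤300).
The gained quadrant is reported as its own category rather than merged into
another — the generator never plants it, so on synthetic data it stays
empty, but real maps can populate it. Sites map to genes whose promoter
window contains the summit; a gene reached by several categories is counted
in each. Per category the summary reports sites, genes, DE genes, the exact
DE percentage, the mean −1 displacement (after − before rel_pos; positive is
toward the TSS) and the mean NFR change.

## Differential expression

Per gene, a two-sided two-sample Student t-test with pooled variance between
the condition replicate blocks, flagged at raw P < 0.05. No multiplicity
correction is applied by default because the gene-category cross is defined
on the raw-P criterion; Welch (`equal_var=False`) and Benjamini–Hochberg
(`bh_correct=True`) are available. The z-transformation used for the
occupancy–expression comparison standardizes per-condition mean expression
across genes (sample sd, n−1).

## Gibbs motif discovery

The classical fixed-width site sampler: one site per sequence; each sweep
holds a sequence out, builds the PWM from the remaining sites with 0.5
pseudocounts per base, and re-samples the held-out offset proportional to
the PWM/background likelihood ratio (background = input base composition,
floored so no base has zero probability). After every sweep a phase-shift
move tries sliding the entire alignment by up to ±3 positions and accepts an
improvement — the standard remedy for the register-shifted local optima a
per-sequence sampler cannot escape. The run keeps the best-scoring state
(summed log2 likelihood ratio of the chosen sites) over a fixed iteration
budget (150 sweeps) and 3 restarts; fixed budgets give deterministic
runtime, and runs are bit-reproducible given the seed. Scanning reports the
best log-odds window per sequence on both strands; the default hit threshold
is half the PWM's maximal attainable log-odds, which on the synthetic
conditions separates embedded sites from the best window of a background
sequence. Width defaults to 12.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions and are not tuned per analysis.

* **Architecture.** One synthetic chromosome; non-overlapping promoter slots
  (10 kb window + 2 kb gap), random strands, one transcript per gene.
  Each promoter carries a phased array: −1 at −(nfr_halfwidth + spacing/2),
  +1 at the mirror position, +2..+4 at 190-bp steps, all with Gaussian
  positional jitter (sd 15 bp by default — a free stand-in for the unknown
  resolution of real positioned-nucleosome calls). With zero jitter the NFR
  width is exactly 2·nfr_halfwidth + spacing − 147 = 183 bp.
* **Repositioning plant.** The array splits at the NFR into blocks {−1} and
  {+1..+4}; the within-block dyad gap (190 bp) is below the 300-bp
  threshold while the cross-NFR gap (330 bp) is above it. A nucleosome moved
  out of a block while its neighbors stay would sit within 190 bp of a
  stable neighbor's after-state position and be invisible to a
  nearest-neighbor caller, so repositioning is planted per block: each block
  moves wholesale with probability `reposition_fraction` (0.114 by default,
  the promoter-proximal repositioning rate the pipeline is designed to
  measure), keeping the per-nucleosome marginal probability exactly that
  fraction. Planted shifts are drawn uniformly from [min_shift, max_shift]
  (default [301, 800] bp, random direction) restricted to land >300 bp from
  every before-state dyad of the promoter and inside the window. A planted
  event is therefore detectable by construction, and with zero jitter the
  called set equals the planted set exactly. Consequence for calibration:
  nucleosome statuses are block-correlated, so the sampling error of the
  recovered fraction is the design SE `sqrt(p(1−p)·Σb²)/Σb` over block
  sizes b (≈1.84× the naive per-nucleosome binomial SE for the 1+4
  template); tests use 3 design SEs.
* **Peaks.** Of `n_peaks_after` induced-state peaks (default 2 per
  promoter), `frac_peaks_unique` (0.36) are unique to the induced state; the
  rest are duplicated into the before set. Unique peaks are planted by
  category: 31% within 300 bp of a before-state dyad, of which 70% at a
  repositioned dyad (cleared >300 bp from every after-state dyad) and 30% at
  a stable one; the remainder in nucleosome-free upstream territory, >300 bp
  from every dyad of both maps. These three proportions mirror the
  site-category ratios the summary stage is meant to reproduce.
* **Expression.** Replicates (3 per condition) are baseline N(8, 1) plus
  N(0, 0.5) noise; genes hosting a repositioning-coupled peak get a ±5.0
  condition effect (10 sigma — coupled genes are designed to be essentially
  always differentially expressed), and a fraction `alpha_null` (0.10) of
  the remaining genes get the same effect as background so the non-coupled
  categories show a low but nonzero DE rate.
* **Sequences.** One 200-bp uniform-background sequence per unique peak;
  with probability 0.8 the 12-mer consensus (default `TGACGTCATCGA`, a
  non-self-overlapping word so register errors are penalized) is embedded at
  a position Gaussian-jittered (sd 15) around the summit-centered offset,
  with each motif base mutated to a different base with probability 0.10.
* **Determinism.** One seed; every stage draws from a stage-keyed child
  generator (`SeedSequence(seed, spawn_key=(stage,))`), so identical configs
  give byte-identical outputs and stages are independently reproducible.

### What the generator does not emulate

Uniform per-promoter nucleosome counts (exactly 5) — so the
occupancy-vs-expression correlation is degenerate on synthetic data and the
pipeline skips it there with a log line; real maps vary in occupancy and
feed it normally. No occupancy/fuzziness signal, no MNase or array-probe
bias, no overlapping promoters, no distal (enhancer) binding, no
sequence-dependent nucleosome positioning. Passing tests therefore
demonstrate correctness of the rules and statistics under planted truth, not
performance on real chromatin maps.

## Problem sizes and numerical choices

Validation runs use 300–2,500 promoters for truth-table checks, 30,000
promoters (150,000 nucleosomes per state) for fraction-recovery calibration,
2,500 genes for type-I calibration of the t-test, and 50 planted sequences
×5 seeds for motif recovery — sizes chosen so the full suite exercises
every claim at meaningful statistical resolution on a single CPU. Histogram
bins are half-open everywhere, including the last bin. Percentages in
summary tables are exact (no rounding); undefined quantities (empty bins,
missing −1/+1, empty categories) are NaN/flagged rather than zero-filled.
Chromosome names are opaque strings; nothing is assembly-dependent.

## Known limitations

Nearest-neighbor matching cannot see a repositioning event whose origin lies
within the threshold of any retained after-state dyad — with 190-bp phasing
this is a property of the 300-bp rule itself, not of the implementation, and
it is why the generator plants per block. Censored displacements are
excluded from rank-sum comparisons, which slightly understates differences
when unmatched windows are common. The site sampler assumes exactly one
motif occurrence per sequence (no ZOOPS); sequences without a planted site
contribute noise sites to the PWM tail.
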