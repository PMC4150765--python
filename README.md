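# nucleoshift

Integrative analysis of promoter nucleosome repositioning, transcription
factor (TF) binding, and gene expression between two cellular states —
typically before and after inducing a TF.

**Who it is for.** Computational epigenomics work where you have, per
condition, positioned-nucleosome calls (MNase footprints as BED), TF peak
intervals (BED, optional summit column), a TSS annotation (BED6 or TSV) and
replicate expression (TSV), and want to know whether TF binding that
coincides with local nucleosome repositioning is the binding that changes
transcription.

## The model

All promoter-relative geometry is strand-aware, with promoters spanning
−7.5 kb to +2.5 kb of the TSS. A nucleosome is its dyad center with a
147-bp footprint; phased nucleosomes are labeled −1, +1, +2, … outward from
the TSS, and the nucleosome-free region (NFR) is the −1/+1 edge-to-edge gap.

* **Repositioning (300-bp rule).** Pair each before-state promoter
  nucleosome with the nearest after-state dyad in the same window; the
  displacement is ΔN = |center_after − center_before|. The nucleosome is
  *repositioned* when ΔN > 300 bp (no counterpart within ±150 bp of a
  placement covering the same linker). Displacement distributions are
  compared with the two-sided Wilcoxon rank-sum test (exact enumeration for
  both n ≤ 10, tie-corrected normal approximation otherwise).
* **Site classification.** For each peak unique to the induced state
  (zero interval overlap with the before set), let d_b, d_a be
  summit-to-nearest-dyad distances in the two maps. With t = 300 bp:
  d_b ≤ t < d_a → *repositioning_coupled*; d_b ≤ t, d_a ≤ t →
  *co_occupied*; d_b > t, d_a > t → *nucleosome_independent*;
  d_b > t ≥ d_a → *nucleosome_gained*. Sites map to genes whose promoter
  window contains the summit; a gene in several categories counts in each.
* **Expression.** Per gene, a pooled-variance two-sample Student t between
  replicate blocks at P < 0.05 (Welch and Benjamini–Hochberg behind flags);
  per-condition means are z-transformed across genes for the
  occupancy–expression Pearson correlation.
* **Motif.** Fixed-width (12) Gibbs site sampler: hold one sequence out,
  build the PWM from the rest (pseudocount 0.5), re-sample the held-out
  site ∝ PWM/background likelihood ratio, with phase-shift moves and
  best-state tracking over restarts; log-odds scanning on both strands.

A synthetic-data generator plants all of this with recorded ground truth
(repositioning events per phasing block, site categories, DE effects, motif
offsets), so every stage is testable end to end without any external data.

## Worked example

The numbered drivers under `analysis/` run the whole story on one
deterministic synthetic dataset (1000 promoters, seed 11) and write tables
under `results/`:

```
$ python analysis/01_simulate.py
genes: 1000
nucleosomes per state: 5000
planted repositioned: 574 (11.48%)
peaks before/after: 1280/2000 (720 unique to induced)

$ python analysis/03_repositioning.py
induced vs control: 5000 nucleosomes, 541 repositioned (10.82%)
...
depleted-analogue: 0.28% repositioned
Wilcoxon rank-sum induced vs depleted-analogue: P = 6.31e-21

$ python analysis/05_site_classification.py
720 induced-unique sites:
nucleosome_independent    497
repositioning_coupled     156
co_occupied                67
              category  n_sites  n_genes  n_de  de_percent  mean_minus1_shift
 repositioning_coupled      156      112   112      100.00            -175.59
           co_occupied       67       65    11       16.92             -19.28
nucleosome_independent      497      403   102       25.31             -64.90
```

Reading this: with positional jitter on, the caller recovers 10.82% of
nucleosomes as repositioned against a planted 11.48% (jitter blurs events
near the threshold); a near-null "depleted" analogue shows that the
displacement distribution shift is highly significant; and every gene whose
induced-unique binding site coincides with a repositioned nucleosome is
differentially expressed (planted 10-sigma effects), against ~17–25%
background in the co-occupied and independent categories. The motif driver
recovers the planted consensus exactly
(`06_motif_discovery.py`: `recovered consensus TGACGTCATCGA`, 72.6% of peak
sequences carry a hit, 99.4% of hits within 50 bp of the peak center).

The same pipeline runs from the shell on files:

```
nucleoshift simulate --outdir sim --seed 3
nucleoshift reposition --before sim/nucleosomes_before.bed \
    --after sim/nucleosomes_after.bed --tss sim/tss.bed --outdir out
nucleoshift run --outdir out            # full pipeline + summary table
```

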