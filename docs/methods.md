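# Methods

## The analysis

`aluhic` links transposable-element (TE) content to chromatin-interaction
(CI) frequency measured by Hi-C at 40-kb resolution, inside topological
domains. The pipeline is:

1. **Stratify and filter bin-pairs.** A bin-pair is *intra-domain* when
   both 40-kb bins lie fully inside one common domain, *non-intra* when
   both lie in (different) domains, *boundary* otherwise. Boundary pairs
   are excluded throughout. The lower frequency threshold is the
   arithmetic mean of the non-intra frequencies (treating inter-domain
   contacts as the false-positive noise floor); intra pairs below it are
   discarded. The upper threshold is the left edge of the first empty
   unit-width histogram window of the intra frequencies (an outlier cut);
   the fraction removed is reported relative to pairs surviving the lower
   threshold. The lower bound is inclusive, the upper exclusive.
2. **TE metrics per pair.** For a selector (class, family or Alu age
   group), over the pair's combined 80-kb region:
   *coverage* = merged covered bases / 80 kb; *enrichment score* = number
   of copies whose midpoint lies in the region (midpoints prevent double
   counting across adjacent bins); *density* = enrichment score divided by
   the maximum possible same-family copies, i.e. count × mean family
   length / 80 kb, with the mean copy length computed genome-wide.
3. **Binned correlation.** Retained pairs are split into `n_bins`
   (default 50; 20 and 100 as robustness settings) equal-width frequency
   bins spanning [min, max]; empty bins are dropped; each bin contributes
   (mean frequency, mean metric). Pearson r over these points with a
   two-sided t test at n−2 df. Two correlations (e.g. intra vs non-intra)
   are compared with a Fisher-z two-sample z test.
4. **Sequence composition by origin.** Every base of a pair is assigned to
   exactly one origin class — Alu, SINE/non-Alu, non-SINE — with
   precedence Alu > SINE/non-Alu on overlapping annotations. Per class:
   GC content (G/C bases per base; N counts toward length, never GC), CpG
   density (CpG sites per G/C base; a site belongs to the class of its C
   position), methylation density (methylated fraction of CpG sites).
   Class lengths sum to 80 kb exactly, and per-class GC contributions sum
   to the background GC — these conservation identities are asserted
   exactly in the tests.
5. **Regulatory elements.** Active enhancers = maximal H3K4me1 ∩ H3K27ac
   overlap regions; active TSSs = TSS positions covered by H3K4me3 peaks
   (per gene, the TSS with the most supporting peaks; ties by summed peak
   signal, then 5′-most). Element counts per pair feed the same binned
   correlation. Genome bins are ranked into k = 5 equal-count groups by
   Alu coverage and element counts are correlated with group mean
   coverage. Enhancers are Alu-derived when their reference point (summit,
   else midpoint) lies inside an Alu copy; their ±20-kb flanking Alu
   coverage is tested against random genome windows with a one-sided
   binomial test (success = window coverage above the background mean,
   with the success probability estimated from the background itself) and
   a permutation cross-check on the window-mean. Peak sets are matched
   across conditions by mutual-nearest pairing at < 250 bp.

## The synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale (default: 2 chromosomes × 8 Mb, 40-kb bins).

* **Domains** tile each chromosome completely with lognormal lengths
  (mean 1 Mb, log-sd 0.5) snapped to the bin grid.
* **Contact frequencies.** Each bin carries a latent log-activity
  `a_b ~ N(0, 0.5)`. Intra-domain pairs at distance d Mb draw
  `f = 15 · exp(−0.8·d + a_i + a_j + ε)`, `ε ~ N(0, 0.5)`; non-intra
  pairs draw Exponential(mean 2). These defaults give an intra mean ≈ 15,
  a lower threshold ≈ 2 and an upper threshold within a factor ~10 of the
  mean — the same mean-to-extreme proportions as real normalized 40-kb
  Hi-C frequencies. An optional domain-level (compartment-like) activity
  component exists but defaults to 0: concentrating activity in whole
  domains makes the domain, not the bin, the effective sampling unit and
  destabilises the binned estimates at this scale.
* **Repeats.** Alu copies per bin are Poisson with mean `2 + 0.4 · f̄_b`
  where `f̄_b` is the bin's realized mean intra frequency — this plants
  the positive Alu–frequency coupling. Copy lengths are N(300, 30) ≥ 50
  (modern Alus are ~300 bp); the age-group mix is AluJ:AluS:AluY =
  0.25:0.55:0.20. L1, MIR, LTR and DNA elements are placed
  frequency-independently at 6, 7, 9 and 6 copies per bin — the per-bin
  copy numbers of the corresponding families in the RepeatMasker
  annotation of the human genome. Copies never overlap within a family
  (overlaps across families exercise the partition precedence rule).
* **Sequence.** CpG dinucleotides are planted at 0.06 per position inside
  Alus and 0.01 outside; the remaining positions are filled i.i.d. with a
  GC probability adjusted so the realized GC fraction matches 0.60 inside
  Alus and 0.41 outside (the planted CpGs would otherwise inflate it).
  Background C·G adjacencies also form CpG sites, so the realized CpG
  density is planted + incidental; recovery tests target the realized
  composition, not the planting rate.
* **Methylome.** Every CG dinucleotide receives a binary call:
  Bernoulli(0.92 / 0.90 / 0.78) inside AluJ / AluS / AluY copies
  (matching the "old Alus above 90%, AluY below 80%" ordering), 0.20 near
  TSSs (±1 kb), 0.70 in gene bodies, 0.75 elsewhere.
* **Regulatory marks.** Enhancer events per bin are Poisson
  (0.05 + 0.03·f̄_b), each emitting overlapping H3K4me1/H3K27ac peaks;
  60% of events center inside an Alu copy of their bin. H3K4me3 events
  (Poisson 0.05 + 0.02·f̄_b) land on TSSs within the bin.
* **Remap loss.** 6.68% of bins per chromosome are dropped (with every
  pair touching them) before writing, emulating coordinates lost in an
  assembly liftover.
* A truth manifest (JSON) records the full configuration, planted
  coupling signs, realized Alu copy count and realized per-subfamily
  methylation rates.

What the generator does **not** emulate: matrix-balancing artefacts,
realistic repeat sequence models (copies are composition-only, not
alignable), read-level bisulfite noise, chain-based liftover geometry, or
inter-chromosomal contacts. Passing recovery tests therefore demonstrates
that the estimators recover planted couplings of realistic magnitude at
desk scale — not that the original genome-scale measurements would
reproduce.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere; RepeatMasker input
  (1-based inclusive) is converted on read.
* Self bin-pairs (i = j) are rejected: density normalisation assumes an
  80-kb two-bin region.
* Strand is read and preserved but ignored by all coverage and count
  computations.
* Binning x-values are per-bin mean frequencies (not midpoints); the last
  bin is right-closed; empty bins reduce n.
* `detect_upper_threshold` scans integer-aligned windows from
  floor(min); with no empty window below the maximum it returns
  floor(max) + step.
* Coverage groups are equal-count (quintiles), remainder to the lowest
  groups, ties broken by genomic order.
* Peak matching is mutual-nearest one-to-one, which makes shared counts
  symmetric and deterministic; distance ties prefer the left neighbour.
* The binomial enrichment test defines success as "window coverage above
  the background mean" with p0 estimated from the background; a
  permutation test on the window-mean ships as a cross-check, and both
  are reported.
* Degenerate inputs raise rather than return sentinels: constant metrics,
  |r| = 1 in the Fisher transform, empty strata, CpG calls that are not
  CG in the sequence.

## Known limitations

* At the default desk scale (~4–5 × 10³ retained intra pairs over ~370
  usable bins), the null distribution of the 50-point binned correlation
  is wider (sd ≈ 0.23) than the independent-points t-distribution
  (sd ≈ 0.14) would suggest: sparse high-frequency bins carry high
  leverage, and pairs sharing a bin share its repeat counts. Null
  estimates for uncoupled families therefore occasionally reach |r| ≈
  0.3–0.5. The planted Alu coupling (r ≈ 0.75–0.95) is unambiguous
  against this floor. At the original data's scale (~9 × 10⁵ pairs) the
  effect is negligible.
* The per-million-year methylation-change estimate is a two-point
  difference quotient of group densities over group mean ages; with the
  default planted densities (0.92 at 81 Myr vs 0.90 at 36 Myr) it gives
  ≈ 4.4 × 10⁻⁴ per Myr (0.044 %/Myr). A much smaller figure sometimes
  quoted for this quantity (0.004 %/Myr) does not follow from these
  densities and ages by that formula; the operation implements the
  formula and makes no attempt to reproduce the smaller figure.
* Expression data has no synthetic generator; the rank-sum comparison of
  active vs inactive genes is exercised on directly constructed samples.
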