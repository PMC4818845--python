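# aluhic

Transposable-element enrichment analysis of Hi-C chromatin interactions.

Alu elements — the ~300-bp primate SINE family with over a million copies
in the human genome — are not scattered at random: their local density
tracks how often a genomic region participates in chromatin contacts.
`aluhic` implements the full analysis chain that quantifies this link from
normalized 40-kb Hi-C bin-pair frequencies and repeat annotation:

* stratification of bin-pairs into intra-domain / non-intra / boundary
  against a topological-domain annotation, with a data-derived lower
  frequency threshold (mean inter-domain frequency) and upper outlier
  threshold (first empty unit histogram window);
* three per-pair TE metrics over the combined 80-kb region — coverage,
  copy count (enrichment score), and density
  `count · mean_family_length / 80 kb` — for TE classes (SINE, LINE, LTR,
  DNA), families (Alu, L1, MIR, …) and Alu age groups (AluJ, AluS, AluY);
* binned Pearson correlation: pairs are split into 50 equal-width
  frequency bins and r is computed over (mean frequency, mean metric)
  points, with a two-sided t test (df = n − 2) and a Fisher-z test for
  comparing correlations between strata;
* origin-partitioned sequence composition: each pair's bases are assigned
  to Alu / SINE-non-Alu / non-SINE, and GC content, CpG density (CpG per
  G/C base) and methylation density (methylated fraction of CpG sites)
  are accounted per class, with exact conservation identities;
* regulatory elements: active enhancers (H3K4me1 ∩ H3K27ac), active TSSs
  (H3K4me3 on TSS), their counts vs frequency and vs Alu-coverage
  quintiles, and a binomial enrichment test of Alu coverage around
  Alu-derived enhancers against random genome windows.

Because the original genome-scale inputs (full Hi-C matrices, RepeatMasker
tracks, a whole methylome) are far beyond desk scale, the package ships a
seeded synthetic-data generator that emulates all of them — genome FASTA
with elevated GC/CpG inside Alu insertions, domains, bin-pair frequencies,
repeat annotation with Alu placement coupled to contact frequency, a
binary-call methylome with age-dependent Alu methylation, histone peaks
and genes — plus a truth manifest so every estimator can be tested against
what was planted. See `docs/methods.md` for the model and its limits.

## Worked example

```sh
aluhic run-all --simulate --seed 1 --out run1
```

simulates the default bundle (2 × 8 Mb genome) into `run1/inputs/`, runs
every stage and writes `run1/report.json`. The threshold line it prints:

```
{"lower": 1.993733100417466, "upper": 77.0, "retained_intra": 4614, ...}
```

means: the mean inter-domain frequency 1.99 was used as the lower cutoff,
the first empty unit window of the intra frequencies started at 77, and
4,614 intra-domain pairs survived both cuts. `aluhic report
run1/report.json` then summarises the correlation tables, e.g.

```
intra Alu: r=0.933 p=5.89e-23 n=50
intra L1: r=-0.185 p=0.198 n=50
```

— the planted Alu–frequency coupling is recovered as a strong positive
binned correlation over 50 frequency bins, while the
frequency-independent L1 placement shows none. The same library calls are
available in Python:

```python
from aluhic import (default_config, simulate_bundle, stratify_and_filter,
                    TEIndex, family_profile)

bundle = simulate_bundle(default_config({"seed": 1}))
strat = stratify_and_filter(bundle.binpairs, bundle.domains)
profile = family_profile(strat.intra, TEIndex(bundle.repeats), n_bins=50)
print(profile["Alu"])   # CorrelationResult(r=0.933..., p=5.9e-23, n=50)
```

Other subcommands (`simulate`, `validate`, `filter`, `enrich`,
`composition`, `regulatory`) expose the individual stages; every flag has
a YAML config twin (`--config`).

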