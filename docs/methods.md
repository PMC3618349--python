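# Methods

This note records the models, parameter choices and numerical
conventions behind `sppmap`, and what the simulation-based tests do and
do not demonstrate.

## Simulated population and array

The simulator emulates the statistical structure that the caller
assumes, not the physics of hybridization.

**Pedigree.** An F1 between fully homozygous parents `A` and `B` is
selfed for `n_generations` (default 6, i.e. F7) by single-seed descent.
Each gamete receives Poisson(L/100) crossovers per chromosome with
uniform positions — the Haldane model, no interference.  The published
map functions assume Kosambi-style interference for distance
conversion; using an interference-free gamete model while mapping with
Kosambi is an intentional simplification (it slightly inflates the
frequency of tight double crossovers relative to real meiosis, see
*Curation* below).  Heterozygosity halves each generation, so the
simulator reproduces the (1/2)^g closed form within Monte-Carlo error
(cross-checked by a dedicated test).  Ground truth retained per line:
diploid genotype mosaics, heterozygous tracts, crossover counts, and
the genetic position of every unigene and SPP site.

**Array.** 25-mer probes tile every 2 bp on alternating strands, so up
to 13 probes overlap a 2-bp window.  GC content per probe is
Binomial(25, 0.5) clipped to [5, 20] — this populates every GC bin the
caller builds; baseline intensity is linear in GC
(`1 + gc_effect·(gc − 12.5)`, default slope 0.03, scale 1000).
Intensity = baseline × allele factor × lognormal noise
(`noise_sd` = 0.1 on the log scale by default).  A probe overlapping a
polymorphic site keeps factor 1 on the `A` allele, `1 − d` (default
depression d = 0.5) on `B`, and `1 − d/2` on a heterozygous tract —
array DNA is bulked from many sibling plants, so a het line contributes
both alleles; the bulk-mixture mean is our assumption, as no published
value exists.  Anti-genomic probes draw from a lognormal whose median
sits one order of magnitude below the genomic baseline
(`background_scale` = 0.1, log-sd 0.5): low enough that >95% of genomic
probe×chip measurements survive the 90th-percentile background filter,
high enough that the filter is exercised.  Each RIL gets two replicate
chips, each parent four.  An optional bad-chip switch shuffles half of
a chip's values to exercise replicate QC.

**Scale defaults.** Population-structure defaults are the reference
experiment's: 213 RILs, nine chromosomes with the published
linkage-group lengths (144–234 cM), F7, duplicate RIL chips, four
parental chips.  The unigene count is a size knob (default 900;
`demo_config()` uses 300 unigenes, 40 RILs, two 120-cM chromosomes):
array size does not change the statistical structure, only runtime.
Half the unigenes are polymorphic, with each 2-bp window an SPP site at
rate 0.1 (~20 sites per 400-bp polymorphic unigene, matching the
published mean of 20.6 SPPs per polymorphic unigene).  Unigenes span
0.007 cM of genetic map, which reproduces the low observed rate of
recombination inside a transcript (split consensus haplotypes).

**What the simulator does not emulate.** Cross-hybridization between
paralogs, probe-sequence-specific affinity, spatial chip artifacts,
partial signal depression that depends on mismatch position inside the
25-mer, and normalization residue.  Passing the recovery tests
therefore shows the pipeline's logic is correct under its own model
assumptions — not that real arrays achieve the same concordance.

## Caller conventions

* GC bins are one per distinct GC count; the reference set value is the
  plain (unweighted) mean of the bin's genomic probes per chip.  The
  alternative reading — positionally weighted reference means — is
  window-dependent and would make the reference a per-window quantity;
  we use the window-independent plain mean and note the ambiguity.
* Percentiles use linear interpolation (the numpy default), documented
  because percentile dialects differ; the background rule is "less
  than", so equality with the cutoff keeps a probe.
* The positional weight curve is triangular, `w(d) = 1 − |d|/13`
  clipped at zero (maximal on the window, zero beyond 12 bp).  The
  originally used curve was derived empirically and never published;
  any callable with those shape constraints can be plugged in, and the
  window statistic is the weight-normalised mean over valid overlapping
  probes.
* The bimodal gap search takes the *first* super-threshold gap in the
  sorted per-chip SPPdev values (deterministic; ties cannot occur on
  continuous data).  δ defaults to 0.2.  Windows whose parental chips
  straddle the gap, or sit on the same side, are discarded with a
  reason code; the handling of a straddling parent is our rule, as no
  published rule exists.
* Range filters default to: mean SPPdev ≥ 0.2, missing fraction ≤ 0.12,
  mean valid probes ≥ 3, span ≥ 2 bp.  The criteria names are from the
  reference method; the values are ours and are exposed on the CLI.
* Replicate QC correlates chips over the 2000 highest-variance genomic
  probes (log scale) and flags a RIL when its replicate correlation
  falls more than 0.05 below either replicate's best correlation to an
  outside chip.  The margin matters: a line with a near-pure parental
  genome has almost no polymorphic signal, so its replicate correlation
  is baseline-level for benign reasons and a strict nearest-neighbour
  rule would false-flag it.
* Splitting a unigene into two consensus haplotypes requires at least
  two RILs showing a clean positional switch; the split point minimises
  total within-side disagreement.  RILs with conflicting calls and no
  positional pattern are set to missing at the locus.  The minimum
  evidence used originally is unpublished; the threshold is exposed.

## Mapping conventions

* Pairwise r̂ is the raw apparent recombinant fraction over
  pairwise-complete RILs — this is what bin tables and pairwise-r
  outputs report.  For *distances*, the selfing fixed point
  R = 2r/(1+2r) is inverted (r = R/(2(1−R))) before the Kosambi (or
  Haldane) function, because several rounds of selfing accumulate
  recombinants and an uncorrected sum of adjacent distances converges
  to roughly twice the gametic map.  `ril_correction=False` restores
  raw behaviour.  The correction is capped at r = 0.4999 so extreme
  apparent fractions remain mappable.
* Grouping is single-linkage over edges with r̂ ≤ `r_max` (default 0.2)
  and ≥ 30 co-observed RILs.  The threshold must sit several standard
  errors below the unlinked expectation r̂ = 0.5; with 40 RILs the
  sampling SD at r = 0.5 is ≈ 0.08, so a 0.35 threshold would bridge
  chromosomes with near-certainty while 0.2 keeps the false-bridge
  expectation well below one edge.  At 213 RILs either value separates
  chromosomes; 0.2 is the safe default across population sizes.
* Bins are connected components of the zero-recombination graph
  (co-observed pairs with r̂ = 0): a component of size ≥ 2 is a bin when
  every co-observed internal pair is zero and a super-bin otherwise;
  isolated loci are singletons.  Representatives have the least missing
  data, ties broken by four-letter code; all tie-breaks package-wide
  use code order, for determinism.
* Ordering minimises COUNT (summed recombination events between
  adjacent representatives) by greedy insertion followed by local
  search to a fixpoint: segment reversals (2-opt), single-marker
  relocations (or-opt) and exhaustive permutation of 5-marker windows
  (ripple).  The 2-opt pass is essential — window ripple alone cannot
  undo a large-scale reversal and strands the order in a poor local
  optimum.  Orientation puts the end with the smaller code first
  (anchoring to a prior consensus map is not available here).
* Rescue: allelically skewed loci excluded by the minor/major ≤ 0.2
  filter are re-admitted into any group whose largest internal gap
  exceeds 20 cM when they link at r̂ ≤ `r_max`; the group is then
  re-binned and re-ordered, and the gap before/after reported.

## Curation conventions

* A 3-marker window is het-indicative when its middle call differs
  from two agreeing flanks (A-B-A / B-A-B — an apparent double
  crossover) or when ≥ 2 calls are missing.  A single transition
  (A-A-B) is an ordinary crossover junction and must *not* count;
  flagging it would mask every genuine recombination event.  Chains of
  ≥ `cluster_min` (default 2) overlapping indicative windows become
  regions; masking sets all calls inside a region to missing.  An
  alternative per-region missing-rate z-score was considered and
  rejected as needing a noise model the data does not provide.
* Curation operates on all mapped loci expanded in genetic order (bin
  members at their representative's position, code order within a bin),
  not on representatives alone: a "single locus differing from its
  flanks" is a locus-level notion, and the expansion gives the masking
  rules the density they assume.
* Double-recombinant masking removes singleton calls that disagree with
  both agreeing nearest non-missing flanks, iterated to a fixpoint,
  but only when the flanking loci lie within `max_span_cm` (default
  2 cM) of each other.  The rule's premise is that a genuine double
  crossover inside the flanked interval is vanishingly rare; that holds
  unconditionally at ~0.4-cM bin density but not on sparser maps, where
  under the no-interference gamete model single-locus blocks spanning
  several cM are real recombination (verified against simulation
  truth: most masked singletons on the sparse demo map were correct
  calls).  At high density every singleton falls below the guard, so
  the original behaviour is recovered; `max_span_cm=None` disables the
  guard.  The trade-off: isolated genotyping errors whose flanks are
  far apart are indistinguishable from genuine tight doubles and are
  *not* masked at sparse density — replicate-consistent calling is the
  primary error defence, and curation a safety net.
* Masking only ever converts calls to missing; allele identity is never
  flipped.  After each stage, order and distances are recalculated
  within the existing groups (membership, bins and representatives are
  kept fixed — re-binning on masked data would churn representatives
  and make the staged lengths incommensurable).
* Stage lengths are not mathematically monotone: masking shrinks r̂
  numerators but also denominators, so an error-free map can lengthen
  by a fraction of a percent after masking.  Tests assert monotonicity
  on the demo pipeline, where artifacts dominate, and 2% stability on
  error-free matrices.

## Statistics

* Distortion: χ² against 1:1 on A/B counts only (the caller emits no
  heterozygote calls), 1 df, no continuity correction (n = 213 is
  large), raw P at 0.05/0.01 tiers with a Bonferroni option off by
  default.  Type-I error is calibrated by simulation to 0.03–0.07 at
  α = 0.05.
* Interval clustering: locus counts per 5-cM interval vs Poisson(µ),
  with tail categories pooled (and the head category, if needed) so
  every expected frequency is ≥ 1 — the pooling rule is ours — and
  degrees of freedom reduced by one for the estimated mean.
* Crossovers are counted as call transitions per RIL over markers
  nearest each 5-cM grid point (ties: least missing, then code).
* Concordance between two call matrices compares cells non-missing in
  both, matched by unigene and RIL id.
* Simulation-truth comparisons exclude cells where the truth is
  heterozygous: a biallelic A/B caller cannot represent them (they are
  ~1.6% of cells and are reported separately), so concordance measures
  calling accuracy, not het handling.

## Export

Quasi-genome spacers are `round(cM gap × bp_per_cm)` with
`bp_per_cm = 1,730,000` — the published constant, kept verbatim even
though 1585 cM × 1.73 Mb slightly exceeds the 2.7-Gb genome it was
derived from — and a 100-N floor between co-located markers.
Within-bin order is deterministic by code (the original display
ordered bin members randomly; determinism wins here).  Placeholder
locus sequences are 1 kb of seeded pseudo-random bases, since the
actual transcript sequences are not part of this package's scope.  For
a unigene split into two consensus-haplotype loci, both positions are
displayed only on different groups or > 5 cM apart, else only the 5′
half.

## Problem sizes

The validation suite runs the demo configuration (40 RILs × 2
chromosomes × 300 unigenes ≈ 57,000 probes × 88 chips), a 50-RIL
two-chromosome truth-matrix fixture, a 2000-line single-chromosome
pedigree for the heterozygosity closed form, a 200-line nine-chromosome
pedigree for crossover counts, and 100–1000-replicate calibrations of
the statistical tests; the full suite completes in well under a minute
and the acceptance script in under a minute.  These sizes give
Monte-Carlo error comfortably inside every asserted tolerance; scaling
the simulator up changes runtimes, not logic.

## Known limitations

* The weight curve, SPP filter values, split-evidence threshold,
  grouping thresholds and double-recombinant span guard are reasoned
  defaults, not fitted to any real chip data.
* Single-linkage grouping can split a chromosome at a coverage gap in
  sparse simulations (the fragments remain chromosome-pure); anchor
  loci can relabel and merge such fragments when a prior map exists.
* Ordering is a local-search heuristic; on dense, low-signal regions
  the order of very tightly linked markers is not identifiable from 40
  RILs, and only rank correlation with truth — not exact order — is
  asserted.
* Map-length recovery at demo scale has irreducible sampling variance
  of several percent (recombinant fractions estimated from 40 lines);
  seed-to-seed spread of the curated length is roughly ±8%.
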