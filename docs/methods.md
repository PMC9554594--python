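# Methods

## Scope and data model

The package analyses four kinds of measurement: per-nodule positions along
root axes (mm from the root–shoot junction, i.e. the proximal extremity),
nucleotide sequences of a replicon, tables of ortholog search hits, and
centroided negative-mode ion lists.  All external text formats are plain
CSV/TSV/FASTA/BED; genomic coordinates are 1-based inclusive in text I/O and
0-based half-open in BED, matching the conventions of the respective
ecosystems.

## Jenks natural-breaks windowing

Given pooled 1D positions and *k* classes, the natural-breaks criterion
minimises SDCM, the sum of squared deviations of each value from its class
mean, over all contiguous partitions of the sorted data.  The fit statistic
is GVF = (SDAM − SDCM)/SDAM with SDAM the total squared deviation from the
grand mean; GVF = 1 is a perfect classification, and we define GVF = 1 at
SDAM = 0 (all values identical).  Nodulation windows are read from the class
limits as [class minimum, class maximum].

Two solvers are provided:

* `jenks_exact` — Fisher-style dynamic programming over the sorted order,
  O(k·n²) with prefix sums, globally optimal and deterministic.  Ties in
  optimal cost are broken toward earlier split points.  It is the reference
  and the default for n ≤ 5,000.
* `jenks_iterative` — a budgeted local search for the classical
  "iterations" setting: random contiguous initialisations (the first is a
  deterministic equal-count split) followed by moves that only ever decrease
  SDCM: (i) relocating one break to its best position between its
  neighbours, (ii) jointly relocating two adjacent breaks, and (iii)
  ejecting a break (merging its two classes) and re-inserting it at the best
  position inside any class.  Each accepted move draws on a total budget of
  25,000; restarts continue until the budget is exhausted (capped at 250
  restarts).  The tiered neighbourhood escapes the single-move local optima
  that plain boundary nudging stalls in, and on inputs up to n = 200 the
  search empirically always reaches the exact optimum (asserted in the
  tests); by construction its GVF can never exceed the exact solver's.

For uniform data the optimal k-class quantisation has within-class variance
1/k² of the total, so GVF → 1 − 1/k² (0.99 for k = 10); the suite asserts
this within ±0.005 at n = 5,000.  The 500-value uniform control on 0–250 mm
therefore sits near 99% GVF — above the 98% working bound — while producing
ten near-equal windows: a high GVF alone does not demonstrate windowed
nodulation, which is why window spans and clustered fractions are reported
alongside.

Binning conventions: spacing and position histograms use left-closed
right-open bins starting at 0 (a value on an edge belongs to the upper bin);
ties at Jenks class boundaries assign the value to the lower class.  The
clustered fraction defaults to the gap basis (share of consecutive same-root
gaps under 3 mm), with a nodule basis (share of nodules whose nearest
same-root neighbour is closer than the threshold) available; both are
reported by the pipeline since the two operationalisations differ slightly.
An empty denominator raises an error rather than returning NaN.

## Synthetic nodulation generator

Real nodulation data show discrete windows that widen toward the root apex
and front-loaded density.  The generator reproduces this with the simplest
adequate process: per root, window counts are Poisson with an equal share of
`mean_nodules_per_root` per window (density therefore falls as windows
widen), and within-window positions are normal around the window centre
(default SD 1.5 mm), truncated to the window.  The layout places the first
window (default 10 mm) at the junction; window i+1 is longer by a
multiplicative factor (default 1.1) and is preceded by a gap of
`gap_ratio` × its own length (default 0.5), leaving bare root at the apex.
The uniform pattern draws Poisson counts and i.i.d. uniform positions.  The
default study simulates 15 plants per condition on 250 mm roots, with a
wild-type rate of 10 nodules/root and a regulator-mutant rate of 30
(a tripling); ground-truth window intervals are stored on the generated set
so recovery can be asserted (≥ 8/10 centres within ±3 mm at ~450 pooled
nodules).

What the generator does not emulate: root-to-root length variation, nodule
size–position coupling, measurement error in positions, and any
autoregulation-of-nodulation feedback between nodule number and placement.
Passing tests therefore demonstrate that the estimators recover the stated
generative structure, not that real roots follow it.

## Replicon simulation and the GC rank test

The simulated replicon defaults to 595,108 bp at GC 0.592 with a 4,500 bp
island at GC 0.518 (a deficit of 0.074).  Bases are drawn with an exact G+C
count per segment and shuffled uniformly: exact-count composition pins every
segment's realised GC to its nominal value for every seed (a pure i.i.d.
draw would miss the island's ±0.01 contract in roughly a sixth of seeds),
while the shuffle leaves no positional or dinucleotide structure.  The
sequence is exchangeable, so the rank test stays calibrated.

The rank test tiles windows of exactly the target's length across the
replicon (step 0.4 kb, reused from the profiling scan since rank quantiles
are insensitive at this density), computes the target's GC separately, and
reports rank = 1 + #(windows below) + ½·#(ties) and quantile =
rank/(n_windows + 1).  Windows overlapping the target are excluded by
default ("rest of the replicon" semantics); a flag includes them, and the
whole-sequence mean GC is always reported so either deficit definition can
be formed.  Fewer than 20 null windows raises an error.  Calibration is
asserted by a Kolmogorov–Smirnov test of quantile uniformity over 200
homogeneous-replicon seeds.

## Ortholog clusters and species summaries

Hit similarity is coverage × identity, both normalised to 1; under the
customary search thresholds (coverage ≥ 0.5, identity ≥ 0.3) it spans
0.15–1.0.  Cluster assignment sorts one strain's hits per contig by start
coordinate and opens a new cluster when the gap (end of the previous hit to
the start of the next, floored at 0 for overlaps; strand ignored) exceeds
600 kb; clusters lacking iaaM or iaaH are discarded.  The cluster score is
(#distinct query genes hit) + (mean similarity of the best hit per query) —
a transparent stand-in for search-tool cluster scores, comparable only
within this package.  Best-hit selection prefers the most similar in-cluster
hit and falls back to the global maximum, with deterministic tie-breaks
(higher identity, then lexicographically smaller subject accession).
Species summaries drop unassigned ("sp.") species, contaminated entries,
non-assemblies and taxonomy-check failures, and order by maximum cluster
score with species name as the final key (a total order).  Representative
genomes are chosen lexicographically: representative flag, taxonomy check,
completeness level, fewer contigs, accession.  Alignment concatenation keeps
taxon order from the first alignment, uses the taxon intersection unless
strict, and emits a `MODEL, name = start-end` partition block.

## Ion annotation and group statistics

Monoisotopic masses are summed from an in-package table covering C, H, N, O,
S and P (unknown elements are rejected); the test suite cross-checks the
table against an independent mass library to 1e-5 Da.  The [M−H]⁻ m/z
subtracts the proton mass (1.00727646 Da), retaining the electron on the
anion — the physically correct convention for deprotonation.  An ion is
annotated when |observed − expected| ≤ 0.001 Da; among multiple candidates
the smallest |Δ| wins, with deltas equal within 1e-5 Da broken by compound
name.  Raw ion counts are compared without normalisation.

The ANOVA F and p are computed from the classical sum-of-squares
decomposition (p from the F survival function) so degenerate inputs have
defined answers: no between-group variance gives F = 0, p = 1; zero
within-group variance with distinct means gives p = 0.  No Welch correction
is applied (ordinary one-way ANOVA).  Tukey HSD uses the studentized range
with pooled variance (Tukey–Kramer for unequal n) via scipy.  Compact
letters follow the insert-and-absorb construction — every significant pair
splits each column containing both members, subset columns are absorbed —
which guarantees exactly that two groups share a letter iff their adjusted
p exceeds α; letters are ordered by descending group means.

The ion-table generator draws log-normal intensities with a given CV
(default 0.2, n = 6 per group) around per-group means, jitters true m/z by
at most ±0.0003 Da, and places decoys at least 0.002 Da (twice the matching
tolerance) from every true mass, so annotation sensitivity and specificity
are exactly testable.  Configuring jitter above the intended tolerance warns
rather than fails — the resulting degraded match rate is then by design.

## Pipeline determinism and problem sizes

The pipeline fans a single global seed out to stages via
`numpy.random.SeedSequence(seed).spawn`, one child per stage in a fixed
order, so stages are independently reproducible; reports are JSON with
sorted keys and no timestamps (identical config + seed ⇒ byte-identical
report), and the manifest records stage seeds and SHA-256 hashes of every
artifact.  Default problem sizes are the study's own: 15 plants per
condition, a 500-value control, the full 595 kb replicon, 200-seed
calibration loops and 10,000 null simulations for ANOVA calibration; these
run comfortably on a single CPU.

## Known limitations

* The iterative Jenks solver is a randomized local search; its equality
  with the exact solver on n ≤ 200 is an empirical property asserted by
  tests, not a theorem.  The exact solver should be preferred whenever
  n ≤ 5,000.
* The cluster score is not any external tool's score; published score
  ranges cannot be compared against it.
* Real replicon sequences have compositional structure (codon bias, repeat
  content) the exchangeable simulation lacks; on real data the rank test's
  null is correspondingly conservative or anticonservative depending on
  autocorrelation.
* Annotation considers only the [M−H]⁻ adduct and resolves each ion to at
  most one compound; isomers at the same formula are indistinguishable by
  accurate mass alone.
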