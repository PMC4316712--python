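# Methods

## Problem and overall design

Somatic copy-number surveys of chromosome 21 across tumor types must combine
cohorts profiled on very different aCGH platforms: BAC arrays with ~100 kb
probe spacing on chr21 and oligo arrays with ~30–55 kb spacing. `mdr21`
implements a harmonization-first design: every sample is segmented and called
on its own platform, and only the discrete calls are projected onto one fixed
grid of anchor positions, where per-cohort deletion/amplification frequencies
and recurrent deletion regions are computed. Candidate tumor-suppressor
features are then those inside a recurrent deletion region that are also
downregulated in at least two independent expression datasets of their class
(genes vs. miRNAs, never pooled).

## Segmentation (CBS)

For one sample's ordered log2 ratios `x_1..x_n` the change statistic of an
arc (window) `x[i:j]` against its complement is the standardized mean
difference

    T(i,j) = |mean(arc) − mean(rest)| / (σ̂ · sqrt(1/k + 1/(n−k))),  k = j−i,

with σ̂ the whole-series sample standard deviation (ddof=1). σ̂ is constant
across arcs, so it affects neither the argmax nor the permutation test
(permutation leaves the multiset, hence σ̂, unchanged); it only sets the
scale of the reported T. On the circularized series every arc is a linear
window or the complement of one and T is complement-symmetric, so the search
runs over linear windows only. Admissible windows satisfy
`min_width ≤ k ≤ n − min_width` and leave each flank empty or ≥ `min_width`
probes, which keeps every emitted segment at least `min_width` probes unless
the whole series is shorter. Ties are broken toward the smallest window
start, then the smallest end.

Significance uses a seeded permutation test,
`p = (1 + #{T* ≥ T_obs}) / (1 + P)` with `P = n_permutations`. The recursion
accepts the maximal-T split when `p ≤ alpha` and recurses into the resulting
two or three parts. Defaults: `alpha = 0.01`, `P = 1000`, `min_width = 3` —
common CBS practice; no undo-splits pruning is applied (a config hook is the
natural place to add it). Each recursion node draws its permutation stream
from a seed derived from (root seed, node bounds), so sibling decisions
cannot perturb one another and lowering alpha can only coarsen the result.

Two engineering choices worth knowing:

* The permutation loop stops early once the exceedance count already proves
  `p > alpha`; the accept/reject decision is identical to evaluating all P
  permutations with the same seed. The public `permutation_pvalue` always
  evaluates all P and returns the exact p.
* The per-permutation max-T search is O(n²); it dispatches to a compiled
  (numba) kernel when available, with a pure-numpy reference path otherwise.
  Both paths are deterministic.

Missing probe values are dropped per sample before segmentation; segment bp
bounds snap to the retained probes (start = first probe position, end = last
probe position + 1, half-open).

## Calling

Default caller: fixed thresholds on the segment mean, loss ≤ −0.2 <
neutral < +0.2 ≤ gain (cuts inclusive), the conventional ±0.2 log2 aCGH
rule. Three states suffice because downstream analysis consumes only loss
and gain frequencies. A cohort-level alternative fits a 3-component Gaussian
mixture over probe-count-weighted segment means by EM (neutral component
initialized at 0, flanks at data quantiles pushed past ±0.3), assigns by
maximum posterior with ties to neutral, and falls back to the threshold rule
on degenerate fits (component collapse or fewer than 3 distinct means). The
weighted EM is implemented in-package because the stock mixture fitters do
not accept per-observation weights.

## Harmonization

The anchor grid places `n_anchors` (default 5000) positions at
`floor((k+0.5)·L/n)` along a chromosome of length `L` (default 48,129,895 bp,
a config constant). An anchor takes the state of the segment containing it;
an uncovered anchor takes the nearest segment's state within `max_gap` bp
(ties to the left segment), otherwise it is missing for that sample.
`max_gap` defaults to twice the coarsest cohort's median probe spacing —
wide enough that inter-segment gaps inherit the flanking state (effectively
a midpoint split between segments), narrow enough that true probe deserts
stay missing. Frequencies at an anchor divide loss (or gain) counts by the
number of informative samples there. The cross-tumor summary is the
per-anchor **median** of cohort frequencies (not a pooled-sample frequency),
so no cohort dominates by size.

## Deletion-region detection

Per cohort, maximal runs of anchors with `del_freq ≥ f_min` (default 0.25)
are found, bridging interior dips of up to `max_gap_anchors` (default 5)
anchors and discarding runs with fewer than `min_anchors` (default 3)
qualifying anchors. Runs are unioned across cohorts and overlapping runs
merged — necessary because a region can be private to one small cohort while
others are flat there. Region bp bounds extend half an anchor spacing beyond
the flanking anchors. Per-region, per-cohort frequency is sample-level: a
sample is deleted in the region when ≥ `sample_fraction` (default 0.5) of its
informative anchors there are loss; the denominator is samples with ≥ 1
informative anchor. Detection threshold, gap bridging and the sample-level
summarization are reconstruction choices, all config-exposed; an
anchor-averaged frequency would be the natural alternative summarization.
Amplification-region detection is symmetric (`direction="amp"`) but untuned.

## Differential expression

All matrices are quantile normalized (every column receives the
cross-column rank means; ties get the mean of their rank means; missing
cells are rank-skipped by interpolation and stay missing). Gene datasets use
per-feature Welch's t (unequal variances; pooled-variance t available) with
two-sided p from the Welch–Satterthwaite approximation and
Benjamini–Hochberg FDR. miRNA datasets use a SAM analysis:
`d = (mean_t − mean_n)/(s + s0)` with the pooled standard error
`s = sqrt((1/n_t + 1/n_n)(SS_t + SS_n)/(n_t + n_n − 2))` and `s0` the median
of all `s` (the full SAM s0-optimization grid is deliberately not
reproduced). The permutation FDR at threshold `t` is the median over label
permutations of `#{|d*| ≥ t}` divided by `#{|d| ≥ t}`; a feature's q is the
minimum FDR over thresholds at or below its own |d| (which enforces
monotonicity), capped at 1. `s0` is computed once from the observed labels
and reused for permutations; designs with at most `n_perm` distinct label
assignments are enumerated exhaustively. "Downregulated" means effect < 0
and q < 0.05 throughout; the 0.05 cutoff is a reconstruction choice.

## Integration

A feature overlaps a region when their half-open intervals share ≥ 1 bp.
The candidate rule is exact and deterministic: inside ≥ 1 detected region
AND downregulated in ≥ `min_datasets` (default 2) datasets of the feature's
own class. Over-representation of a query set against GMT-supplied pathway
sets uses the upper-tail hypergeometric test with BH across sets; the
default query is the union of target sets of the candidate miRNAs
(direction-aware, mirroring the use of downregulated-miRNA targets). Target
and pathway sets are frozen input files, never fetched live.

## Synthetic study conditions

The default scenario pack emulates the four-cohort survey: breast 359, lung
78, melanoma 34, Wilms 18 samples on layouts of 500 / 500 / 900 / 1600
uniformly spaced probes (chr21-scale densities of BAC 33K/32K, 60K and
2×105K designs). Gaussian i.i.d. probe noise: 0.15 (BAC-like) and 0.25
(oligo-like) log2 units; no wave/GC artifacts are simulated. Deletions shift
carried probes by −0.8 log2 — a heterozygous loss under realistic tumor
purity; purity has no separate parameter. Three deletion regions are
planted: a ~481 kb proximal region carried by lung (0.269), breast (0.117)
and melanoma (0.617); a ~12 Mb mid-arm region in melanoma (0.5); and a
~391 kb distal region in Wilms only (0.5). Overlapping lesions are legal;
the later lesion in list order overrides the shift on the overlap.

Planted breakpoints sit on the probe-grid boundaries of the cohorts that
carry them (multiples of L/100 for the first two regions — shared boundaries
of the 500- and 900-probe layouts — and of L/1600 for the Wilms region).
This is the standard convention in segmentation benchmarks: a breakpoint
strictly inside an inter-probe gap is unrecoverable below half the gap width
by any method, so off-grid placement would measure probe spacing rather than
algorithm error. The Wilms-only region is wider than its real-data
counterpart because a ~40 kb lesion falls below one probe spacing on every
layout simulated here. Consequences for interpretation: passing recovery
tests demonstrates correct behaviour at platform-resolvable breakpoints and
i.i.d. noise; they say nothing about wave artifacts, breakpoints inside
probe gaps, or focal events below probe resolution.

Matched expression truth: four gene datasets (tumor/normal 30/10, 25/25,
15/10, 8/5) over one deterministic 200-gene annotation and four miRNA
datasets (15/15, 12/12, 10/10, 8/8) over 300 features, noise 0.3, planted
log-fold-change −1.5. Planted-down sets are arranged so that exactly three
genes and three miRNAs satisfy the candidate rule, with decoys that fail
each single condition (down in only one dataset, or down everywhere but
outside every region).

## Numerical and degenerate-input conventions

* Constant series: T = 0 at the leftmost admissible arc; permutation p = 1.
* Zero variance in both groups: t = 0, p = 1 on equal means; p = 0 with a
  `degenerate` flag otherwise. All-zero SAM `s`: s0 falls to machine-epsilon
  scale, flagged.
* Internally all coordinates are 0-based half-open; reports print 1-based
  inclusive.
* One global seed fans out to stages, cohorts and samples by stable blake2b
  hashing, so any stage is reproducible in isolation.
* Problem sizes in the test suite: oracle checks run at n ≤ 50 where
  exhaustive search is exact; recovery and specificity checks run the full
  default pack (489 samples) once and twenty lesion-free replicates.

## Known limitations

* Frequencies are per cohort; pooling several datasets of one tumor type is
  out of scope, as is probe-level cross-platform signal fusion or batch
  correction.
* No significance model for recurrence (GISTIC-style q-values); regions are
  threshold-defined.
* The caller collapses to three states; high-level amplifications and
  homozygous losses are not distinguished.
* Real-data ingestion expects the generic probe-matrix TSV contract on a
  single assembly; platform-native raw files and liftover are not handled.
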