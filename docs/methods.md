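# Methods

This note documents the models and procedures implemented in `promarch`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show about
real promoter sequences.

## The Kappa Index of Coincidence

The index of coincidence from classical cryptanalysis measures how often
two texts agree positionwise. Applied to a single DNA window `A` of length
`L`, the window is compared against each of its `N = L − 1` shifted copies;
shift `u` contributes the percentage of agreeing positions among the
`L − u` overlapping ones, and the average over shifts, rounded to two
decimals, is the window's KIC:

```
KIC(A) = round( 100/N · Σ_{u=1..N} c_u / (L − u) , 2 )
c_u = #{ i : A[i] = A[i+u] }
```

Closed-form anchors: a homopolymer agrees everywhere at every shift, so
KIC = 100.00 exactly; an i.i.d. uniform window agrees with probability 1/4
per position, so E[KIC] = 25 exactly. The statistic is invariant under the
complement relabeling A↔T, C↔G (relabeling preserves the match structure).

**Shift convention.** Published descriptions of this recipe are ambiguous
about whether the suffix at shift `u` runs to the end of the window or
stops one character short; a fully literal reading of the latter makes the
final shift compare against an empty suffix (a division by zero). We
default to the well-defined full-suffix reading (`mode="full"`), under
which the homopolymer anchor holds exactly, and expose the truncated
reading as `mode="literal"` (the empty final shift contributes nothing;
the divisor stays `N`). Both modes are covered by an independent
brute-force oracle in the test suite. Under `literal` a homopolymer scores
(N−1)/N·100 ≈ 96.55 at L = 30, which is the observable fingerprint of the
off-by-one.

**Rounding.** Per-window values are rounded to two decimals *before* any
averaging, matching what window-level software stores; for 470-window
means the difference against unrounded averaging is far below 0.01.

**A useful identity.** Summed over all shifts, the coincidences in a
window equal `Σ_b C(n_b, 2)` where `n_b` are the window's base counts —
arrangement only redistributes matches across shifts. Because shift `u` is
weighted by `1/(L−u)`, matches at long shifts count more, but in practice
the mean KIC of a promoter is governed by its window composition profile:
more concentrated composition (skew, tracts, repeats) means higher KIC.
This identity drives the generator calibration discussed below.

## Relative (C+G)%

Whole-promoter content is `CG_tot = 100·(#C+#G)/(#A+#T+#C+#G)`. Window
values are expressed relative to the promoter:
`CG_sw = CG_tot · (#C+#G)_window / (#A+#T+#C+#G)_window`, so `CG_sw` lives
in `[0, CG_tot]` and an all-C/G window returns `CG_tot` itself. For
compositionally homogeneous sequences the window mean of `CG_sw`
approaches `CG_tot²/100`.

## Sliding-window profiling

Windows of `window_size` = 30 nt advance by `step` = 1 nt; a sequence of
length `L` produces `⌊(L − window_size)/step⌋` windows starting at offsets
0, step, 2·step, … — a 500 nt promoter yields exactly 470 windows, i.e.
470 pattern lines. Offsets are zero-based internally; exported tables
report 1-based window starts.

`N` bases are accepted on input but are not countable: they are excluded
from `CG_tot`, and any window containing an `N` is skipped entirely (it
contributes no pattern line); profiles report the skipped count. A
sequence whose countable bases are zero, or shorter than
`window_size + 1`, is an error.

## Patterns and centers of weight

A pattern draws one vertical line per window at `x = CG_sw` from the
baseline to `y = KIC`. Overlap density is counted on x quantized to
`bin_width` = 0.5 percentage points (continuous x never collides exactly);
rendering maps density linearly blue→red with fixed endpoints, and the
SVG backend is salted and stripped of date metadata so identical inputs
give byte-identical files.

The center of weight is the unweighted component-wise mean of the line
coordinates — each window counts equally — which makes the y-coordinate of
the center exactly the promoter's mean KIC. A density-weighted variant
(`density_weighted=True`) is available for emphasising dense clusters; it
is not the default because the unweighted mean is the quantity whose group
averages are reported downstream.

Per-promoter summaries carry mean and median KIC (median of an even count
is the central pair's mean), `CG_tot`, the window-mean of `CG_sw`, and the
center of weight.

## Cohort statistics

Group summaries are arithmetic means and medians over per-promoter mean
KIC and `CG_tot`, with min/max extremes attributed to gene symbols.

The two-group comparison defaults to the two-sided Mann–Whitney rank test
on per-promoter mean KIC: group sizes in disease panels are small (n ≈ 15)
and the distributional shape is unknown, so a rank test is the safer
default; Welch's unequal-variance t-test is available by flag. The
asymptotic normal form without continuity correction is used so that
comparing a group against an identical copy gives p = 1.0 exactly; at
n ≈ 15 per group the normal approximation is accurate far beyond the 0.01
decision threshold used here. When both axes (mean KIC and `CG_tot`) are
tested jointly, the two p-values are Holm-adjusted and the smaller
adjusted value is reported.

## The intermediary partition

Some promoters sit *between* the two phenotype clouds on the
(`CG_tot`, mean KIC) plane. The partition rule makes that notion explicit
and reproducible; all parameters live in `PartitionRule` and serialize to
a plain dict.

1. **Core boxes.** Each group gets an interquartile box per axis. The box
   is estimated as `median ± MAD` (for symmetric data the MAD equals half
   the interquartile range, so this estimates the same box), because the
   estimate must survive contamination: if a third of a group's members
   are genuinely intermediary, a plain 75th percentile lands *on* the
   contaminants and the box swallows exactly the promoters the rule should
   flag. The plain quantile box remains available
   (`box_estimator="quantile"`). A degenerate (zero-area) box falls back
   to the group's range box with a warning.
2. **Labels.** A promoter inside both boxes is `INTERMEDIARY`; inside
   exactly one box it takes that box's core label; outside both boxes it
   is `INTERMEDIARY` only when *stranded between* the groups — its x has
   crossed at least `gap_margin` = 0.25 of the horizontal gap between the
   boxes measured from its own side, and it lies inside the convex hull
   spanned between the whisker-expanded boxes (`whisker` = 2.0 IQR per
   side, which sets the hull's vertical generosity). Otherwise it keeps
   its own core label.

The gap-margin gate is scale-free: it tolerates ordinary within-group
spread on the CG axis regardless of the gap's absolute width, where a
fixed own-box whisker either leaked clean stragglers (too narrow) or
swallowed planted intermediates (too wide). Box re-estimation after
relabeling (`refine_iterations` > 1) is available but off by default:
with the robust box it is unnecessary, and label feedback can shrink the
boxes on clean panels.

Measured on synthetic panels at defaults (100 seeds, 31 promoters, 5
planted intermediates among the 15 AT-compact-labeled): 4.7 of 5 planted
promoters recovered on average, 98% overall label accuracy. Membership in
a real intermediary phenotype additionally reflects gene-association
evidence that no geometric rule can see; the rule formalizes only the
architectural component.

## The synthetic promoter generator

The generator exists so that every pipeline stage is testable offline. It
emulates four archetypes: `at_compact` (AT-rich with short poly(dA)/
poly(dT) tracts in tandem), `cg_rich` (CG-rich, strand-skewed, with short
poly(dC)/poly(dG) tracts and CG-dinucleotide repeat stretches),
`intermediate` (between the two on both axes) and `uniform` (i.i.d.
null).

Backgrounds come from a first-order chain whose stationary composition is
pinned to the requested values by a 4-state eigenvector fixed-point
calibration:
`at_fraction` sets A+T, `base_skew` the within-pair A:T and G:C imbalance,
and `cpg_boost` multiplies the C→G transition. Homopolymer tract events
(Poisson with `tract_density` per 100 nt; 1–3 tandem blocks of 3–8 nt,
alternating bases from `tract_alphabet`) and CG-dinucleotide repeat
stretches (`str_density`, lengths 8–14) are written over the background,
preserving length. Panels derive one child seed per promoter from a single
master seed via `numpy.random.SeedSequence`; ground-truth archetypes
travel in each record's `source` tag.

**Calibration and its limits.** By the coincidence identity above, a
near-i.i.d. sequence has mean KIC ≈ 100·Σ_b p_b², so composition alone
pins the baseline: ≈ 30 at 73% AT, 25 at uniform. Real AT-rich promoter
cohorts have been reported with mean KIC well below that baseline, which
requires long-range anti-coincident arrangement that no stationary
short-memory process can produce — tract mosaics do not help, because
same-base tracts recur within a 30 nt window at long, heavily weighted
shifts and *raise* KIC. The archetype defaults therefore reproduce the
cohort-level *contrasts* rather than absolute published levels: the
AT-compact group sits near KIC 31 / CG 26, the CG-rich group near KIC 35 /
CG 55 (a four-point KIC gap and a ~30-point CG gap, ordering preserved in
100/100 seeded replicates; rank-test p < 0.01 in 100/100), and the
intermediate archetype lands between the clouds on both axes. The `cg_rich`
skew (`base_skew` = 0.72) is a synthetic device for raising single-base
concentration, not a claim about real promoter strand asymmetry; CpG
density beyond composition is carried by the boost and the CG-repeat
stretches (verified against i.i.d. sequences regenerated at the same
overall CG%). Passing tests on these panels demonstrate that the pipeline
recovers group structure of the stated effect size — not that real
promoter cohorts have these parameters.

Problem sizes used by the test suite and the acceptance script — 100
replicate panels of 31 promoters for contrast and partition experiments,
10,000 windows for the uniform-mean check, 200 random sequences for
oracle equivalence — are chosen so the full run completes in well under a
minute while keeping Monte-Carlo error far from every decision boundary.

## Numerical and interface choices

- Window KIC and profile computation are vectorized per shift with prefix
  sums (O(L·window) per promoter) and verified per-window against a naive
  brute-force transcription in both shift modes.
- All percent quantities are plain floats; only KIC is rounded (two
  decimals, as defined). Exported TSVs format floats to four decimals with
  a fixed column order, making reruns byte-identical.
- Phenotype labels are a closed set (`T1D`, `T2D`, `IDM`, `BACKGROUND`,
  `UNLABELED`); panel configs assign at most one phenotype per id, and
  panels reject duplicate ids.
- The CLI writes a JSON manifest (tool version, command, full config,
  inputs, outputs) with every run; logs go to stderr and results to files,
  so commands compose in pipelines.

## Known limitations

- The generator does not model transcription-factor binding sites,
  TATA/Inr elements, nucleosome positioning signals, or real CpG-island
  structure; see the calibration note above for what that implies about
  absolute KIC levels.
- The intermediary rule is one defensible formalization of "between the
  clouds"; real phenotype assignment also uses evidence outside the
  (CG, KIC) plane.
- KIC is undefined on windows containing `N`; promoters dominated by `N`
  runs lose most of their windows and their summaries thin out
  accordingly.
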