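# promarch

Promoter architecture profiling with the **Kappa Index of Coincidence
(KIC)** and **relative (C+G)%** sliding-window patterns.

`promarch` is a small toolkit for comparing the compositional architecture
of gene promoters — for example the 500 bp upstream regions of genes
associated with type 1 vs type 2 diabetes, where AT-rich low-coincidence
promoters separate from CG-rich, CpG-dense, high-coincidence promoters. It
turns each promoter sequence into an *image-based pattern* (one vertical
line per sliding window), condenses every pattern to a *center of weight*,
aggregates per-promoter statistics into phenotype-group summaries, tests
two groups for architectural differences, and flags promoters whose
architecture is *intermediary* between two phenotype clouds. A synthetic
promoter generator with controlled archetypes makes the whole pipeline
testable without any database downloads.

## The statistics

**Kappa Index of Coincidence.** For a window `A` of length `L` (default 30
nt) with `N = L − 1` shifts, the window is compared positionwise against
every shifted copy of itself:

```
KIC(A) = 100/N · Σ_{u=1..N}  #{ i : A[i] = A[i+u] } / (L − u)
```

rounded to two decimals. A homopolymer scores exactly 100; an i.i.d.
uniform random window scores ≈ 25 (match probability 1/4 per position).
Homopolymer tracts, simple sequence repeats and skewed base composition
push the value up, which makes KIC a compact scalar for "how organised" a
stretch of DNA is.

**Relative (C+G)%.** The promoter total is `CG_tot = 100·(#C+#G)/(#A+#T+#C+#G)`;
each window's value is re-expressed on the promoter's own scale,
`CG_sw = CG_tot · (#C+#G in window)/(countable bases in window)`, so window
values live in `[0, CG_tot]`.

**Patterns and centers of weight.** Sliding a 30 nt window with step 1
over a 500 nt promoter yields 470 `(CG_sw, KIC)` pairs; each pair is drawn
as a vertical line at `x = CG_sw` up to `y = KIC`, coloured blue→red by how
many lines share the same x bin. The unweighted mean of the line
coordinates is the pattern's center of weight — one point per promoter,
used for genome-wide distribution plots and group comparison.

**Cohort analysis.** Phenotype groups are summarised by means/medians of
per-promoter mean KIC and total CG% (extremes carry gene attribution), and
compared with a two-sided Mann–Whitney rank test (Welch's t available).
The intermediary partition puts a robust interquartile box around each
group on the (CG%, KIC) plane and labels promoters stranded in the gap
between the boxes as `INTERMEDIARY`.

## Worked example

Generate a 31-promoter synthetic panel (15 AT-compact "T1D-like", 16
CG-rich "T2D-like") and run the full pipeline:

```
$ promarch simulate -o demo --seed 7
simulate: 31 promoters -> demo
$ promarch analyze demo/panel.fasta --panel demo/panel_config.tsv -o demo/results
analyze: wrote 4 tables to demo/results
$ cat demo/results/group_summaries.tsv
phenotype  n   mean_kic  median_kic  mean_cg  median_cg  kic_min  ...
T1D        15  31.3713   31.2879     25.1067  25.2000    29.7811  ...
T2D        16  34.5909   34.3965     56.7750  56.2000    32.2877  ...
$ cat demo/results/comparison.tsv
group_a  group_b  axis      statistic_name  statistic  p_value
T1D      T2D      mean_kic  mannwhitney_u   6.0000     0.0000
```

The AT-compact group sits low on both axes (mean KIC ≈ 31.4, CG ≈ 25), the
CG-rich group high (≈ 34.6, ≈ 57), and the rank test on per-promoter mean
KIC is overwhelmingly significant (U = 6, p < 10⁻⁴). `partition.tsv` labels
every promoter `CORE_T1D` / `CORE_T2D` / `INTERMEDIARY` (none intermediary
in this clean panel), and `manifest.json` records the exact configuration
so that re-running reproduces every table byte for byte.

Single values behave the way the closed forms promise:

```python
>>> from promarch import kappa_ic, cg_percent_total
>>> kappa_ic("A" * 30)
100.0
>>> kappa_ic("ACGTACGTACGTACGTACGTACGTACGTAC")   # period-4 repeat
24.14
>>> cg_percent_total("ATGC")
50.0
```

Rendering one promoter's pattern (`promarch pattern demo/panel.fasta
T1D_01 -o out`) writes an SVG with the 470 coloured lines and the black
center-of-weight circle, plus the line table as TSV.

## Layout

- `src/promarch/sequence_io.py` — FASTA + panel-config reading/writing, record validation
- `src/promarch/kic.py` — KIC and (C+G)% numerics, sliding-window profiling
- `src/promarch/patterns.py` — pattern construction, summaries, rendering
- `src/promarch/cohorts.py` — group statistics, rank test, intermediary partition, background distributions
- `src/promarch/simulate.py` — archetype-based synthetic promoter generator
- `src/promarch/cli.py` — `promarch` command-line interface
- `docs/methods.md` — models, parameter choices, calibration notes, limitations
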