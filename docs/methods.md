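# Methods

## Model and assumptions

The pipeline estimates a network-wide monotonic trend in a water-quality
parameter from an unbalanced panel of sites. Its core assumption is that
each site's measurements fluctuate around a site-specific level that is
stable except for a possible common linear drift. Medians are used at every
aggregation step because chlorophyll and nutrient data are right-skewed
with episodic extremes (algal blooms); the median of a site-year is robust
to both outliers and uneven within-year sampling effort.

The anomaly construction removes the site level before any cross-site
aggregation. This is what makes the estimator robust to staggered
enrollment: a site contributes only its *deviations* from its own long-term
median, so sites with systematically high or low levels entering or leaving
the network shift nothing. The annual medians of a site are treated as
independent across years; no autocorrelation correction is applied to the
OLS fit (a known limitation, below).

## Eligibility criteria

A site enters the analysis for a parameter when:

1. samples fall in the study window (default 1993–2016);
2. samples fall in May–October;
3. a qualifying year covers all three seasonal bins (May–Jun, Jul–Aug,
   Sep–Oct) with ≥ 1 sampling event each;
4. both halves of the record (split windows, default 1993–2004 and
   2005–2016; the `lagos_ne` preset uses 1993–2002 / 2003–2013) contain
   ≥ 1 event;
5. depth ≤ 2 m (skipped when depth is unrecorded, as in regional databases
   whose samples are surface/epilimnion by construction);

and the site has ≥ 10 qualifying years. A sampling *event* is a unique
(site, date) with ≥ 1 retained measurement of the parameter.

**Coverage mode.** Whether criterion 3 qualifies each counted year
("strict") or merely the site ("site") is genuinely ambiguous in
field practice. The default is strict — a year counts toward the 10-year
minimum only if all three bins are covered for that parameter, and only
such years flow downstream — because the criterion is phrased per year and
strictness prevents sparsely sampled years from diluting annual medians.
"site" mode is provided for sensitivity analysis.

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| molar TN:TP factor | 30.974/14.007 ≈ 2.2113 | — | atomic weight P over N at full precision; 2.21 is a display rounding, and rounding would compound over thousands of ratios |
| trophic boundaries | 3.5 / 9 / 24 | µg/L chl | 3.5 is the oligo–mesotrophic limit; 9 follows from the meso→eutrophic century rate of 0.055 µg/L/yr ((9−3.5)/100); 24 is a conventional hypereutrophic boundary; boundary values belong to the upper class (left-closed intervals) |
| α (criterion 1) | 0.10 | — | the unique conventional cut that counts p = 0.065 as support and p = 0.14 as insufficient, matching practitioner judgment on these data |
| pattern fraction | 2/3 | — | the share of nonzero-anomaly years that must fall on the expected side of the record's midpoint, in a consistent direction; years exactly at the midpoint go to the early half; exact-zero anomalies are excluded from the counts |
| magnitude thresholds | 0.02, 0.035, 3.5, 0.1, 0.26 | units/yr | century-scale meaningful changes divided by 100 (2 °C policy limit; trophic-state limits 3.5/350/10 µg/L; N-limited vs P-limited median molar TN:TP gap 61−35 = 26); comparison is ≥, so a slope exactly at threshold counts |
| min sites/year | 3 | — | a cross-site median of < 3 sites is not a summary; years at exactly 3 are retained but flagged (`low_n_flag`) |
| reference basis | median of annual medians | — | step 2 operates on step 1's output, keeping the reference insensitive to within-year sampling intensity; a "raw" basis (median of all reference-period measurements) is available for sensitivity |
| reference period | full window | — | the whole record is the baseline; configurable sub-window supported |
| quantile convention | linear interpolation | — | numpy default, fixed so summary tables are reproducible |
| below-detection rows | retained as reported | — | default keeps all data; `detection_limit_sensitivity` reruns the pipeline without censored rows and reports whether classifications change |

All even-count medians use the midpoint of the two central order
statistics, everywhere.

Degenerate inputs: a constant yearly-anomaly series is the null by
construction and is reported as slope 0, p 1, r² 0 (OLS is undefined there
because the residual variance is 0); constant *years* are a hard error;
fewer than 3 retained years cannot be fit, fewer than 4 cannot be
pattern-assessed.

## Synthetic data: what it emulates, what it does not

`simulate_program` generates a monitoring program under the stated study
world: 40 sites, 1993–2016, May–October visits per seasonal bin (weekly
temperature → 8/bin, bi-weekly chlorophyll → 4/bin, nutrients three times
per season → 1/bin), staggered enrollment/dropout, persistent site levels,
and optional common linear trends. Parameters sharing a visit count share
sampling dates — one grab sample analyzed for several parameters — so
event-level TN/TP pairing behaves as in real programs.

Noise is Gaussian for temperature (sd 1.9 °C, the published sample sd) and
multiplicative lognormal for concentrations, with log-sds chosen once from
published mean/median ratios (mean/median = e^{σ²/2}): chl 1.23, TN 0.68,
TP 0.88. Site levels are Gaussian for temperature (mean 23 °C, sd 1 °C) and
lognormal factors (log-sd 0.5) around the published medians (3.5 / 460 /
15 µg/L) for concentrations. Injected trends are added on the original
scale after the noise so the injected slope is the estimand. Censoring
replaces values below a detection limit by the limit and flags them.

The generator does **not** emulate temporal autocorrelation within sites,
spatially correlated site effects, method changes over time, or
season-within-year structure beyond the visit schedule. A green test on
synthetic data therefore establishes correctness of the aggregation
arithmetic and the estimator's behavior under enrollment bias and skewed
noise — not robustness to serially correlated errors.

The three-lake scenario (`fig9_scenario`) encodes the qualitative bias
demonstration: lake levels 5 / 10 / 15 with sd 1, the low lake observed
only in 1993–2004, the high lake only in 2005–2016, no within-site trend.
Every year holds exactly two sites, so its estimator harness aggregates
with `min_sites_per_year=2`. Its acceptance property is Monte-Carlo (the
naive raw-mean estimator rejects the true null in ≥ 90% of replicates, the
anomaly estimator in ≤ 10%), not a match to any particular simulated slope,
which is seed-dependent.

## Design choices that were genuinely open

- **Event-level TN/TP pairing** (same site, date, depth) for the molar
  ratio: the only interpretation that never mixes dates; replicates within
  an event are collapsed to medians first. Site-year pairing is available
  via the pairing argument.
- **Direction symbols** `-`/`--` for declines are implemented symmetrically
  even though only positive and null trends arise in the motivating data.
- **Unweighted OLS**: each retained year is one point regardless of its
  site count. Low-site years are flagged and handled by the leave-year-out
  sensitivity check rather than by weighting, which would change the
  estimand.
- **Eligibility does not drop low-site years**; that rule belongs to the
  yearly aggregation stage, where the affected years are known.

## Known limitations

- OLS p-values assume independent yearly anomalies; serial correlation
  would make them anti-conservative.
- The pattern criterion is a counting rule on signs; it ignores anomaly
  magnitudes and is insensitive to non-monotone change.
- Trophic-state boundaries above the oligo–mesotrophic limit are
  convention-dependent and configurable; distribution tables depend on them.
- The simulator's lognormal noise model cannot produce the bounded,
  quantized values real laboratory reporting creates (detection-limit
  heaping aside).
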