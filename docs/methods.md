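# Methods

This note documents the models, conventions, and design choices behind
`heatscreen`, in the order the pipeline runs them.

## Vulnerability harmonization

Three tract-level indices are placed on a common [0, 100] percentile scale.
CES ships percentiles and is used as-is; SVI ships an overall ranking on
[0, 1] and is multiplied by 100 in the reader; HHAI ships raw scores, which
are converted with average-rank percentiles, `100 · r̄ᵢ / n`, where `r̄ᵢ` is
the mean rank of tied observations.  This convention makes the maximum
exactly 100 and is idempotent; min-rank or `(r − ½)/n` conventions differ
only in tie handling and can be substituted by transforming scores before
calling `to_percentile_ranks`.  Because no public documentation states
which tie convention the original HHAI conversion used, the choice is
documented here rather than claimed as a reproduction.

Tracts missing any index value are removed before all comparisons (score
developers assign NA to zero-population or data-poor tracts; keeping them
would bias agreement statistics toward whichever indices report them).
Empty cells and a configurable sentinel (default −999, a common SVI
dialect) both count as missing.

A tract is *vulnerable* under an index when its percentile is **at or
above** the threshold (default 75; the boundary is inclusive).  The
compound score is the count of flags; agreement is reported as the 8-cell
Venn partition, whose counts always sum to the filtered tract count.
Region assignment takes the region holding the tract's largest area
fraction, with a deterministic lexicographic tie-break (logged), since
"greater area" alone does not resolve exact ties.  Density deciles use
linear-interpolation quantile edges on raw densities; a log transform
would give identical bins and is used only for display.

## Exposure metrics

All daily series are restricted to April 1 – October 31 (214 days/year);
the season sits inside one calendar year, so no season spans a year
boundary.

**Heat-wave thresholds** are the 95th percentiles (linear-interpolation
quantile) of the pooled seasonal daily `Tmax` and `Tmin` over 1950–1999.
Pooling covers all historical years and all models present in the series
for the tract; computing per-model thresholds and averaging would shrink
extremes and is not done.  A minimum of 100 seasonal days (configurable)
guards against degenerate estimates.

**Event counting.**  An exceedance day is *strictly* above threshold
("surpass"); a `strict=False` switch provides the ≥ convention.  Each
maximal run of ≥ 2 consecutive exceedance days is one event regardless of
length — the standard epidemiological duration-window reading, not
⌊length/2⌋ events.  Runs break at data gaps of more than one day, so they
never span the off-season.  Annualized rates are period totals divided by
the period's year count (equivalently the mean of per-year counts, since
runs cannot cross years).  Multi-model summaries are arithmetic means over
models per period, and the exposure delta is projected minus current mean.
Current-period rates come from modeled series, not observations, so both
periods share the models' statistical behavior.

**Heat index.**  Temperatures are carried in °C and converted to °F only
inside the heat-index routine, which implements the NWS algorithm: the
simple average `0.5·(T + 61 + (T−68)·1.2 + 0.094·RH)` when it is below
80 °F, otherwise the Rothfusz regression with the low-humidity adjustment
(RH < 13 %, 80 ≤ T ≤ 112) and high-humidity adjustment (RH > 85 %,
80 ≤ T ≤ 87).  The algorithm has genuine steps at the branch handover
(≤ ~1.9 °F) and at the adjustment-region edges (≤ ~2.1 °F); the tests bound
them rather than pretend continuity.  A day counts as a heat-index day
when HI ≥ 91 °F (inclusive), one statewide threshold.  Each day pairs
`Tmax` with the same day's *minimum* relative humidity — the most
conservative daytime pairing, chosen and documented here because the
source datasets provide daily minimum RH; days missing humidity are
skipped with a logged count.

## Risk overlay

Exposure deltas are summarized in fixed-width percentile bins (default
2.5, i.e. 40 bins tiling [0, 100], top edge inclusive) with the arithmetic
mean per bin (median available).  Equal-width bins on percentile ranks put
~n/40 tracts in each bin, which is why "about 200 per bin" holds at n ≈
8000.  The joint risk flag is an explicit operationalization — vulnerable
under the chosen criterion AND exposure delta at or above the statewide
upper quartile (inclusive at the boundary) — provided as a convenience,
not a claim about any agency's definition.

## Intervention analysis

Raw project rows collapse to one record per (project id, tract): earliest
year (used for the pre/post AB 1550 split — a project spanning 2016–2017
is "pre"), text concatenated in year order with duplicates dropped, award
amounts carried but never aggregated.  Keyword matching is case-insensitive
plain substring over whitespace-normalized text; a word-boundary mode is
available but off by default, since phrase lists are multi-word and
substring matching is the simpler, more inclusive convention.  A category
applies iff ≥ 1 include phrase matches any of the three text fields and no
exclude phrase matches any; exclusion always dominates, and an intervention
may receive several categories (cross-category duplicates count once per
category in per-category tables and once in overall totals).

Allocation tables report percentages over compound scores 0–3 (summing to
100 where populated) with the statewide share of score-≥ 1 tracts as the
reference line; per-index shares with the CES∖HHAI vs HHAI∖CES intervention
ratio (reported as NaN when the denominator is empty); and pre
(2015–2016) vs post (2017–2019) group shares with their percentage-point
changes, where a tract both CES-vulnerable and low-income belongs to the
disadvantaged group only.

## Synthetic data

The generators emulate the *structure* the analysis assumes, not any real
geography:

- **Tracts.**  A standard-normal latent vulnerability factor drives all
  three index scores with loading 0.75 each (a realistic between-index
  correlation: strong but far from collinear).  The residual mixes
  index-specific noise with an urban-density covariate (loadings 0.25 CES,
  0.6 HHAI, 0.1 SVI) and, for CES, a pollution component (0.45), scaled so
  each score has unit variance; at loading 1 the indices collapse to the
  latent factor exactly.  Density is a two-component log-normal (90 %
  urban ≈ 1 500 /km², 10 % rural ≈ 12 /km²).  2 % of values per index are
  set missing to exercise the completeness filter.  Nine region labels are
  sampled with fixed weights dominated by the populous south.
- **Climate.**  Daily `Tmax` = tract baseline (mean 25 °C, sd 4 — the
  seasonal mid-level, so July means sit near 35 °C and April near 22 °C)
  + a sinusoid of amplitude 10 °C peaking in late July + a per-model offset
  (±0.3–0.6 °C) + period warming (+0.8 °C current, +2.0 °C projected vs
  historical, a mid-century moderate-emissions magnitude) + AR(1) noise
  (φ = 0.7, stationary sd 3 °C) so multi-day exceedance runs occur at
  realistic rates.  `Tmin` subtracts a positive diurnal range (mean 14 °C);
  minimum RH is anti-correlated with the `Tmax` anomaly (−1.5 %/°C around a
  30 % base, clipped to [0, 100] — a dry-summer climate).  The projected
  warming is amplified by `1 + 0.5·(latent percentile/100 − ½)` so
  high-vulnerability tracts warm somewhat faster, planting the positive
  vulnerability–exposure gradient the overlay should detect.
- **Interventions.**  Projects sample tracts with weight
  `exp(targeting_strength · CES percentile / 100)` (strength 2 ≈ the
  observed concentration of funding in disadvantaged tracts; 0 is uniform).
  60 % carry one planted category whose phrase comes from that category's
  vocabulary; the four vocabularies are disjoint, so the default keyword
  rules recover every planted label exactly — an overlap can be introduced
  by editing `category_vocab` to exercise the multi-label path.  Unplanted
  projects occasionally embed an include phrase together with an excluded
  program name to exercise the exclusion path.  20 % of projects duplicate
  into a second year and 10 % into a second tract.

What the generators deliberately do **not** emulate: spatial
autocorrelation between tracts, coastal/inland regional climate structure,
leap-second calendrical detail, or realistic funding award amounts.
Passing tests therefore demonstrate that the *methods* behave correctly on
data with the assumed structure, not that any particular real-world number
is reproduced; statistics derived from the real state datasets require
those downloads.

## Problem sizes and determinism

Everything is deterministic given the seed: each generator draws from
`numpy` Generators keyed by (seed, stream), so running one generator never
perturbs another, and pipeline reruns are byte-identical.  The acceptance
script assesses vulnerability on the full 8 000-tract default scenario but
computes exposure on a deterministic, evenly spaced 240-tract subsample
(240 tracts × 4 models × 90 years × 214 days ≈ 18.5 M daily rows) — enough
to estimate medians, deltas, and the overlay gradient stably while keeping
a single-CPU run under a minute.  Unit tests use smaller scenarios
(hundreds of tracts, 3–12 climate tracts) chosen to keep the whole suite
fast while preserving every structural property under test.

## Known limitations

- Heat-index behavior far outside the Rothfusz fitting region (e.g.
  T > 112 °F at high RH) extrapolates the regression; the analysis only
  thresholds at 91 °F, where the fit is sound.
- The HHAI tie-handling and the SVI release year of the original datasets
  are unknown; both are configurable reader/ranking options rather than
  baked-in claims.
- The shipped keyword rule set matches the synthetic vocabularies and is
  illustrative; real project screening requires the user's own
  include/exclude lists (the published ones exist only as an image).
- Region assignment consumes precomputed area-overlap fractions; no GIS
  geometry is performed.
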