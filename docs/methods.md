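# Methods

## The surveillance problem

A medical web site's search log is a pre-diagnostic signal: people search
for symptoms near illness onset, before (or instead of) seeing a doctor.
The log is anonymous — each record is a timestamp and the raw query text,
nothing else — so the unit of analysis is the weekly count of queries
matching a pattern of interest. Two confounders stand between raw counts
and an epidemiologically interpretable series:

1. **Secular growth.** Site usage grows several-fold over a multi-year
   span, so raw counts of any query rise regardless of disease activity.
2. **Seasonal browsing volume.** Total usage itself is higher in winter.
   Dividing by the same-week total would therefore *remove* genuine
   winter disease seasonality along with the browsing seasonality, and
   dividing by a yearly total would ignore the within-year growth.

The package's normalization resolves this with a *reference query*: a
common term whose weekly count shows secular growth but no seasonal
cycle. Its smoothed trend estimates expected search volume per week, and
every series of interest is divided by that expectation. Growth cancels;
seasonal and epidemic excursions survive.

## Pattern matching

Patterns are pipe-separated alternatives, each optionally flanked by `*`.
Matching is whole-token for a bare alternative and substring on a starred
side, always under full Unicode case folding, never accent folding
(spelling variants are enumerated explicitly, e.g. `diarre|diarré`).
The token rule keeps morphologically distinct forms distinct
(`kräkningar` does not match `kräkning`), while the star form captures
Swedish compounding (`*kräk*` matches `projektilkräkningar`). For a
single-sided star, the starred side accepts any characters (including
none) and the other side must sit on a whitespace-or-string boundary.
The original matching behaviour for unstarred terms is not formally
specified anywhere; whole-token semantics is this package's documented
choice, and the test suite pins it against an independent token-scan
oracle.

## Week calendars

Monday-start weeks are strict ISO-8601 (week 1 contains the year's first
Thursday). Sunday-start weeks — the dialect of external relative-volume
feeds — are labeled by the ISO week of the Monday they contain, i.e. the
Sunday-start week (y, w) begins one day before ISO week (y, w). This
makes cross-dialect alignment a pure relabeling: a bijection that loses,
duplicates, and invents nothing, verified by property test.

Missing-log weeks are declared as explicit date ranges and stored as NaN.
They are never inferred from zeros, because a zero-count week is an
observation, not an absence.

## Trend estimation

`fit_trend` runs a tricube-weighted local polynomial regression of the
reference counts on the week index:

- **degree** (default 2): a local quadratic follows the curvature of
  saturating growth without chasing noise;
- **fraction** (default 0.6): each fit uses the nearest 60% of points.
  The window must span well over 52 weeks so that an annual cycle in the
  reference (should one leak in) averages out of the trend rather than
  becoming part of it;
- no robustness iterations: the reference is a high-count series and the
  smoother must track genuine level shifts.

With degree 1 the smoother reproduces classic non-robust LOWESS
(agreement with `statsmodels` to ~1e-12 on a shared fixture). Fitted
values are floored at half the smallest positive fitted value so that
normalization never divides by ~0 at span edges; the fit uses observed
weeks only and the resulting model is evaluable across gaps.

Bandwidth selection is deliberately manual (exposed in configuration and
on the CLI); the trend is meant to be inspected, not cross-validated.

`choose_reference_diagnostics` screens reference candidates. The
seasonality score is the *adjusted* fraction of detrended variance
explained by week-of-year means — adjusted because the raw between-group
R² has a null expectation of (k−1)/(n−1), about 0.33 for three years of
weekly data, which would make white noise look seasonal. The adjusted
score is ≈0 under the null, ≈1 for a pure annual cycle. The growth score
is the fitted trend's end/start ratio.

## Requests, windows, comparisons

A trend request covers exactly 260 weeks (5 × 52) ending the week before
the request week. The fixed 260-week length keeps window semantics
identical across 53-week ISO years; the anniversary of the window's last
week is marked in each year to ease year-over-year reading.

`rescale_0_100` reproduces the external feed's convention (max = 100).
`lead_lag` computes Pearson correlation at integer lags, pairing series
*a* at week w+k with series *b* at week w; negative best lag means *a*
leads. Ties prefer the smaller |lag|, then the negative one. Each tested
lag requires ≥ 10 observed pairs. No significance testing is attached —
the comparison is descriptive.

## The synthetic world

The generator produces the conditions the pipeline is designed for:

| parameter | default | meaning |
|---|---|---|
| span | 2005-W27, 260 weeks | five years of weekly data |
| growth | logistic, 500 → 2500 queries/week | ~5-fold usage increase |
| volume seasonality | 0.25 | winter-peaked cosine (mid-January) on total volume |
| reference | "herpes", share 0.04 | growth-only; share of the growth curve, not of seasonal total |
| disease | "kräk", base share 0.02 | token form `kräkningar`, compounds (`kräksjuka`, …), phrases (`kräkningar barn`, …) |
| epidemic | peak 2009-W02, height 8, width 3 | Gaussian multiplicative excursion |
| media | one spike (2009-W47, 40 articles, decay 2 w) | +0.5 relative emission per 100 articles/week |
| noise | Poisson | negative-binomial optional via `overdispersion` |
| gap | 2006-06-05 .. 2006-07-09 | five missing-log weeks |

Weekly levels are desk-scale (~390k entries over the span, generated and
analysed in a few seconds); they are an order of magnitude below a real
national site's volume, which only makes the acceptance checks *harder*
(relative Poisson noise is larger).

Form-level structure: the disease's bare word carries an epidemic
coupling of 0.4 while compounds and phrases couple fully, emulating the
observation that the generic word has substantial background (curiosity)
usage while compound queries are written by the ill. This is what makes
the star-pattern series strictly dominate the token series in counts and
exceed it in correlation with the injected epidemic. About 15% of
entries carry case variation to exercise case-insensitive matching.

The external 0–100 feed is the injected epidemic excursion plus
media-driven and white "curiosity" noise, rescaled and keyed to
Sunday-start weeks.

What the generator does **not** emulate: realistic vocabulary beyond a
small lexicon, user sessions or repeat queries, day-of-week structure
(timestamps are uniform within the week; only weekly aggregates are
consumed), holiday effects, and drift in spelling habits. Passing tests
therefore demonstrate the pipeline's correctness under the stated
statistical structure, not robustness to every artefact of real logs.

## Numerical and edge-case choices

- Peak week ties break to the earliest week.
- Rescaling clips at 100.0 to absorb float round-off; all-zero series
  are rejected rather than silently scaled.
- `read_log` skips malformed lines with a counter but rejects a file in
  which more than half the lines fail (almost certainly a dialect
  mismatch). Extra declared columns are dropped with a warning so
  identity-bearing fields can never enter the pipeline.
- Raw-count series validate non-negative integrality; scaled series
  validate the [0, 100] range; week sequences must be strictly
  increasing within one convention, and cross-convention comparison is
  an error rather than a guess.
- With several near-equal annual epidemics the *global* peak week is not
  a stable recovery target under Poisson noise (it can hop between
  winters); the stock scenario injects a single epidemic, and recovery
  is asserted to ±1 week at the stock seed. A width-3 Gaussian peak can
  still miss by 2 weeks for a small fraction of seeds — that is a
  property of the noise level, not of the estimator.

## Known limitations

- Only weekly aggregation is implemented (the bucket logic generalizes,
  but nothing else is tested).
- The trend is refitted on demand; there is no caching or incremental
  nightly update.
- Lead/lag is descriptive; no confidence intervals.
- The media feed is a local CSV; no live news-search integration.
- Report delivery is file-based; an SMTP hook would slot into
  `run_subscriptions` but is intentionally absent.
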