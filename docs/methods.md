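# Methods

## The measurement model

The quantity of interest is *collective* traumatic grief in a geographic
community, observed through the daily frequency of memorial tweets that
reference that community. Two modeling commitments follow:

- **Spatial context by lexicon, not geotag.** Fewer than 1% of tweets carry
  location data, and the populations of interest are the least likely to
  enable it. A tweet is attributed to a territory when its text contains an
  *online territory identifier* — a faction name, acronym, hashtag or
  renamed-block label that uniquely signals one territory. A tweet naming two
  territories is fanned out to both streams rather than discarded: the unit
  of analysis is the territory-day count, and a memorial naming two
  communities is evidence about both. Killer ("k")-suffixed identifiers name
  a rival faction but are still counted for the identifier's owner — the
  tweet references that faction — a choice the matching layer exposes via the
  `via_killer_form` flag.
- **Counting, not reading.** Relevance filtering is binary; no sentiment or
  content scale is inferred. Identical texts by different users on the same
  day are deliberately all counted — simultaneous identical memorials are
  exactly the collective signal — while same-user/same-day duplicates are
  collapsed to one.

## Lexicon matching

Texts are matched token-wise after *squashing* (lowercase, strip
non-alphanumerics), so `R.I.P`, `#rip` and `rip` coincide while `trip` does
not (whole-token matching; multi-word variants match across single spaces).
Grief and territory matches inside @-mention tokens are ignored: a handle
such as `@rip_legend` supplies neither grief content nor spatial context.
The spec for grief hits only requires the mention exclusion; extending it to
identifiers is this package's choice, for the symmetrical reason.

"Primarily numeric" identifiers are excluded at compile time, operationalized
as more than 50% digit characters among non-space characters. Identifier
uniqueness across territories is a hard invariant (a shared identifier would
silently double-count), and a duplicate raises naming both claimants.

Keyword validation (`validate_keywords`) fits LDA topic modeling
(scikit-learn's `LatentDirichletAllocation`, batch mode, seeded) on a token
corpus and ranks the tokens of the topic carrying the most aggregate weight
on grief-lexicon word forms. It is a diagnostic for lexicon curation, not a
pipeline stage.

## Preprocessing

Fixed rule order: retweet filter → handle-keyword filter → same-user/
same-territory/same-day exact-text dedup (earliest kept) → lowercase +
masking → punctuation/length/repeat normalization → lemmatization. Masking
replaces territory identifiers (longest first, killer forms included),
URLs, emails, phone numbers and mentions with `_IDENTIFIER_`, `_URL_`,
`_EMAIL_`, `_PHONE_`, `_MENTION_`; lowercasing precedes masking so
identifier matches are exact. Masking makes downstream features
territory-agnostic; the sentinels themselves are legitimate features.

Token normalization: punctuation becomes spaces (sentinels pass through
intact); runs of ≥ 3 identical characters collapse to one (`looool → lol`);
tokens of length ≤ 2 are dropped *after* collapsing (so `nooo → no` is then
dropped — the two steps are otherwise unordered in the source procedure);
remaining tokens are lemmatized. The lemmatizer is a small deterministic
suffix-rule component (plural → singular, `-ing`/`-ed` stems, a short
irregular table), applied to a fixpoint so normalization is idempotent — an
invariant the property tests enforce. It is intentionally conservative: its
job is to merge inflectional variants consistently, not linguistic coverage.

## Relevance

The annotation rule marks a tweet relevant iff it has ≥ 1 grief hit and ≥ 1
territory hit and is not flagged as a celebrity-death subject, an
out-of-city event, or a handle-only keyword artifact. The flags are context
that text alone cannot always supply; they come from annotation tooling or,
on synthetic data, from the generator (where the rule reproduces the
generator's labels exactly — a cross-module consistency property).

The trained classifier is an L2-regularized logistic regression
(`liblinear`, C = 1.0, threshold 0.5, seeded) over token-count features of
the masked text. A linear model was chosen deliberately: coefficients are
auditable by the domain experts whose judgments the model encodes, which
matters in a surveillance-adjacent application. Model-vs-truth agreement is
reported as Cohen's kappa, κ = (p_o − p_e)/(1 − p_e) with chance agreement
p_e from the raters' marginal frequencies; κ = 1 is returned for perfect
agreement, and the degenerate p_e = 1 case (only reachable through floating
point, since both-raters-constant-and-equal implies p_o = 1) returns 0 with
a warning. The human inter-annotator benchmark in this design regime is
κ ≈ 0.95; it is a reference point, not an assertion the package tests.

## Spike detection

Per territory: daily counts over the inclusive study window, local dates in
America/Chicago. Territories with fewer than `stable_presence_min = 100`
relevant tweets are excluded (no stable online presence). *Candidate days*
have at least `min_count = 2` tweets — one tweet is not collective.
`k = ceil(top_fraction × #candidate days)` with `top_fraction = 0.01`; the
k candidate days with the largest counts are spikes, ties broken by larger
baseline-relative score, then earlier date. The score is a z-score against
the territory's own all-days mean and SD by default (`fold` = count/baseline
is the alternative); per-territory standardization is what makes spikes
comparable across territories whose daily averages differ by an order of
magnitude.

The "top 1%" denominator is genuinely ambiguous (all days? nonzero days?
threshold-exceeding days?); this package fixes *candidate days* as the
default and exposes both knobs in `SpikeConfig` rather than hard-coding a
guess. Degenerate cases are defined, not errors: no candidate days → no
spikes; zero variance → z-score 0.

## Event matching

An event matches a spike when any ledger alias appears (squashed-token
matching, so `#LILJOSH` hits "lil josh") in any member tweet and the event's
territory equals the spike's. Matched spikes are typed with precedence
acute > anniversary > general:

- **acute**: 0 ≤ (spike − death) < 7 days — "hours and days immediately
  following" loss; the week-long default is configurable.
- **anniversary**: within ± 2 days of a yearly recurrence (later year, same
  month/day) of the death date or, when known, the birth date. The 2-day
  tolerance reflects observed spikes one day off the exact anniversary.
  Feb-29 recurrences map to Feb-28 in non-leap years. Birthday recurrences
  are only memorial after the death.
- **general**: name-matched with no date relation — typically multi-decedent
  memorials. A name hit *before* the event's death also falls through to
  general: mourning can only follow death.

Reports give per-territory tweets, daily average (2 dp), spikes, matches and
match rate (1 dp); aggregates give totals plus the *unweighted* mean and
median of per-territory match rates. The pooled rate
(total matches / total spikes) is a different statistic and is reported
under its own name (`overall_match_rate_pct`); territories with zero spikes
have an undefined rate and are excluded from the mean/median. The package
ships the 18-territory reference summary of the original five-year
deployment as a data fixture; aggregating it reproduces the published
totals, means and medians exactly (the acceptance suite checks this), with
one printed daily-average value kept as published even though it is
internally inconsistent with its own tweet count — it is never asserted
against the calendar arithmetic.

## The synthetic stream

What it emulates, per territory-day: relevant-tweet counts are
Poisson(baseline + Σ event contributions), where an event contributes
`burst_magnitude · 2^(−days_since_death/halflife)` from its death day onward
and `anniversary_magnitude` on yearly death/birth recurrences. Any decaying
kernel is consistent with "hours and days immediately following", so the
kernel is a config knob; the default halflife is 1 day. Noise classes —
celebrity-death, out-of-city, handle-keyword, numeric-confusable — are
independent Poisson streams whose templates violate exactly one relevance
rule by construction; retweets and same-user duplicates are sampled per
original. Timestamps are uniform within the local (America/Chicago) day.
Output is byte-identical for a fixed seed.

Default study conditions (`default_config`): the five-year window
2012-01-01..2016-12-31 (1,827 days); 18 territories whose baselines follow
the reference deployment's per-territory daily averages, floored at 0.10
tweets/day so every territory clears the 100-tweet stable-presence bar with
Poisson margin (mean baseline ≈ 0.35/day, the deployment's mean); per-event
burst magnitude `max(12.5, 20 × baseline)` — 12.5 expected tweets is the
deployment's typical spike size, and the max() keeps every burst at least
20× its territory's baseline; anniversary magnitude equal to the burst
magnitude. High-activity territories carry more events (and hence in-window
anniversaries), mirroring the observed pattern that busy territories
produced the most spikes; low-activity territories get a single late-window
death. At 1% of candidate days, a territory at 0.35 tweets/day yields on
the order of one to three spike slots over five years, so the engineered
ledger keeps each territory's spike-day count within that budget.

Ground truth bookkeeping: `injected_spike_days` records the engineered
*onset* days — each burst's day 0 and each anniversary date — provided the
injected expectation exceeds `injected_day_min_ratio` (default 20) times the
baseline. Decay-tail days (day 1, 2, …) are deliberately not recorded: they
are aftermath, not engineered spike days, and a top-fraction detector's
budget could never cover them in low-baseline territories.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic language (templated texts are trivially
separable, so classifier kappas near 1 are an upper bound, not a forecast);
user social structure (no follower graph, no per-user posting habits);
identifier drift and obsolescence over time; deleted accounts; emoji; and
observational noise in the ledger itself (real ground-truthing requires
manual triangulation).

## Numerical and protocol choices

- Rounding follows the reporting convention: percentages and means to one
  decimal, daily averages to two.
- Train/test protocol for the classifier: a 2,219-tweet labeled random
  sample (the hand-coding budget of the reference deployment), stratified
  only by chance, 80/20 split, seeded. The permutation null is the standard
  one: train on permuted labels, score held-out folds against those same
  permuted labels (scoring against the *true* labels retains a small
  residual signal, since permuted labels still agree with truth at chance
  rates while features carry real signal).
- All seeds are plain integers; every stochastic component (generator,
  sampling, LDA, logistic regression) takes one.

## Limitations

Beyond the generator's idealizations above: the top-1% rule makes the
*number* of spikes a function of activity level, so sparse territories get
at most one or two calls per window regardless of how many losses they
suffered; the acute/anniversary windows are calendar heuristics, not
clinical definitions; alias matching is substring-based and will miss
nicknames not present in the ledger; and sub-daily (hourly) detection and
multi-day episode merging are out of scope.
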