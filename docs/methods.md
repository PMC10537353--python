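# Methods

## Data model

The unit of analysis is the *flowering calendar*: a dense plants × weeks
grid of non-negative integer flower-bud counts for one
(department, semester, accession) census cell.  Weeks are 1-based indices
within a flowering semester; calendar dates are deliberately not modelled,
because the analysis is entirely within-semester and the two flowering
periods (FP I: November–April, FP II: May–October) are fixed semester
labels, not date ranges.  The default semester width is 26 weeks — a
six-month window censused weekly — and is configurable everywhere it
matters (`n_weeks`).  Weeks with no observation are zeros by convention;
plants whose entire semester is zero are excluded from descriptor
computation (and counted), since a non-flowering individual carries no
information about synchrony or within-plant variability.  Plants may be
present in some semesters and absent in others; each calendar is analysed
with the plants it has, with no imputation.

## Descriptors

**Synchrony `r_i`** is the mean of |Spearman rho| over all unordered plant
pairs.  Ties (the many zero weeks) take mid-ranks, the standard Spearman
convention; no p-value is attached.  The absolute value is applied per
pair *before* averaging, so two plants with perfectly opposite timing
contribute 1, not −1: the descriptor measures overlap of temporal
structure, not its direction.  A pair in which either series is constant
has undefined rank correlation; such pairs are excluded from the average
and reported (`n_pairs_used`, `n_pairs_dropped`) rather than imputed as 0
or 1 — neither substitution is defensible, and upstream exclusion of
non-flowering plants makes constant series rare in practice.  If every
pair is undefined the cell's `r_i` is NaN and the row is flagged, never
silently dropped.

**Temporal variability `CV_i`** averages each plant's coefficient of
variation (sd/mean of the weekly series).  The sample standard deviation
(denominator n−1) is the default; the population form is available
(`cv_denominator="n"`) because the convention is not universal and the
choice shifts every CV by a factor of √((n−1)/n).  Under the sample
convention a single positive spike among n otherwise-zero weeks gives
CV = √n exactly, which the tests use as a closed-form anchor.

**Events** counts the weeks in which the accession's population total is
positive.  It is a bounded discrete count and is summarised descriptively
by medians (per site × semester, per accession, overall) rather than
modelled.

## Newstrom classification

The Newstrom taxonomy (continual / sub-annual / annual / supra-annual) is
qualitative in origin; this package pins it to explicit numeric rules so a
label is reproducible and auditable.  On a multi-semester weekly total
series (two semesters = one year):

- flowering *cycles* are maximal runs of flowering weeks separated by at
  least `cycle_gap` zero weeks (default 8 — two months of silence starts a
  new cycle);
- a record flowering in at least `month_coverage` (default 80%) of 4-week
  "months" with no pause longer than `gap_weeks` (default 4) is
  **continual**, taking precedence over sub-annual;
- otherwise a single cycle spanning more than one year is
  **supra-annual**; more than one cycle per year is **sub-annual**; one
  cycle per year is **annual**; an all-zero record is **none**.

Months are consecutive 4-week blocks of the grid because the data model
has no dates.  The thresholds are configurable and echoed in every
`PatternClass`, since they are this package's operationalisation, not part
of the original taxonomy.  The label is invariant under positive scaling
of the series (only zero/non-zero structure and run lengths matter).

## Inference

The inferential stage is a fixed-effects, two-step procedure on the
descriptor table.  A three-factor screen (site, semester, accession, all
two-way interactions) lets the analyst check whether accession carries any
signal; dropping it and refitting the two-factor model
site + semester + site × semester is a deliberate analyst decision, not an
automated model selection.  All ANOVA tables use Type-II sums of squares:
each term is tested by the residual-SS drop when it is added to the model
containing every other term that does not contain it, with the F
denominator taken from the full model.  Type II is order-invariant and
coincides with the sequential decomposition on balanced designs (a test
asserts this on random balanced layouts, and another checks agreement with
statsmodels' `anova_lm(typ=2)` on full-rank designs).

Missing cells are structural in this problem: an annual-regime site
produces no descriptors in FP II semesters, so the site × semester design
can be rank-deficient.  `fit_aov` raises by default, naming the aliased
design columns; with `on_aliased="drop"` it proceeds the way R's `lm`
does — pseudoinverse fit, degrees of freedom from matrix rank — which is
what the pipeline uses, because refusing to fit would make the realistic
study layout unanalysable.

A significant interaction (α = 0.005, a deliberately conservative
threshold guarding against false positives across separately modelled
responses) is decomposed two ways: one-way simple effects of site within
each semester, Bonferroni-adjusted over the number of strata tested; and
all pairwise site comparisons per semester with pooled-variance t tests
(Welch optional), Bonferroni-adjusted over the full family of performed
comparisons (pairs × strata).  The family size `m` is always reported,
because "Bonferroni-adjusted" is meaningless without it.  Diagnostics —
Shapiro–Wilk on the saturated cell-means residuals and median-centred
Levene across cells (the robust Brown–Forsythe form) — are computed at
0.05 and annotate the analysis; they never block it.  A constant response
yields NaN diagnostics with a warning instead of an error.

## Simulator

The generator is phenomenological: it emulates pulsed flowering, not its
climatic causes.  A regime prescribes population event weeks; each plant
joins each event with probability `participation`, displaced by a rounded
Normal(0, `jitter_sd`) week jitter (clamped to the semester — semesters do
not wrap), and contributes `round(s_i · m_e · ε)` buds with per-plant
scale `s_i ~ LogNormal(0, plant_scale_sigma)`, per-event magnitude
`m_e ~ LogNormal(amplitude_mu, amplitude_sigma)` and week noise
`ε ~ LogNormal(0, 0.1)`.  Lognormal amplitudes with Bernoulli
participation produce the heavy-spike, many-zero series that give CV_i in
the 2–4 range typical of strongly pulsed flowering.  Counts round
half-away-from-zero; collisions of jittered events on one week add.

Preset parameters (fixed once, per regime):

| preset | events | participation | jitter sd (wk) | amplitude μ (log buds) | amplitude σ | rationale |
|---|---|---|---|---|---|---|
| annual-north | 2, FP I only | 0.95 | 0.5 | log 150 | 0.5 | few, synchronised, high-amplitude events; silent in FP II |
| continual-central | 15 spread | 0.70 | 1.5 | log 40 | 0.8 | many scattered low-amplitude events year-round |
| continual-south | 7 spread | 0.85 | 0.8 | log 60 | 0.7 | continual but sparser and more synchronised (cooler site) |

The event counts (2 and 15) are the regimes' defining feature; the
south regime's 7 events sits in between, matching a continual site with
markedly fewer events.  Participation, jitter and amplitude spreads are
this package's choices — no generative statistics exist for them — chosen
so each regime's descriptor signature (annual: high r_i, high CV_i, few
events; continual: the reverse) is an emergent property of the mechanism,
not hard-coded.  The default study design crosses 4 departments ×
4 semesters × 15 accessions with 10–20 plants per cell (5–10 in Quindío,
reflecting high establishment mortality there).

What the simulator does *not* emulate: climate forcing (rain pulses,
insolation), plant mortality over time, branch-level structure,
within-week dynamics, or any accession effect (accessions differ only by
sampling noise, matching the finding that genotype carries no descriptor
signal).  Passing tests therefore demonstrate correctness of the
computational chain and qualitative regime ordering — not quantitative
agreement with any particular field census.

## Numerical choices

- Climate departmental means use exact decimal arithmetic with
  round-half-away-from-zero at the printed precision; binary floats
  misround half-unit averages (e.g. 107.5, 75920.5), and half-away is the
  only convention consistent with every published mean.  The published
  table's day-length column is stored as printed, including its
  internally inconsistent unit label.
- All simulation randomness flows from one seeded `numpy` generator;
  study cells draw from `SeedSequence` spawns in a fixed order, so any
  subset of cells is reproducible and no global state is touched.
- Descriptor equality checks against brute-force reimplementations are
  asserted at 1e-12 on a seeded battery of small calendars (≤4 plants,
  ≤6 weeks, counts 0–3); the full space is astronomically large, so a
  seeded random sample plus property-based tests stand in for
  enumeration.
- The null calibration of the interaction test (20,000 replicates,
  4 × 4 × 10 balanced layout) uses a vectorised closed-form balanced
  ANOVA, cross-checked against `fit_aov` on a subset of replicates to
  1e-8; replicate-by-replicate model fitting would be needlessly slow.

## Limitations

- The Newstrom thresholds are operational defaults, not community
  standards; sensitivity to them should be explored on real data.
- Bonferroni families are defined per analysis run (strata for simple
  effects; pairs × strata for pairwise comparisons); other family
  definitions are defensible and change adjusted p-values by a constant
  factor.
- The simulator's amplitude and participation parameters are not
  estimated from data; only the qualitative ordering of regimes is a
  supported claim.
- No mixed models or blocking terms are fitted; the inference stage is a
  fixed-effects ANOVA on cell-level descriptors.
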