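# Methods

This note documents the models behind `mobisynth`, the parameters that
matter, what the toy-region generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## 1. Population synthesis

### Joint-distribution estimation

Inputs per zone: exact counts by gender × 5-year age band (0–4 … 95+,
configurable); per municipality: a gender × age band × civil status
cross-tabulation, where civil status is `age<18`, `couple` or `single`.

The zone-level joint distribution is the IPF solution with the municipal
cross-tab as seed and the zone's gender × age counts as the only
constrained margin: each municipal (gender, band) slice is rescaled to the
zone count, so civil status follows the municipal conditional
P(civil | gender, band). Only gender and age are therefore matched
exactly; zone civil-status shares converge to the fitted shares as zone
size grows. A two-margin variant (additionally constraining zone civil
totals) is deliberately not used: the `age<18` column is structurally
pinned to the zone's minor population, which makes independently scaled
civil targets infeasible in general.

The generic K-axis `ipf_fit` (alternating proportional scaling,
tolerance 1e-6 on the maximum absolute marginal residual, 1000 iterations,
structural zeros preserved) backs both this stage and the probability
adjustment of Section 2.

### Integerisation

Truncate-replicate-sample (TRS): floor every cell, then allocate the
remaining units by sampling cells without replacement with probability
proportional to the fractional parts. TRS is unbiased and preserves the
grand total; applying it per (gender, band) row makes the zone's gender
and age marginals exact, which is why the marginal evaluation reports 0%
differences at any scale.

Integer ages are uniform within the band, restricted to the side of the
age-18 boundary that the civil status implies (the open-ended top band is
capped at 99).

### Household formation

- **Couples.** Couple-status persons split into two gender groups; group
  one sorted by age, group two by a *proxy* age = own age + a Normal(−2, 4)
  year offset (seeded, configurable). Rank-order matching reproduces
  assortative age pairing with controllable noise; the proxy's exact
  definition was an open design point and this offset model is our choice.
  Pairing is truncated to the smaller group and to the zone's
  couple-household target; the surplus flows to "other".
- **Singles.** Single-status adults fill single households up to the zone
  target (seeded random order).
- **Children.** Each person under 18 joins the household (couple or
  single) whose closest qualifying adult satisfies
  18 ≤ adult − child ≤ 50 years, minimising that gap, ties to the lower
  household id. The window bounds are configurable.
- **Other.** Everyone unassigned is pooled per zone into households of
  uniform size 2–6 (the trailing household may be smaller). Targets that
  exceed the available persons are capped with a warning, never an error.

Household size and child counts are recomputed from membership, so
membership always partitions the person table.

## 2. Generative attribute assignment

The generative model is classifier → IPF → sampling:

1. a probabilistic classifier trained on the travel survey predicts each
   person's category probabilities. The default is multinomial logistic
   regression (one-hot categoricals, standardised numerics) — desk-scale,
   deterministic, and calibrated in aggregate on its training data. The
   `ChoiceModel` contract (an ordered choice set plus
   `predict(features) → row-stochastic matrix`) admits any drop-in, e.g. a
   shallow neural classifier.
2. the n × K probability matrix is adjusted by biproportional scaling with
   row targets 1 and column targets equal to the official category totals
   (rescaled proportionally to sum to n). Structural zeros survive; a
   category with positive target but zero predicted mass is an error.
3. one category per person is drawn independently from the adjusted rows,
   so realised totals concentrate around the targets at the binomial rate.

Applied in order, each attribute conditioning on those before it:

- **Employment × studenthood** (four joint categories; a person can be
  both). Probabilities for `employed`/`both` are zeroed below age 17.
  Zones publish only employee and student totals, which under-determine
  the four category targets; the `both` total is taken from the model's
  predicted mass, clipped to its feasible interval
  [max(0, E+S−N), min(E, S)].
- **Income class** over {No, Low, Lower-middle, Upper-middle, High}
  (bounds 0, [1,180), [180,300), [300,420), [420,1000) kSEK), fitted to
  municipal class counts.
- **Car ownership** over {0, 1, 2, 3+} for adults (minors own none). The
  zone statistic is a *car count*, not per-category person counts, so the
  category targets are obtained by exponentially tilting the predicted
  category counts c_k by t^k and solving the monotone scalar equation
  E[cars] = zone total. The household car count is the maximum over
  members (configurable to sum); "3+" counts as 3.

## 3. Activity generation

The day runs from 3 AM to 3 AM; internally all times are hours since 3 AM
in [0, 24], which makes ordering monotone and day-wrap explicit.
Serialisation converts to decimal clock hours with one decimal.

- **Participation.** Empirical conditional distribution of the eight
  home-containing subsets of {H, W, S, O} given (employment, studenthood),
  backing off to the pooled distribution. Home is always present.
- **Duration classes and travel time.** Per-type class boundaries are the
  survey's empirical tertiles (low/moderate/high). The class combination
  *and* the daily travel-time range class are drawn jointly from the
  empirical distribution conditioned on (participation set, employment,
  studenthood) — a single categorical draw, so cross-type correlations
  survive. Travel-time classes default to (0, 0.5], (0.5, 1], (1, 2],
  (2, 4] hours (configurable).
- **Durations.** Per (type, class), durations are drawn from the survey's
  1-hour histograms with uniform within-hour jitter, and the tuple is
  rejected until 24 − t_hi ≤ Σt < 24 − t_lo. After 100 rejections
  (configurable) the last draw is rescaled onto the midpoint of the band
  and the agent flagged for audit. Stay-at-home days are the degenerate
  case: zero travel, t_H = 24 exactly, the band check does not apply.
- **Sequence matching.** Candidates share the participation set; filters
  on gender, age band, employment, studenthood are relaxed from the last
  attribute until non-empty. The winner minimises the Euclidean distance
  between (t_H, t_W, t_S, t_O) tuples, ties to the smallest respondent id
  (verified against exhaustive search). With no donor at all the sequence
  falls back to a canonical pattern (H, H-W-H, H-S-H, …) and is flagged.
- **Scheduling.** The episode spanning 3 AM is the sequence's first/last
  entry; its post-3 AM length is drawn from the survey's empirical anchor
  distribution for that activity type, clamped to [5%, 95%] of the
  episode's duration (with no anchor model: an even split). Every other
  instance of a type gets an equal share of the type's total duration, and
  the residual 24 − Σt (which the band constraint places inside the
  travel-time class) is split equally over the gaps. Whether total travel
  time should be split equally or per-trip-modelled was open; equal split
  is our documented choice. Episode + gap times tile 24 h to 1e-6 by
  construction.

## 4. Location and mode assignment

- **Virtual zones.** Zone × grid-cell intersections weighted by the
  cell's share of the zone's grid population (uniform, with a warning, if
  the zone's grid total is zero). In the toy geometry zones are unions of
  whole cells, so intersections are exact.
- **Home buildings.** Household → virtual zone by weight; building type
  by P(detached | size) = logistic(−3.0 + 1.2·size), i.e. singles mostly
  in apartments, five-person households mostly in detached houses;
  concrete building uniform within the cell, falling back to the parent
  zone. Homes are always detached houses or apartments.
- **Gravity model.** P(j | i) ∝ m_j·exp(−β·d_ij) with straight-line
  centroid distances (planar metres; haversine available for geographic
  input). β per (purpose, mode) solves the moment condition
  model mean trip distance = observed mean (Brent root-finding on
  [1e-5, 50] /km; a non-bracketable root is a fit error carrying the
  attainable range). Attraction masses: zone population for work/other,
  total school footprint for school. At least 20 trips per cell required.
- **OD probabilities.** Supplied OD flows take precedence, with trip
  purposes mapped {work → W} and {business, other, private → O}; school
  has no OD trip purpose, so S destinations always come from the gravity
  model.
- **Modes.** One tour mode per agent from a survey-trained choice model
  on age, gender, employment, studenthood and car access; the Car (driver)
  probability is zeroed for carless households and for minors. Per-trip
  modes equal the tour mode; an optional walk-substitution probability
  (default 0) can perturb single trips.
- **Destinations.** Per trip, the destination CDF (over zones ordered by
  increasing distance from the current origin) is inverted at the agent's
  travel-time quantile among all same-mode trips in the run — a direct
  mechanisation of "longer travel time, farther destination". Activities
  chain: each trip starts from the previous activity's zone. Buildings
  are drawn within the destination zone from the purpose-appropriate
  usage type, weighted by footprint area; a zone lacking such a building
  falls back to the nearest zone that has one (flagged). All home
  episodes of an agent reuse the household building.

## 5. The toy-region generator

The fixture module emulates the full input suite with known ground truth:

- Geometry: municipalities are rows of rectangular zones, each zone a run
  of whole 1 km grid cells; zone populations uniform in 700–2700 by
  default (the defining size range of the zone system).
- Demography: one multinomial draw per zone over gender × band × civil
  with a plausible age pyramid and age-dependent couple shares; municipal
  cross-tabs are *sums of the zone draws*, so all aggregate tables are
  exactly consistent by construction, and grid-cell populations partition
  zone totals exactly.
- Behaviour: participation probabilities by (employment, studenthood);
  truncated-normal daily durations (home 14±2 h on [8,24], work 8±1 h on
  [1,14], school 6±1 h on [1,12], other 2±1 h on [0.25,8]); a
  distance-and-car mode-utility model; deterrence rates per
  (purpose, mode) between 0.08 and 0.8 /km; mode speeds 5–40 km/h. These
  parameters are persisted (`ground_truth.yaml`) so recovery tests can
  assert against them.
- Survey diaries are built directly on the 3 AM-anchored day with home as
  the anchor; home duration absorbs the day's slack, mirroring how real
  diaries close. OD matrices follow the true gravity model exactly;
  `survey_trips` are individual draws from it.

What it does **not** emulate — and what passing tests therefore cannot
show about real data: irregular zone geometry and polygon clipping;
measurement error, non-response and weighting in surveys; multi-day and
weekend behaviour; congestion (travel times derive from gaps, not a road
network); intra-household schedule coordination; and any calibration to a
specific country's published shares.

## 6. Numerical choices and limitations

- Seeds: every stage derives its generator from `SeedSequence([seed, k])`
  with a fixed per-stage k, so a single seed makes the entire run —
  including CSV bytes — reproducible.
- Default problem sizes: tests and the acceptance script use 10 zones of
  ~1000 inhabitants (≈10k agents) and a 2000-respondent survey; all
  stage algorithms are linear or near-linear in agents and were chosen to
  exercise every code path at that scale.
- Gravity recovery accuracy: with 2000 trips per (purpose, mode) the
  moment estimator's sampling error is roughly 10% relative for the
  weakest deterrence cell; the acceptance check therefore averages the
  estimates of three independent trip samples.
- The travel-time/distance coupling is assessed on assigned zone-centroid
  distances — the quantity the rank rule controls; building-to-building
  distances add within-zone scatter on the order of the zone size.
- Ties: couple matching breaks ranks by person id; donor matching by
  respondent id; child assignment by household id. All fallbacks
  (duration rescale, canonical sequence, building fallback) are flagged in
  the outputs for audit.
- Known limitations: trip-based chaining of destinations (not tours
  anchored at home); no public-transport timetables or network routing;
  income is a class, not an amount; the couple matcher pairs across the
  two gender groups only.
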