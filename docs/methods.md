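# Methods

This note documents the models and procedures implemented in
`fledgelink`, the assumptions behind them, the defaults of the synthetic
world, and the numerical choices that a maintainer would otherwise have
to reverse-engineer.

## 1. Chick age and sex from resighting data

**Age from P8.** Chick age is the inverse of the Gompertz growth curve of
the eighth primary, `P8(t) = A·exp(−exp(−k·(t − T)))` with asymptote
A = 247 mm, growth rate k = 0.095 d⁻¹ and inflection T = 19.3 d:
`age = T − ln(−ln(P8/A))/k`. The inversion is exact (round-trips to
1e-9 d across t ∈ [5, 100]); inputs outside (0, A) are rejected with an
error naming the asymptote. Ages are kept real-valued and floored only
when binned into 10-day classes (40 = 35–44 d, 50 = 45–54 d, …; ages
below 35 d are outside the post-fledging window and rejected).

**Visual sex rule.** Resighting evidence carries a situation code 1–7.
Codes 1, 2, 5, 7 (copulation, clear partner difference, molecularly sexed
partner, night incubation) are *certain*; 3, 4, 6 are *uncertain*. If
certain identifications exist and all name one sex, that settles it.
Otherwise — including the case of certain identifications of *both*
sexes, which we deliberately let fall through to the count rule — the sex
is the majority sex when total female and male identifications (certain
and uncertain weighted equally) differ by more than two, else unknown.
The rule is order-independent by construction.

## 2. Trajectory segmentation

Distances are great-circle on the WGS-84 mean sphere (R = 6371.0088 km);
at the 10 m contact scale the spherical error is far below a centimetre.
Interval speeds are computed from positions and elapsed time, not from
the logger's instantaneous speed field (which is kept as a classifier
feature only) — this makes segmentation robust to speed-field dropout.

* **Flight bout**: maximal run of consecutive intervals with average
  speed ≥ 5 km/h (inclusive). Intervals longer than a gap cap (default
  30 min) never join a bout, so sparse post-departure data cannot create
  spurious multi-hour "flights".
* **Departure day**: first UTC calendar day (configurable offset) on
  which the bird travelled > 100 km (strict) in southward direction
  between the day's first and last fix (southward = last fix at lower
  latitude; the distance is geodesic by default, with a pure-latitudinal
  variant behind a switch, since the original phrasing does not fix the
  metric) *and* the day's last fix lies > 50 km (strict) south of the
  colony, measured as north–south separation.
* **Departure moment**: among flight bouts with net displacement ≥ 30 km
  (inclusive) starting on the departure day or the preceding day (to
  catch evening departures), the earliest; the moment is the timestamp of
  that bout's start fix — the last fix at which the bird has not yet
  moved. A departure day without any qualifying bout raises an explicit
  inconsistency error rather than being dropped silently.

## 3. Dyadic contact

Each chick fix is paired with the temporally nearest parent fix
(equidistant neighbours resolve to the earlier fix, for determinism; one
parent fix may serve several chick fixes). Pairs are retained when
|Δt| < 10 min (strict), or at any Δt once the parent has departed while
the chick has not — the birds are then certainly hundreds of kilometres
apart and the row records certain non-contact. Contact is a strict
`distance < threshold` with 10 m primary and 50 m sensitivity thresholds.

Daily summaries require ≥ 130 linked fixes (out of the 144 implied by a
perfect 10-min day) for overall contact and ≥ 100 acceleration-complete
linked fixes for behaviour-specific contact (begging, foraging); the
35–136 d age window is applied before these completeness filters (the
ordering is configurable; the original description does not state it).
Pairs need ≥ 10 qualifying days, using only data strictly before the
chick's departure day. Distance-to-nest summaries are computed over
contact fixes only. After both birds depart, candidate meetings are
screened as nearest-fix pairs closer than 25 km, returned as a table for
review rather than auto-classified — at migration flight speeds a few
minutes of timestamp offset already exceeds any contact threshold.

## 4. Behaviour classification

Bursts (1.6 s of 20 Hz tri-axial acceleration paired to each GPS fix) are
cut into non-overlapping segments of 0.4, 0.8 or 1.6 s; only full
segments are kept, so truncated bursts contribute what they contain.
Features per segment: per-axis mean, SD, min, max, skewness, kurtosis,
dominant spectral frequency and its power (zero-padded 256-point DFT of
the mean-detrended axis; padding refines the coarse native grid of short
segments), the three pairwise axis correlations (defined 0 for a constant
axis), ODBA (mean summed absolute deviation from the axis means) and GPS
speed. All features except means, minima and maxima are invariant to a
constant offset on all axes.

The classifier is a 200-tree random forest with balanced class weights
(begging is rare in real annotated material), seeded and evaluated on a
stratified 70/30 split with per-class F-measures; pooling
(forage = search/handle/ingest, rest = sit/stand, fly = active/passive)
is applied to predictions and truth before scoring, so within-group
confusion is not penalised. F is defined 0 when precision + recall = 0.
Because walking and foraging share similar signatures, a habitat rule
rewrites forage labels at fixes outside foraging habitat (freshwater,
brackish or marine polygons; point-in-polygon on unprojected WGS-84
coordinates, which is safe at polygon ≫ GPS-error scale) to walking;
fixes outside map coverage are treated as land by default (configurable,
logged).

## 5. Mixed models and selection

Daily contact is binomial (successes = contact fixes, trials = linked
fixes) — the day-level aggregate matches the "proportion of time" unit
and the day filters — and nest distance during contact is Gamma with log
link, floored at 1 m (0.001 km, logged) since Gamma support excludes
zero. Both carry a correlated random intercept and (standardized-)age
slope per chick, optionally per chick–parent pair. Chick age is
z-standardized inside the model; `age_slope_per_day()` back-transforms.

No maintained Python package fits these by maximum likelihood, so
`fledgelink.glmm.MixedGLM` implements the Laplace approximation directly:
per-group 2-d random-effect modes found by damped Newton iterations with
per-group step halving (closed-form 2×2 solves, vectorized over groups),
and the marginal likelihood maximized by L-BFGS-B over fixed effects plus
(log σ0, log σ1, atanh ρ) and, for Gamma, log shape — the box bounds keep
the optimizer out of the flat saturation regions ρ → ±1 and σ → 0/∞.
This is the same approximation lme4 uses at nAGQ = 1; the test suite
checks agreement with `glmer` to ~4 decimals in fixed effects and ~0.05
in log-likelihood. Standard errors are Wald, from the numerically
differentiated Hessian of the marginal log-likelihood; a fit is flagged
non-converged when the optimizer fails or the fixed-effect variances are
not positive, and such candidates are excluded from selection with a log
entry.

Candidate sets are all subsets of {age, chick sex, parent sex} with year
always included and no interactions (8 models per response). AICc is
`−2ℓ + 2k + 2k(k+1)/(n−k−1)` with k counting every estimated parameter
(fixed effects, both random-effect SDs, their correlation, and the Gamma
shape) and n the number of day-level aggregates — the natural unit here,
though the effective sample size of a mixed model is ambiguous; with
~1100 days the correction is small either way. The most parsimonious
model is the fewest-parameter model within 2 ΔAICc (inclusive) of the
best; ties on parameter count break by lower AICc.

Feeding observations use one randomly selected observation per chick
(seeded), counts per 10-day age class regressed on the class midpoint
with a Poisson log link, and feeding distance regressed on unbinned age
by OLS. The first-year survival comparison is a two-sided Z test of a
binomial cohort rate against a mark-recapture reference, combining both
standard errors.

## 6. The synthetic world

The simulator's defaults are the study's stated conditions: 10-min GPS
cadence, 1.6 s/20 Hz bursts, 15 families over three years at a Wadden-Sea
colony (53.4833° N, 6.25° E), chick departures at 108–139 d, a 35–136 d
analysis window, ~5% fix dropout and ~5% incomplete/missing bursts,
1–6 h GSM fixes after departure. Contact probability is
`logit p = −2.3 − 0.03·(age−35) + year effect + b0 + b1·(age−35)`; the
baseline and decay are derived from the reported average contact
proportions (8.0% at 40 d, 1.9% at 90 d at the 10 m threshold), and the
year effects (2016: 0, 2017: −1.5, 2018: +0.5) encode the reported
pattern of a very-low-care 2017. The per-chick random-effect SDs (1.0 on
the intercept, 0.02 d⁻¹ on the slope, correlation −0.2) place the
among-chick heterogeneity at the same order as the fixed effects, the
qualitative regime the study describes. Begging occurs only during
contact (probability 0.2 given contact — chosen for testability; the
real begging share of contact time is smaller). GPS positional error
(default 3 m, configurable — no value is reported for the trackers) is
applied to the underlying path; metre-scale contact offsets are then
placed in the measured frame, so an injected contact episode (< 5 m) is a
statement about recorded proximity and is recoverable at 10 m, while
non-contact placements start at 60 m so that their own GPS error cannot
cross 50 m.

Movement is deliberately minimal: an AR(1) wander around a slowly
drifting daily site within ~8 km of the colony before departure, and
straight-line 45–55 km/h southbound flight at departure — 10-min fixes
are retained through the first migratory flight (the antenna network is
still in range at departure; detection would otherwise be impossible by
construction) before the GSM regime begins. Evening departures
(~20% of migrants) leave after 22:30 so that less than 100 km falls
before midnight, exercising the eve-day branch of the departure-moment
rule. One family per simulation optionally departs jointly (parent 4 min
behind the chick on the same bearing) to exercise the joint-departure and
post-departure proximity paths.

Acceleration signatures per behaviour are frozen constants
(`CLASS_SIGNATURES`): a static posture per axis, a sinusoidal component
(frequency, per-axis amplitude), a noise SD and a GPS-speed range. No
published waveforms exist for these behaviours; the table encodes their
qualitative descriptions — begging is a low-frequency (1.4 Hz)
large-amplitude heave/surge oscillation, active flight high-frequency
(5.5 Hz) flapping, sitting/standing near-static postures, passive flight
near-static at flight speed. All within-class variability (frequency,
amplitude, phase, posture jitter and additive noise) scales with the
`acc_noise` knob, so `acc_noise = 0` is a degenerate, perfectly separable
world and the default `acc_noise = 1` is separable-but-overlapping (walk
and beg share spectra at short segments, which is why begging classifies
best at 1.6 s).

**What a green test does and does not establish.** The synthetic world
has no tides, weather, energetics or multi-colony structure; behaviour
sequences are i.i.d. given contact rather than autocorrelated bouts; and
class-signature separation is an assumption, not a measurement. Recovery
tests therefore establish that the estimators are correct for data
satisfying their own assumptions at the study's scale — not that the
field data satisfy those assumptions.

## 7. Numerical details and edge cases

* Timestamps are UTC throughout and rounded to milliseconds at
  generation so every table survives CSV round-trips bit-identically;
  chick and parent fix times are jittered ±30 s to keep
  nearest-timestamp linkage honest.
* Nearest-fix ties resolve to the earlier fix; boolean filters use the
  strict/inclusive senses listed in §2–3 (strict for "more than",
  inclusive for "at least").
* `summarise_daily` keeps a day that passes either completeness filter
  and reports NaN for the quantities whose filter failed; days failing
  both are dropped.
* Degenerate inputs fail loudly: all-zero (or all-one) binomial contact
  responses, fewer than two feeding age classes, n ≤ k+1 in AICc, empty
  candidate sets, zero-length tracks.
* Random-forest seeds, subsampling seeds and simulation seeds are always
  explicit; the pipeline manifest hashes every output-determining
  parameter (not the output directory), so a repeated run reproduces
  byte-identical tables and the same hash.

## Known limitations

* The Laplace approximation shares lme4's small-cluster bias; with 16
  chicks the random-effect SDs are noisy (the Wald CIs on fixed effects
  still calibrate at ≥ 90% empirical coverage in the recovery suite).
* The feature set for classification is a reasonable summary-statistic
  family, not a re-derivation of any previously published feature list.
* Post-departure "meetings" are screened, not adjudicated: the output is
  a candidate table for inspection.
* Northward (spring) migration, stopover structure, survival estimation
  from mark-recapture and map rendering are out of scope.
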