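# Methods

## The problem being modeled

An interruptive EHR reminder for shingles vaccination fires at essentially
every eligible outpatient encounter (patient age ≥ 50, no recorded
vaccination workflow), and clinicians acknowledge only a small minority of
firings.  A suppression system predicts, per upcoming encounter, whether
the assigned clinician will interact with the alert, and withholds the
alerts least likely to be acted on.  The package implements that system
end to end against a synthetic cohort, because the interesting questions —
does the feature construction leak, does the threshold behave, does an
on/off pilot detect order loss — are about the *machinery*, which must be
testable without protected data.

## Synthetic cohort (`synthetic_ehr`)

One alert event per alert-eligible encounter.  The generative model, in
the order it runs:

**Clinicians.**  Each of `n_clinicians` gets a latent response propensity
p_i — the per-encounter probability of interacting with the alert at a
scheduled visit — drawn from a Beta distribution scaled to
`propensity_range` (default [0, 0.92]).  The default shape Beta(0.2, 1.2)
is continuous and heavy-tailed: most clinicians almost never respond, a
thin tail responds most of the time, and after calibration ~2–3% of
clinicians sit at the 0.92 cap, so observed interaction frequencies span
the full 0–92% range.  The shape was chosen so the *oracle*
discriminability of the cohort (AUROC of the true event probability
against realized interactions) is ≈ 0.93, in line with what a
high-performing alert-response model achieves on real data; an earlier
two-cluster mixture was rejected both because real interaction
frequencies form a continuum and because a bimodal score distribution
makes median-based thresholds unstable in small validation folds.  An
optional second Beta component (`high_responder_fraction`) reintroduces a
bimodal cohort for sensitivity studies.  Clinician visit volumes are
lognormal (σ = 0.6), normalized.

**Calibration.**  A single multiplicative scale s is applied to the drawn
propensity sample (clipped to the range) and found by bisection
(tolerance 1e-6) so that the visit-volume-weighted mean per-event
interaction probability of the *realized* cohort equals
`target_interaction_rate` (default 0.16).  Calibrating against the
realized sample rather than the infinite-population mixture matters at
desk scale: with O(100) clinicians, population-level calibration leaves
~2-percentage-point cohort-to-cohort noise in the marginal rate, while
sample-level calibration leaves only binomial noise (~0.3 pp at 20k
events).  A closed-form check of the population mean of the clipped,
scaled mixture (via regularized incomplete beta functions) is used in
tests.

**Visit types.**  A fraction `walkin_fraction` (default 0.15) of
encounters are walk-ins.  The configured ignored rates (walk-in 0.91,
scheduled 0.87) fix only the *ratio* of the two visit-type propensity
multipliers; the multipliers are normalized to volume-weighted mean one
so the overall interaction target is untouched.  The two ignored rates
and the 16% marginal are not jointly attainable (any mixture of 9% and
13% interacted is below 16%); the marginal targets win because they are
the cohort-defining quantities, and the visit-type contrast survives as a
relative effect with the correct direction and approximate magnitude.

**Orders.**  Response is hierarchical: interact ~ Bernoulli(p_i ×
visit-type multiplier), then order | interact ~ Bernoulli(c(age)), with
c linear in patient age (relative slope `order_age_slope` = 0.5 across
ages 50–90) and normalized against the realized patient-age sample so
the marginal order rate is exactly `target_order_rate` (default 0.05).
This construction guarantees orders ⊂ interactions and decouples the two
calibration targets.  Non-order interactions split
override/postpone/open-without-signing at 0.5/0.3/0.2 — the split is
cosmetic; nothing downstream distinguishes them beyond the interaction
flag.

**Volume.**  Daily encounter counts are Poisson with mean
`mean_encounters_per_day` × normalized weekday weight.  Default weights
(Mon–Sun 1.1, 1.1, 0.75, 1.05, 1.0, 0.35, 0.30) encode quiet Wednesdays
and much quieter weekends.  Timestamps are uniform over office hours.

**Determinism.**  Every stage draws from `default_rng([stage_tag, seed])`
— fixed per-stage sub-streams, so adding a stage never perturbs earlier
draws, and identical config + seed gives byte-identical logs.

**What the generator does not emulate.**  No diagnosis content, no
comorbidity structure, no within-clinician temporal autocorrelation
beyond the optional decay, no seasonal vaccination effects, no competing
alerts, and no behavioral reaction of clinicians to the suppression
itself (responsiveness drift is available as a multiplicative per-week
decay, default off, which slightly perturbs the calibrated marginals when
enabled).  Passing tests therefore demonstrate that the machinery is
correct and well-calibrated under the stated cohort structure — not that
the model would reach any particular performance on a specific hospital's
data.

## Features (`features`)

`as_of` for an encounter is the day before its service date: the
deployment scores tomorrow's appointments with data available today, and
all history features use events with timestamp strictly before `as_of`
(so the most recent usable event is two days before the visit — one day
of pipeline latency plus the same-day exclusion).  Clinician history:
short-term (30-day) and long-term (full-history) interaction rates over
fired alerts, plus counts.  The "recent encounters" count includes
suppressed encounters — a visit happens whether or not its alert fired —
while rate numerators and denominators use fired alerts only, since a
suppressed alert offers no response opportunity.  Patient history: prior
alerts, interactions, orders.  Empty-history rates are NaN, passed
natively to the trees; "no history yet" stays visible as signal instead
of being imputed away.  Categorical columns are integer-encoded with the
map persisted beside the model; unseen categories at scoring time become
NaN.

The default label is interacted-or-ordered; since an order can only be
signed through the opened order set, this reduces to the interaction
flag.  An `ordered_only` labeling is available.

## Model (`model`)

XGBoost, `binary:logistic`, learning rate 0.3, max depth 6, min child
weight 1, no row or column subsampling, up to 1000 rounds with log-loss
early stopping (patience 50) on the validation fold, `tree_method=hist`,
single-threaded for reproducibility.  (One published description of this
configuration prints "maximum tree depth = 0.6", which is not a valid
depth; it is read here as 6, the conventional companion of these
defaults.)  Splits are by clinician — all of a provider's rows share a
fold — in exact 80/10/10 proportions for one-shot experiments, and by a
stable SHA-256 hash of the clinician id inside the daily loop so that
fold membership never churns as the window grows.  No class reweighting
for the ~16% positive rate by default (`scale_pos_weight` exposed).
Cross-validation is clinician-level k-fold with an inner 80/20 clinician
split providing the early-stopping monitor.

## Threshold (`calibration`)

The operating point is a suppression fraction q (default 0.5, a
stakeholder decision in deployment).  Threshold = the order statistic at
rank ⌊q·n⌋ of the validation scores (lower/type-1 quantile — always an
observed score), suppression strict (`score < threshold`).
Consequences, by construction: the realized suppressed fraction on the
derivation set never exceeds q even with tied scores; with all-distinct
scores it is within 1/n of q; all-equal scores suppress nothing; q = 1 is
the one exception, mapped to +∞.  The trade-off curve reports, per q:
ignored-among-suppressed (benefit), orders-among-suppressed, and "order
reduction" defined as suppressed orders / all rows — so at q = 1 it
equals the set's overall order rate — with suppressed-orders /
total-orders also reported in what-if summaries.  A nested clinician-level
cross-validation (outer k folds; inner 80/20 split derives the threshold;
the outer fold pays the cost) estimates out-of-sample order reduction.

## Daily loop and pilot (`pipeline`)

Each cycle, run on date d: refit from scratch (no warm start — the
simplest faithful reading of daily retraining; warm start would only
complicate reproducibility at this scale) on all fired alerts with
timestamp < d back to the fixed window start; re-derive the q-threshold
from the hash-assigned validation fold; score appointments for d + 1.
Walk-in visits (the deployed architecture never saw them) and initial
primary-care visits are excluded with explicit reasons and never
suppressed; appointments with no prior history are scored with sentinel
features, not excluded.  The pilot alternates whole ISO weeks on/off
(on-first by default; the pilot start must be a Monday).  Responses for
all pilot encounters are drawn once, up front, from the behavior model;
suppression then erases the draw for withheld alerts.  This makes (a) the
off arm byte-identical to a pipeline-free simulation under the same
seeds, and (b) a clinician's counterfactual response independent of the
decision — the correct exchangeability structure for an on/off
comparison.  Suppressed events stay in the stored log (they count as
encounters) but never become training rows, since their response is
unobservable.  An append-only ledger records one row per pilot day.

## Evaluation (`evaluation`)

ISO-week aggregates (Monday start) because of the strong weekly volume
pattern.  Alerts-per-order is reported both from counts accumulated over
each arm and from means of weekly counts.  SNR maps useful outcomes to
signal and ignored no-follow-up alerts to noise: s/(a − s), equal to
r/(1 − r) for the per-alert rate r.  Arm comparisons use the one-sided
Welch (unequal-variance) t-test with Welch–Satterthwaite degrees of
freedom, alternative "suppression reduces the metric"; the Welch form is
used because it — and not the pooled-variance test — reproduces reference
p-values computed from published weekly summaries (0.38 / 0.20 versus
pooled 0.37 / 0.18).  The daily acceptance curve is a centered 5-weekday
rolling mean (weekends dropped; endpoint windows truncate).  The
monitoring report flags any weekday whose fired-alert volume strays more
than k·SD (default 3) from its trailing 28-weekday mean.

## Problem sizes and numerical choices

Defaults are sized for a desk machine.  Reference scenario: 120
clinicians, 5000 patients, ~120 encounters/day over 26 weeks (≈ 21,700
alerts) — large enough that the calibrated marginals sit within a few
tenths of a point of their targets and cross-validation is stable.  The
pilot studies use 300 clinicians at ~80 encounters/day with the same
26-week history before a 6-week pilot: the suppression threshold is a
*median of a clinician-clustered score sample*, and its stability is
governed by the number of validation-fold clinicians, so the pilot
scenario spends its budget on cohort width rather than depth.  Bisection
tolerances are 1e-6; quantiles are exact order statistics, not
interpolations; ties in provider assignment break by interaction count,
then earliest action, then lexicographic id.

## Known limitations

The generator's independence assumptions (clinician ⊥ patient ⊥ visit
type, stationary propensities) are stronger than reality; the calibrated
marginals are exact but the joint structure is idealized.  The
suppression feedback loop — suppressed alerts vanish from response
history, freezing low responders' rates — is present in the simulation as
it would be in deployment, and is only partially mitigated by counting
suppressed encounters as exposures; long-running deployments would need
drift monitoring (the report's anomaly flags are a first line).  P-values
from 3-week arms have little power; they are descriptive, as in any short
pilot.  The CV AUROC on synthetic data characterizes the machinery under
the stated cohort structure and is not a claim about any real cohort.
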