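# Methods

This note documents the models, rules and numerical choices behind
`sepval`, and what the synthetic-data tests do and do not establish about
real data.

## Clinical classifiers

All three classifiers operate on a per-event *worst-value panel*: the most
abnormal physiologic and laboratory values abstracted from the first 28 h
of a hospitalization. Every field may be absent, and **absence is treated
as normal** — an absent value contributes zero SOFA points and never
satisfies a qSOFA or EHR criterion. Consequently, deleting a measurement
can never flip a classifier from negative to positive (a property the test
suite asserts under random field deletion), and prevalences are lower
bounds relative to fully observed data. Only events with chart-confirmed
infection as a primary reason for hospitalization are eligible to be
classified sepsis by any clinical definition; raw scores are still emitted
for ineligible events.

**SOFA.** Points 0–4 per organ system, summed over six systems; sepsis at
total ≥ 2 (the criterion is read as the *total* across systems, not ≥ 2
within one system, and no baseline subtraction is applied because only
worst in-hospital values exist). The default threshold table
(`DEFAULT_SOFA_TABLE`, fully config-overridable):

| system         | variable             | 1 pt   | 2 pt  | 3 pt  | 4 pt  |
|----------------|----------------------|--------|-------|-------|-------|
| respiratory    | PaO₂/FiO₂            | <400   | <300  | <200  | <100  |
| hematological  | platelets ×10³/µL    | <150   | <100  | <50   | <20   |
| hepatic        | bilirubin mg/dL      | ≥1.2   | ≥2.0  | ≥6.0  | ≥12.0 |
| neurological   | GCS                  | 13–14  | 10–12 | 6–9   | <6    |
| renal          | creatinine mg/dL     | ≥1.2   | ≥2.0  | ≥3.5  | ≥5.0  |
| cardiovascular | MAP / vasopressors   | MAP<70 | any vasopressor | — | — |

Two published refinements cannot be expressed on an abstracted panel and
are handled as documented switches: the requirement of ventilatory support
for respiratory points 3–4 is **off** by default
(`options.respiratory_support_required`), because support status is a
single boolean here; and vasopressor *dose* tiers (3–4 cardiovascular
points) are collapsed to a flat 2 points (`vasopressor_points`), because
doses are not abstracted. Urine-output renal tiers are likewise absent from
the panel and omitted.

**qSOFA.** Count of {altered mentation, SBP ≤ 100, RR ≥ 22}; sepsis at
≥ 2. Boundary values meet their criteria. Altered mentation is a
disjunction: GCS < 15 *or* any non-alert AVPU level (voice, pain,
unresponsive) — either source alone suffices.

**EHR.** Any one of six organ-dysfunction markers classifies the event.
The published "platelets < 100 cells/µL" is interpreted as
< 100 ×10³/µL (100 cells/µL is not physiologically meaningful; the
surveillance criterion is the thrombocytopenia threshold).

## Claims algorithms and episodes of care

Claims carry day-precision dates only, so all intervals are closed date
intervals. "Discharge date" is a claim's thru-date and "admission date"
its from-date. Inpatient claims chain-merge into one episode when a
claim's from-date is at most one day after the running maximum thru-date —
this reproduces the discharge-on-or-day-before-admission rule and also
merges overlapping stays (overlap is strictly stronger than adjacency).
The merge is the transitive closure of the pairwise relation; the tests
verify equality against a brute-force closure oracle on random claim sets.
Outpatient and carrier claims never merge with each other; one whose
from-date falls inside an inpatient episode attaches to it (contributing
its codes), otherwise it forms a singleton episode. This outpatient
handling is an explicit extension: the merging rule is stated for
inpatient claims only, but episodes are defined over all three claim
types. Diagnosis position is ignored (all listed codes count).

ICD-9 codes are canonicalized (uppercase, whitespace and decimal point
removed); code-set patterns are exact codes or trailing-`*` prefixes, where
a prefix matches strict extensions but not the bare stem. The shipped
taxonomy is a **placeholder**: explicit severe sepsis/septic shock
(995.92, 785.52), a CMS measure list (995.91, 995.92, 785.52), and
representative infection and organ-dysfunction families. Published
inventories are substantially larger; every downstream number is relative
to the taxonomy in use, which is why it lives in config.

An episode is **implicit/explicit**-positive if it has ≥ 1 infection code
AND ≥ 1 organ-dysfunction code, or ≥ 1 explicit code; **CMS**-positive if
it has ≥ 1 CMS-list code. The recorded basis is the first firing route in
the fixed order explicit → implicit → CMS.

## Linkage and exclusions

An event links to an episode of the same participant when the admission
date lies in [start, end]. With several candidates the earliest-starting,
then longest, episode wins (the multi-match count is logged; the paper's
rule is unstated and the choice affects at most that fraction). Events are
excluded, with disjoint logged reasons, when outside the study window
(default 2003-02-05 … 2012-12-31), when admitted on/after the
participant's first Part C (managed care) enrollment, or when Parts A+B
were not active on the admission date — such events are not expected in
fee-for-service claims. Claims flags are false for retained, unmatched
events. The primary-infection-in-claims subgroup (matched AND
chart-confirmed primary infection) supports the sensitivity rerun, as does
a recent-years window rerun (default 2009-01-01 … 2012-12-31).

## Agreement statistics

From each 2×2 table (index = claims algorithm, standard = clinical
criterion): observed agreement (a+d)/n, sensitivity a/(a+c), specificity
d/(b+d), PPV a/(a+b), NPV d/(c+d), and Cohen's κ = (p₀−pₑ)/(1−pₑ) with pₑ
from the marginal products. Zero-denominator statistics are reported
absent (NaN), never zero.

Confidence intervals use a **participant-clustered, bias-corrected (BC)
percentile bootstrap**: whole participants, with all their events, are
resampled with replacement (B = 1000, α = 0.05 by default). The bias
correction shifts the anchor percentiles to Φ(2z₀ ± z_{α/2}) where
z₀ = Φ⁻¹(fraction of replicates below the point estimate); replicates
exactly equal to the point estimate count as half below (mid-probability
correction; the tie rule is otherwise arbitrary), and the fraction is
clamped away from 0/1 before the normal quantile. BC rather than BCa: only
bias correction is specified for this analysis and no acceleration term is
estimated; a plain `percentile` switch exists for comparison. Degenerate
replicates (undefined statistic) are dropped with a logged count; a BC
interval that fails to bracket the point estimate is flagged with a
warning, not an abort. Resampling is implemented on per-participant cell
contributions, so with one event per participant it reduces *exactly* (same
seed, same draws) to an event-level bootstrap — asserted in tests. No
multiple-testing adjustment is applied. Outputs carry proportions; report
tables round percentages to 1 d.p.

## Mortality

Per-event follow-up runs from admission to the earliest of death, loss of
A+B coverage (end of the covering interval), first Part C enrollment, loss
to follow-up, or 90 days. In-hospital deaths count; a death tied with a
censoring date counts as a death. A same-day death or censoring
contributes 0.5 day of person-time (config-overridable) to avoid
zero-denominator artifacts. Rates are 100 × deaths / person-years
(365.25-day years), reported overall, per classifier-positive group, and
within the four cells of each claims × clinical pair; cell deaths and
person-years decompose exactly to the totals. Multiple events per
participant each contribute their own (possibly overlapping) event-anchored
follow-up, since rates are event-anchored. Proportional-hazards modelling
is deliberately out of scope; the pipeline emits an event-level survival
dataset (time in days, status, flags, covariates) for any standard fitter.

## Synthetic cohort generator

The generator emulates the five input tables with a **binary latent
sepsis state** per event (prevalence π = 0.22 by default) that jointly
drives three things, making every downstream estimate testable against
known truth:

1. **Panels** — per-field conditional distributions given the state:
   truncated normals for pressures, respiratory rate, PaO₂/FiO₂ and
   platelets; log-normals for creatinine, bilirubin and lactate;
   categoricals for GCS/AVPU; Bernoullis for vasopressors/ventilation.
   Missingness is independent per-field Bernoulli, with higher rates for
   blood-gas-derived fields (60% for PaO₂/FiO₂) than routine labs
   (10–35%). A richer multi-organ latent structure was rejected as
   unidentifiable from published marginals alone.
2. **Codes** — a linked inpatient episode exists with probability
   `match_rate` (0.95); given one, an infection code appears with
   state-independent probability 0.90, an organ-dysfunction code with
   state-dependent probability (0.068 | 0.72), an explicit severe-sepsis
   code (0.01 | 0.32) and an extra CMS-only code (0.01 | 0.215). Explicit
   codes are also CMS codes; otherwise the emitted code pools are disjoint
   across taxonomy roles, so the claims-flag operating characteristics
   against the latent state have exact closed forms
   (`expected_operating_characteristics`), e.g.
   P(implicit/explicit⁺ | s) = m·[p_e(s) + (1−p_e(s))·p_inf·p_od(s)].
3. **Deaths** — competing exponential draws per event with hazards
   (0.35 | 2.40) per person-year by state; a participant's death date is
   the earliest draw, and events after death are dropped.

Realism features that do not disturb the closed forms: stays are sometimes
split into two chained inpatient claims (exercising the merge rule),
unmatched events may leave an unrelated outpatient claim a month later,
participants carry background claims placed clear of any admission, and
coverage interruptions (A/B loss 4%, Part C 6%, loss to follow-up 3%)
trigger the exclusion and censoring paths. A minimum 150-day gap between a
participant's admissions keeps episodes from different events from
merging.

Defaults were calibrated once so that, at the default scale
(9522 participants, ~2217 analysis events), the five classifier
prevalences land within ~2 percentage points of the published marginals
(SOFA 24.4, implicit/explicit 21.1, EHR 14.9, CMS 11.2, qSOFA 8.3%), the
linked-primary fraction near 59.9%, and the SOFA-positive 90-day mortality
rate near 140 per 100 PY. A single binary state cannot reproduce all five
published group mortality rates simultaneously (observed claims-positive
groups carry excess risk beyond what clinical severity explains), so
mortality orderings are asserted directionally only. What passing tests
show is therefore that the *machinery* is correct and calibrated to the
published marginal structure — not that the generator reproduces the joint
distribution of real abstracted labs or real coding practice.

## Problem sizes and numerical notes

The default pipeline run (seeded, B = 1000) completes in seconds. The test
suite uses: an exhaustive kappa check against an independent
implementation on all 2×2 tables with n ≤ 12; episode merging vs a
brute-force closure oracle on ≤ 8 random claims per participant; a
bootstrap-coverage study of 200 simulated cohorts of 2000 participants
(B = 1000) checking 93–97% empirical coverage of the closed-form κ; and a
parameter-recovery run at ~50k analysis events (27k participants with
follow-up disruptions dialled down, which are orthogonal to the
code-assignment model) requiring agreement with the closed forms within 3
Monte-Carlo standard errors. All randomness flows from explicit seeds;
per-pair bootstrap seeds are spawned deterministically from the run seed,
and identical configuration + seed reproduces every output byte for byte
(the run manifest records the config hash, seeds and row counts needed to
do so).

## Known limitations

* The placeholder taxonomy understates real code inventories; absolute
  claims prevalences and agreement levels shift with the taxonomy.
* No ICD-10 support, no real Medicare file layouts, no DRG/procedure
  logic, no present-on-admission flags.
* Lab fields are conditionally independent given the latent state; real
  panels are correlated within organ systems.
* Exclusion uses the first Part C start even if managed care later ends
  (a literal reading of the exclusion rule).
* Identifiers are assumed exact; no probabilistic record linkage.
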