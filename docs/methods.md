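# Methods

## The indicator model

The package treats a health facility, not a patient, as the unit of
analysis. Patient-level measurements from three routine sources are
reduced to facility-level summary indicators, which are then aggregated
(within-country five-number summaries, cross-facility percentile
benchmarks) and correlated with each other. The premise is that
individual adherence cannot be observed directly — every routine measure
is an indirect proxy with a different bias — but that facility-level
summaries of several proxies, examined together, are informative about
facility performance.

All dates are ISO 8601 in files and integer day offsets in memory; every
interval is half-open `[start, end)`, which removes off-by-one ambiguity
in coverage arithmetic. Each patient's observation window is anchored at
their own index visit (a clinic day that is also a fill day) and runs
`window_days` days ("six months" = 180, "a year" = 365).

### Dispensing-based indicators

Coverage is interval arithmetic over fills. Under the default
**stockpile** policy, supply from each fill begins at the exhaustion day
of all prior supply if the patient refilled early (possession-style
accounting: dispensed days of medicine are a quantity the patient keeps);
under **truncate**, each fill covers only its literal interval and
overlap is discarded. Both policies are first-class because field
practice does not determine one; stockpile is the default since
discarding early-refill supply understates possession. Supply from fills
dated before the window never spills in: the indicator is a function of
in-window data only, at the cost of slightly understating coverage for
patients who stockpiled just before their index visit (a known
limitation).

The treatment-gap indicator flags a run of at least `gap_threshold_days`
(default 30) consecutive uncovered days. The run search starts at the
first in-window fill. Under the default `include_trailing` scope it
extends to the window end, so a patient who stops collecting — lost to
follow-up — is visible to the indicator; `between_fills_only` stops at
the last fill and reproduces the stricter between-dispensings reading. A
patient with no fills at all is scored as fully uncovered under
`include_trailing` and undefined under `between_fills_only`. "Gap" is
read as *uncovered days*, not raw inter-visit interval: with 30-day
supplies a 30-day inter-visit interval is normal, and only uncovered
time is abnormal. One consequence of anchoring the search region at the
first fill, accepted deliberately: the region is data-dependent, so
adding an *earlier* fill can lengthen the reported maximal run even
though it adds medicine (it extends the region backward). Coverage
itself is monotone in fills under both policies.

The percent-of-days-covered denominator is the fixed window length `W`,
never time-from-first-fill, and the 95%-coverage cut
(`coverage_target_pct`) uses `pct_days_covered >= 95`. Dispensing
indicators are computed for the entire sample (including lost-to-follow-
up patients) and, separately, for patients still in treatment at window
end; both variants are emitted so their facility-level correlations can
be compared.

### Attendance and self-report indicators

Appointment lateness is `attended − scheduled` in whole days; negative
is early. The punctuality windows are 0, 3 and 30 days; "within 3 days"
is the preferred single measure because with a 30-day supply and a
28-day appointment lead a patient who returns when medicine runs out is
2 days late but never uncovered. A never-attended appointment counts in
the denominator and fails every window — these flags nest (on-time ⇒
within-3 ⇒ within-30) by construction.

Exit interviews yield `pct_doses_taken = 100·(prescribed − missed)/
prescribed` over a 3-day recall and a perfect-adherence flag
(`missed = 0`). An interview with zero prescribed doses is excluded from
numerator and denominator alike. Pill-count and clinic-note self-report
indicators are deliberately not computed: the recording rates observed
in the field (15% and 45% of records) make them unusable, and the
recording *flags* exist in the data model only so the simulator can
reproduce that missingness.

### Aggregation and uncertainty

Two aggregation levels never mix. Patient-pooled percentages (each
record counts once) carry normal-approximation binomial intervals
`p ± z·√(p(1−p)/n)` with `z = 1.96` and no continuity correction; this
is the arithmetic that reproduces published survey half-widths exactly
(e.g. 96.0% at n = 373 → ±2.0) and is therefore the only CI method in
scope (no Wilson/exact option). Mean-of-percentage indicators (days
covered, doses taken) instead carry `z·SE` of the per-patient
distribution. Facility-level values feed the five-number summaries and
benchmarks; using the facility median keeps a few outlying facilities
from skewing country summaries. Percentiles are linear interpolation
between order statistics (`h = (n−1)·q`, numpy's default) — the
convention is stated here and in the CLI help because reasonable
alternatives differ at small n. Benchmarks print poor tail first; for
the gap indicator, where high is poor, the percentile axis is mirrored
(`q → 100 − q`) so every row reads poor-to-good.

An indicator that cannot be computed at a facility (no dispensing
records, no interviews, empty appointment log) is a missing value,
never zero, everywhere: in the indicator table (empty CSV cell), in
summaries (reduced facility counts), and in correlations.

### Correlation

Facility indicators are correlated pairwise with Pearson's
product-moment r over the facilities where both members of the pair are
defined (pairwise deletion — per-cell n varies with missingness), with
two-sided p from the t transform at n − 2 df, computed via
`scipy.stats.pearsonr`. With n = 2 the correlation is ±1 by construction
and reported without a p-value; zero variance in either vector leaves
the cell undefined. p-values are raw: the analysis is descriptive and
a multiplicity correction would misrepresent how such tables are read.

## The synthetic cohort generator

The generator emulates the data-generating mechanism the indicators
assume, not any particular country's data. Per patient, fills follow a
renewal process: each fill supplies `refill_interval_days` (default 30)
and schedules an appointment `appointment_lead_days` later (default 28,
the common 30-day-supply/28-day-appointment pattern). The next fill is
drawn from a three-part mixture — on time (probability `p_on_time`,
default 0.76), short delay (geometric past the scheduled day, mean
`short_delay_mean_days` = 5; geometric because it is memoryless and
one-parameter, the field data giving no delay distribution), or long gap
(probability `p_long_gap`, default 0.02 per interval: the next fill
comes `long_gap_min_days` (default 40) plus a geometric excess after the
current supply runs out). Dropout is absorbing with per-interval hazard
derived from `monthly_dropout_hazard` (default 0.01). Attendance is not
simulated independently: the attended date of each appointment *is* the
next fill date, so the dispensing–attendance correlation structure
emerges mechanically, as it does in clinics where medicine collection
and visits co-occur.

Interviews sample up to 30 patients per facility from those still
attending (a patient who dropped out cannot be interviewed at the exit
door — the same survivorship the real exit-interview design has).
Self-report over-reports by design: a patient with uncovered days
reports zero missed doses with probability `p_report_perfect_given_gap`
(default 0.55); otherwise reported missed doses are proportional to the
uncovered fraction of the window. The defaults were chosen once so that
a default-parameter population lands in the observed regimes — pooled
perfect self-report in the low-to-mid 90s while dispensing coverage sits
lower, treatment-gap prevalence near 15%, on-time attendance near 75% —
and are not tuned thereafter. Recording flags are drawn at the two
field-observed rates (pill count 15%, self-report note 45%).

Determinism is structural: a scenario seed is spawned per facility and
per patient (`numpy` `SeedSequence`), and each refill interval consumes
a fixed number of draws regardless of branch, so identical configs give
byte-identical CSVs and changing one mixture weight perturbs only the
affected branch of the affected patients. This is what makes the
monotonicity property (mean days covered non-increasing in `p_long_gap`)
testable at a fixed seed.

`study_like_scenario` builds a heterogeneous four-country survey-shaped
scenario: facility parameters drawn around the defaults with mild
country shifts, ~100 record reviews and ≤ 30 interviews per facility,
and a few facilities (default 4) that keep no dispensing records, so
missingness propagates to summaries and correlation cells exactly as it
must with real registers. A `two_cohort` flag adds, per facility, a
recent 4-month sample that contributes only appointment records,
mirroring a two-sample record review (long-term dispensing cohort +
recent attendance cohort).

What the generator does **not** model — and what passing tests therefore
do not establish about field data: re-engagement after dropout,
transfers between facilities, regimen switches or variable
days-supplied, mortality distinct from dropout, seasonal or
day-of-week clinic effects, transcription error in paper registers, and
any clinical outcome. Tests against it validate the *arithmetic and
aggregation machinery* under a plausible mechanism, not the field
values of any indicator.

## Numerical and scale choices

* Coverage uses exact integer interval arithmetic; the test suite
  checks it against an independent per-day boolean possession grid on
  randomized histories under both policies and both gap scopes.
* Percentages are computed at full precision and rendered to one
  decimal in reports.
* Facility gap-indicator recovery is validated against a direct
  Monte-Carlo renewal simulation (stdlib RNG, 10⁵ patients) at
  long-gap probabilities {0.02, 0.10, 0.25} with 2,000 patients per
  facility — within 3 binomial standard errors.
* Default analysis scales (40 facilities × 100 patients in the
  acceptance script, 12–16 facilities in invariant tests) were chosen
  as the smallest sizes at which sampling noise cannot flip the
  qualitative conclusions being checked.
* Ties and degenerate inputs: empty tables yield missing indicators
  with zero denominators; a single facility value yields a flat
  five-number summary; `p ∈ {0, 100}` yields a zero CI half-width.

## Known limitations

* The binomial intervals ignore facility-level clustering; design-based
  or random-effect intervals are out of scope on purpose (the published
  survey intervals are simple binomial, and reproducing their arithmetic
  is a goal).
* The CSV contracts are a reconstruction of what paper ART registers
  hold; real register exports will need mapping to them.
* Pre-window supply is discarded (see above), slightly biasing PDC
  downward for early-stockpiling patients.
* The simulator's behavioural distributions are stand-ins; nothing in
  the package depends on their specific shapes beyond the recovery and
  monotonicity properties tested.
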