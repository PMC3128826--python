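# Methods

## Model and assumptions

All dosing computations assume a linear, open one-compartment model with
first-order elimination: a dose *D* (bioavailable fraction *F*) distributes
instantly into an apparent volume *V*<sub>d</sub> and declines as
e^(−*k*<sub>e</sub>·t). Repeated dosing superposes linearly, giving the
accumulation ratio AR = 1/(1 − e^(−*k*<sub>e</sub>τ)) and the closed-form
steady-state peak, trough and average used throughout (`pk_core`). The model
presumes time-invariant parameters, no saturable kinetics, and no active
metabolites; renal or hepatic impairment, heart failure, and other states
that change *Cl* or *V*<sub>d</sub> are out of scope.

Oral dosing is computed as an *F*-scaled bolus. This is adequate when
absorption is essentially complete early in the interval; the package uses
the conventional cut-off *k*<sub>a</sub>/*k*<sub>e</sub> ≥ 5 and attaches a
warning to any oral computation for a drug below it (or with no
*k*<sub>a</sub> on record). Explicit first-order-absorption curves are
deliberately not modelled. Genuinely two-compartment drugs can be treated by
substituting the terminal rate constant β for *k*<sub>e</sub> and the central
volume *V*<sub>c</sub> for *V*<sub>d</sub> (`two_compartment_alias`), after
which every operation applies unchanged.

Two conventions are worth stating explicitly because the bundled data make
them visible:

* **C**<sub>ss,avg</sub> uses clearance (*F·D*/(*Cl*·τ)) while the peak and
  trough use *V*<sub>d</sub> and *k*<sub>e</sub>. The tabulated *Cl* and
  *k*<sub>e</sub>·*V*<sub>d</sub> come from independent literature pools and
  are **not** reconciled internally; for morphine they agree to 0.1%, for
  fentanyl they differ by ~67%. The identity
  C<sub>max,ss</sub>·(1 − e^(−*k*<sub>e</sub>τ))/(*k*<sub>e</sub>τ) =
  *F·D*/(*Cl*·τ) therefore holds exactly only when *Cl* :=
  *k*<sub>e</sub>·*V*<sub>d</sub>, and that is how the property is tested.
  Designs for drugs with discordant parameters can predict peaks or troughs
  outside the window even at the designed dose; these are surfaced as plan
  warnings rather than hidden by internal re-fitting.
* **Time to steady state** is the 5-half-lives rule on the *tabulated*
  half-life, while every exponential uses *k*<sub>e</sub>. The tabulated
  t<sub>1/2</sub> and ln2/*k*<sub>e</sub> disagree for several opioids
  (morphine: 3.9 h vs 2.18 h) because they were pooled independently;
  `consistency_check` flags entries deviating more than 10%. *k*<sub>e</sub>
  is authoritative for decline calculations because the worked dosing
  interval (τ<sub>max</sub> = 6.5 h for morphine's 10–80 μg/L window)
  follows from it.

## Reference data

`data/opioid_pk_parameters.csv` carries pooled population estimates for 12
opioids (13 entries: controlled-release oxycodone has two release phases):
t<sub>1/2</sub>, *k*<sub>e</sub>, *V*<sub>d</sub>/kg, *Cl*/kg, route-specific
*F*, and *k*<sub>a</sub>. Values reported per minute (the CR phase-I row) are
stored in `*_min` columns and converted on load (×60 for rates, ÷60 for the
half-life); everything is canonical after loading: μg, L, hours, μg/L.
Doses in mg appear only at I/O boundaries (×0.001 scaling).

Choices embedded in the table:

* Oral bioavailability ranges collapse to a working average, with the range
  kept as metadata. Morphine uses *F*<sub>oral</sub> = 0.40 — the value the
  reference dosing examples use, equal to the midpoint of the reported
  0.15–0.64 range. Tramadol's sex-specific 0.73/0.79 is stored as 0.76 with
  the pair kept as the range.
* The bundled morphine window is 10–80 μg/L with a 20 μg/L analgesic
  threshold (the values used by the worked examples); the narrower
  literature range 9.3–80 μg/L is exported separately as
  `MORPHINE_LITERATURE_WINDOW`.
* *k*<sub>a</sub> is reference data only; no operation derives it.
* Default body weights when a patient gives none: 86.6 kg (male), 74.4 kg
  (female) — US adult averages. An unspecified sex requires an explicit
  weight; there is no silent fallback.

## Regimen design

`design_limited_fluctuation` picks the target average as the logarithmic
mean of the window — the time-average of an exponential decline from
C<sub>max</sub> to C<sub>min</sub>, strictly between the geometric and
arithmetic means — then the longest practical interval not exceeding
τ<sub>max</sub>, then the maintenance dose rate·τ.
The practical grid defaults to {2, 4, 6, 8, 12, 24} h (user-overridable);
τ<sub>max</sub> below the smallest grid entry raises a design-infeasible
error recommending an infusion or a controlled-release form.

Rounding is half-up to a strength granularity: 5 mg by default for doses of
10 mg and above, 1 mg below, overridable. Loading/starting doses are
reported at 1 mg precision (the finer precision clinicians quote for a
one-off dose). The predicted steady state is always recomputed from the
*rounded* dose — the plan describes what would actually be administered —
and the exact value is reported alongside. Rounding drift above 5%, a
predicted peak/trough outside the window, and a trough below the analgesic
threshold (with the crossing time, solved from
C<sub>max,ss</sub>·e^(−*k*<sub>e</sub>t) = threshold) are warnings, not
errors: near-boundary dosing is a clinical judgement, not a validation
failure. A dose that rounds to zero at the finest strength is kept unrounded
with a warning.

`design_infusion` reports the post-bolus concentration from the *rounded*
loading dose, so it lands slightly off target (8 mg into 334.8 L gives
23.9 ≈ 24 μg/L against a 25 μg/L target), matching what would be observed.

## Evaluation and back-calculation

`assess_regimen` classifies the steady-state *average* against the closed
window interval (a value exactly on a bound is within the window);
`mixed` is reserved for regimens whose average is inside but whose
fluctuation breaches both bounds. Sub-threshold time per interval is clamped
to [0, τ]: a threshold above the peak means the whole interval is below.

`back_calculate_dose` inverts C<sub>ss,avg</sub> = *F·D*/(*Cl*·τ),
interpreting the observed concentration as the steady-state average with no
postmortem redistribution — an approximation, labelled as such in reports.
Forensic reports additionally quote the dose in a ×0.001-scaled,
2-significant-figure convention used in bedside summaries (e.g. a
21,900 μg/L oxycodone level with τ = 4 h reports as 3700 ≈ 4 mg); the
library value itself is always in canonical μg.

## Bootstrap pooling

The population value of a PK parameter is estimated from per-study means,
each study one independent, equally weighted data point. `bootstrap_mean`
draws `n_boot` resamples with replacement (default 1000, the convention the
bundled table was built with), reports the mean and SD of the resample
means, and a BCa 95% interval:

* bias term z₀ = Φ⁻¹ of the fraction of resample statistics below the
  observed mean, with ties counted half so discrete data cannot push z₀ to
  ±∞; the fraction is clipped to [½B⁻¹, 1 − ½B⁻¹];
* acceleration a = jackknife skewness of leave-one-out means,
  Σd³ / (6·(Σd²)^{3/2}), set to 0 when the denominator vanishes;
* endpoints at quantiles Φ(z₀ + (z₀ ± z<sub>α/2</sub>)/(1 − a(z₀ ± z<sub>α/2</sub>)))
  of the resample distribution (linear-interpolation quantiles).

All studies identical short-circuits to a degenerate zero-width estimate.
Each call uses a single dedicated seeded generator; the seed is recorded in
the output, and identical inputs and seed reproduce the estimate bit for
bit. The bundled table itself is shipped as transcribed reference data: the
underlying per-study values are not published, so the estimator is validated
by simulation, not by reproducing the table.

`generate_study_table` emulates the pooling model for tests: per-study means
drawn from Normal(μ, σ<sub>between</sub>), redrawn while non-positive so a
table can stand in for a positive PK parameter. Redrawing (rather than
clipping) keeps the mean approximately unbiased for σ ≪ μ; for σ comparable
to μ the truncation bias is real, which is why test scenarios use moderate
σ/μ. What the generator does **not** emulate: within-study sampling error,
unequal study sizes and reliabilities, reporting/selection bias, and
heavy-tailed between-study heterogeneity. Passing the simulation suite
therefore shows the estimator is correct under the stated sampling model,
not that pooled literature values are unbiased for any real opioid.

Simulation sizes used by the test suite (chosen to keep Monte-Carlo error
well below the tolerances asserted): 10,000 resamples for point-estimate
error bounds, 20,000 for interval-endpoint comparisons (including the
independent cross-check against `scipy.stats.bootstrap`'s BCa), 50,000 for
the SD-convergence check, and a coverage study of 500 replicate tables of
20 studies each. The coverage simulation uses 5000 resamples per table —
above the 1000 default — because quantile-estimation noise at B = 1000
measurably erodes empirical coverage; BCa for a mean of 20 normal studies
is known to run slightly below nominal (~92–93%) even asymptotically in B.

## Numerical conventions

* Validation errors, not clamping, for degenerate inputs (τ ≤ 0, dose ≤ 0,
  inverted windows, F outside (0, 1]).
* `accumulation_ratio` uses `expm1` for small *k*<sub>e</sub>τ accuracy; the
  identity AR·(1 − e^(−*k*<sub>e</sub>τ)) = 1 holds to machine precision.
* No rounding inside `pk_core`; rounding lives in `design` and reporting.
* Half-up rounding is floor(x/g + 0.5)·g, avoiding banker's-rounding
  surprises at midpoints.
* Writing the parameter table and reloading reproduces every numeric field
  bit-exactly (`repr` round-trip).

## Known limitations

Single-compartment misspecification, interindividual variability (~25% on
population parameters), and assay error mean predicted and measured
concentrations will differ; the package quantifies none of these beyond the
stated warnings. Biphasic controlled-release superposition is not simulated
(the CR phase parameters are stored, each phase usable separately). Dose
titration schedules, rescue dosing, equianalgesic rotation, renal/hepatic
adjustment, and metabolite kinetics are out of scope.
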