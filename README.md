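# opioidpk

Desk-scale clinical pharmacokinetics for opioid dosing: design a dosing
regimen, evaluate an existing one against a therapeutic window, back-calculate
a dose from a measured plasma level, and pool literature-reported population
PK parameters by bootstrap resampling.

The package is aimed at pharmacometrics-minded prescribers, clinical
pharmacologists, and forensic toxicologists who want the standard
one-compartment algebra — the kind done with a calculator at the bedside —
available as a tested library and command line, with the population parameter
values for 12 commonly prescribed opioids bundled.

## Model

The body is treated as a single well-mixed compartment with first-order
elimination (rate constant *k*<sub>e</sub>, h⁻¹). For repeated bolus doses *D*
with bioavailability *F* at interval τ:

- accumulation ratio **AR** = 1 / (1 − e^(−*k*<sub>e</sub>·τ))
- peak **C**<sub>max,ss</sub> = (*F·D* / *V*<sub>d</sub>) · AR, trough
  **C**<sub>min,ss</sub> = C<sub>max,ss</sub> · e^(−*k*<sub>e</sub>·τ)
- average **C**<sub>ss,avg</sub> = *F·D* / (*Cl*·τ)
- longest interval keeping the decline inside a window (C<sub>min</sub>,
  C<sub>max</sub>): **τ**<sub>max</sub> = ln(C<sub>max</sub>/C<sub>min</sub>) / *k*<sub>e</sub>
- target average for a window: the logarithmic mean
  (C<sub>max</sub> − C<sub>min</sub>) / ln(C<sub>max</sub>/C<sub>min</sub>)
  (exponential decline, not the arithmetic mean)
- loading dose **D**<sub>L</sub> = (C<sub>target</sub> − C<sub>p</sub>)·*V*<sub>d</sub>/*F*;
  constant infusion **k**<sub>0</sub> = C<sub>target</sub>·*Cl*

Oral doses are treated as boluses scaled by *F* whenever absorption is much
faster than elimination (*k*<sub>a</sub> ≥ 5·*k*<sub>e</sub>; the package
checks and warns otherwise). Two-compartment drugs can be handled by
substituting the terminal rate constant β for *k*<sub>e</sub> and the central
volume *V*<sub>c</sub> for *V*<sub>d</sub>.

The `popboot` module estimates a population parameter as the mean of
per-study means (each study one equally weighted data point), with bootstrap
SD and a bias-corrected and accelerated (BCa) 95% confidence interval.

## Worked example

Design an IV morphine regimen for the average US male (86.6 kg) holding
steady-state levels inside the 10–80 μg/L therapeutic window:

```sh
$ opioidpk design --opioid morphine --route iv --sex male --format text
Regimen plan — morphine [limited_fluctuation, route iv_bolus]
  patient: 86.6 kg (male)
  target Css,avg: 33.7 ug/L
  tau_max: 6.5 h
  dosing interval: 6 h
  maintenance dose: 25 mg (exact 25.01 mg)
  predicted steady state: Cmax 75.3 / Cavg 33.6 / Cmin 11.2 ug/L (AR 1.17)
  time to steady state: 19.5 h
  warning: trough-below-analgesic-threshold: level falls below 20 μg/L about
  4.2 h into each 6-h interval; watch for breakthrough pain towards the end
  of the interval
```

Reading the output: the target average 33.7 μg/L is the logarithmic mean of
the window; the decline from 80 to 10 μg/L at *k*<sub>e</sub> = 0.318 h⁻¹
takes 6.5 h, so 6 h is the longest practical interval; the dosing rate
33.7 μg/L × 123.8 L/h over 6 h gives 25.01 mg, rounded to a practical 25 mg.
The predicted trough (11.2 μg/L) stays inside the window but dips below the
evidence-based 20 μg/L analgesic level late in the interval, which the plan
flags.

The same library calls are available in Python:

```python
from opioidpk import Patient, design_limited_fluctuation, load_opioid_table

table = load_opioid_table()
morphine = table.lookup("morphine")
plan = design_limited_fluctuation(morphine, Patient(sex="male"), morphine.window)
print(plan.tau, plan.dose_rounded)   # 6.0 25000.0 (μg)
```

Other subcommands: `evaluate` (verdict on an existing regimen, e.g. 10 mg
oral q8h in the average male averages 4.0 μg/L — subtherapeutic), `simulate`
(concentration–time CSV over a steady-state interval), and `bootstrap`
(pool a per-study CSV into mean ± SD with a BCa 95% CI).

## Caveats

This is a decision-support calculation layer, not a clinical device.
One-compartment population parameters carry ~25% interindividual variation,
and the bundled half-life and *k*<sub>e</sub> come from independent literature
pools that are not mutually consistent for every opioid (the package exposes a
consistency check and warns). See `docs/methods.md` for the full account of
assumptions, conventions, and limitations.
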