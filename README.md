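# ventdss

Two-stage decision support for mechanical-ventilator settings.

Configuring a ventilator — breath frequency, tidal volume, inspired-oxygen
fraction (FiO2) and the pressure-/volume-support mode — is normally the
attending physician's job, and in small facilities without a lung-mechanics
team the choice rests on limited experience.  `ventdss` implements a
two-stage pipeline that assists that decision for patients with COPD, ARDS
or cerebrovascular disease (CVD):

1. **Diagnosis scoring.**  Entries are first checked against plausibility
   windows (a pH of 9.0 is flagged as a possible faulty entry, not fed
   onward).  Each candidate disease is then scored from the frequencies of
   15 clinical findings in its historical cohort: with occurrence
   proportions p_i, the score is the self-weighted average
   F = Σ w_i p_i, w_i = p_i / Σ p_j — a number that always lies between the
   smallest and largest proportion scored.  The physician confirms (or
   overrides) the top-ranked disease.
2. **Setting recommendation.**  Small multilayer perceptrons map ten inputs
   (disease code, core body temperature, pulse, systolic and diastolic
   pressure, PEEP, pSO2, pH, pCO2, bicarbonate) to the four settings: a
   tanh-hidden-layer regression net for frequency / tidal volume / FiO2 and
   a logistic-output net for the support mode.  Six training algorithms are
   implemented from the ground up — Levenberg–Marquardt, Bayesian
   regularization (evidence framework, with an effective-parameter count γ),
   one-step secant, BFGS, and cyclical-/sequential-order per-sample updates
   — and benchmarked with 10-fold cross-validation.

Because the original 158-patient hospital dataset is unavailable, the
package ships a synthetic-cohort generator that reproduces the published
statistical skeleton exactly (group sizes 30/65/63, every per-finding
abnormality count, mode frequencies) and drives the settings from a known
physiological rule, so the full pipeline is testable end to end.  See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
from ventdss import CohortSpec, generate_cohort, fit_bundle, recommend, PatientRecord
from ventdss.estimators import MLPVentilatorRegressor, SupportModeClassifier

cohort = generate_cohort(CohortSpec(seed=1))          # 158 synthetic patients
bundle = fit_bundle(
    cohort,
    regressor=MLPVentilatorRegressor(hidden_units=30, algorithm="lm",
                                     max_epochs=200, random_state=1),
    classifier=SupportModeClassifier(hidden_units=5, algorithm="bayes_reg",
                                     max_epochs=100, random_state=1),
)

patient = PatientRecord(
    patient_id="new-001", core_body_temperature=38.1, pulse=112.0,
    arterial_systolic_pressure=100.0, diastolic_blood_pressure=70.0,
    peep=8.0, pso2=86.0, ph=7.31, po2=70.0, pco2=55.0, bicarbonate=20.0,
)
result = recommend(patient, bundle, accept_diagnosis=True)
```

Output:

```
CVD: 0.7378
ARDS: 0.6442
COPD: 0.6358
accepted: CVD
frequency   29.9 breaths/min
tidal vol   349 mL
FiO2        0.26
mode        PS
```

Stage 1 ranks the three diseases by the frequency-weighted score of the
findings this patient presents (fever, tachycardia, elevated PEEP, low
saturation, acidosis, hypoxemia, hypercapnia, low bicarbonate); CVD scores
highest and, with `accept_diagnosis`, feeds stage 2.  The recommended
settings reflect the patient's physiology: an elevated pCO2 of 55 mmHg
drives the recommended breath frequency up, the PEEP of 8 cmH2O pulls the
tidal volume down, and the saturation of 86 % asks for modest supplemental
oxygen.  A record that fails the plausibility check is returned blocked,
with the offending fields listed, unless explicitly overridden.

The same flows are available from the shell:

```
ventdss generate --seed 1 -o cohort.csv
ventdss diagnose --patient cohort.csv
ventdss train cohort.csv --algorithm lm --hidden 30 -o bundle.json
ventdss evaluate cohort.csv --k 10 --seed 1 -o report.csv
ventdss recommend --patient new_patients.csv --bundle bundle.json
```

`evaluate` prints a per-algorithm "mean ±s" table of cross-validated success
rates per output parameter, where regression success is
100·(1 − mean |error| / range) and classification success is percent
agreement.

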