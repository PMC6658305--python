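# pvfever

Postvaccination fever analysis from caregiver-recorded temperature logs.

Childhood vaccinations commonly cause short, self-limiting fevers, and
caregivers increasingly log their child's temperatures and antipyretic doses
in mobile apps. Such patient-generated health data are irregularly sampled —
caregivers measure when they are worried — so characterising a fever episode
requires more than reading off a time series. `pvfever` is a reusable
pipeline for epidemiologists and biostatisticians working with this kind of
data: it extracts fever episodes from irregular temperature logs, describes
antipyretic-use behaviour, and runs the comparative statistical battery
across vaccine types and antipyretic groups. A seeded synthetic cohort
generator with known ground truth makes every stage testable end to end.

## The model

For each vaccination record, readings within the 48 h post-vaccination
window are interpolated piecewise-linearly (fever progression between
neighbouring measurements is treated as linear). With fever defined as
T ≥ 38.0 °C:

- **onset** *t*ₒₙ — first time the imputed curve reaches 38.0 °C, solved by
  exact linear inversion of the bracketing segment (if the first reading is
  already febrile, onset is that reading's time and is flagged censored);
- **offset** *t*ₒff — last time the curve falls below 38.0 °C; records whose
  final reading is still febrile yield no episode;
- **duration** = *t*ₒff − *t*ₒₙ; **Tmax** — maximum raw reading in window.

Records pass a filtering cascade (demographics present → single vaccination
per child-day → ≥ 5 in-window readings → episode with both onset and offset
→ ≥ 100 records per vaccine) before analysis. The battery comprises Welch
*t* tests (antipyretic vs no-antipyretic), one-way ANOVA with a Levene
homogeneity check and a Dunnett T3 post hoc (Welch-type pairwise statistics
referred to the studentized maximum modulus distribution — appropriate under
unequal variances), binary logistic regression of high fever
(Tmax ≥ 39.0 °C) on age, weight and sex with a VIF multicollinearity screen,
and onset-aligned mean temperature trajectories over [−3, +24] h with
straight-line decay fits.

## Worked example

```python
from pvfever import AnalysisConfig, FeverStudy

study = FeverStudy.from_simulation(
    n_children=2000, seed=42,
    config=AnalysisConfig(min_records_per_vaccine=50))
results = study.fit()
print(results.summary())
```

Output (abridged):

```
Filtering cascade (records surviving each stage):
                   input: 2081
       with_demographics: 2030
      single_vaccination: 1868
            min_readings: 1737
            onset_offset: 1017
     vaccine_min_records: 953

Antipyretic pattern: 15.85% of first doses within 1 h; cumulative 55.25% by
10 h; 86.81% of located first doses at >= 38.0 C

Maximum temperature (C): F(4,948) = 51.2, p = 4.79e-39; Levene p = 2.05e-06
  Dunnett T3 grouping: {hepatitis A, influenza} > {DTaP, Japanese encephalitis} > {pneumococcus}

High-fever logistic model [All] (n=953, events=121):
  ...
   weight_kg: B = 0.185 (SE 0.096), p = 0.0539, OR = 1.203 (0.997-1.452)

Post-onset decay (pooled across vaccines):
   no antipyretic: slope -0.050 C/h, R2 = 0.75
      antipyretic: slope -0.042 C/h, R2 = 0.90
```

Reading it: of 2,081 simulated vaccination records, 953 yield a complete
fever episode and survive all filters. Dosing behaviour concentrates at the
38.0 °C threshold; the Levene test rejects homogeneous variances, so vaccine
groups are compared with the Dunnett T3 procedure, which recovers the
three-tier reactogenicity ordering built into the generator. The medicated
group's post-onset temperature declines more slowly (−0.042 vs −0.050 °C/h):
antipyretics suppress temperature only transiently, and medicated fevers run
longer.

The same pipeline runs from the shell:

```bash
pvfever run --n 2000 --seed 42 --out out/     # simulate -> extract -> report
pvfever extract --in out/ --out episodes.csv  # on existing CSVs
```

`FeverStudy.from_csv(...)` analyses real data given the three CSV streams
(`temperatures.csv`, `vaccinations.csv`, `doses.csv`; see
`pvfever.records` for the schemas).

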