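# adhind — facility-level indicators of ART adherence and clinic attendance

HIV treatment programs in resource-limited settings need to know, per
clinic, how well patients are kept on antiretroviral therapy (ART) — but
individual adherence is private and every routine measure of it is
indirect. `adhind` computes a standardized set of facility-level
adherence and attendance indicators from the three data sources such
clinics already keep on paper:

* **pharmacy dispensing records** → proportion of days covered (PDC) by
  dispensed medicine over a fixed retrospective window, and the
  percentage of patients with a *treatment gap* (a run of ≥ 30
  consecutive uncovered days);
* **clinic appointment logs** → the percentage of appointments attended
  on or before the scheduled day, within 3 days, and within 30 days;
* **patient exit interviews** → the percentage reporting perfect
  adherence and the mean percentage of doses taken over the previous
  3 days.

It is written for program monitors, health-systems researchers, and
biostatisticians who want these indicators computed reproducibly,
aggregated per facility, benchmarked across facilities, and correlated
with each other — plus a seeded synthetic cohort generator so the whole
pipeline is testable without access to patient data.

## The statistics

For a patient with fills at days $t_1 \le \dots \le t_k$ inside a
half-open window $[0, W)$ (default $W = 180$), each supplying $s_i$ days
of medicine, coverage under the default **stockpile** carryover policy
credits fill $i$ from $\max(t_i, e_{i-1})$ where $e_{i-1}$ is the
exhaustion day of all prior supply (an early refill is banked); under
**truncate**, fill $i$ covers $[t_i, t_i + s_i)$ and overlaps are
collapsed by set union. Then

$$\mathrm{PDC} = 100 \cdot \frac{|\text{covered days}|}{W},$$

and the patient has a treatment gap if the longest run of consecutive
uncovered days — searched from the first in-window fill to the window
end (`include_trailing`, so patients lost to follow-up count) or to the
last fill (`between_fills_only`) — is at least $G = 30$ days.
Appointment lateness is $d = \text{attended} - \text{scheduled}$ days,
with attendance "within $k$ days" meaning $d \le k$ for
$k \in \{0, 3, 30\}$ and a never-attended appointment failing every
window.

Patient-pooled percentages $\hat p$ carry normal-approximation binomial
intervals $\hat p \pm z\sqrt{\hat p(1-\hat p)/n}$ with $z = 1.96$.
Facility-level values are summarized within country by median, minimum,
25th, 75th percentile and maximum; cross-facility benchmarks report the
configured percentiles poor-tail-first (orientation reversed for the
gap indicator, where high is poor). Facility indicators are correlated
pairwise (Pearson $r$, two-sided $p$ from the $t$ transform with
$n - 2$ df, pairwise deletion so $n$ varies per cell).

## Worked example

```python
from adhind import AdherenceStudy
from adhind.simulate import generate_scenario, study_like_scenario

scenario = study_like_scenario(seed=1, n_facilities=12, patients_per_facility=100)
tables = generate_scenario(scenario, "demo_data")       # writes the 5 CSVs
results = AdherenceStudy.from_tables(tables).fit()       # or .from_csv_dir("demo_data")
print(results.summary())
```

prints (excerpt):

```
Patient-pooled indicators (value +/- 1.96*SE, n)
--------------------------------------------
country                           TOTAL     Ethiopia       Kenya      Rwanda      Uganda
indicator
pct_perfect_self_report      93.3 (2.6)  100.0 (0.0)  91.1 (5.9)  88.9 (6.5)  93.3 (5.2)
mean_pct_days_covered        91.4 (1.1)   93.6 (2.0)  90.7 (1.8)         NaN  90.8 (1.9)
pct_patients_gap_ge_30       21.1 (2.8)   19.5 (5.5)  21.0 (4.6)         NaN  22.3 (4.7)
pct_attended_on_time         78.6 (1.0)   82.4 (1.8)  68.6 (2.3)  80.3 (1.9)  82.8 (1.9)
pct_attended_within_3        86.2 (0.8)   89.7 (1.5)  78.8 (2.0)  89.1 (1.5)  86.8 (1.7)
```

Reading it: pooled over every interviewed patient, 93.3% ± 2.6 reported
perfect adherence in the last 3 days; dispensed medicine covered 91.4%
of patient-days over the 180-day window; 21.1% of patients had a ≥ 30-day
gap; 78.6% of appointments were attended on or before the scheduled day.
The NaN cells are honest missingness: in this scenario several
facilities (three of them in the simulated Rwanda) keep no dispensing
records, so their dispensing indicators are undefined — not zero — and
they drop out of those summaries and of the affected correlation cells.
`results.facility_indicators`, `.pooled`, `.country_summaries`,
`.benchmarks`, `.correlations`, and `.boxplot_data()` expose the
underlying tables; `results.save("out/")` writes the whole bundle.

The same pipeline is available from a shell:

```sh
adhind run --seed 1 --n-facilities 12 --out-dir out/
adhind compute --dispensing d.csv --appointments a.csv --interviews i.csv \
    --patients p.csv --facilities f.csv --carryover stockpile --out indicators.csv
```

## Layout

| module | contents |
| --- | --- |
| `adhind.model` | `AdherenceStudy` / `AdherenceResults` — the fitting surface |
| `adhind.indicators` | coverage, gap, punctuality, self-report, facility rows |
| `adhind.summarize` | pooled CIs, five-number summaries, benchmarks |
| `adhind.correlate` | pairwise-deletion Pearson correlation matrix |
| `adhind.simulate` | synthetic cohort generator and scenario configs |
| `adhind.io` | CSV contracts, validation with reject reports |
| `adhind.cli` | `adhind simulate|compute|summarize|correlate|report|run` |

See `docs/methods.md` for the full methodological account.
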