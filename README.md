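# bcscea

Cost-utility analysis of surgical strategies for **in situ breast cancer in
Sweden**: a six-state Markov cohort model comparing **mastectomy**,
**lumpectomy without irradiation** and **lumpectomy with irradiation** over
a 30-year horizon, for health economists and HTA analysts who want a
scriptable, testable re-implementation of the published Excel-based
analysis — deterministic results, probabilistic sensitivity analysis (PSA),
cost-effectiveness planes and acceptability curves included.

## The model in brief

A cohort of 58-year-old patients enters cancer-free (state A) after
successful first surgery and moves yearly between six states — A cancer-free,
B loco-regional recurrence, C remission after recurrence, D metastasis,
E remission after metastasis, F death — under strategy-specific transition
matrices.  Evidence is converted to annual probabilities with the
constant-hazard formula

```
p = 1 − exp(−r t),        r = −ln(1 − CI) / T   (for cumulative incidences)
```

Recurrence risk (A→B) is time-dependent (follow-up windows 0–5, 5–10,
10–30 years) and is the only input that differs between strategies; the
mastectomy schedule is transferred from Swedish lumpectomy evidence via an
incidence-rate ratio of 1.27.  Age-specific background mortality from a
life table is overlaid on all living states.  Costs (2020 SEK; healthcare
and societal perspectives) and QALYs are discounted at 3 %/year and
summarised as incremental cost-effectiveness ratios

```
ICER = (Cost_A − Cost_B) / (QALY_A − QALY_B)
```

after excluding strongly and extendedly dominated strategies, then
classified against the Swedish bands (moderate = 100,000–499,999 SEK/QALY,
high = 500,000–1,000,000, …).  The PSA redraws all uncertain parameters
(Beta for probabilities/utilities, Gamma for costs, truncated Normal for
entry age) across 1,000 iterations and reports CEAC curves based on net
monetary benefit `NMB = λ·QALY − cost`.

The confidential inputs of the original analysis are replaced by
generators: a Gompertz–Makeham life table calibrated to Swedish-female-like
mortality, and a synthetic 725-patient cost registry (96 mastectomy / 629
lumpectomy) whose pooled lumpectomy arm is split on the DRG reference cost
of 36,439 SEK.  Real tables/extracts can be supplied as CSV
(`read_lifetable`, `read_registry`).  See `docs/methods.md` for the full
model description and conventions.

## Worked example

```python
from bcscea import (Strategy, default_parameters, generate_lifetable,
                    run_all, incremental_analysis)

params = default_parameters()          # packaged base case, 2020 SEK
lifetable = generate_lifetable()       # synthetic mortality schedule
results = run_all(params, lifetable)

for s, r in results.items():
    print(f"{s.value:18s} QALY={r.qaly:6.2f}  "
          f"HC={r.cost_healthcare:>11,.0f}  SOC={r.cost_societal:>11,.0f}")

cea = incremental_analysis(results, "healthcare")
icer = cea.icers[Strategy.LUMPECTOMY_RT]
print(f"ICER lumpectomy+RT vs lumpectomy: {icer:,.0f} SEK/QALY "
      f"({cea.categories[Strategy.LUMPECTOMY_RT]})")
print(f"mastectomy: {cea.dominance[Strategy.MASTECTOMY]}")
```

prints

```
mastectomy         QALY= 12.04  HC=  1,249,930  SOC=  1,445,993
lumpectomy_no_rt   QALY= 12.04  HC=    656,648  SOC=    719,682
lumpectomy_rt      QALY= 12.70  HC=    907,878  SOC=  1,068,933
ICER lumpectomy+RT vs lumpectomy: 376,173 SEK/QALY (moderate)
mastectomy: strongly_dominated
```

Mastectomy is the costliest strategy under both perspectives and is
strongly dominated; adding irradiation to lumpectomy buys 0.67 QALYs at a
"moderate" cost per QALY from the healthcare perspective (the societal ICER,
522,944 SEK/QALY, falls in the "high" band).  Absolute QALY/cost levels
depend on the mortality schedule — supply a real national life table via
`read_lifetable` for reproduction runs.

The same pipeline is scriptable from the shell:

```bash
bcscea deterministic --synthetic-lifetable --out results/
bcscea psa --synthetic-lifetable --n-iter 1000 --seed 1 --out results/psa/ --plot
bcscea synth --seed 1 --out data/        # life table + registry CSVs
```

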