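# lifehorizon

Lifetime-horizon survival and healthcare-cost analysis for
diagnosis-registry cohorts.

Chronic-disease registries follow patients for 10–20 years, but the
questions that matter — *how many years of life does this diagnosis cost,
and what will lifetime care cost?* — live beyond the end of follow-up.
`lifehorizon` answers them with the semiparametric relative-survival
extrapolation used in national claims-registry studies:

1. **Observed survival** S(t) by the Kaplan–Meier product-limit estimator
   on a monthly grid from diagnosis.
2. **Matched reference survival** S_ref(t) for sex-, age- and calendar-
   year-matched referents whose mortality follows a national life table
   (exact expectation, or Monte-Carlo simulation of referent lifetimes).
3. **Rolling extrapolation**: W(t) = logit(S(t)/S_ref(t)) is fitted with a
   restricted cubic spline, predicted one month ahead, the prediction is
   appended to the fitting window and the oldest point dropped, and the fit
   is rolled forward until S_ref ≈ 0. Under a constant excess hazard λ,
   S(t)/S_ref(t) = e^(−λt) and W(t) is asymptotically linear, which is what
   makes the linear-tailed spline a sound tail model.
4. **Life expectancy** LE = ∫S(t)dt; **loss-of-LE** = ∫S_ref − ∫S.
5. **Lifetime cost** = Σ_t S(t)·ĉ(t)·(1+r)^(−t/12), where ĉ(t) is the
   CPI-adjusted mean monthly cost among survivors, smoothed with a trailing
   precision-weighted window, discounted at r = 3%/yr, in 2017 USD
   (30.44 TWD/USD).

Uncertainty comes from a patient-level bootstrap (matched referents
regenerated per resample); group contrasts use a z-test. Because the real
national-insurance registry data are access-restricted, the package ships a
synthetic registry generator with known ground truth (Gompertz reference
mortality, additive group-specific excess hazard, Gamma monthly costs with
end-of-life escalation) so every stage is testable end to end.

It is aimed at health-economics and epidemiology analysts who have a
patient-level registry extract (or want to study the method itself on
synthetic data).

## Worked example

```python
import lifehorizon as lh

sc = lh.SyntheticScenario()          # n=10,000 synthetic registry
recs, lt, truth = lh.simulate_registry(sc)
res = lh.analyze_stratum(recs, lt, name="all")
e, c = res.extrapolation, res.cost
print(f"LE after diagnosis : {e.le:6.2f} years")
print(f"Reference LE       : {e.le_ref:6.2f} years")
print(f"Loss of LE         : {e.loss_of_le:6.2f} years")
print(f"Lifetime cost      : ${c.lifetime_cost:,.0f} (2017 USD, 3%/yr discount)")
print(f"Cost per life-year : ${c.cost_per_life_year:,.0f}")
```

prints

```
LE after diagnosis :  23.65 years
Reference LE       :  28.37 years
Loss of LE         :   4.72 years
Lifetime cost      : $56,026 (2017 USD, 3%/yr discount)
Cost per life-year : $2,369
```

Read: a cohort diagnosed at mean age ~53 would live another 28.4 years
under general-population mortality; the disease's excess mortality removes
4.7 of them. The expected discounted lifetime healthcare cost is ~$56k,
i.e. ~$2.4k per expected life-year. (The generator's truth for this
scenario is LE 22.91 / loss 5.47 years — single-run agreement is limited by
the extrapolation's Monte-Carlo noise at n = 10,000; see
`docs/methods.md`.)

The same analysis, stratified and file-driven, from the shell:

```bash
lifehorizon simulate --out-dir sim/                 # patients, costs, life table, truth
lifehorizon estimate --patients sim/patients.csv --costs sim/costs.csv \
    --life-table sim/life_table.csv --bootstrap 200 --out-dir out/
lifehorizon report --results out/results.csv
```

`estimate` writes full-precision `results.csv` (one row per stratum:
depression status/subtype, sex, age band), `ztests.csv`, per-stratum
survival curves and a `run_log.yaml` recording every setting. A
`--min-dx-year 2003` flag reproduces the restriction to the
biologics-era subcohort.

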