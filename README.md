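# statincea

A lifetime Markov cohort cost–utility model comparing **high-intensity
statin (HIS)** against **low-to-moderate-intensity statin (LMIS)** for
secondary prevention in post-hospitalized acute coronary syndrome (ACS)
patients, from the Indonesian payer perspective. It is aimed at health
economists and health-technology-assessment analysts who want a fully
scriptable, testable re-implementation of this decision model — base-case
ICER, probabilistic sensitivity analysis (PSA), cost-effectiveness
acceptability curves (CEAC), tornado diagram data, and a
modelling-convention sweep.

## The model

Five health states: Resolved ACS (**RA**), Myocardial Infarction (**MI**),
Cardiac Arrest (**CAr**), Revascularization (**Rv**) and Death (**D**,
absorbing). The whole cohort enters at age 30 in RA and advances in 1-year
cycles to age 100. Event-state mortality (tpMI_D, tpCAr_D, tpRv_D) is
age-banded in 5-year bands from 30–34 to 80–84, the last band held for
older ages. The HIS arm differs only through three hazard ratios applied
to transitions into MI, CAr and Rv (HR 0.77, 1.07, 0.73).

Each cycle accrues per-state direct medical costs (Indonesian INA-CBGs
tariffs, in IDR), the annual statin cost for everyone alive
(3,908,568 IDR/yr for HIS vs 1,474,656 IDR/yr for LMIS) and
utility-weighted life-years. Costs are discounted at 3% per year; QALYs
are left undiscounted in the base case (see `docs/methods.md` for why).
The headline statistic is the incremental cost-effectiveness ratio

```
ICER = (Cost_HIS − Cost_LMIS) / (QALY_HIS − QALY_LMIS)   [IDR per QALY]
```

judged against two Indonesian willingness-to-pay thresholds:
192,514,839 IDR/QALY (stated WTP for life-saving disease) and
206,319,831.79 IDR/QALY (3× GDP per capita).

The PSA redraws every uncertain parameter per iteration — Beta for
probabilities and utilities, Gamma for costs, Lognormal for hazard ratios,
each moment-matched to the published mean and SE — and reruns both arms
with the same draw. The one-way analysis moves one parameter at a time to
mean ± 1.96·SE and ranks parameters by ICER spread.

## Worked example

```
$ statincea base-case --out-dir results/base
HIS: cost 690,602,617.70 IDR, 49.6843 QALY
LMIS: cost 612,483,053.73 IDR, 47.4040 QALY
HIS vs LMIS: ICER 34,258,686.19 IDR/QALY
```

Per patient over a lifetime, high-intensity therapy costs
78,119,563.97 IDR more and gains 2.2803 QALYs, i.e. about 34.26 million
IDR per QALY gained — well below both WTP thresholds, so HIS is
cost-effective in the base case. `results/base/` also holds the
per-cycle traces, a JSON summary and a manifest of the exact
configuration.

```
$ statincea psa --n 1000 --seed 1 --out-dir results/psa
PSA n=1000: ICER (ratio of means) 34,086,703.89 IDR/QALY; resampled draws: 0
```

The CEAC table written alongside shows HIS cost-effective in 100% of the
1000 draws at both thresholds. `statincea owsa` writes the tornado table
(the cost discount rate has the widest ICER spread), and
`statincea sweep --reference <icer>` enumerates all 128 combinations of
the modelling-convention switches and ranks them by deviation from a
reference ICER.

The same pipeline is available as a library:

```python
from statincea import ModelConfig, builtin_table1, evaluate_strategy, icer

p = builtin_table1()
res = icer(evaluate_strategy(p, "HIS"), evaluate_strategy(p, "LMIS"))
print(res.icer)  # 34258686.19...
```

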