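# tregmap

Pulse-chase fate-mapping analysis of regulatory T cell (Treg) pool ontogeny
and turnover across mouse tissues.

## The problem

Foxp3⁺ Tregs colonize lymphoid and nonlymphoid organs starting shortly after
birth, but the adult pool of each tissue is assembled on very different
schedules: lymphoid organs renew continuously, while tissues such as the skin
retain a large cohort of neonatally generated cells with minimal adult
turnover. Tamoxifen-inducible fate mapping reads this out: a pulse given in
week *w* of life heritably tags every Treg generated up to the end of the
recombinase activity window, so the tagged fraction measured at a common
analysis age is a *cumulative* readout of pool generation through week *w*.

`tregmap` provides, for users analysing such experiments or designing new
ones:

* **a cohort-structured simulator** of tissue Treg pool assembly — daily
  generation influx *g(t)*, per-cell division probability *π(t)*, birth-day
  dependent loss (residency), a finite labeling window with per-tissue
  tagging efficiency *E*, mouse-level overdispersion (Beta, concentration
  *κ*) and finite flow-cytometry sampling — with an exact expectation engine
  usable as an oracle;
* **the retrospective decomposition**: per-pulse-week group medians
  *F<sub>w</sub>* → efficiency correction *F̂<sub>w</sub> = min(F<sub>w</sub>/E, 1)* →
  isotonic (pool-adjacent-violators) projection onto nondecreasing cumulative
  values → per-week increments *p<sub>w</sub> = F̂<sub>w</sub> − F̂<sub>w−1</sub>*
  with a "generated later" tail, bootstrap CIs and 10×10 waffle rendering;
* **turnover estimation**: two-point replacement rates
  *r = ln(F₁/F₂)/(t₂−t₁)*, exponential-with-plateau label-decay fits
  *F(t) = π<sub>res</sub> + (F₀−π<sub>res</sub>)e^{−r(t−t₁)}* with half-lives,
  and constant-pool persistence ratios;
* **paired marker statistics**: exact Wilcoxon signed-rank comparison of
  marker-positive fractions between tagged and untagged Tregs within mice,
  with Benjamini–Hochberg FDR control.

A bundled scenario (`tregmap/datasets/paper_scenario.yaml`) encodes the
published per-tissue kinetics (spleen, lymph nodes, lungs, liver, colon with
GATA3⁺/RORγt⁺/double-negative subsets, visceral adipose tissue, skin); the
daily influx is solved at load time from the declared cumulative targets, so
the generative model reproduces them exactly in expectation.

## Worked example

```python
from tregmap import (load_scenario, simulate_cohort,
                     PoolCompositionModel, LabelDecayModel, waffle_text)

scn = load_scenario()                                   # bundled scenario
cohort = simulate_cohort(scn, "ontogeny", seed=1)       # 480 mice, 6 pulse weeks
res = PoolCompositionModel(cohort, "skin", scn.efficiency).fit(bootstrap=1000, seed=7)
print(res.summary())
```

```
Treg pool composition by generation week -- tissue: skin
group statistic: median; efficiency: 0.990; bootstrap: 1000
  week  increment  cumulative  [95% CI]
     1      0.602       0.602  [0.553, 0.660]
     2      0.242       0.844  [0.161, 0.295]
     3      0.043       0.887  [0.010, 0.093]
     4      0.004       0.891  [0.000, 0.057]
     5      0.041       0.932  [0.000, 0.076]
     6      0.029       0.961  [0.000, 0.090]
    >6      0.039       1.000  [0.008, 0.050]
```

About 60% of the adult skin pool is estimated to arise in the first week of
life and ~84% within the first two — the strong neonatal bias that
distinguishes skin from lymphoid tissue (run the same model with
`tissue="LN"` to see ~25% by week 2). `waffle_text(res.waffle(), ...)`
renders the familiar 10×10 dot-plot view of the same composition.

Label decay after an adult (week-10) pulse quantifies renewal:

```python
adult = simulate_cohort(scn, "adult_pulse", seed=2)
print(LabelDecayModel.from_cohort(adult, "spleen").fit().summary())
```

```
Label-decay fit -- spleen (free plateau, 4 timepoints)
  F0            : 0.9640
  plateau       : 0.5662
  rate (per wk) : 0.17926
  half-life (wk): 3.87
  SSE           : 1.456e-02
```

The splenic tagged fraction decays towards a plateau of non-replaced cells —
continuous renewal — whereas the same fit for skin or VAT stays high.
`two_point_rate(0.60, 8, 0.35, 28)` gives the skin's neonatal-label
replacement rate, ≈0.027/week (half-life ≈26 weeks).

The command line mirrors the library:

```sh
tregmap simulate --seed 1 --out cohort.csv
tregmap reconstruct --cohort cohort.csv --tissue skin --efficiency 0.99 --out composition.csv
tregmap turnover --cohort adult.csv --tissue VAT --out decay.csv
tregmap phenotype --cohort cohort.csv --tissue lungs --out report.csv
tregmap all --outdir run/           # full pipeline, deterministic per seed
```

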