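# dcflux

Kinetic modelling of dendritic-cell (DC) trafficking from an immunisation
site in skin to the draining lymph node (dLN), as measured with
photoconvertible (Kaede) reporter mice.

In a Kaede photoconversion experiment, cells present in the footpad at the
moment of violet-light exposure switch irreversibly from green to red; any
red cell later found in the popliteal lymph node must have migrated there
from the footpad. Counting red cells in skin and dLN across photoswitch and
harvest schedules yields time courses that a compartmental model can turn
into rates, delays and residence times. `dcflux` implements that model,
fits it simultaneously across treatment conditions (alum/LPS inflammation
vs saline steady state) and photoswitching strategies, selects among
candidate migration-rate structures by AIC, and reports the biological
summaries.

## The model

A photoconverted cohort of `x0` cells is labelled in skin at time `t_pc`
(hours post-injection). Cells leave skin with a per-cell hazard μ(t), spend
a fixed transit time τ in the lymphatics, and are then lost from the dLN
(death and egress conflated) at a first-order rate δ:

```
X(t) = x0 · exp(−∫_{t_pc}^{t} μ(s) ds)                                 skin
Y(t) = ∫_{t_pc}^{max(t_pc, t−τ)} μ(s) X(s) e^{−δ(t−s−τ)} ds            dLN
```

with condition-specific hazards

```
μ_saline(t) = μ0                 μ_alum(t) = μ0 + α·t·e^{−m·t}
```

The inflammatory pulse peaks at `t = 1/m` at a fold-change
`1 + α e^{−1}/(m μ0)` over baseline. Fitting is least squares on
`ln(count + 1)`, simultaneous over both sites, both conditions and all
photoswitching strategies, with multi-start Nelder–Mead on log-transformed
parameters; candidate models (constant vs pulsed alum hazard, shared vs
per-condition δ) are compared with the least-squares AIC
`n·ln(RSS/n) + 2(k+1)`. Derived summaries follow first-order kinetics:
half-life `ln2/rate`, mean residence `1/rate`, and the labelling time
`t(f) = T·ln(1/(1−f))` for a pool with mean turnover time `T`.

## Worked example

```python
import dcflux as dc

truth = dc.canonical_parameters()          # mu0=1/132, tau=2.6 h, pulse peak 26 h
syn = dc.simulate_dataset(dc.study_designs(), truth, seed=1)

table = dc.compare_models(syn.dataset,
                          settings=dc.OptimizerSettings(n_starts=4, seed=0))
print(table.summary())
print(table[table.winner].summary())
```

prints (abridged):

```
Model selection (least-squares AIC)
------------------------------------------------------------
model  k      rss     aic delta_aic akaike_weight
   M3 20   7.6188 -857.73      0.00         1.000
   M2 19   9.5135 -802.87     54.86         0.000
   M1 18  56.1210 -350.52    507.21         0.000
   M0 17 234.9583   14.04    871.77         0.000
winner: M3

model:       M3
n obs:       256    free params: 20
...
dLN half-life (alum):        9.53 h
dLN half-life (saline):      4.03 h
skin mean residence:         6.09 d
transit time:                2.15 h
peak migration at:          28.89 h (10.8-fold)
```

The pulsed-alum/per-condition-δ model (M3) wins decisively, and the fitted
summaries sit close to the generating truth (alum dLN half-life 9.5 h,
saline 3.8 h, skin residence 5.5 d, peak at 26 h, 10-fold): labelled DC
persist longer in an inflamed node, and inflammation transiently boosts
skin egress roughly ten-fold around one day post-challenge. The transit
delay τ is weakly identified on these sparse schedules (no dLN harvest
earlier than 12 h after photoconversion) — bootstrap intervals for τ span
more than an order of magnitude, which is why the dense 2-h schedule of
`dc.dense_designs()` exists.

The same pipeline runs from a shell:

```
dcflux --seed 1 simulate --designs study --out data.csv
dcflux --seed 1 select --data data.csv --out selection.json
dcflux --seed 1 fit --data data.csv --model M3 --n-boot 100 --out fit.json
dcflux report --fit fit.json --out summary.json
```

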