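# Methods

## Model

`dcflux` models a single photoconverted cohort per photoswitching strategy.
At the photoconversion time `t_pc` (hours post-injection; the package uses
the post-injection clock throughout, converting photoconversion-relative
harvest times only at the CSV reader boundary), `x0` cells in skin carry the
red label. Three processes follow:

1. **Skin egress.** Each labelled cell leaves skin with hazard μ(t):
   constant `μ0` under saline, `μ0 + α t e^{−mt}` under alum/LPS. All skin
   loss is migration — no death or proliferation in skin is modelled — so
   the labelled skin pool is the survival curve
   `X(t) = x0 exp(−M(t_pc, t))` with the cumulative hazard `M` available in
   closed form. The mean skin residence time at steady state is therefore
   `1/μ0`.
2. **Lymphatic transit.** Every egressing cell reaches the dLN after a
   fixed delay τ. Cells in transit are counted in neither site.
3. **dLN loss.** Labelled cells in the dLN are removed at a first-order
   rate δ that deliberately conflates death and egress; δ may differ
   between conditions.

The dLN balance is solved as an explicit convolution integral (equivalent
to the delay differential equation with `Y(t_pc) = 0`), not with a generic
DDE stepper: the integrand is smooth and exponentially damped, the form is
exactly testable against closed-form special cases, and the delay enters
only as a shift of the integration limit.

Assumptions worth keeping in mind: one lymph node; no re-entry of cells
into skin; no label dilution (photoconversion is irreversible on the
experiment's time scale); the unlabelled (green) population is not
modelled; counts, not percentages, are the observable.

## Numerics

* **Quadrature.** The convolution is evaluated with a composite
  Gauss–Legendre rule (12 panels × 6 nodes, mapped onto the exact
  integration span of each prediction). For these integrands the rule
  agrees with the constant-hazard closed form to machine precision and
  with a midpoint Riemann sum at dt = 0.001 h to ~1e-10 relative. A
  left-endpoint Riemann sum at the same dt carries its own first-order
  bias of about 1e-5 near sharp early transients, which is why the
  midpoint rule serves as the brute-force oracle in the tests.
* **Degeneracy.** The constant-hazard closed form switches to its
  L'Hôpital limit when |μ − δ| < 1e-8 per hour to avoid catastrophic
  cancellation.
* **Overflow safety.** All quadrature exponents are ≤ 0 on the true
  integration domain; they are clipped at 0 so that zero-span dummy rows
  (harvests inside the transit window) cannot overflow for extreme
  parameter proposals during optimisation.

## Fitting

The objective is `Σ [ln(count + c) − ln(prediction + c)]²` with offset
`c = 1` cell: the observation noise is multiplicative and counts span
orders of magnitude, so log-scale residuals weight sites and conditions
comparably; the one-cell offset keeps zero counts (harvests inside the
transit window) finite. On noiseless data the objective is exactly
scale-free: multiplying all counts by a constant moves only the fitted
pool sizes.

All rate and time parameters are optimised as natural logarithms
(positivity by construction) with multi-start Nelder–Mead: the first start
comes from moment heuristics (saline skin log-slope for μ0, late dLN
log-slopes for δ, earliest dLN lead time for τ, the alum/saline dLN ratio
for the pulse amplitude), the rest are log-uniform perturbations of ±1.5
decades. If the best run ends on the iteration cap, one restarted simplex
polishes it. Ties in the final loss are broken deterministically toward
the lexicographically smallest log-parameter vector.

**Initial pool sizes.** One `x0` is fitted per (condition, photoconversion
time) strategy rather than per design row: two designs that photoswitch the
same condition at the same time observe the same physical pool, so sharing
the parameter is both more parsimonious and better identified than a fully
free per-design policy. Because predictions are proportional to `x0`, these
parameters are separable: the inner minimisation over each group's log-x0
is solved by a short Newton iteration inside the objective (concentrated /
profiled least squares), and Nelder–Mead searches only the shared kinetic
parameters — 3 to 6 dimensions instead of up to 20. A
`from-recruitment-curve` policy (pool sizes tied to a fitted recruitment
curve) is available as an alternative.

**Identifiability.** If a dataset has no dLN harvest earlier than 12 h
after photoconversion, τ is flagged weakly identified: the data then
constrain τ only through its small effect on the accumulation integral,
and bootstrap intervals for τ open up to more than an order of magnitude.
The dense 2-h harvest schedule (`dense_designs`) removes the flag and
pins τ to ~±10%.

**Uncertainty.** Confidence intervals are percentile bootstrap over
replicate mice, case-resampled within each (design, site, harvest) cell
and refitted warm-started from the point estimate. Whether to prefer
profile likelihood instead is an open choice; the percentile bootstrap was
chosen because the replicate structure makes cell-wise resampling natural
and it needs no curvature assumptions.

## Model family and selection

Four candidates span the structural questions — is the alum hazard pulsed,
and does dLN loss differ between conditions?

| label | alum hazard | saline hazard | δ | free kinetic params |
|---|---|---|---|---|
| M0 | constant | constant | shared | μ0, τ, δ |
| M1 | constant | constant | per-condition | μ0, τ, δ_a, δ_s |
| M2 | pulse | constant | shared | μ0, α, m, τ, δ |
| M3 | pulse | constant | per-condition | μ0, α, m, τ, δ_a, δ_s |

Members are compared on the identical dataset with the least-squares AIC
`n ln(RSS/n) + 2(k+1)`, counting the residual variance as a parameter and
every fitted `x0` in `k`; AICc is available behind a flag for small-n work
but AIC is the default criterion. Fits proceed in order of increasing
complexity and each model warm-starts from the optima of the models nested
within it, which guarantees nested RSS monotonicity. If a simpler nested
model lies within ΔAIC < 2 of the minimum, it is reported as the winner
(flagged), reflecting the usual parsimony convention.

## Synthetic data

The generator emulates the experimental designs the model was built for:

* **Schedules.** Three families, both conditions, n = 4 mice, skin + dLN:
  delayed-switch (photoswitch 0/4/8/12 h, harvest 24/48 h), fixed-switch
  (photoswitch 12 h, harvest 24/36/48/72 h) and sliding-switch
  (photoswitch 12/24/36/60 h, harvest 12 h later).
* **Canonical truth.** μ0 = 1/132 h⁻¹ (5.5-day skin residence), τ = 2.6 h,
  m = 1/26 h⁻¹ (peak at 26 h), α = 9 μ0 m e (10-fold peak), δ_alum =
  ln2/9.5 h⁻¹, δ_saline = ln2/3.8 h⁻¹.
* **Recruitment.** The photoconvertible pool available at `t_pc` is
  `r0 + β t_pc e^{−b t_pc}` under alum (flat `r0` under saline), with
  defaults r0 = 500 cells, peak 3 × r0 at 18 h — the same rise-then-fall
  family as the migration pulse, calibrated to the observed ~3-fold rise
  of skin DC numbers over the first day. Only the shape is constrained by
  the biology; the functional form and the absolute scale r0 are package
  choices, and all recovery targets are rates/times, which are scale-free.
* **Noise.** Mean-one multiplicative lognormal noise per mouse,
  σ² = ln(1 + cv²) with the mean-correcting shift, default cv = 0.2 —
  replicate SDs in this kind of count data scale with the mean. Counts are
  real-valued by default; an optional Poisson layer exists but is off,
  since the fitted quantities are means.

What passing recovery tests therefore show: *given* this noise structure
and these schedules, the pipeline returns the generating rates. They do
not certify the error model of any real experiment (mouse-level random
effects, gating variability and counting error are not emulated), nor the
recruitment dynamics, which real data would have to inform.

## Problem sizes used in the validation experiments

Parameter recovery uses 100 simulated studies on the sparse schedules and
40–100 on the dense 2-h schedule; selection operating characteristics use
100 seeds under the pulse truth and 50 under the null; bootstrap widths use
60–80 draws. Study fits use 5 Nelder–Mead starts (selection: 2 plus
nested warm starts) with the 1e-4 simplex tolerance — the medians reported
by these experiments are insensitive to further starts or tighter
tolerances, which is how these sizes were chosen. The full-precision
defaults (20 starts, 1e-6 simplex tolerance, 5000 iterations) remain the
`OptimizerSettings` defaults for single-dataset analyses. A formal
bootstrap coverage simulation (hundreds of datasets × hundreds of draws)
is out of the validation suite's scope; the qualitative checks (collapse
at cv = 0, decade-wide τ intervals on sparse designs) stand in for it.

## Known limitations

* δ conflates death and egress by construction; the data cannot separate
  them.
* Percentage-of-LN readouts are not modelled, only counts.
* The pulse form `α t e^{−mt}` is one convenient unimodal family; the data
  constrain its rise-peak-decay shape, not the algebraic form.
* With free pool sizes, μ0 is informed almost entirely by the skin decay
  curves; designs without skin harvests leave it nearly unidentified.
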