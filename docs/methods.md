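# Methods

## Model structure and assumptions

The model tracks one adolescent in continuous time with three stocks:
depressive symptoms `D` (CDI units), rumination `R` (response-styles
subscale rescaled to 0–39 by removing the 13-point instrument floor, so the
published means of ~10–13 sit in the interior of the scale), and past
stressors kept alive `S` (life-event units). Each of `D` and `R` adjusts
with a first-order delay toward a linear indicated value; `S` is a bathtub
filled by the ongoing-stressor rate `u(t)` and drained at `S/M`, where the
memory time `M = max(θ9·R, M_min)` grows with rumination:

    τ_R dR/dt = (θ1 + θ2·D + θ3·G + θ4·S + θ5·R + εR) − R
    τ_D dD/dt = (θ6 + θ7·R + θ8·D + εD) − D
        dS/dt = u − S/M

Key assumptions: all behavioral couplings are linear (the only
nonlinearities are the memory-time floor and the instrument clamps);
process noise enters the indicated values, not the stocks, so noise-free
fixed points are exact; gender acts solely through the additive rumination
shift θ3; stressor exposure is a constant individual rate (real life events
arrive in bursts — see Limitations).

The self-coefficients θ5 and θ8 sit *inside* the indicated values, so the
continuous model and a discrete one-month autoregressive reading share the
fixed point `D* = (θ6 + θ7·R)/(1 − θ8) ≈ 10.7` at the cohort mean
rumination 11.59 — consistent with observed mean CDI ≈ 9.5–9.8. With the
shipped estimates, the closed-form fixed point for a girl at mean inflow
(4.97 events per 6 months) is `(D*, R*, S*) = (9.90, 10.32, 12.60)`, and
the loop gain `g = θ5 + θ2θ7/(1−θ8) + θ4·u·θ9` reaches 1 at
`u ≈ 1.53` events/month: above that, no finite fixed point exists and
trajectories grow until clamped.

## Parameters

| name | meaning | default | units |
|---|---|---|---|
| θ1 | rumination constant | −1.2504 | score |
| θ2 | depression → rumination | 0.4236 | – |
| θ3 | gender (girl) shift on rumination | 2.5152 | score |
| θ4 | active stressors → rumination | 0.2518 | score/event |
| θ5 | rumination self-coefficient | 0.1639 | – |
| θ6 | depression constant | 0.3730 | score |
| θ7 | rumination → depression | 0.0699 | – |
| θ8 | depression self-coefficient | 0.8894 | – |
| θ9 | rumination → memory time | 1.4741 | months/score |
| θ10 | rumination-noise stationary SD | 7.8735 | score |
| θ11 | depression-noise stationary SD | 0.0002 | score |
| θ12 | noise correlation time | 1.6008 | months |

Numerical settings: stock adjustment times `τ_R = τ_D = 1` month (one Euler
month corresponds to one step of the discrete autoregressive reading;
exposed in config), integration step `dt = 0.125` month (explicit
Euler–Maruyama; the validation `dt ≤ min(τ_R, τ_D, θ12)/4` keeps the scheme
stable, and halving `dt` moves noise-free trajectories by < 0.1%), clamps
`D ∈ [0, 52]`, `R ∈ [0, 39]`, `S ≥ 0` (instrument ranges), memory-time
floor `M_min = 0.25` month (outflow cannot be faster than the weekly recall
scale of the instruments; prevents division blow-up as `R → 0`). θ10/θ11
are stationary standard deviations (their table row is labelled "Standard
Deviation" despite a σ² symbol).

## Noise process

εR and εD follow the AR(1) discretization
`ε' = ε(1 − dt/θ12) + q·z`, `z ~ N(0,1)`, with the innovation SD
`q = σ·sqrt((dt/θ12)(2 − dt/θ12))` chosen so the stationary SD equals σ
*exactly* (plain Euler–Maruyama scaling `σ·sqrt(2dt/θ12)` would inflate it
by ~2% at the default step). The lag-Δ autocorrelation is
`(1 − dt/θ12)^(Δ/dt)`, the Euler approximation of `exp(−Δ/θ12)` (0.522 vs
0.536 at Δ = 1 month). Noise states are initialized from their stationary
distribution, so the 7-month study-horizon simulations carry no burn-in
transient. Setting σ = 0 recovers deterministic geometric decay.

## Synthetic cohort

The generator emulates the study design: 353 girls and 308 boys; initial
conditions drawn as independent truncated normals per gender matched to the
published wave-1 means/SDs (girls D 9.98/6.45, R 12.78/7.71, S 4.97/3.14;
boys 8.91/6.04, 10.23/7.06, 4.96/3.52); waves at months 0/4/7 with
rumination observed at all three waves and depression/stressors at waves 1
and 3 only; observations rounded to integers and clipped to instrument
ranges. Each individual's constant inflow is their baseline six-month
checklist count divided by 6. Measurement noise defaults to 0 (the
estimation treats process noise only).

What the generator does **not** emulate: baseline cross-correlations among
D0, R0, S0 (not reported; independence is assumed, configurable), attrition
and missing-not-at-random patterns, bursty life-event arrival, and item-level
instrument structure. Tests passing on these cohorts therefore establish
internal consistency of the pipeline, not fit to the original data.

### Initial stressor-stock conventions

The checklist counts events over the past six months — a *flow* measure —
while the model state is the *stock* of stressors still kept alive. Two
mappings are provided:

* `count` (cohort default): stock = count. This is the plainest reading and
  the convention used for the memory-time cohort experiment.
* `balance` (experiments default): stock = (count/6) × M(R0), the level a
  sustained history at that event rate implies given the individual's
  memory time. High ruminators accumulate far more than the raw count
  (group 1 of the factorial: 56.6 vs 11.25).

The factorial and sensitivity experiments default to `balance` because only
that convention reproduces the documented qualitative trajectory shapes —
immediate symptom growth in the sustained-stressor all-high group and a
rise-then-decline hump when ongoing stressors stop — whereas under `count`
both groups first dip for ~16 months while `S` builds up. Both conventions
are exposed (`CohortSpec.s0_mode`, `s0_mode=` on the experiment functions).

## Indirect inference

The auxiliary-statistic vector contains, per gender: means and sample SDs
of rumination at waves 1–3 and of depression and stressors at waves 1 and 3
(28 entries), plus the correlations corr(R1,R2), corr(R2,R3), corr(D1,D3),
corr(S1,S3), corr(R1,D3), corr(D1,R3), corr(S1,R3), corr(S1,D3) (16
entries) — the moments a three-wave, two-instrument-schedule design
identifies. The objective is the diagonal weighted quadratic distance
between observed and simulated statistics, with weights the inverse
variances of the observed statistics from a 500-replicate nonparametric
bootstrap over individuals (full optimal weighting is out of scope).
Degenerate statistics (zero variance) get correlation 0 with a warning and
weight 0.

Common random numbers — the same seed set at every θ — make the objective
deterministic and exactly zero when the candidate equals the
data-generating parameters under the same streams. Minimization is
Nelder–Mead with perturbed restarts (default 10; simulated objectives
remain kinked in θ even with common random numbers because observations are
rounded to instrument integers). Each evaluation averages statistics over
`n_sim = 5` synthetic cohort copies for variance reduction. Standard errors
are parametric-bootstrap: resimulate B panels at the estimate, re-estimate
each, take the spread; non-convergent replicates are dropped (error if
fewer than B/2 survive).

Recovery behavior at the shipped estimates: on panels of 5,000 individuals,
(θ7, θ8, θ9) are recovered within ±25% (typically within a few percent for
θ7/θ8), with absolute errors ordered θ7, θ8 < θ9 — matching the ordering of
their reported standard errors. The full 12-parameter problem is weakly
identified from three waves (θ1/θ2/θ5 trade off against each other), which
is why the recovery experiment fixes the well-identified subset.

## Experiments

* **Memory time.** Each individual's `M(t)` is averaged over every
  integration step of the 7-month horizon (unweighted, endpoints included),
  then averaged within groups: all girls/boys, and initially depressed
  individuals (CDI > 16) split at the published overall mean rumination
  11.59 (fixed, not recomputed). Gender contrasts use Welch's t-test.
* **Factorial.** 16 groups per gender: initial depression and rumination at
  mean ± 1 SD, prior stressors and six-month ongoing-stressor totals at
  mean + 2 SD (high) or 0 (low, avoiding negative counts); inflow varies
  fastest in the group ordering, then prior stressors, then rumination,
  then depression. 2,500 replicates per group over 120 months, identical
  inputs, independent noise streams; per-month mean, 12.5th/87.5th
  percentile envelope (numpy linear-interpolation percentiles; the
  estimator is not specified in the source material) and fraction above the
  clinical cut-off 16.
* **Sensitivity grid.** Mean symptoms at month 120 over an initial
  rumination × inflow grid with depression and prior stressors at the
  girls' means (9.98, 4.97); 100 noise replicates per cell by default, or a
  single deterministic run with noise off.

## Design choices in open territory

* Exact supplementary equations of the source model are not available; the
  linear indicated-value forms above are a reconstruction that reproduces
  the published fixed-point magnitudes and loop-gain behavior but not every
  published simulation number. In particular, simulated memory times for
  boys overall and for depressed low-rumination girls run high: the θ2·D
  channel pulls rumination up toward ~11 for initially depressed
  individuals over the study horizon, lengthening their memory time, which
  the original equations evidently damped. The package reports what the
  reconstructed model actually produces.
* Rumination's 0–39 scale is inferred from the instrument's 13–52 range and
  the published means; the offset is not stated in the source.
* The groups-differing-only-in-initial-depression comparison (factorial
  groups 1 vs 9) converges to within ~0.7 CDI units by month 120, but the
  gap decays through the coupled reinforcing loops with an effective time
  constant much longer than the 9-month depression-stock constant, so the
  two means still differ by ~3 units at month 24.

## Known limitations

Constant stressor inflow suppresses the burstiness of real life events;
the linear couplings cannot saturate except at the instrument clamps; all
parameters are population-level (no individual heterogeneity beyond initial
conditions and exposure); and calibration quality is bounded by the
auxiliary statistics a three-wave design can pin down.
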