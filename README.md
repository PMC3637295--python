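# germthresh

Population-based threshold models for seed germination over temperature
and storage time.

Short-lived seeds — the motivating case is aspen (*Populus tomentosa*),
whose cottony seeds survive only weeks under ambient conditions — face two
clocks at once: germination must outrun both unfavourable temperature and
viability loss in storage. `germthresh` implements the family of probit
threshold models that quantify this race, a simulator for the underlying
seed populations, and the estimation machinery to fit the models to
cumulative germination time courses.

## The models

Each seed occupies a percentile *g* ∈ (0, 1) of its lot; thresholds are
quantiles of a normal or log-normal population distribution, and the
cumulative germinated fraction at any condition is Φ of a linear predictor
(Φ = standard normal CDF, T in °C, germination time t in h, storage time
p in d):

| model | cumulative fraction g | population threshold |
|---|---|---|
| thermal time (TT) | Φ([ln((T−T_b)·t) − ln θ_T(50)]/σ_lnθ) | θ_T(g) log-normal, shared base temperature T_b |
| modified TT, low range | Φ([T − θ_Tm/t − T_m(50)]/σ_Tm) | minimum temperature T_m(g) normal, θ_Tm constant |
| maximum lifetime (MLT) | Φ([p_max(50) − p − θ_A/t]/σ_pmax) | lifetime p_max(g) normal; θ_A the aging time constant |
| aging thermal time (ATT) | Φ([p_max(50) − p − θ_AT/((T−T_b)·t)]/σ_pmax) | as MLT with θ_A = θ_AT/(T−T_b) |

The two-phased variants split the suboptimal range at `T_split`
(default 12.5 °C): cold-range germination is governed by a distributed
minimum temperature (MTT) or by a median lifetime that declines as
p_maxi(50) − k·(T_i − T) below an inflection temperature T_i (ATT).
Two normalizations undo the treatment effects: multiplying a stored-seed
germination time by (1 − p/p_max(g)) recovers the control time course,
and the normalized thermal time θ_NT = (T−T_b)(1 − p/p_max(g))·t_g
collapses every temperature × storage treatment onto a single curve.

## Worked example

Fit the two-phased thermal model to a simulated control-seed experiment
(6 temperatures × 3 replicates of 50 seeds, hourly scoring) and compare
it with the single-phase model by AIC:

```python
import germthresh as gt

generator = gt.MTTParams(
    low=gt.MTTLowParams(theta_Tm=383.9, T_m50=4.4, sigma_Tm=3.79),
    high=gt.TTParams(theta_T50=149.1, T_b=9.5, sigma_lnTheta=0.56),
)
lot = gt.simulate_lot(generator, gt.SimulationDesign(storage_days=(0.0,), rng_seed=42))
print(gt.compare_run(lot, pair="tt_vs_mtt")[["model", "aic", "rmse", "preferred"]])
```

```
model          aic      rmse  preferred
   tt  -323.094081  0.513666      False
  mtt -1193.361586  0.087161       True
```

The two-phased description wins by ~870 AIC points: cold-range
germination is limited by each seed's minimum temperature, not by
accumulated thermal time.  Fitting the two phases recovers the
generating constants (`theta_Tm=367.5 [383.9]`, `T_m50=4.61 [4.4]`,
`T_b=9.99 [9.5]`, ...) — probit-scale RMSE 0.087 is pure binomial
sampling noise.

The scripts in `examples/` walk through each capability: forward
prediction and percentile times, thermal-model comparison, storage aging
and the normalization collapse, the combined aging-thermal-time fit, and
the viability-loss curve.  Each prints the numbers it computes and one
line on what they mean.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline results from scratch: the linear and
two-segment regressions of 1/θ_A on temperature from the published aging
time constants, noiseless and binomial-lot parameter recovery for every
model family, the storage-time normalization collapse, and the AIC
preference for the two-phased thermal model across 100 simulated lots.
Progress is logged to standard error; the JSON result object is written
to `--out`.
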