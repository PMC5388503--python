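# msocc

Multi-season, multi-state occupancy models with imperfect detection, for
territory-monitoring studies of territorial species — the motivating design is
a seven-year survey of 72 Eurasian Eagle-owl nesting territories, each visited
four times per breeding season and scored 0 (no sign of occupancy), 1
(occupied, no evidence of reproduction) or 2 (occupied with evidence of
successful reproduction).

## The model

Each territory has a latent seasonal state m ∈ {0, 1, 2} (unoccupied /
occupied without success / occupied with success), constant within a season
and Markov between seasons. With ψ_t[m] the occupancy probability given
previous state m, and R_t[m] the breeding-success probability given occupancy,
the transition row from state m is

    ( 1 − ψ[m],   ψ[m](1 − R[m]),   ψ[m]·R[m] )

Observation is imperfect with no false positives: at survey j, a state-1
territory is detected with probability p[1]_j; a state-2 territory is detected
with probability p[2]_j and, once detected, shows evidence of reproduction
with probability δ_j (δ_1 ≡ 0: evidence cannot exist at the courtship-stage
survey). ψ and R are logit-linear in previous state, year and habitat
covariates (zone, ruggedness, crops, scrub, distance); the site likelihood
marginalizes the latent state path with a rescaled forward algorithm.

On top of the likelihood the package provides AIC ranking with Akaike weights
w_i = exp(−ΔAIC_i/2)/Σ exp(−ΔAIC_j/2), two-phase structure selection,
model averaging with Burnham–Anderson unconditional standard errors,
detection-ignorant (naïve) summaries for comparison, and a synthetic-data
generator with the full study design for validation.

## Worked example

`examples/fit_best_model.py` simulates a 72-territory, 7-season study from
the default (owl-like) generating values and refits the headline model —
occupancy depending on previous state, success on year, previous state and
ruggedness:

```
model: psi(State) R(State+Year+Ruggedness)
K = 25, AIC = 2665.91, deviance = 2615.91, converged = True

parameter   estimate             95% CI
psi[0]         0.502   (0.336, 0.667)
psi[1]         0.857   (0.750, 0.923)
psi[2]         0.986   (0.949, 0.996)
R[0]           0.427   (0.149, 0.760)
R[1]           0.656   (0.446, 0.819)
R[2]           0.837   (0.691, 0.922)
p1[1]          0.722   (0.613, 0.810)
...
delta[4]       0.912   (0.863, 0.944)

average estimated occupancy over all site-years: 0.909 (naive: 0.897)
```

Read: a territory unoccupied last season is re-occupied with probability
~0.50, one that bred successfully with probability ~0.99 (the
win-stay:lose-switch signature; the generating values were 0.53 / 0.85 /
0.98). Detection of failed breeders declines across the four surveys while
evidence of reproduction becomes near-certain by the last survey, and the
naïve occupancy understates the model-based estimate because detection is
imperfect. The other examples cover dataset simulation
(`simulate_dataset.py`), two-phase selection with model averaging
(`model_selection.py`) and a simulate-and-refit calibration study
(`parameter_recovery.py`).

A thin CLI wraps the same pipeline:

```
msocc simulate --seed 1 --out runs/sim
msocc fit-select --data runs/sim/histories.txt --out runs/fit
msocc recovery --n-replicates 25 --n-sites 200 --out runs/rec
```

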