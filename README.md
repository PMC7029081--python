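# metasym

Transmission dynamics of heritable bacterial symbionts in insect host
metacommunities: deterministic and exact stochastic simulation of coupled
vertical-transmission / horizontal-transmission / demography / migration
models for two symbionts sharing one host species, plus Bayesian estimation
of the transmission parameters from prevalence time series.

## Who this is for

Experimentalists and modellers studying heritable insect symbionts (think
*Wolbachia*-, *Spiroplasma*- or *Hamiltonella*-style endosymbionts) who want
to (i) simulate how two symbionts spread and co-occur across a set of host
populations linked by migration, (ii) design release experiments that can
identify transmission parameters, and (iii) fit and compare mechanistic
transmission models against observed prevalence data.

## The models

Hosts in patch *i* are susceptible (S), singly infected (I_A, I_B) or
coinfected (X). The full metacommunity model tracks, for each patch,

```
S_i' = ν_b[φ(X_i + I_Ai + I_Bi) + S_i] - ν_d S_i
       - β_A (I_Ai + q X_i) S_i / N_it - β_B (I_Bi + q X_i) S_i / N_it
       - m S_i + Σ_{l≠i} ρ_{i,l} m S_l
```

and its analogues for I_A, I_B and X. The three processes are:

* **Demography and vertical transmission** — all classes reproduce at ν_b
  and die at ν_d; an infected mother's offspring is symbiont-free with
  probability φ, and a transmitting coinfected mother produces I_A / I_B / X
  offspring with conditional probabilities c_A / c_B / 1−(c_A+c_B).
* **Horizontal transmission** — frequency-dependent: forces of infection
  divide by the patch- and time-specific population size N_it. Coinfected
  hosts transmit each symbiont with modifier q; singly infected hosts
  acquire the second symbiont with susceptibility ψ.
* **Migration** — per-capita emigration at rate m, routed between patches by
  a column-stochastic matrix ρ (optionally built from pairwise distances
  with an exponential dispersal kernel).

Two reductions matter in practice: the closed two-symbiont **experiment
model** (no demography, no migration; four parameters β_A, β_B, q, ψ) and
the single-symbiont **SI model** `I' = β I (N − I) / N`, whose solution is
the logistic curve.

Simulation is available both as ODE integration (`integrate`) and as exact
event-driven stochastic simulation with Gillespie's direct method
(`gillespie_simulate`).

## Inference

Observed data are counts of infected hosts among `n_assayed` at each
sampling time (`PrevalenceSeries`, a tidy CSV). The likelihood is binomial
(multinomial over classes for two-symbiont data) around the class fractions
of a fresh ODE solve; priors default to half-Normal(0, 5) on rates and
modifiers. Sampling uses adaptive random-walk Metropolis on log-transformed
parameters, by default with 3 chains, 2,000 warm-up iterations, 5,000 total
iterations and thinning by 3. Fits carry pointwise log-likelihood matrices
so model variants can be compared by WAIC (`compare_models`).

## Worked example

Simulate a release experiment — one infected host released into 49
susceptibles, three replicate populations assayed every 2 days with binomial
observation error, true transmission rate 0.50/day — and re-estimate the
rate:

```python
from metasym import (MCMCConfig, ModelSpec, fit_mcmc,
                     generate_single_release_dataset, posterior_summary)

series = generate_single_release_dataset(beta=0.50, seed=0)
fit = fit_mcmc(series, ModelSpec("si_single"), config=MCMCConfig(seed=0))
print(posterior_summary(fit))
```

prints

```
          q2.5       q50     q97.5
beta  0.484986  0.503249  0.523528
```

i.e. a posterior median of 0.503/day with 95% credible interval
[0.485, 0.524], comfortably containing the generating rate 0.50. The same
workflow from the shell:

```bash
metasym generate-single --beta 0.5 --seed 0 -o data.csv
metasym fit --data data.csv --model si_single --seed 0 -o fit_out
```

The four-population coinfection experiment
(`generate_coinfection_dataset`, initial mixtures (90,0,0,10), (90,5,5,0),
(88,10,0,2), (88,0,10,2)) identifies all four of β_A, β_B, q, ψ the same
way with `ModelSpec("experiment_two_symbiont")`.

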