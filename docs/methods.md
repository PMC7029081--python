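# Methods

## Model structure

The package implements three nested compartment models for two symbionts in
one host species. State per patch is (S, I_A, I_B, X): susceptible, singly
infected with symbiont A or B, coinfected. All rates are per day.

**Full metacommunity model.** Within-patch dynamics couple demography and
vertical transmission with frequency-dependent horizontal transmission;
among-patch dynamics are per-capita emigration routed by a matrix ρ.
The demographic terms are written so that total births equal ν_b·N: every
class reproduces at ν_b, offspring of susceptible mothers are susceptible,
offspring of infected mothers are susceptible with probability φ, and a
vertically transmitting coinfected mother's offspring class follows the
categorical split (c_A, c_B, 1−(c_A+c_B)). Infection does not change birth
or death rates. The published rendering of these equations collapses some
brackets; the grouping used here is the unique one consistent with the
prose definitions of φ, c_A and c_B and with birth-rate conservation.

**Routing convention.** ρ[i, l] is the probability that an emigrant from
patch l lands in patch i (destination-row, source-column); each source
column sums to one over the other patches, so emigrants always land
somewhere. With a single patch (J = 1) migration is a no-op even if m > 0 —
there is nowhere to go. Distance-based routing uses
ρ[i,l] ∝ exp(−d_{i,l}/λ) by default (a Gaussian kernel is also available);
the kernel family is a modelling choice, not a claim about any particular
insect.

**Empty patches.** A patch with N = 0 has force of infection 0 (no hosts,
no contacts) rather than a division by zero.

**Continuous vs integer states.** ODE work treats classes as continuous
densities; the Gillespie simulator enforces non-negative integer counts.

## Simulation

`integrate` wraps scipy's adaptive RK45 with rtol 1e-8 / atol 1e-10 and
clips solver-noise negatives to zero (anything below a tolerance that
scales with total population size is treated as an integration fault and
raised with the last good state). The SI model's solution is logistic and
the solver is held to 1e-6 relative error against that closed form in the
tests.

`gillespie_simulate` is Gillespie's direct method: exponential waiting time
from the total rate, categorical event identity. Event channels per patch
are the four infection transitions, births (mother class drawn proportional
to counts, offspring class by the vertical-transmission split at event
time), per-class deaths, and per-class emigration with a routed
destination. The simulator is exact for the underlying Markov jump process;
the test suite checks its mean against the master-equation solution of the
SI pure-birth chain. Note that the *mean* of the stochastic process is not
the ODE solution at finite N: for the SI model at N = 500 the stochastic
mean lags the deterministic curve by ≈ 4–5% around the epidemic peak
growth phase (the classic β·Var[I]/N correction), which is visible at
2,000-replicate Monte-Carlo precision.

## Synthetic experiments

`generate_single_release_dataset` emulates a transmission-rate release
experiment: one infected host in a population of 50 (49 susceptible), the
epidemic following the SI model with β = 0.50/day by default, three
replicate populations, sampled every 2 days. The experiment horizon is not
part of the protocol's published description; 20 days is used because the
epidemic is essentially complete at the default rate. Each host's infection
status is assayed at every sampling time (n_assayed = N, configurable), and
observed counts are drawn multinomially over the host classes — so each
class count is marginally Binomial(n_assayed, class fraction) and counts
can never exceed the number assayed. Replicate k draws from an RNG
substream keyed by (seed, k), making its data invariant to how many
replicates are requested.

`generate_coinfection_dataset` emulates the four-population coinfection
experiment: populations of 100 hosts started from the four mixtures
(90,0,0,10), (90,5,5,0), (88,10,0,2), (88,0,10,2), evolved under the closed
experiment model and assayed on all three infected classes, again every 2
days over 20 days. The generating parameters used by the tests and the
acceptance script, (β_A, β_B, q, ψ) = (0.5, 0.35, 0.7, 1.2), were chosen
once as a biologically plausible regime: two unequal transmission rates of
the same order as the single-symbiont experiment, partially suppressed
transmission from coinfected hosts (q < 1), and mild facilitation of
secondary infection (ψ > 1), so all four parameters shape the transient
dynamics the design is meant to expose.

What the generators deliberately do not emulate: demographic turnover
during the experiment, assay misclassification, loss of hosts to sampling,
and between-replicate environmental variation. Passing the recovery tests
therefore shows the estimator is correct and calibrated *for the stated
observation model*, not that real release experiments are this clean.

## Inference

The likelihood of a prevalence record is binomial in the model's predicted
infected fraction; records of I_A, I_B and X at one time are the natural
multi-class extension, a multinomial over {S, I_A, I_B, X} with index
n_assayed. Each likelihood evaluation re-solves the ODE at the proposed
parameters. The likelihood path uses a compiled fixed-step RK4 integrator
whose step is tied to the fastest transmission time scale
(dt = 0.02 / max(1, r)); its truncation error (~1e-6 of a class fraction,
asserted against the adaptive reference solver in the tests) is orders of
magnitude below counting noise. A predicted fraction of exactly zero facing
a positive count yields −∞ (a rejected proposal, not an exception);
parameter proposals so extreme that the step budget would explode are
treated the same way.

Priors default to half-Normal(0, 5) on rates and on q and ψ — a vague
prior truncated to the physically meaningful domain — and Uniform(0, 1) on
probabilities (φ, c_A, c_B). Sampling is adaptive random-walk Metropolis on
transformed parameters (log for positive parameters, logit for unit-interval
ones, Jacobians included): the proposal's global scale follows a
diminishing Robbins–Monro adaptation toward 0.44 (1-d) / 0.30 acceptance
and its shape is the empirical covariance of the warm-up history, with all
adaptation frozen at the end of warm-up so retained draws come from a fixed
kernel. Chains start from independent prior draws (up to 50 re-draws if the
posterior is non-finite there). Defaults are 3 chains, 2,000 warm-up of
5,000 total iterations, thinning by 3; draws kept per chain are
(iterations − warmup) // thin. The sampler core is a standalone function
and is validated against the analytic Beta posterior of a conjugate toy and
against a direct grid integration of the release-experiment posterior.

Convergence diagnostics (split R-hat, effective sample size) come from
arviz. `posterior_summary` reports pooled-chain empirical quantiles with
linear interpolation (default 2.5/50/97.5%). Fits on data with no
information flag `wide_posterior:<name>` when a parameter's 95% posterior
width is ≥ 90% of its prior width.

**Calibration.** At the release-experiment scale (3 replicates, N = 50,
observations every 2 days), the 95% credible interval for β covers the
generating value in 95.0% of 200 simulation seeds, and the spread of
posterior medians across seeds (0.0094) matches the Fisher-information
standard deviation (0.0096). Individual 20-seed windows fluctuate
binomially around that rate.

## Model comparison

WAIC on the log scale: elpd_i = log mean_s exp(ll_si) − Var_s(ll_si), with
the sample (ddof = 1) variance, summed over observations; the standard
error is sqrt(n·Var_i(elpd_i)) and pairwise model differences use the
paired pointwise variance. Fits are only comparable when their data
fingerprints (a hash of the observation table) match. The pointwise
matrices are retained in `FitResult` so other criteria can be added.

## Numerical conventions

* Quantiles: linear interpolation of order statistics.
* Observation substreams: `SeedSequence((seed, k))` per replicate.
* Thinning keeps post-warm-up iterations j with (j+1) % thin == 0.
* CSV output is comma-separated UTF-8 with a mandatory header; generation
  metadata rides in `# key: json` comment lines so round trips are lossless.
* Problem sizes in the test suite (e.g. 400-run master-equation comparison,
  reduced-iteration fits in non-headline tests) were chosen as the smallest
  sizes at which the Monte-Carlo error bounds in the assertions are
  meaningful.

## Known limitations

* The full J-patch model can be fitted in code (patches as replicates), but
  identifiability of migration and demography from prevalence data alone is
  untested; the supported inference surfaces are the SI and the two-symbiont
  experiment models.
* No gradient-based samplers; posteriors with strong correlations beyond
  the four-parameter experiment model may mix slowly.
* The observation model assumes perfect assays; misclassification would
  need an extra layer.
* Mark–recapture-style estimation of migration parameters is out of scope.
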