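"""Bayesian estimation of transmission parameters from prevalence data.

The likelihood compares observed infection-class counts with the class
fractions predicted by a fresh ODE solve at the proposed parameters: a
binomial probability for single-class (infected / not) data and its natural
multi-class extension, a multinomial over {S, I_A, I_B, X}, for two-symbiont
data.  Priors default to half-Normal(0, 5) on rates and on the q and psi
modifiers — a vague prior truncated to the meaningful (non-negative) domain.

Sampling uses an adaptive random-walk Metropolis algorithm on transformed
parameters (log for positive parameters, logit for probabilities), with the
proposal scale and covariance adapted during warm-up only, so the retained
chain targets the exact posterior.  The default chain/warm-up/thinning
configuration (3 chains, 2,000 warm-up, 5,000 iterations, thin 3) matches
the release-experiment fitting protocol.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from ._fastode import solve_experiment_states
from .observe import PrevalenceSeries
from .params import ModelParams, SymbiontParams, DemographyParams, MigrationParams
from .simulate import IntegrationError, integrate
from .state import CLASSES

__all__ = [
    "HalfNormal",
    "Normal",
    "Uniform",
    "PriorSpec",
    "MCMCConfig",
    "ModelSpec",
    "FitResult",
    "log_likelihood",
    "log_prior",
    "fit_mcmc",
    "adaptive_metropolis",
    "posterior_summary",
    "diagnostics",
    "predict_fit",
]

logger = logging.getLogger(__name__)

#: parameters constrained to [0, 1] (logit-transformed, uniform prior default)
_UNIT_PARAMS = frozenset({"phi", "c_A", "c_B"})


# --------------------------------------------------------------------------
# priors

@dataclass(frozen=True)
class HalfNormal:
    """Half-Normal(0, scale) on [0, inf)."""

    scale: float = 5.0

    def logpdf(self, x: float) -> float:
        if x < 0:
            return -np.inf
        return (math.log(2.0) - math.log(self.scale) - 0.5 * math.log(2 * math.pi)
                - 0.5 * (x / self.scale) ** 2)

    def sample(self, rng: np.random.Generator) -> float:
        return abs(rng.normal(0.0, self.scale))


@dataclass(frozen=True)
class Normal:
    mu: float = 0.0
    sigma: float = 1.0

    def logpdf(self, x: float) -> float:
        z = (x - self.mu) / self.sigma
        return -0.5 * z * z - math.log(self.sigma) - 0.5 * math.log(2 * math.pi)

    def sample(self, rng: np.random.Generator) -> float:
        return rng.normal(self.mu, self.sigma)


@dataclass(frozen=True)
class Uniform:
    lo: float = 0.0
    hi: float = 1.0

    def logpdf(self, x: float) -> float:
        if self.lo <= x <= self.hi:
            return -math.log(self.hi - self.lo)
        return -np.inf

    def sample(self, rng: np.random.Generator) -> float:
        return rng.uniform(self.lo, self.hi)


@dataclass
class PriorSpec:
    """Per-parameter priors; unlisted parameters fall back to the default."""

    priors: dict[str, Any] = field(default_factory=dict)
    default: Any = field(default_factory=HalfNormal)

    def get(self, name: str):
        if name in self.priors:
            return self.priors[name]
        if name in _UNIT_PARAMS:
            return Uniform(0.0, 1.0)
        return self.default


def log_prior(params: dict[str, float], prior: PriorSpec) -> float:
    """Joint log prior density: the sum of independent per-parameter terms."""
    return float(sum(prior.get(name).logpdf(value) for name, value in params.items()))


# --------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class MCMCConfig:
    """Chain layout of the sampler.

    Retained draws per chain are the post-warm-up iterations kept every
    ``thin`` steps, i.e. ``(n_iterations - n_warmup) // thin`` (floor
    division: iteration ``j`` after warm-up is kept when ``(j + 1) % thin == 0``).
    """

    n_chains: int = 3
    n_warmup: int = 2000
    n_iterations: int = 5000
    thin: int = 3
    seed: int = 0
    max_init_tries: int = 50

    def __post_init__(self) -> None:
        if not (self.n_iterations > self.n_warmup >= 0):
            raise ValueError("need n_iterations > n_warmup >= 0")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iterations - self.n_warmup) // self.thin


_MODEL_FREE_DEFAULTS = {
    "si_single": ("beta",),
    "experiment_two_symbiont": ("beta_A", "beta_B", "q", "psi"),
    "full_metacommunity": ("beta_A", "beta_B", "q", "psi", "nu_b", "nu_d",
                           "phi", "c_A", "c_B", "m"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant to fit and which parameters are free vs fixed.

    Process switches for model-comparison studies are expressed by fixing
    parameters: e.g. vertical transmission off is ``fixed={"phi": 1.0}``,
    migration off is ``fixed={"m": 0.0}``.
    """

    model_tag: str
    free: tuple[str, ...] = ()
    fixed: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_tag not in _MODEL_FREE_DEFAULTS:
            raise ValueError(f"unknown model_tag {self.model_tag!r}")
        free = tuple(self.free) or tuple(
            p for p in _MODEL_FREE_DEFAULTS[self.model_tag] if p not in self.fixed)
        object.__setattr__(self, "free", free)
        all_params = set(_MODEL_FREE_DEFAULTS[self.model_tag])
        covered = set(self.free) | set(k for k in self.fixed if k != "rho")
        if set(self.free) & set(self.fixed):
            raise ValueError("a parameter cannot be both free and fixed")
        if not covered >= all_params - {"rho"} or not set(self.free) <= all_params:
            missing = all_params - covered
            extra = set(self.free) - all_params
            raise ValueError(
                f"free + fixed must exactly cover the model's parameters; "
                f"missing {sorted(missing)}, unknown {sorted(extra)}")

    def model_params(self, free_values: dict[str, float]) -> ModelParams:
        vals = {**self.fixed, **free_values}
        if self.model_tag == "si_single":
            return ModelParams(symbiont=SymbiontParams(beta_A=vals["beta"], beta_B=0.0))
        sym = SymbiontParams(**{k: vals[k] for k in ("beta_A", "beta_B", "q", "psi")})
        if self.model_tag == "experiment_two_symbiont":
            return ModelParams(symbiont=sym)
        demo = DemographyParams(**{k: vals[k] for k in ("nu_b", "nu_d", "phi", "c_A", "c_B")})
        rho = np.asarray(vals.get("rho", [[0.0]]))
        mig = MigrationParams(m=vals["m"], rho=rho, J=rho.shape[0])
        return ModelParams(symbiont=sym, demography=demo, migration=mig)


# --------------------------------------------------------------------------
# likelihood

class _LikelihoodData:
    """Pre-pivoted view of a PrevalenceSeries for fast repeated evaluation.

    One *observation* (a pointwise likelihood unit) is one (replicate, time)
    record: a binomial for single-class (infected) data, a multinomial over
    the host classes otherwise.  Observations are ordered by (replicate,
    time).  Replicates of the single-population models evolve independently,
    so they are stacked as rows of one vectorized ODE solve; for the full
    metacommunity model the replicates are the coupled patches of one system.
    The ODE is solved with rtol 1e-6 / atol 1e-9 — well below observation
    noise on count data.
    """

    rtol = 1e-6
    atol = 1e-9

    def __init__(self, series: PrevalenceSeries, spec: ModelSpec):
        self.spec = spec
        self.classes = series.classes
        self.single_class = self.classes == ["infected"]
        inits = series.metadata.get("initial_conditions")
        if inits is None:
            raise ValueError(
                "series metadata must carry 'initial_conditions' (one (S, I_A, I_B, X) "
                "vector per replicate) to define the ODE initial state")
        self.replicates = series.replicates
        if len(inits) < len(self.replicates):
            raise ValueError("metadata initial_conditions shorter than replicate list")
        self.init = np.asarray([inits[k] for k in range(len(self.replicates))], dtype=float)
        rep_idx = {rid: k for k, rid in enumerate(self.replicates)}

        df = series.data
        keys = df[["replicate", "time"]].drop_duplicates().sort_values(
            ["replicate", "time"])
        self.n_obs = len(keys)
        all_times = np.unique(df["time"].to_numpy(float))
        self.solve_times = (all_times if all_times[0] == 0.0
                            else np.concatenate([[0.0], all_times]))
        self.obs_rep = np.array([rep_idx[r] for r in keys["replicate"]], dtype=int)
        self.obs_time = np.searchsorted(self.solve_times, keys["time"].to_numpy(float))

        pivot = df.pivot_table(index=["replicate", "time"], columns="class",
                               values="count", fill_value=0).reindex(
            pd.MultiIndex.from_frame(keys), fill_value=0)
        counts = pivot[self.classes].to_numpy(float)
        n = df.groupby(["replicate", "time"])["n_assayed"].first().reindex(
            pd.MultiIndex.from_frame(keys)).to_numpy(float)
        # last column: hosts assayed in none of the tracked classes
        self.counts_full = np.hstack([counts, (n - counts.sum(axis=1))[:, None]])
        if (self.counts_full < 0).any():
            raise ValueError("class counts exceed n_assayed")
        self.n_vec = n
        self._lgamma_const = gammaln(n + 1) - gammaln(self.counts_full + 1).sum(axis=1)
        self._class_cols = None if self.single_class else np.array(
            [CLASSES.index(c) for c in self.classes])

    def _solve(self, params: ModelParams) -> np.ndarray:
        """Class fractions (T, R, 4) at the solve times."""
        tag = self.spec.model_tag
        if tag == "full_metacommunity":
            states = integrate(tag, params, self.init, self.solve_times,
                               rtol=self.rtol, atol=self.atol).states
        else:
            # independent single populations: rows of one compiled solve of
            # the coinfection system (the SI model is its beta_B = 0 case)
            try:
                states = solve_experiment_states(self.init, self.solve_times,
                                                 params.symbiont)
            except ValueError as exc:
                raise IntegrationError(str(exc), self.solve_times[0], self.init) from None
        N = np.maximum(states.sum(axis=2, keepdims=True), 1e-300)
        return states / N

    def pointwise(self, params: ModelParams) -> np.ndarray:
        """Per-observation log-likelihood vector; -inf entries are flags, not errors."""
        try:
            frac = self._solve(params)
        except IntegrationError as exc:
            logger.warning("ODE solve failed at proposed parameters: %s", exc)
            return np.full(self.n_obs, -np.inf)
        f = np.clip(frac[self.obs_time, self.obs_rep, :], 0.0, 1.0)  # (n_obs, 4)
        if self.single_class:
            p = f[:, 1:].sum(axis=1, keepdims=True)
        else:
            p = f[:, self._class_cols]
        p_full = np.hstack([p, np.clip(1.0 - p.sum(axis=1), 0.0, 1.0)[:, None]])

        k = self.counts_full
        impossible = ((p_full <= 0) & (k > 0)).any(axis=1)
        terms = np.where(k > 0, k * np.log(np.where(p_full > 0, p_full, 1.0)), 0.0)
        ll = self._lgamma_const + terms.sum(axis=1)
        ll[impossible] = -np.inf
        return ll


def log_likelihood(
    series: PrevalenceSeries,
    spec: ModelSpec,
    params: dict[str, float] | Sequence[float],
) -> tuple[float, np.ndarray]:
    """Total and pointwise log-likelihood of the data under the model.

    ``params`` maps the spec's free parameter names to values (or gives them
    positionally in ``spec.free`` order).  A predicted fraction of exactly 0
    facing a positive count yields ``-inf`` (returned, not raised).
    """
    if not isinstance(params, dict):
        params = dict(zip(spec.free, np.asarray(params, dtype=float)))
    data = _LikelihoodData(series, spec)
    pw = data.pointwise(spec.model_params(params))
    total = float(pw.sum())
    return total, pw


# --------------------------------------------------------------------------
# sampler core

def adaptive_metropolis(
    logpost: Callable[[np.ndarray], tuple[float, Any]],
    x0: np.ndarray,
    config: MCMCConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list, float]:
    """Adaptive random-walk Metropolis in R^d.

    ``logpost`` returns ``(log density, auxiliary)``; auxiliaries of retained
    draws are collected.  The proposal is a multivariate normal whose global
    scale follows a diminishing Robbins-Monro adaptation toward a target
    acceptance rate (0.44 in 1-d, 0.3 otherwise) and whose shape is the
    empirical covariance of the warm-up history.  Adaptation stops at the end
    of warm-up, so retained draws come from a fixed, valid Markov kernel.

    Returns (kept draws ``(n_kept, d)``, kept auxiliaries, acceptance rate).
    """
    x = np.array(x0, dtype=float)
    d = x.size
    lp, aux = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log posterior")
    target = 0.44 if d == 1 else 0.30
    log_scale = math.log(2.38 / math.sqrt(d))
    chol = np.eye(d)
    history = np.empty((config.n_warmup, d))
    kept = np.empty((config.n_kept, d))
    kept_aux: list = []
    n_accept = 0
    n_post = 0

    for it in range(config.n_iterations):
        prop = x + math.exp(log_scale) * (chol @ rng.standard_normal(d))
        lp_p, aux_p = logpost(prop)
        accept = np.isfinite(lp_p) and math.log(rng.random()) < lp_p - lp
        if accept:
            x, lp, aux = prop, lp_p, aux_p
        if it < config.n_warmup:
            history[it] = x
            log_scale += (float(accept) - target) / (1.0 + 0.1 * it) ** 0.6
            if d > 1 and it >= 200 and it % 100 == 0:
                cov = np.cov(history[it // 2: it + 1].T) + 1e-10 * np.eye(d)
                chol = np.linalg.cholesky(cov)
        else:
            n_accept += int(accept)
            n_post += 1
            j = it - config.n_warmup
            if (j + 1) % config.thin == 0 and (j + 1) // config.thin <= config.n_kept:
                kept[(j + 1) // config.thin - 1] = x
                kept_aux.append(aux)
    rate = n_accept / max(n_post, 1)
    return kept, kept_aux, rate


# --------------------------------------------------------------------------
# fit result

@dataclass
class FitResult:
    """Posterior draws and everything model comparison needs.

    ``draws[name]`` has shape (n_chains, n_kept); ``log_lik`` has shape
    (n_chains, n_kept, n_obs) and holds the pointwise log-likelihood of every
    retained draw.
    """

    draws: dict[str, np.ndarray]
    log_lik: np.ndarray
    spec: ModelSpec
    prior: PriorSpec
    config: MCMCConfig
    data_fingerprint: str
    acceptance_rates: list[float] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    series_metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return int(np.prod(next(iter(self.draws.values())).shape))

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].ravel()

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(
            posterior={k: v for k, v in self.draws.items()},
            log_likelihood={"obs": self.log_lik},
        )

    def save(self, directory) -> None:
        """Draws to CSV, everything else to JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        C, K = next(iter(self.draws.values())).shape
        frame = pd.DataFrame({
            "chain": np.repeat(np.arange(C), K),
            "draw": np.tile(np.arange(K), C),
            **{name: arr.ravel() for name, arr in self.draws.items()},
        })
        frame.to_csv(directory / "draws.csv", index=False)
        np.savetxt(directory / "log_lik.csv",
                   self.log_lik.reshape(C * K, -1), delimiter=",")
        meta = {
            "spec": {"model_tag": self.spec.model_tag, "free": list(self.spec.free),
                     "fixed": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                               for k, v in self.spec.fixed.items()}},
            "config": {k: getattr(self.config, k)
                       for k in ("n_chains", "n_warmup", "n_iterations", "thin", "seed")},
            "data_fingerprint": self.data_fingerprint,
            "acceptance_rates": self.acceptance_rates,
            "flags": self.flags,
            "series_metadata": self.series_metadata,
            "shape": [C, K],
        }
        (directory / "fit.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "FitResult":
        directory = Path(directory)
        meta = json.loads((directory / "fit.json").read_text())
        C, K = meta["shape"]
        frame = pd.read_csv(directory / "draws.csv")
        names = [c for c in frame.columns if c not in ("chain", "draw")]
        draws = {n: frame[n].to_numpy().reshape(C, K) for n in names}
        log_lik = np.loadtxt(directory / "log_lik.csv", delimiter=",", ndmin=2)
        return cls(
            draws=draws,
            log_lik=log_lik.reshape(C, K, -1),
            spec=ModelSpec(meta["spec"]["model_tag"], tuple(meta["spec"]["free"]),
                           meta["spec"]["fixed"]),
            prior=PriorSpec(),
            config=MCMCConfig(**meta["config"]),
            data_fingerprint=meta["data_fingerprint"],
            acceptance_rates=meta["acceptance_rates"],
            flags=meta["flags"],
            series_metadata=meta.get("series_metadata", {}),
        )


def data_fingerprint(series: PrevalenceSeries) -> str:
    payload = series.data.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# --------------------------------------------------------------------------
# transforms between the constrained and the sampling scale

def _transforms(names: Sequence[str]):
    to_z, to_theta, logjac = [], [], []
    for name in names:
        if name in _UNIT_PARAMS:
            to_z.append(lambda th: math.log(th / (1 - th)) if 0 < th < 1 else
                        (37.0 if th >= 1 else -37.0))
            to_theta.append(lambda z: float(expit(z)))
            logjac.append(lambda z: float(-z - 2 * math.log1p(math.exp(-z)))
                          if z > -30 else z)
        else:
            to_z.append(lambda th: math.log(max(th, 1e-300)))
            to_theta.append(math.exp)
            logjac.append(lambda z: z)
    return to_z, to_theta, logjac


def fit_mcmc(
    series: PrevalenceSeries,
    spec: ModelSpec,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> FitResult:
    """Sample the posterior of the free parameters given a prevalence series.

    Chains are initialized from independent prior draws (re-drawn up to
    ``config.max_init_tries`` times if the posterior is non-finite there) and
    run independently with per-chain RNG substreams of ``config.seed``.
    """
    prior = prior or PriorSpec()
    config = config or MCMCConfig()
    if len(series.data) == 0:
        logger.info("empty data: the posterior reduces to the prior")
        data = None
    else:
        data = _LikelihoodData(series, spec)
    names = list(spec.free)
    to_z, to_theta, logjac = _transforms(names)
    n_obs = data.n_obs if data is not None else 0

    def logpost(z: np.ndarray) -> tuple[float, np.ndarray]:
        theta = {n: f(z[i]) for i, (n, f) in enumerate(zip(names, to_theta))}
        lp = log_prior(theta, prior) + sum(f(z[i]) for i, f in enumerate(logjac))
        if not np.isfinite(lp):
            return -np.inf, np.empty(0)
        if data is None:
            return lp, np.empty(0)
        pw = data.pointwise(spec.model_params(theta))
        total = pw.sum()
        if not np.isfinite(total):
            return -np.inf, pw
        return lp + total, pw

    all_draws = np.empty((config.n_chains, config.n_kept, len(names)))
    log_lik = np.empty((config.n_chains, config.n_kept, max(n_obs, 1)))
    rates = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), int(c))))
        z0 = None
        for _try in range(config.max_init_tries):
            theta0 = [prior.get(n).sample(rng) for n in names]
            cand = np.array([f(t) for f, t in zip(to_z, theta0)])
            if np.isfinite(logpost(cand)[0]):
                z0 = cand
                break
        if z0 is None:
            raise RuntimeError(
                f"could not find a finite-posterior initialization in "
                f"{config.max_init_tries} prior draws")
        kept, kept_aux, rate = adaptive_metropolis(logpost, z0, config, rng)
        all_draws[c] = kept
        if n_obs:
            log_lik[c] = np.stack(kept_aux)
        rates.append(rate)

    draws = {n: np.stack([[to_theta[i](z) for z in all_draws[c, :, i]]
                          for c in range(config.n_chains)])
             for i, n in enumerate(names)}
    result = FitResult(
        draws=draws,
        log_lik=log_lik if n_obs else np.empty((config.n_chains, config.n_kept, 0)),
        spec=spec,
        prior=prior,
        config=config,
        data_fingerprint=data_fingerprint(series) if len(series.data) else "empty",
        acceptance_rates=rates,
        series_metadata=dict(series.metadata),
    )
    _flag_weak_posteriors(result, prior)
    return result


def _flag_weak_posteriors(result: FitResult, prior: PriorSpec) -> None:
    """Flag parameters whose posterior is about as wide as their prior."""
    rng = np.random.default_rng(12345)
    for name, arr in result.draws.items():
        pr = prior.get(name)
        prior_draws = np.array([pr.sample(rng) for _ in range(2000)])
        prior_width = np.subtract(*np.quantile(prior_draws, [0.975, 0.025]))
        post_width = np.subtract(*np.quantile(arr.ravel(), [0.975, 0.025]))
        if prior_width > 0 and post_width > 0.9 * prior_width:
            result.flags.append(f"wide_posterior:{name}")


# --------------------------------------------------------------------------
# summaries, diagnostics, prediction

def posterior_summary(
    fit: FitResult, levels: Sequence[float] = (2.5, 50.0, 97.5)
) -> pd.DataFrame:
    """Pooled-chain empirical quantiles (linear interpolation) per parameter."""
    rows = {}
    for name in fit.draws:
        pooled = fit.pooled(name)
        rows[name] = np.quantile(pooled, np.asarray(levels) / 100.0, method="linear")
    return pd.DataFrame(rows, index=[f"q{lv:g}" for lv in levels]).T


def diagnostics(fit: FitResult) -> pd.DataFrame:
    """Split R-hat and effective sample size per parameter (via arviz).

    With a single chain R-hat is undefined and reported as NaN.
    """
    import arviz as az

    idata = az.from_dict(posterior={k: v for k, v in fit.draws.items()})
    ess = az.ess(idata)
    out = {"ess": {k: float(ess[k].values) for k in fit.draws}}
    if fit.config.n_chains >= 2:
        rhat = az.rhat(idata)
        out["rhat"] = {k: float(rhat[k].values) for k in fit.draws}
    else:
        out["rhat"] = {k: float("nan") for k in fit.draws}
    return pd.DataFrame(out)


def predict_fit(
    fit: FitResult,
    times: Sequence[float],
    levels: Sequence[float] = (2.5, 50.0, 97.5),
    replicate_index: int = 0,
    max_draws: int = 400,
) -> dict[str, Any]:
    """Posterior predictive class-fraction bands.

    Solves the ODE for (a thinned subset of) retained draws from the stated
    replicate's initial conditions and returns pointwise quantiles of the
    class fractions.  Draws whose solve fails are skipped and counted.
    """
    times = np.asarray(times, dtype=float)
    inits = fit.series_metadata.get("initial_conditions")
    if inits is None:
        raise ValueError("fit carries no initial conditions to predict from")
    init = np.asarray(inits[replicate_index], dtype=float)[None, :]
    names = list(fit.draws)
    pooled = np.stack([fit.pooled(n) for n in names], axis=1)
    if pooled.shape[0] > max_draws:
        idx = np.linspace(0, pooled.shape[0] - 1, max_draws).astype(int)
        pooled = pooled[idx]
    solve_times = times if times[0] == 0 else np.concatenate([[0.0], times])
    keep = np.isin(solve_times, times)
    classes = ["infected"] if fit.spec.model_tag == "si_single" else list(CLASSES[1:])
    curves = []
    n_failed = 0
    for row in pooled:
        theta = dict(zip(names, row))
        try:
            traj = integrate(fit.spec.model_tag, fit.spec.model_params(theta),
                             init, solve_times)
        except IntegrationError:
            n_failed += 1
            continue
        states = traj.states[keep, 0, :]
        N = states.sum(axis=1)
        if fit.spec.model_tag == "si_single":
            frac = (states[:, 1:].sum(axis=1) / N)[:, None]
        else:
            frac = states[:, 1:] / N[:, None]
        curves.append(frac)
    if not curves:
        raise RuntimeError("every posterior draw failed to integrate")
    arr = np.stack(curves)  # (draws, T, n_classes)
    qs = np.quantile(arr, np.asarray(levels) / 100.0, axis=0)
    return {
        "times": times,
        "classes": classes,
        "quantiles": {f"q{lv:g}": qs[i] for i, lv in enumerate(levels)},
        "n_failed": n_failed,
    }
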