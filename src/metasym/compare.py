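"""Formal model comparison via WAIC (expected log pointwise predictive density).

For a pointwise log-likelihood matrix ``L`` (draws x observations) the WAIC
estimate of the expected log predictive density is

    elpd_i = log(mean_s exp(L_si)) - Var_s(L_si)        (per observation i)
    elpd   = sum_i elpd_i,   se = sqrt(n * Var_i(elpd_i))

and models fitted to the *same* observations are compared by the pairwise
differences of their pointwise elpd contributions, whose standard error uses
the paired variance.  Larger elpd means better expected predictive fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .infer import FitResult

__all__ = ["waic", "compare_models", "ModelComparison"]


def waic(log_lik: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    """WAIC from a (draws, observations) pointwise log-likelihood matrix.

    Returns ``(elpd, se, p_waic, pointwise_elpd)`` on the log scale.
    """
    L = np.asarray(log_lik, dtype=float)
    if L.ndim != 2 or L.size == 0:
        raise ValueError("log_lik must be a non-empty (draws, observations) matrix")
    S, n = L.shape
    lppd_i = logsumexp(L, axis=0) - np.log(S)
    p_i = L.var(axis=0, ddof=1) if S > 1 else np.zeros(n)
    elpd_i = lppd_i - p_i
    se = float(np.sqrt(n * elpd_i.var(ddof=1))) if n > 1 else 0.0
    return float(elpd_i.sum()), se, float(p_i.sum()), elpd_i


@dataclass
class ModelComparison:
    """Per-model elpd estimates and pairwise differences.

    ``table`` has one row per model (elpd, se, p_waic, rank); ``differences``
    holds every ordered pair's elpd difference (antisymmetric) with the
    paired-difference standard error.
    """

    table: pd.DataFrame
    differences: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def compare_models(fits: list[FitResult], names: list[str] | None = None) -> ModelComparison:
    """Compare models fitted to the same observations by WAIC.

    All fits must carry pointwise log-likelihood matrices over identical data
    (checked by fingerprint).
    """
    if len(fits) < 2:
        raise ValueError("model comparison needs at least 2 fitted models")
    fps = {f.data_fingerprint for f in fits}
    if len(fps) != 1:
        raise ValueError(f"fits were made on different data (fingerprints {sorted(fps)})")
    names = names or [f"model_{i}:{f.spec.model_tag}" for i, f in enumerate(fits)]

    pointwise = []
    rows = []
    for f in fits:
        C, K, n = f.log_lik.shape
        elpd, se, p, elpd_i = waic(f.log_lik.reshape(C * K, n))
        pointwise.append(elpd_i)
        rows.append({"elpd_waic": elpd, "se": se, "p_waic": p})
    table = pd.DataFrame(rows, index=names)
    table["rank"] = table["elpd_waic"].rank(ascending=False).astype(int)
    table = table.sort_values("elpd_waic", ascending=False)

    diffs = []
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                continue
            d = pointwise[i] - pointwise[j]
            n = d.size
            diffs.append({
                "model_a": a,
                "model_b": b,
                "elpd_diff": float(d.sum()),
                "se_diff": float(np.sqrt(n * d.var(ddof=1))) if n > 1 else 0.0,
            })
    return ModelComparison(table=table, differences=pd.DataFrame(diffs))
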