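"""MCMC convergence diagnostics, DIC, and DIC-based model selection.

Convergence is judged by the Gelman–Rubin potential scale reduction
factor (PSRF): chains are considered converged when the multivariate
PSRF (Brooks–Gelman largest-eigenvalue form) is below 1.1.  Model
comparison uses the deviance information criterion DIC = D̄ + pD with the
Spiegelhalter plug-in effective-parameter count pD = D̄ − D(θ̄), the
deviance being the conditional Gaussian deviance given the fitted random
effects.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ModelSpec, build_design
from .pglmm import (MCMCSettings, PosteriorSamples, PriorSpec,
                    REDUCED_SETTINGS, gibbs_fit)

log = logging.getLogger(__name__)

__all__ = ["ConvergenceReport", "gelman_rubin", "dic", "stepwise_selection"]

PSRF_THRESHOLD = 1.1


@dataclass
class ConvergenceReport:
    psrf: pd.Series                 # univariate PSRF per parameter
    multivariate_psrf: float
    ess: pd.Series
    threshold: float = PSRF_THRESHOLD
    passed: bool = field(init=False)

    def __post_init__(self):
        self.passed = bool(self.multivariate_psrf < self.threshold)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"psrf": self.psrf, "ess": self.ess})
        df.attrs["multivariate_psrf"] = self.multivariate_psrf
        return df


def _chain_matrices(chains) -> np.ndarray:
    """Stack chains into (m_chains, n_draws, p)."""
    mats = [np.atleast_2d(np.asarray(c, dtype=float)) for c in chains]
    mats = [m if m.ndim == 2 else m[:, None] for m in mats]
    mats = [m.reshape(m.shape[0], -1) for m in mats]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"chains must have equal shapes, got {sorted(shapes)}")
    return np.stack(mats)


def gelman_rubin(chains, parameter_names=None,
                 threshold: float = PSRF_THRESHOLD) -> ConvergenceReport:
    """Gelman–Rubin PSRF per parameter plus the Brooks–Gelman multivariate PSRF.

    ``chains`` is a list of >= 2 equal-shape draw matrices (draws x
    parameters).  Univariate PSRF is sqrt(((n-1)/n W + B/n) / W) with W
    the mean within-chain variance and B/n the variance of chain means;
    the multivariate factor replaces B/W by the largest eigenvalue of
    W⁻¹B and carries the (m+1)/m correction.
    """
    arr = _chain_matrices(chains)         # (m, n, p)
    m, n, p = arr.shape
    if m < 2:
        raise ValueError("need >= 2 chains")
    if n < 10:
        raise ValueError("need >= 10 draws per chain")
    if parameter_names is None:
        parameter_names = [f"p{i}" for i in range(p)]

    chain_means = arr.mean(axis=1)                      # (m, p)
    W_mat = np.zeros((p, p))
    for c in range(m):
        dev = arr[c] - chain_means[c]
        W_mat += dev.T @ dev / (n - 1)
    W_mat /= m
    grand = chain_means.mean(axis=0)
    dev_m = chain_means - grand
    B_mat = n * (dev_m.T @ dev_m) / (m - 1)             # B (between, scaled by n)

    W = np.diag(W_mat)
    if np.any(W <= 0):
        bad = [parameter_names[i] for i in np.where(W <= 0)[0]]
        raise ValueError(f"degenerate chain (zero within-chain variance): {bad}")
    var_hat = (n - 1) / n * W + np.diag(B_mat) / n
    # estimator noise can push the ratio below 1; floor there
    psrf = np.maximum(np.sqrt(var_hat / W), 1.0)

    # Brooks–Gelman: largest eigenvalue of W^{-1} B / n
    lam1 = float(np.linalg.eigvals(np.linalg.solve(W_mat, B_mat / n)).real.max())
    mpsrf = max(float(np.sqrt((n - 1) / n + (m + 1) / m * lam1)), 1.0)

    # ESS per parameter across pooled chains
    from .pglmm import _ess
    ess = pd.Series({name: _ess(arr[:, :, i])
                     for i, name in enumerate(parameter_names)})
    return ConvergenceReport(
        psrf=pd.Series(psrf, index=parameter_names),
        multivariate_psrf=mpsrf, ess=ess, threshold=threshold)


def convergence_report(samples: PosteriorSamples,
                       threshold: float = PSRF_THRESHOLD) -> ConvergenceReport:
    """Gelman–Rubin report over all parameters of a fit."""
    names = samples.parameter_names
    chains = []
    for c in samples.chains:
        chains.append(np.column_stack(
            [c.beta, c.sigma2_p[:, None], c.sigma2_e[:, None]]))
    return gelman_rubin(chains, parameter_names=names, threshold=threshold)


def _deviance(y, X, beta, u, sigma2_e) -> float:
    r = y - X @ beta - u
    n = y.shape[0]
    return float(n * (np.log(2 * np.pi) + np.log(sigma2_e)) + (r @ r) / sigma2_e)


def dic(samples: PosteriorSamples, y, X) -> tuple[float, float, float]:
    """(DIC, pD, mean deviance) from the stored per-draw deviances.

    D(θ̄) plugs the posterior means of (beta, u, sigma2_e) into the
    conditional Gaussian deviance; pD = D̄ − D(θ̄).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    devs = np.concatenate([c.deviance for c in samples.chains])
    if devs.size == 0:
        raise ValueError("no retained draws")
    d_bar = float(devs.mean())
    beta_bar = np.concatenate([c.beta for c in samples.chains]).mean(axis=0)
    u_bar = np.concatenate([c.u for c in samples.chains]).mean(axis=0)
    s2e_bar = float(np.concatenate(
        [c.sigma2_e for c in samples.chains]).mean())
    d_hat = _deviance(y, X, beta_bar, u_bar, s2e_bar)
    if not np.isfinite(d_hat):
        raise ValueError("non-finite deviance at the posterior mean")
    p_d = d_bar - d_hat
    return d_bar + p_d, p_d, d_bar


def stepwise_selection(data: pd.DataFrame, A, candidates,
                       base_effect: str = "div_rate",
                       priors: PriorSpec | None = None,
                       settings: MCMCSettings | None = None,
                       transform_map=None) -> pd.DataFrame:
    """Fit every candidate subset (always including ``base_effect``), rank by DIC.

    ``candidates`` are effect names from the family dataset; all 2^k
    subsets unioned with the base effect are fitted at ``settings``
    (default: the reduced selection settings) and returned sorted
    ascending by DIC.  Failed fits are annotated, not fatal.
    """
    settings = settings or REDUCED_SETTINGS
    priors = priors or PriorSpec()
    candidates = list(candidates)
    rows = []
    for k in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            effects = [base_effect] + list(combo)
            spec = ModelSpec(name="+".join(effects), main_effects=effects)
            if transform_map:
                spec.transform_map.update(transform_map)
            try:
                y, X, labels = build_design(data, spec)
                fit = gibbs_fit(y, X, A, priors, settings, labels=labels)
                dic_val, p_d, d_bar = dic(fit, y, X)
                rows.append({"model": spec.name, "n_effects": len(effects),
                             "DIC": dic_val, "pD": p_d, "mean_deviance": d_bar,
                             "error": ""})
            except Exception as exc:  # partial table on failures
                log.warning("selection fit failed for %s: %s", spec.name, exc)
                rows.append({"model": spec.name, "n_effects": len(effects),
                             "DIC": np.nan, "pD": np.nan,
                             "mean_deviance": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows).sort_values(
        "DIC", na_position="last").reset_index(drop=True)
    return table
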