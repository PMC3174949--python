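"""Two-component Gaussian mixture estimation for signal/noise separation.

Normalized intensities on a slide are modeled as a mixture of two normal
populations: a non-reactive (noise) component with mean mu1 and variance
var1, and a reactive (signal) component with mean mu2 and variance var2.
Parameters are estimated by expectation maximization, initialized from the
empirical moments of two suitable control-peptide groups.  Calls are made
from the fitted noise component alone: the exceedance probability

    p_hat(y) = P(Y >= y | Y ~ Normal(mu1, var1)) = 1 - Phi((y - mu1)/sigma1)

is the chance a pure-noise draw is at least as large as the observation, and
a peptide is called when p_hat < alpha (default alpha = 0.05, i.e. the value
lies strictly above the upper 5% quantile q_hat = mu1 + z_{0.95} * sigma1 of
the noise distribution).  Relying on the noise component makes the cutoff
adaptive to the slide's noise level and robust to misspecification of the
(harder to estimate) signal component; a posterior local-FDR mode based on
both components is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from rapmad.errors import ConfigError, DataError, StateError

#: EM convergence: relative log-likelihood change tolerance and iteration cap.
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000

#: Variance floor (log2-intensity scale) preventing component collapse.
VARIANCE_FLOOR = 1e-6

#: Default mixing-weight initialization: most peptides are expected inert.
DEFAULT_WEIGHTS = (0.9, 0.1)


@dataclass
class MixtureFit:
    """Result of a two-Gaussian EM fit; component 1 is the noise component
    (mu1 <= mu2 is enforced at exit)."""

    mu1: float
    var1: float
    mu2: float
    var2: float
    pi1: float
    pi2: float
    responsibilities: Optional[np.ndarray] = None
    loglik_trace: list = field(default_factory=list)
    converged: bool = False

    def summary(self) -> dict:
        return {
            "mu_noise": self.mu1,
            "var_noise": self.var1,
            "mu_signal": self.mu2,
            "var_signal": self.var2,
            "weight_noise": self.pi1,
            "weight_signal": self.pi2,
            "n_iterations": len(self.loglik_trace),
            "converged": self.converged,
            "loglik": self.loglik_trace[-1] if self.loglik_trace else None,
        }


@dataclass(frozen=True)
class ExceedanceResult:
    """Noise-exceedance probability of one normalized intensity."""

    value: float
    p_hat: float
    cutoff_quantile: float
    exceeds: bool


def init_from_controls(nonreactive: Sequence[float], reactive: Sequence[float]) -> MixtureFit:
    """Initial mixture parameters from two control groups' empirical moments.

    The non-reactive group seeds the noise component, the reactive group the
    signal component; weights start at (0.9, 0.1).  A zero group variance is
    floored with a warning rather than rejected.
    """
    a = np.asarray(nonreactive, dtype=float)
    b = np.asarray(reactive, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each control group needs at least 2 values for initialization")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DataError("non-finite control values")
    var1 = max(float(np.var(a, ddof=1)), VARIANCE_FLOOR)
    var2 = max(float(np.var(b, ddof=1)), VARIANCE_FLOOR)
    return MixtureFit(
        mu1=float(np.mean(a)),
        var1=var1,
        mu2=float(np.mean(b)),
        var2=var2,
        pi1=DEFAULT_WEIGHTS[0],
        pi2=DEFAULT_WEIGHTS[1],
    )


def _log_density(x: np.ndarray, fit_params) -> np.ndarray:
    mu1, var1, mu2, var2, pi1, pi2 = fit_params
    lp = np.empty((x.size, 2))
    lp[:, 0] = np.log(pi1 + 1e-300) + stats.norm.logpdf(x, mu1, np.sqrt(var1))
    lp[:, 1] = np.log(pi2 + 1e-300) + stats.norm.logpdf(x, mu2, np.sqrt(var2))
    return lp


def em_fit(
    values: Sequence[float],
    init: MixtureFit,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> MixtureFit:
    """Fit the two-component Gaussian mixture by EM.

    Standard alternation of E-step responsibilities and M-step weighted
    moments, with a variance floor applied each M-step.  Iteration stops when
    the relative log-likelihood improvement drops below ``tol`` or after
    ``max_iter`` rounds; components are relabeled at exit so mu1 <= mu2.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise DataError(f"EM needs at least 4 observations, got {x.size}")
    if not np.isfinite(x).all():
        raise DataError("non-finite values passed to EM")
    if np.ptp(x) == 0:
        raise DataError("all values identical; mixture fit is degenerate")
    params = (init.mu1, init.var1, init.mu2, init.var2, init.pi1, init.pi2)
    if not all(np.isfinite(params)):
        raise DataError("non-finite initial parameters")

    trace: list[float] = []
    converged = False
    resp = None
    for _ in range(max_iter):
        lp = _log_density(x, params)
        ll_obs = logsumexp(lp, axis=1)
        ll = float(ll_obs.sum())
        # E step
        resp = np.exp(lp - ll_obs[:, None])
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        var = np.maximum(var, VARIANCE_FLOOR)
        pi = nk / x.size
        params = (float(mu[0]), float(var[0]), float(mu[1]), float(var[1]), float(pi[0]), float(pi[1]))
        if trace and abs(ll - trace[-1]) <= tol * max(abs(trace[-1]), 1.0):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
    # responsibilities under the final parameters
    lp = _log_density(x, params)
    resp = np.exp(lp - logsumexp(lp, axis=1)[:, None])

    mu1, var1, mu2, var2, pi1, pi2 = params
    if mu1 > mu2:
        mu1, var1, mu2, var2, pi1, pi2 = mu2, var2, mu1, var1, pi2, pi1
        resp = resp[:, ::-1]
    return MixtureFit(
        mu1=mu1, var1=var1, mu2=mu2, var2=var2, pi1=pi1, pi2=pi2,
        responsibilities=resp, loglik_trace=trace, converged=converged,
    )


def noise_quantile(fit: MixtureFit, alpha: float = 0.05) -> float:
    """Upper-alpha quantile q_hat of the fitted noise component."""
    if not (0.0 < alpha <= 1.0):
        raise ConfigError(f"alpha must lie in (0, 1], got {alpha}")
    return float(stats.norm.ppf(1.0 - alpha, loc=fit.mu1, scale=np.sqrt(fit.var1)))


def exceedance_prob(value: float, fit: MixtureFit, alpha: float = 0.05) -> ExceedanceResult:
    """Probability that a noise draw is at least as large as ``value``.

    ``exceeds`` is True exactly when p_hat < alpha, equivalently when the
    value lies strictly above the noise component's upper-alpha quantile.
    """
    if not (0.0 < alpha <= 1.0):
        raise ConfigError(f"alpha must lie in (0, 1], got {alpha}")
    p = float(stats.norm.sf(value, loc=fit.mu1, scale=np.sqrt(fit.var1)))
    return ExceedanceResult(value=float(value), p_hat=p, cutoff_quantile=alpha, exceeds=p < alpha)


def exceedance_probs(values: Sequence[float], fit: MixtureFit) -> np.ndarray:
    """Vectorized p_hat over an array of normalized intensities."""
    return stats.norm.sf(np.asarray(values, dtype=float), loc=fit.mu1, scale=np.sqrt(fit.var1))


def posterior_fdr(values: Sequence[float], fit: MixtureFit, threshold: float = 0.5):
    """Local false-discovery rates from the full mixture, and the call-set FDR.

    local_fdr(y) = pi1 phi1(y) / (pi1 phi1(y) + pi2 phi2(y)) is the posterior
    probability of the noise component; peptides with local_fdr < threshold
    form the call set, whose estimated FDR is the mean local fdr among calls.
    Returns (local_fdr array, call mask, call-set FDR or None if no calls).
    This is an alternative calling mode, off by default, that leans on the
    normality of the signal component as well as the noise component.
    """
    x = np.asarray(values, dtype=float)
    lp = _log_density(x, (fit.mu1, fit.var1, fit.mu2, fit.var2, fit.pi1, fit.pi2))
    denom = logsumexp(lp, axis=1)
    with np.errstate(invalid="ignore"):
        local = np.exp(lp[:, 0] - denom)
    if fit.pi2 == 0:
        local = np.ones_like(local)
    calls = local < threshold
    fdr = float(local[calls].mean()) if calls.any() else None
    return local, calls, fdr
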