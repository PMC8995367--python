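"""Cumulative Gaussian psychometric function fitting.

A decision set (all decisions of a session, or the subset chosen as more
confident) is summarised per signed contrast difference ``delta`` as
``k`` "test reported higher" out of ``n`` decisions.  The psychometric
model is

    p(delta) = lambda/2 + (1 - lambda) * Phi((delta - mu) / sigma)

with PSE ``mu``, slope parameter ``sigma`` (SD of the cumulative Gaussian)
and a symmetric lapse rate ``lambda`` (equal asymptotes, appropriate for a
left/right report recoded as "test higher").  Contrast sensitivity is
``1/sigma``.  Fitting maximises the binomial log-likelihood with a weak
Beta(1.5, 20) penalty on the lapse rate, from a fixed grid of starting
points, so results are deterministic.  Goodness of fit is the deviance D,
twice the log-likelihood ratio of the saturated binomial model to the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr  # standard normal CDF, vectorised
from scipy.special import xlogy

# parameter bounds (percent-contrast units for mu and sigma)
SIGMA_BOUNDS = (0.1, 100.0)
LAMBDA_BOUNDS = (0.0, 0.1)
MU_SPAN = 2.0          # mu searched within the delta range widened by this factor
_LAPSE_PRIOR_A, _LAPSE_PRIOR_B = 1.5, 20.0


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted psychometric function for one decision set."""

    mu: float
    sigma: float
    lam: float
    deviance: float
    n_total: float
    converged: bool = True

    @property
    def sensitivity(self) -> float:
        """Contrast sensitivity, the inverse SD of the fitted function."""
        return 1.0 / self.sigma

    def predict(self, delta) -> np.ndarray:
        """Probability of a 'test higher' report at contrast difference(s)."""
        return _predict(np.asarray(delta, float), self.mu, self.sigma, self.lam)


def aggregate_proportions(deltas, decisions) -> np.ndarray:
    """Tally decisions into per-level counts.

    Returns a structured view as an array of shape (levels, 3) with columns
    (delta, n, k) where ``k`` counts 'test higher' reports; sorted by delta.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("no decisions to aggregate")
    higher = np.asarray(decisions) == "higher"
    levels, inverse = np.unique(deltas, return_inverse=True)
    n = np.bincount(inverse, minlength=levels.size)
    k = np.bincount(inverse, weights=higher, minlength=levels.size)
    return np.column_stack([levels, n, k])


def _predict(delta, mu, sigma, lam):
    return lam / 2.0 + (1.0 - lam) * ndtr((delta - mu) / sigma)


def _nll(params, delta, n, k):
    """Penalized negative log-likelihood and its gradient in
    (mu, log sigma, lambda)."""
    mu, log_sigma, lam = params
    sigma = np.exp(log_sigma)
    z = (delta - mu) / sigma
    phi = np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi)
    p = np.clip(lam / 2.0 + (1.0 - lam) * ndtr(z), 1e-12, 1 - 1e-12)
    ll = np.sum(xlogy(k, p) + xlogy(n - k, 1.0 - p))
    # Beta(1.5, 20) penalty on the lapse rate keeps lambda identifiable
    # at 7-point designs without forcing it to zero.
    lam_c = min(max(lam, 1e-12), 1 - 1e-12)
    penalty = (_LAPSE_PRIOR_A - 1) * np.log(lam_c) \
        + (_LAPSE_PRIOR_B - 1) * np.log1p(-lam_c)
    dl_dp = k / p - (n - k) / (1.0 - p)
    grad = -np.array([
        np.sum(dl_dp * (-(1.0 - lam) * phi / sigma)),
        np.sum(dl_dp * (-(1.0 - lam) * phi * z)),
        np.sum(dl_dp * (0.5 - ndtr(z)))
        + (_LAPSE_PRIOR_A - 1) / lam_c - (_LAPSE_PRIOR_B - 1) / (1 - lam_c),
    ])
    return -(ll + penalty), grad


def fit_cumulative_gaussian(counts: np.ndarray) -> PsychometricFit:
    """Penalized maximum-likelihood fit of the cumulative Gaussian.

    Parameters
    ----------
    counts
        Array-like of rows (delta, n, k) as produced by
        :func:`aggregate_proportions`.  ``k`` may be fractional (expected
        counts from a theoretical observer are admissible).

    Notes
    -----
    Degenerate data are reported rather than hidden: response proportions
    carrying no slope information push sigma to its upper bound, perfectly
    separated data push it to the lower bound; both raise a warning and
    mark the fit as not converged.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 3:
        raise ValueError("counts must be rows of (delta, n, k)")
    mask = counts[:, 1] > 0
    counts = counts[mask]
    delta, n, k = counts[:, 0], counts[:, 1], counts[:, 2]
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if len(np.unique(delta)) != len(delta):
        raise ValueError("deltas must be unique within a set")
    if len(delta) < 3:
        raise ValueError(
            f"need >= 3 informative levels to fit, got {len(delta)}")

    saturated = (k == 0) | (k == n)
    if np.all(k == 0) or np.all(k == n):
        warnings.warn("psychometric fit degenerate: responses carry no slope "
                      "information (sigma at upper bound)", RuntimeWarning)
        fit = PsychometricFit(mu=float(np.median(delta)),
                              sigma=SIGMA_BOUNDS[1], lam=0.0,
                              deviance=np.nan, n_total=float(n.sum()),
                              converged=False)
        return PsychometricFit(fit.mu, fit.sigma, fit.lam,
                               deviance=deviance(fit, counts),
                               n_total=fit.n_total, converged=False)
    if np.all(saturated):
        # perfectly separated: the transition lies between the highest
        # all-"lower" level and the lowest all-"higher" level
        warnings.warn("psychometric fit degenerate: data perfectly separated "
                      "(sigma at lower bound)", RuntimeWarning)
        lo = delta[k == 0].max() if np.any(k == 0) else delta.min()
        hi = delta[k == n].min() if np.any(k == n) else delta.max()
        fit = PsychometricFit(mu=float((lo + hi) / 2), sigma=SIGMA_BOUNDS[0],
                              lam=0.0, deviance=np.nan,
                              n_total=float(n.sum()), converged=False)
        return PsychometricFit(fit.mu, fit.sigma, fit.lam,
                               deviance=deviance(fit, counts),
                               n_total=fit.n_total, converged=False)

    span = delta.max() - delta.min()
    mu_lo = delta.min() - (MU_SPAN - 1) / 2 * span
    mu_hi = delta.max() + (MU_SPAN - 1) / 2 * span
    bounds = [(mu_lo, mu_hi),
              (np.log(SIGMA_BOUNDS[0]), np.log(SIGMA_BOUNDS[1])),
              LAMBDA_BOUNDS]
    # fixed multi-start grid: PSE around the centre, shallow and steep slopes
    mid = float(np.median(delta))
    starts = [(m, np.log(s), 0.02)
              for m in (mid, mid - span / 4, mid + span / 4)
              for s in (span / 6 if span else 1.0, span / 1.5 if span else 5.0)]
    best = None
    for x0 in starts:
        res = minimize(_nll, x0, args=(delta, n, k), method="L-BFGS-B",
                       jac=True, bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    mu, log_sigma, lam = best.x
    sigma = float(np.exp(log_sigma))

    converged = True
    if sigma >= SIGMA_BOUNDS[1] * 0.999:
        warnings.warn("psychometric fit degenerate: responses carry no slope "
                      "information (sigma at upper bound)", RuntimeWarning)
        sigma = SIGMA_BOUNDS[1]
        converged = False
    elif sigma <= SIGMA_BOUNDS[0] * 1.001:
        warnings.warn("psychometric fit degenerate: data perfectly separated "
                      "(sigma at lower bound)", RuntimeWarning)
        sigma = SIGMA_BOUNDS[0]
        converged = False

    fit = PsychometricFit(mu=float(mu), sigma=sigma, lam=float(lam),
                          deviance=np.nan, n_total=float(n.sum()),
                          converged=converged)
    return PsychometricFit(fit.mu, fit.sigma, fit.lam,
                           deviance=deviance(fit, counts),
                           n_total=fit.n_total, converged=converged)


def deviance(fit: PsychometricFit, counts: np.ndarray) -> float:
    """Deviance D of a fit: 2 * log LR of the saturated vs the fitted model.

    ``D = 2 * sum[k ln(k/(n p)) + (n-k) ln((n-k)/(n(1-p)))]`` with the
    convention 0*ln(0) = 0.  A fitted probability of exactly 0 or 1 that
    disagrees with the observed count yields +inf (degenerate fit).
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts[:, 1] > 0]
    delta, n, k = counts[:, 0], counts[:, 1], counts[:, 2]
    p = _predict(delta, fit.mu, fit.sigma, fit.lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = xlogy(k, k) - xlogy(k, n * p)
        t2 = xlogy(n - k, n - k) - xlogy(n - k, n * (1.0 - p))
    d = 2.0 * float(np.sum(t1 + t2))
    return np.inf if np.isnan(d) else d
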