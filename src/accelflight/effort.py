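"""Duration-dependent Weibull model of per-flight effort.

Per-flight mean VeDBA values v_i are modelled as Weibull with shape and
scale that both depend on the (log) flight duration T_i through log
links:

    k(T)      = exp(alpha0 + alpha1 * ln T)
    lambda(T) = exp(beta0  + beta1  * ln T)
    v_i ~ Weibull(k(T_i), lambda(T_i))

so both parameters stay positive for every T > 0.  Fitting maximises
the exact log-likelihood over (alpha0, alpha1, beta0, beta1) by
quasi-Newton from moment-based starting values, with a Nelder-Mead
multi-start fallback; non-convergence is flagged, never silent.  The
p-quantile curve is closed form:

    Q(p; T) = lambda(T) * (-ln(1 - p)) ** (1 / k(T)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gamma as gamma_fn

_MAX_EXP = 500.0  # cap on k * ln(v / lambda) against overflow


@dataclass(frozen=True)
class WeibullDurationModel:
    """Fitted coefficients of the duration-dependent Weibull model."""

    alpha0: float
    alpha1: float
    beta0: float
    beta1: float
    n_obs: int
    log_likelihood: float
    converged: bool

    def shape(self, durations) -> np.ndarray:
        """k(T) > 0 for all T > 0."""
        return np.exp(self.alpha0 + self.alpha1 * np.log(np.asarray(durations, dtype=float)))

    def scale(self, durations) -> np.ndarray:
        """lambda(T) > 0 for all T > 0."""
        return np.exp(self.beta0 + self.beta1 * np.log(np.asarray(durations, dtype=float)))


def _neg_log_likelihood(params: np.ndarray, log_t: np.ndarray, log_v: np.ndarray) -> float:
    a0, a1, b0, b1 = params
    log_k = a0 + a1 * log_t
    log_lam = b0 + b1 * log_t
    z = np.exp(log_k) * (log_v - log_lam)  # k * ln(v/lambda)
    if np.any(z > _MAX_EXP):
        return 1e12
    ll = log_k - log_lam + (np.exp(log_k) - 1.0) * (log_v - log_lam) - np.exp(z)
    total = ll.sum()
    if not np.isfinite(total):
        return 1e12
    return -float(total)


def _moment_start(v: np.ndarray) -> tuple[float, float]:
    """Shape/scale start values from mean and coefficient of variation."""
    mean, sd = float(v.mean()), float(v.std())
    cv = sd / mean if mean > 0 and sd > 0 else 0.5
    k0 = float(np.clip(cv**-1.086, 0.2, 50.0))  # Justus approximation
    lam0 = mean / gamma_fn(1.0 + 1.0 / k0)
    return k0, lam0


def fit(durations, vedba_means, min_obs: int = 50) -> WeibullDurationModel:
    """Maximum-likelihood fit of (alpha0, alpha1, beta0, beta1).

    Requires ``min_obs`` observations with strictly positive durations
    and VeDBA values.  Deterministic given the data.
    """
    t = np.asarray(durations, dtype=float)
    v = np.asarray(vedba_means, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("durations and vedba_means must be equal-length 1-D")
    if len(t) < min_obs:
        raise ValueError(f"need at least {min_obs} observations, got {len(t)}")
    if np.any(t <= 0) or np.any(v <= 0):
        raise ValueError("durations and VeDBA values must all be > 0")
    log_t, log_v = np.log(t), np.log(v)

    k0, lam0 = _moment_start(v)
    x0 = np.array([np.log(k0), 0.0, np.log(lam0), 0.0])
    best = minimize(_neg_log_likelihood, x0, args=(log_t, log_v), method="L-BFGS-B")
    if not best.success:
        # multi-start fallback on the slope terms
        for a1 in (-0.2, 0.0, 0.2):
            for b1 in (-0.1, 0.0, 0.1):
                alt = minimize(
                    _neg_log_likelihood,
                    np.array([np.log(k0), a1, np.log(lam0), b1]),
                    args=(log_t, log_v),
                    method="Nelder-Mead",
                    options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-10},
                )
                if alt.fun < best.fun:
                    best = alt
    a0, a1, b0, b1 = best.x
    return WeibullDurationModel(
        alpha0=float(a0),
        alpha1=float(a1),
        beta0=float(b0),
        beta1=float(b1),
        n_obs=len(t),
        log_likelihood=-float(best.fun),
        converged=bool(best.success and np.isfinite(best.fun)),
    )


def quantile_curve(model: WeibullDurationModel, durations, p: float) -> np.ndarray:
    """Q(p; T) = lambda(T) * (-ln(1-p))^(1/k(T)) on a duration grid."""
    if not 0 < p < 1:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    t = np.asarray(durations, dtype=float)
    if np.any(t <= 0):
        raise ValueError("durations must be > 0")
    return model.scale(t) * (-np.log1p(-p)) ** (1.0 / model.shape(t))


def simulate_from_model(model: WeibullDurationModel, durations, seed: int = 0) -> np.ndarray:
    """Draw one VeDBA value per duration, v_i ~ Weibull(k(T_i), lambda(T_i))."""
    t = np.asarray(durations, dtype=float)
    if np.any(t <= 0):
        raise ValueError("durations must be > 0")
    rng = np.random.default_rng(seed)
    return model.scale(t) * rng.weibull(model.shape(t), size=t.shape)
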