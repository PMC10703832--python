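"""Yeo-Johnson power transform: forward/inverse maps and maximum-likelihood
shape estimation.

The Yeo-Johnson transform extends the Box-Cox family to zero and negative
inputs, which respiratory reactance indices (X5, ALX deltas) require.  For a
shape parameter ``lam``:

    y >= 0:  psi(y) = ((y+1)**lam - 1) / lam          (lam != 0)
             psi(y) = log(y+1)                        (lam == 0)
    y <  0:  psi(y) = -((1-y)**(2-lam) - 1) / (2-lam) (lam != 2)
             psi(y) = -log(1-y)                       (lam == 2)

``psi`` is strictly increasing in ``y`` for every ``lam`` and fixes 0, so a
central interval in transformed space maps back to an interval on the
measurement scale.  The shape is estimated by maximising the profile
log-likelihood under a Gaussian model for the transformed sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

__all__ = [
    "TransformParams",
    "yj_forward",
    "yj_inverse",
    "yj_profile_loglik",
    "fit_lambda",
    "fit_transform_params",
    "DegenerateSampleError",
]

# lambda exponents closer to the singular values than this are routed to the
# log branches to keep the log1p/expm1 formulations well conditioned
_LOG_BRANCH_TOL = 1e-8

LAMBDA_BOUNDS = (-5.0, 5.0)
_BRENT_XTOL = 1e-6


class DegenerateSampleError(ValueError):
    """Raised when a sample is constant or too small to fit a transform."""


def yj_forward(y, lam: float):
    """Apply the Yeo-Johnson transform with shape ``lam``.

    Accepts scalars or arrays; returns the same shape.  Uses ``log1p`` /
    ``expm1`` formulations so values near zero lose no precision.
    """
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    pos = y >= 0

    if abs(lam) < _LOG_BRANCH_TOL:
        out[pos] = np.log1p(y[pos])
    else:
        # ((y+1)^lam - 1)/lam computed as expm1(lam*log1p(y))/lam
        out[pos] = np.expm1(lam * np.log1p(y[pos])) / lam

    neg = ~pos
    if abs(2.0 - lam) < _LOG_BRANCH_TOL:
        out[neg] = -np.log1p(-y[neg])
    else:
        out[neg] = -np.expm1((2.0 - lam) * np.log1p(-y[neg])) / (2.0 - lam)

    if out.ndim == 0:
        return float(out)
    return out


def yj_attainable_bounds(lam: float) -> tuple[float, float]:
    """Open interval of values reachable by ``psi(., lam)``.

    For lam > 0 the positive branch is unbounded but the negative branch
    saturates at -1/(2-lam) (when lam < 2); for lam < 2 vice versa.
    """
    # positive branch covers [0, inf) if lam >= 0 else [0, -1/lam)
    hi = np.inf if lam >= 0 else -1.0 / lam
    # negative branch covers (-inf, 0) if lam <= 2 else (-1/(2-lam), 0)
    lo = -np.inf if lam <= 2 else 1.0 / (2.0 - lam)
    return (lo, hi)


def yj_inverse(x, lam: float):
    """Invert the Yeo-Johnson transform.

    Raises :class:`ValueError` when ``x`` lies outside the attainable range
    of ``psi(., lam)``; the message carries the finite bound so callers can
    fall back to a one-sided interval.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = yj_attainable_bounds(lam)
    if np.any(x <= lo) or np.any(x >= hi):
        raise ValueError(
            f"value outside attainable range ({lo}, {hi}) of the "
            f"Yeo-Johnson transform with lambda={lam}"
        )
    out = np.empty_like(x)
    pos = x >= 0
    if abs(lam) < _LOG_BRANCH_TOL:
        out[pos] = np.expm1(x[pos])
    else:
        # inverse of positive branch: (lam*x + 1)^(1/lam) - 1
        out[pos] = np.expm1(np.log1p(lam * x[pos]) / lam)
    neg = ~pos
    if abs(2.0 - lam) < _LOG_BRANCH_TOL:
        out[neg] = -np.expm1(-x[neg])
    else:
        out[neg] = -np.expm1(np.log1p(-(2.0 - lam) * x[neg]) / (2.0 - lam))
    if out.ndim == 0:
        return float(out)
    return out


def yj_profile_loglik(sample, lam: float) -> float:
    """Profile log-likelihood of ``lam`` for a Gaussian model of psi(sample).

    ell(lam) = -(n/2) * log(sigma_hat^2(lam))
               + (lam - 1) * sum_i sign(y_i) * log(|y_i| + 1)

    where sigma_hat^2 is the n-denominator (MLE) variance of the transformed
    sample.  Additive constants independent of lambda are dropped.
    """
    y = np.asarray(sample, dtype=float)
    if y.size < 3:
        raise DegenerateSampleError("need at least 3 observations")
    if np.ptp(y) == 0:
        raise DegenerateSampleError("constant sample: transformed variance is zero")
    t = yj_forward(y, lam)
    var = float(np.var(t))  # n denominator
    if var <= 0:
        raise DegenerateSampleError("constant sample: transformed variance is zero")
    jacobian = float(np.sum(np.sign(y) * np.log1p(np.abs(y))))
    n = y.size
    return -0.5 * n * np.log(var) + (lam - 1.0) * jacobian


def fit_lambda(sample, bounds: tuple[float, float] = LAMBDA_BOUNDS) -> float:
    """Maximum-likelihood Yeo-Johnson shape via bounded Brent search.

    Warns (and still returns) if the optimum sits at a search bound.
    """
    y = np.asarray(sample, dtype=float)
    if y.size < 8:
        raise DegenerateSampleError("need at least 8 observations to fit lambda")
    if np.ptp(y) == 0:
        raise DegenerateSampleError("constant sample")

    res = optimize.minimize_scalar(
        lambda lam: -yj_profile_loglik(y, lam),
        bounds=bounds,
        method="bounded",
        options={"xatol": _BRENT_XTOL},
    )
    lam_hat = float(res.x)
    if min(lam_hat - bounds[0], bounds[1] - lam_hat) < 10 * _BRENT_XTOL:
        warnings.warn(
            f"lambda optimum {lam_hat:.4f} at search bound {bounds}",
            RuntimeWarning,
            stacklevel=2,
        )
    return lam_hat


@dataclass
class TransformParams:
    """Fitted transform for one measurement item in one sex stratum.

    ``mu_t`` / ``sigma_t`` are the mean and sample SD (n-1 denominator) of
    the transformed values, on the unstandardised psi scale.
    """

    lambda_hat: float
    mu_t: float
    sigma_t: float
    n: int
    item: Optional[object] = None
    stratum: Optional[str] = None
    at_bound: bool = field(default=False)

    def to_dict(self) -> dict:
        d = {
            "lambda": self.lambda_hat,
            "mu_t": self.mu_t,
            "sigma_t": self.sigma_t,
            "n": self.n,
            "at_bound": self.at_bound,
        }
        if self.item is not None:
            d["item"] = str(self.item)
        if self.stratum is not None:
            d["stratum"] = self.stratum
        return d


def fit_transform_params(sample, item=None, stratum: str | None = None) -> TransformParams:
    """Fit lambda by profile likelihood and record transformed-space moments."""
    y = np.asarray(sample, dtype=float)
    at_bound = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        lam_hat = fit_lambda(y)
        at_bound = any(issubclass(w.category, RuntimeWarning) for w in caught)
    t = yj_forward(y, lam_hat)
    sigma = float(np.std(t, ddof=1))
    if sigma <= 0:
        raise DegenerateSampleError("transformed sample is constant")
    return TransformParams(
        lambda_hat=lam_hat,
        mu_t=float(np.mean(t)),
        sigma_t=sigma,
        n=int(y.size),
        item=item,
        stratum=stratum,
        at_bound=at_bound,
    )
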