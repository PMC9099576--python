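"""MCMC convergence diagnostics."""

from __future__ import annotations

import numpy as np
from statsmodels.regression.linear_model import yule_walker

from spectragp.errors import DegenerateStatisticError


def _spectrum0(x: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density of a chain segment at frequency zero, estimated from
    an autoregressive fit with AIC order selection (the approach of the
    classical ``spectrum0.ar`` estimator): s0 = sigma2 / (1 - sum(phi))^2.
    """
    n = len(x)
    v = x.var(ddof=1)
    if v == 0:
        raise DegenerateStatisticError("zero-variance chain segment")
    if max_order is None:
        max_order = min(20, n // 20)
    best_aic = n * np.log(v)  # order 0
    s0 = v
    xc = x - x.mean()
    for order in range(1, max_order + 1):
        try:
            rho, sigma = yule_walker(xc, order=order, method="mle")
        except np.linalg.LinAlgError:  # pragma: no cover
            continue
        if sigma <= 0:
            continue
        aic = n * np.log(sigma ** 2) + 2 * order
        if aic < best_aic:
            denom = (1.0 - rho.sum()) ** 2
            if denom > 0:
                best_aic = aic
                s0 = sigma ** 2 / denom
    return s0


def geweke_z(chain: np.ndarray, frac_a: float = 0.1, frac_b: float = 0.5) -> float:
    """Geweke convergence z-score for a single MCMC chain.

    Compares the mean of the first ``frac_a`` of the chain against the mean
    of the last ``frac_b``, standardized by spectral-density estimates of
    each segment's long-run variance.  Under stationarity z is
    asymptotically standard normal.
    """
    chain = np.asarray(chain, dtype=float)
    if chain.ndim != 1 or len(chain) < 100:
        raise DegenerateStatisticError("chain must be 1-D with at least 100 samples")
    if not (0 < frac_a < 1 and 0 < frac_b < 1 and frac_a + frac_b <= 1):
        raise ValueError("segment fractions must be in (0,1) with frac_a + frac_b <= 1")
    n = len(chain)
    first = chain[: int(np.floor(frac_a * n))]
    last = chain[n - int(np.floor(frac_b * n)):]
    if len(first) < 10 or len(last) < 10:
        raise DegenerateStatisticError("segments too short for spectral estimation")
    s_a = _spectrum0(first)
    s_b = _spectrum0(last)
    return float((first.mean() - last.mean())
                 / np.sqrt(s_a / len(first) + s_b / len(last)))
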