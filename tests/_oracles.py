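"""Independent reference implementations used only by the test suite.

These deliberately avoid the code paths of the package: the CSE oracle is
a per-household Python loop over the definition; the Phi-K oracle
integrates the bivariate normal *density* with scipy's dblquad and scans
rho over a successively refined grid; the logistic oracle is statsmodels'
Newton-method maximum-likelihood fit.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate
from scipy.stats import norm


def brute_force_cse(nse_values, burden, cost, threshold):
    """Flag each household by looping over the literal definition."""
    flags = []
    for nse in nse_values:
        oop = burden * cost
        capacity = threshold * nse
        flags.append(oop > capacity)
    return flags


def _bvn_pdf(x, y, rho):
    det = 1.0 - rho * rho
    z = (x * x - 2.0 * rho * x * y + y * y) / det
    return np.exp(-z / 2.0) / (2.0 * np.pi * np.sqrt(det))


def _oracle_cell_probs(px, py, rho):
    """Cell probabilities by numerical integration of the density."""
    ex = norm.ppf(np.concatenate([[0.0], np.cumsum(px)]))
    ey = norm.ppf(np.concatenate([[0.0], np.cumsum(py)]))
    ex[-1], ey[-1] = np.inf, np.inf
    # the density degenerates onto the diagonal as rho -> 1; that regime
    # only feeds the coarse saturation check, so lower accuracy suffices
    # and quadpack's subdivision-limit complaints there are expected
    import warnings

    tol = (1e-11, 1e-9) if rho < 0.999 else (1e-7, 1e-5)
    probs = np.empty((len(px), len(py)))
    with warnings.catch_warnings():
        if rho >= 0.999:
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
        for i in range(len(px)):
            for j in range(len(py)):
                val, _ = integrate.dblquad(
                    lambda y, x: _bvn_pdf(x, y, rho),
                    ex[i], ex[i + 1],
                    ey[j], ey[j + 1],
                    epsabs=tol[0], epsrel=tol[1],
                )
                probs[i, j] = val
    return probs


def _oracle_chi2_of_rho(table, rho):
    n = table.sum()
    px = table.sum(axis=1) / n
    py = table.sum(axis=0) / n
    p = _oracle_cell_probs(px, py, rho)
    indep = np.outer(px, py)
    return n * np.sum((p - indep) ** 2 / indep)


def phik_grid_scan(table, n_levels: int = 6, n_grid: int = 21):
    """Phi-K by scanning rho over a successively refined grid.

    Pearson chi-square computed by hand, pedestal (r-1)(c-1) subtracted,
    and the rho whose binned-bivariate-normal chi-square (via dblquad of
    the density) is closest to the corrected value returned.  Each level
    shrinks the scanned interval by a factor (n_grid - 1) / 2; the
    defaults give a final resolution of 1e-1 / 10^5 = 1e-6 on rho, and
    the returned value sits within half a grid step of the optimum.
    """
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    # same canonical row order as the statistic's definition
    table = table[np.argsort(table.sum(axis=1), kind="stable")]
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    chi2 = np.sum((table - expected) ** 2 / expected)
    r, c = table.shape
    target = chi2 - (r - 1) * (c - 1)
    if target <= 0:
        return 0.0
    chi2_at_max = _oracle_chi2_of_rho(table, 1.0 - 1e-7)
    if chi2 >= chi2_at_max or chi2_at_max <= target:
        return 1.0

    lo, hi = 0.0, 1.0 - 1e-7
    best_rho = None
    for _ in range(n_levels):
        grid = np.linspace(lo, hi, n_grid)
        errs = [abs(_oracle_chi2_of_rho(table, rho) - target) for rho in grid]
        k = int(np.argmin(errs))
        best_rho = grid[k]
        span = grid[1] - grid[0]
        lo = max(0.0, best_rho - span)
        hi = min(1.0 - 1e-7, best_rho + span)
    return float(best_rho)


def newton_logistic(x, y):
    """statsmodels maximum-likelihood logistic fit (Newton's method)."""
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(x, dtype=float))
    res = sm.Logit(np.asarray(y, dtype=float), X).fit(method="newton", disp=0, tol=1e-12)
    return np.asarray(res.params), np.asarray(res.bse)
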