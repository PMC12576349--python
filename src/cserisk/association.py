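"""Dependence between area deprivation and the binary CSE outcome.

Three views, mirroring how deprivation-outcome associations are usually
reported:

* **Phi-K** — a chi-square-based dependence measure for mixed
  binary/ordinal data.  The contingency table's Pearson chi-square, after
  subtraction of its sample "pedestal" (the chi-square expected under
  independence purely from sampling noise), is equated to the chi-square
  of a binned standard bivariate normal with the same margins; the normal
  correlation rho in [0, 1] solving that equation is the statistic.
  Phi-K is 0 under independence and 1 for a diagonal (deterministic)
  table, and unlike Pearson's r it captures non-linear dependence.

* **Logistic regression** — maximum likelihood with a logit link fitted
  by iteratively reweighted least squares (IRLS), reporting the slope per
  ADI point, its Wald CI from the inverse observed information, and the
  odds ratio per point.

* **Decile risk curves** — per-ADI-decile risk percentages, the
  bar-chart view of the same association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats
from scipy.special import expit

from .errors import InputError, NumericalError, SeparationError

__all__ = [
    "bvn_cdf",
    "binned_bvn_chi2",
    "phik",
    "phik_from_table",
    "fit_logistic",
    "LogisticFit",
    "decile_curve",
    "associate_scenarios",
    "AssociationResult",
]

_RHO_MAX = 1.0 - 1e-7


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """Standard bivariate normal CDF P(X <= h, Y <= k; rho).

    Computed as Phi(h)Phi(k) plus the correlation integral

        (1 / 2pi) * int_0^{asin rho} exp(-(h^2 + k^2 - 2 h k sin t)
                                          / (2 cos^2 t)) dt,

    evaluated by adaptive quadrature.  Deterministic and accurate to
    ~1e-10 for |rho| <= 1 - 1e-7; infinite limits reduce to the
    univariate CDF.
    """
    if h == -np.inf or k == -np.inf:
        return 0.0
    if h == np.inf and k == np.inf:
        return 1.0
    if h == np.inf:
        return float(stats.norm.cdf(k))
    if k == np.inf:
        return float(stats.norm.cdf(h))
    rho = float(np.clip(rho, -_RHO_MAX, _RHO_MAX))
    base = float(stats.norm.cdf(h) * stats.norm.cdf(k))
    if rho == 0.0:
        return base

    def integrand(t: float) -> float:
        c = np.cos(t)
        return np.exp(-(h * h + k * k - 2.0 * h * k * np.sin(t)) / (2.0 * c * c))

    val, _ = integrate.quad(integrand, 0.0, np.arcsin(rho), epsabs=1e-12, epsrel=1e-10, limit=200)
    return float(np.clip(base + val / (2.0 * np.pi), 0.0, 1.0))


def _cell_probs(edges_x: np.ndarray, edges_y: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of a binned standard bivariate normal."""
    nx, ny = len(edges_x) - 1, len(edges_y) - 1
    cdf = np.empty((len(edges_x), len(edges_y)))
    for i, ex in enumerate(edges_x):
        for j, ey in enumerate(edges_y):
            cdf[i, j] = bvn_cdf(ex, ey, rho)
    p = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    return np.clip(p, 0.0, 1.0)


def _edges_from_margins(margin: np.ndarray) -> np.ndarray:
    """Normal bin edges whose interval masses match empirical margins."""
    cum = np.concatenate([[0.0], np.cumsum(margin)])
    cum[-1] = 1.0
    return stats.norm.ppf(cum)


def binned_bvn_chi2(table_margins: tuple[np.ndarray, np.ndarray], n: float, rho: float) -> float:
    """Pearson chi-square of a binned bivariate normal against independence.

    The normal is binned on the grid implied by the empirical margins, so
    under rho the cell probabilities p_ij(rho) have exactly those margins;
    the statistic is n * sum_ij (p_ij(rho) - p_i p_j)^2 / (p_i p_j),
    which increases monotonically in rho on [0, 1).
    """
    px, py = table_margins
    p = _cell_probs(_edges_from_margins(px), _edges_from_margins(py), rho)
    indep = np.outer(px, py)
    return float(n * np.sum((p - indep) ** 2 / indep))


def phik_from_table(table: np.ndarray, pedestal_correction: bool = True) -> float:
    """Phi-K of a contingency table (rows x cols of counts).

    Zero-count rows/columns are dropped.  The observed Pearson chi-square
    minus the pedestal (r-1)(c-1) — its expectation under independence —
    is matched to the binned-bivariate-normal chi-square by bracketed
    root finding on rho; tables at or below the pedestal return 0 and
    tables beyond the distribution's maximum dependence return 1.
    """
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    r, c = table.shape
    if r < 2 or c < 2:
        warnings.warn("degenerate contingency table (a margin is zero); Phi-K set to 0")
        return 0.0
    # canonical row order (ascending row margin): the binned bivariate
    # normal is not symmetric under swapping an asymmetric binary margin,
    # so this tie-break makes the statistic invariant under relabeling
    # of the outcome
    table = table[np.argsort(table.sum(axis=1), kind="stable")]
    n = table.sum()
    chi2 = float(stats.chi2_contingency(table, correction=False)[0])
    pedestal = (r - 1) * (c - 1) if pedestal_correction else 0.0
    target = chi2 - pedestal
    if target <= 0.0:
        return 0.0

    margins = (table.sum(axis=1) / n, table.sum(axis=0) / n)

    def f(rho: float) -> float:
        return binned_bvn_chi2(margins, n, rho) - target

    # saturation: dependence at or beyond the distribution's maximum
    chi2_at_max = binned_bvn_chi2(margins, n, _RHO_MAX)
    if chi2 >= chi2_at_max or chi2_at_max - target <= 0.0:
        return 1.0
    try:
        rho = optimize.brentq(f, 0.0, _RHO_MAX, xtol=1e-10, rtol=1e-12, maxiter=200)
    except (RuntimeError, ValueError) as exc:
        raise NumericalError(
            f"Phi-K root find failed (chi2={chi2:.4g}, pedestal={pedestal}, "
            f"table shape {table.shape}): {exc}"
        ) from exc
    return float(rho)


def _bin_fixed_width(y: np.ndarray, n_bins: int, lo: float, hi: float) -> np.ndarray:
    width = (hi - lo + 1.0) / n_bins
    return np.clip(np.floor((y - lo) / width), 0, n_bins - 1).astype(int)


def phik(
    outcome,
    y,
    n_bins_y: int = 10,
    y_range: tuple[float, float] = (1, 100),
    pedestal_correction: bool = True,
) -> float:
    """Phi-K between a binary outcome and an ordinal covariate.

    The covariate is binned into ``n_bins_y`` fixed-width intervals over
    ``y_range`` (deciles of the 1-100 ADI scale by default); the outcome
    stays binary.  Returns 0 (with a warning) when either variable is
    degenerate.
    """
    outcome = np.asarray(outcome).astype(int)
    y = np.asarray(y, dtype=float)
    if outcome.shape != y.shape:
        raise InputError("outcome and covariate must have equal length")
    if len(y) < 2:
        raise InputError("need at least 2 observations")
    ybin = _bin_fixed_width(y, n_bins_y, float(y_range[0]), float(y_range[1]))
    table = np.zeros((2, n_bins_y))
    np.add.at(table, (outcome, ybin), 1.0)
    return phik_from_table(table, pedestal_correction=pedestal_correction)


@dataclass
class LogisticFit:
    """IRLS logistic fit of a binary outcome on one covariate."""

    beta0: float
    beta1: float
    se0: float
    se1: float
    ci_low: float       # 95% Wald CI for beta1, coefficient scale
    ci_high: float
    p_value: float      # Wald test of beta1 = 0
    n_iter: int
    converged: bool

    @property
    def or_per_point(self) -> float:
        return float(np.exp(self.beta1))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def predict_proba(self, x) -> np.ndarray:
        return expit(self.beta0 + self.beta1 * np.asarray(x, dtype=float))


def fit_logistic(
    x, y, tol: float = 1e-8, max_iter: int = 50, alpha: float = 0.05
) -> LogisticFit:
    """Maximum-likelihood logistic regression of y on x by IRLS.

    Newton-Raphson on the Bernoulli log-likelihood with logit link:
    beta <- beta + (X' W X)^-1 X'(y - p) with W = diag(p(1-p)).
    Converges when the largest coefficient change drops below ``tol``.
    Wald standard errors come from the inverse observed information at
    the optimum.

    Raises
    ------
    InputError
        If the outcome has a single class.
    SeparationError
        On complete or quasi-complete separation (diverging slope).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(float)
    if x.shape != y.shape:
        raise InputError("x and y must have equal length")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise InputError("outcome must be binary 0/1")
    if len(classes) < 2:
        raise InputError("outcome has a single class; logistic fit undefined")

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        # separation: fitted probabilities saturate in the direction of y
        if np.all(w < 1e-10) and np.all((eta > 0) == (y > 0.5)):
            raise SeparationError(int(np.sign(beta[1]) or 1))
        w = np.maximum(w, 1e-12)
        XtWX = X.T @ (w[:, None] * X)
        try:
            delta = np.linalg.solve(XtWX, X.T @ (y - p))
        except np.linalg.LinAlgError as exc:
            raise SeparationError(int(np.sign(beta[1]) or 1), f"singular information: {exc}") from exc
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged and np.max(np.abs(beta)) > 1e3:
        raise SeparationError(int(np.sign(beta[1]) or 1))

    p = expit(X @ beta)
    w = np.maximum(p * (1.0 - p), 1e-12)
    cov = np.linalg.inv(X.T @ (w[:, None] * X))
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    zstat = beta[1] / se[1]
    return LogisticFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        se0=float(se[0]),
        se1=float(se[1]),
        ci_low=float(beta[1] - z * se[1]),
        ci_high=float(beta[1] + z * se[1]),
        p_value=float(2.0 * stats.norm.sf(abs(zstat))),
        n_iter=it,
        converged=converged,
    )


def decile_curve(adi, flags) -> pd.DataFrame:
    """Risk percentage per ADI decile ([1-10], [11-20], ..., [91-100]).

    Bins with no households report NaN risk (missing, not zero).
    """
    adi = np.asarray(adi, dtype=float)
    flags = np.asarray(flags).astype(bool)
    if adi.shape != flags.shape:
        raise InputError("adi and flags must have equal length")
    if np.any((adi < 1) | (adi > 100)):
        raise InputError("ADI scores must lie in 1..100")
    idx = _bin_fixed_width(adi, 10, 1.0, 100.0)
    n = np.bincount(idx, minlength=10).astype(float)
    n_risk = np.bincount(idx, weights=flags.astype(float), minlength=10)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n > 0, 100.0 * n_risk / np.where(n > 0, n, 1.0), np.nan)
    lows = np.arange(1, 101, 10)
    return pd.DataFrame(
        {
            "decile": np.arange(1, 11),
            "adi_low": lows,
            "adi_high": lows + 9,
            "n": n.astype(int),
            "n_at_risk": n_risk.astype(int),
            "pct_at_risk": np.round(pct, 2),
        }
    )


@dataclass
class AssociationResult:
    """Phi-K plus logistic summary for one burden scenario."""

    scenario: str
    phik: float
    fit: LogisticFit
    alpha: float = 0.05
    decile: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    @property
    def significant(self) -> bool:
        return self.fit.p_value < self.alpha


def associate_scenarios(
    adi: np.ndarray,
    cse_results,
    n_bins_adi: int = 10,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Run the full association suite for each scenario's flags."""
    out = []
    for r in cse_results:
        flags = np.asarray(r.flags).astype(int)
        value = phik(flags, adi, n_bins_y=n_bins_adi)
        fit = fit_logistic(np.asarray(adi, dtype=float), flags, alpha=alpha)
        out.append(
            AssociationResult(
                scenario=r.scenario.name,
                phik=value,
                fit=fit,
                alpha=alpha,
                decile=decile_curve(adi, flags),
            )
        )
    return out


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabular view of association results, both coefficient and OR scales."""
    return pd.DataFrame(
        {
            "scenario": [r.scenario for r in results],
            "phik": [r.phik for r in results],
            "beta0": [r.fit.beta0 for r in results],
            "beta1_per_adi_point": [r.fit.beta1 for r in results],
            "beta1_se": [r.fit.se1 for r in results],
            "beta1_ci_low": [r.fit.ci_low for r in results],
            "beta1_ci_high": [r.fit.ci_high for r in results],
            "odds_ratio_per_point": [r.fit.or_per_point for r in results],
            "or_ci_low": [r.fit.or_ci[0] for r in results],
            "or_ci_high": [r.fit.or_ci[1] for r in results],
            "p_value": [r.fit.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
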