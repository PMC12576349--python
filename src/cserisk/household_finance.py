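"""Household income imputation and subsistence arithmetic.

Block-group income medians come with ACS margins of error (90% CI
half-widths).  A household's income is a random draw within one standard
deviation of the block-group median, rescaled by a power-law equivalence
scale in household size; subsistence is annualized rent plus food; the
non-subsistence expenditure (NSE) — the base of the catastrophic-expenditure
threshold — is income minus subsistence and may legitimately be negative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import IncomeDrawConfig, PovertyGuideline
from .errors import InputError, LinkageError

#: z quantile at 0.95: ACS margins of error are 90% confidence half-widths.
ACS_Z90 = 1.645


def moe_to_sd(moe):
    """Convert an ACS margin of error (90% CI half-width) to a standard error.

    Parameters
    ----------
    moe : float or array-like
        Non-negative margin(s) of error in dollars.

    Returns
    -------
    float or ndarray
        moe / 1.645.
    """
    arr = np.asarray(moe, dtype=float)
    if np.any(arr < 0):
        raise InputError("margin of error must be non-negative")
    out = arr / ACS_Z90
    return float(out) if np.isscalar(moe) or arr.ndim == 0 else out


def equivalence_scale(size, cfg: IncomeDrawConfig):
    """Size adjustment factor (size / reference_size) ** beta, or 1 if off."""
    size = np.asarray(size, dtype=float)
    if not cfg.size_adjust:
        return np.ones_like(size)
    return (size / cfg.reference_size) ** cfg.beta


def draw_income(income_median, income_moe, size, rng, cfg: IncomeDrawConfig | None = None):
    """Impute household income(s) from block-group estimates.

    Draws from [m - s, m + s] where m is the block-group median and s the
    standard error implied by the margin of error (uniform by default, a
    truncated normal optionally), then applies the equivalence-scale
    size adjustment and floors at 0.

    All array arguments broadcast; with scalar inputs a scalar is returned.
    """
    cfg = cfg or IncomeDrawConfig()
    m = np.atleast_1d(np.asarray(income_median, dtype=float))
    moe = np.atleast_1d(np.asarray(income_moe, dtype=float))
    size_arr = np.atleast_1d(np.asarray(size, dtype=float))
    m, moe, size_arr = np.broadcast_arrays(m, moe, size_arr)

    if cfg.moe_convention == "acs90":
        s = moe / ACS_Z90
    else:
        s = moe.astype(float)

    if cfg.distribution == "uniform":
        base = rng.uniform(m - s, m + s)
    else:
        # truncated normal with sd = s on [m - s, m + s]; degenerate s -> m
        base = np.where(
            s > 0,
            stats.truncnorm.rvs(-1.0, 1.0, loc=m, scale=np.where(s > 0, s, 1.0), random_state=rng),
            m,
        )

    income = base * equivalence_scale(size_arr, cfg)
    income = np.maximum(income, 0.0)
    if np.isscalar(income_median) and np.ndim(size) == 0:
        return float(income[0])
    return income


def compute_profiles(
    households: pd.DataFrame,
    blockgroups: pd.DataFrame,
    guideline: PovertyGuideline,
    rng,
    cfg: IncomeDrawConfig | None = None,
) -> pd.DataFrame:
    """Build the finance profile table for every household.

    Joins each household to its block group, imputes income, and computes
    subsistence (12 * monthly rent + annual food), NSE (income minus
    subsistence, possibly negative) and the federal-poverty flag
    (imputed income below the size-specific guideline threshold).

    Returns a DataFrame with columns ``hh_id, bg_id, size, insured,
    income_annual, subsistence_annual, nse, below_poverty``.
    """
    cfg = cfg or IncomeDrawConfig()
    if len(households) == 0:
        raise InputError("household table is empty")
    unknown = set(households["bg_id"]) - set(blockgroups["bg_id"])
    if unknown:
        raise LinkageError(f"households reference unknown block groups: {sorted(unknown)[:5]}")

    merged = households.merge(blockgroups, on="bg_id", how="left", validate="many_to_one")
    income = draw_income(
        merged["income_median"].to_numpy(),
        merged["income_moe"].to_numpy(),
        merged["size"].to_numpy(),
        rng,
        cfg,
    )
    subsistence = 12.0 * merged["rent_monthly_median"].to_numpy() + merged["food_annual"].to_numpy()
    nse = income - subsistence
    below = income < guideline.threshold(merged["size"].to_numpy())
    return pd.DataFrame(
        {
            "hh_id": merged["hh_id"],
            "bg_id": merged["bg_id"],
            "size": merged["size"],
            "insured": merged["insured"],
            "income_annual": income,
            "subsistence_annual": subsistence,
            "nse": nse,
            "below_poverty": below,
        }
    )


def population_summary(profiles: pd.DataFrame) -> pd.DataFrame:
    """Socioeconomic summary of the cohort (min / quartiles / mean / max).

    Quantiles use linear interpolation between order statistics (numpy's
    default), the convention the published cohort quartiles are compared
    under.  The below-poverty percentage is rounded to 2 decimals.
    """
    if len(profiles) == 0:
        raise InputError("profile table is empty")

    def describe(x: np.ndarray) -> dict:
        return {
            "min": float(np.min(x)),
            "q25": float(np.quantile(x, 0.25)),
            "median": float(np.quantile(x, 0.50)),
            "mean": float(np.mean(x)),
            "q75": float(np.quantile(x, 0.75)),
            "max": float(np.max(x)),
        }

    rows = {
        "nse": describe(profiles["nse"].to_numpy(float)),
        "household_size": describe(profiles["size"].to_numpy(float)),
    }
    out = pd.DataFrame(rows).T
    out.index.name = "variable"
    n = len(profiles)
    n_poor = int(profiles["below_poverty"].sum())
    out.attrs["n_households"] = n
    out.attrs["below_poverty_n"] = n_poor
    out.attrs["below_poverty_pct"] = round(100.0 * n_poor / n, 2)
    out.attrs["nse_iqr"] = rows["nse"]["q75"] - rows["nse"]["q25"]
    return out
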