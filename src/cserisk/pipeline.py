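"""End-to-end orchestration: generate -> finance -> CSE -> association.

One seed in the run config feeds a root ``numpy.random.SeedSequence``;
stage RNG streams are its spawned children in fixed order (census = child
0, income draws = child 1), so a stage can be re-run in isolation and the
whole run is reproducible from the emitted ``run_manifest.json``, which
embeds the full validated config, its hash, and library versions.

Money columns are written with cent precision; percentages follow the
reporting conventions (2 decimals for scenario risk, 1 decimal for
uninsurance-adjusted risk).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import associate_scenarios, association_frame
from .config import RunConfig
from .cse_model import (
    adjust_for_uninsurance,
    flags_to_frame,
    oop_payment,
    results_to_frame,
    scenario_scan,
)
from .errors import InputError
from .household_finance import compute_profiles, population_summary
from .synthetic_census import generate_tables

logger = logging.getLogger("cserisk")

_MONEY_COLS = {
    "blockgroups": ["income_median", "income_moe", "rent_monthly_median", "food_annual"],
    "profiles": ["income_annual", "subsistence_annual", "nse"],
}


def _write_csv(df: pd.DataFrame, path: Path, money_cols: list[str] | None = None) -> None:
    df = df.copy()
    for c in money_cols or []:
        df[c] = df[c].round(2)
    df.to_csv(path, index=False)


def _stage(name: str):
    logger.info("stage %s starting", name)
    return time.perf_counter()


def _done(name: str, t0: float) -> None:
    logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)


def load_census(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read existing block-group and household CSVs named in the config."""
    bgs = pd.read_csv(cfg.blockgroups_csv)
    hhs = pd.read_csv(cfg.households_csv)
    required_bg = {"bg_id", "adi", "income_median", "income_moe", "rent_monthly_median", "food_annual"}
    required_hh = {"hh_id", "bg_id", "size", "insured"}
    if not required_bg <= set(bgs.columns):
        raise InputError(f"blockgroups CSV missing columns {required_bg - set(bgs.columns)}")
    if not required_hh <= set(hhs.columns):
        raise InputError(f"households CSV missing columns {required_hh - set(hhs.columns)}")
    return bgs, hhs


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and write every artifact to cfg.outdir.

    Returns a dict with the in-memory tables (``blockgroups``,
    ``households``, ``profiles``, ``summary``, ``cse_results``,
    ``cse_summary``, ``association``, ``decile_curves``) and the manifest.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seq = np.random.SeedSequence(cfg.seed)
    census_rng, income_rng = (np.random.default_rng(s) for s in seq.spawn(2))

    t0 = _stage("census")
    if cfg.generator is not None:
        gen = cfg.generator.model_copy(update={"seed": cfg.seed})
        bgs, hhs = generate_tables(gen, census_rng)
    else:
        bgs, hhs = load_census(cfg)
    _write_csv(bgs, outdir / "blockgroups.csv", _MONEY_COLS["blockgroups"])
    _write_csv(hhs, outdir / "households.csv")
    _done("census", t0)

    t0 = _stage("finance")
    profiles = compute_profiles(hhs, bgs, cfg.poverty_guideline, income_rng, cfg.income_draw)
    _write_csv(profiles, outdir / "profiles.csv", _MONEY_COLS["profiles"])
    summary = population_summary(profiles)
    summary.round(2).to_csv(outdir / "population_summary.csv")
    _done("finance", t0)

    t0 = _stage("cse")
    results = scenario_scan(profiles, cfg.scenarios)
    cse_summary = results_to_frame(results)
    _write_csv(flags_to_frame(profiles, results), outdir / "cse_results.csv")
    _write_csv(cse_summary, outdir / "cse_summary.csv")
    _done("cse", t0)

    t0 = _stage("association")
    adi = profiles.merge(bgs[["bg_id", "adi"]], on="bg_id")["adi"].to_numpy()
    assoc = associate_scenarios(
        adi, results, n_bins_adi=cfg.association.n_bins_adi, alpha=cfg.association.alpha
    )
    assoc_df = association_frame(assoc)
    _write_csv(assoc_df, outdir / "association.csv")
    deciles = pd.concat(
        [r.decile.assign(scenario=r.scenario) for r in assoc],
        ignore_index=True,
    )[["scenario", "decile", "adi_low", "adi_high", "n", "n_at_risk", "pct_at_risk"]]
    _write_csv(deciles, outdir / "decile_curves.csv")
    _done("association", t0)

    manifest = {
        "config": cfg.model_dump(mode="json"),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {
            "cserisk": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "blockgroups": bgs,
        "households": hhs,
        "profiles": profiles,
        "summary": summary,
        "cse_results": results,
        "cse_summary": cse_summary,
        "association_results": assoc,
        "association": assoc_df,
        "decile_curves": deciles,
        "manifest": manifest,
        "outdir": str(outdir),
    }


def run_from_manifest(path: str | Path) -> dict:
    """Re-run a pipeline exactly as recorded in a run manifest."""
    with open(path) as fh:
        manifest = json.load(fh)
    cfg = RunConfig.model_validate(manifest["config"])
    return run_pipeline(cfg)


def render_tables(artifacts: dict, p_uninsured: float | None = None) -> dict[str, str]:
    """Render the three report tables as plain text.

    table1: cohort socioeconomic summary.  table2: per-scenario risk,
    percentages to 2 decimals, with uninsurance-adjusted risks (the
    product of the risk and the uninsured fraction, 1 decimal) as a
    footnote.  table3: Phi-K and logistic associations, CIs labeled with
    their scale.
    """
    if "summary" not in artifacts or "cse_summary" not in artifacts:
        raise InputError("artifacts must contain 'summary' and 'cse_summary'")
    summary: pd.DataFrame = artifacts["summary"]
    lines1 = ["Socioeconomic profile of generated population"]
    lines1.append(f"n households: {summary.attrs['n_households']}")
    lines1.append(summary.round(2).to_string())
    lines1.append(
        f"Below federal poverty guideline: {summary.attrs['below_poverty_n']} "
        f"({summary.attrs['below_poverty_pct']:.2f}%)"
    )
    lines1.append(f"Non-subsistence expenditure IQR: {summary.attrs['nse_iqr']:.2f}")
    table1 = "\n".join(lines1)

    cse: pd.DataFrame = artifacts["cse_summary"]
    lines2 = ["Modeled risk of catastrophic surgical expenditure",
              f"{'scenario':<22}{'burden':>8}{'cost':>10}{'OOP':>12}{'n at risk':>11}{'% at risk':>11}"]
    for _, row in cse.iterrows():
        lines2.append(
            f"{row['scenario']:<22}{row['burden']:>8.3f}{row['procedure_cost']:>10.2f}"
            f"{row['oop_payment']:>12.2f}{row['n_at_risk']:>11d}{row['pct_at_risk']:>10.2f}%"
        )
    if p_uninsured is not None and len(cse):
        lines2.append(
            f"Adjusted for uninsured fraction {p_uninsured:g} "
            "(product of risk and uninsured fraction; a lower bound):"
        )
        for _, row in cse.iterrows():
            adj = adjust_for_uninsurance(row["pct_at_risk"], p_uninsured)
            lines2.append(f"  {row['scenario']:<22} at least {adj:.1f}% at risk")
    table2 = "\n".join(lines2)

    lines3 = ["Associations between ADI score and CSE risk",
              f"{'scenario':<22}{'Phi-K':>8}{'OR/point':>10}{'beta1 95% CI (coef scale)':>28}{'p':>12}"]
    if "association" in artifacts:
        for _, row in artifacts["association"].iterrows():
            lines3.append(
                f"{row['scenario']:<22}{row['phik']:>8.4f}{row['odds_ratio_per_point']:>10.5f}"
                f"   [{row['beta1_ci_low']:.5f}, {row['beta1_ci_high']:.5f}]"
                f"{row['p_value']:>14.3g}"
            )
    table3 = "\n".join(lines3)
    return {"table1": table1, "table2": table2, "table3": table3}


def plot_decile_curves(artifacts: dict, outdir: str | Path, fmt: str = "svg") -> list[str]:
    """Bar charts of per-decile CSE risk, one file per scenario."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    deciles: pd.DataFrame = artifacts["decile_curves"]
    for name, sub in deciles.groupby("scenario", sort=False):
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.bar(sub["decile"], sub["pct_at_risk"], color="#33638d")
        ax.set_xlabel("ADI decile")
        ax.set_ylabel("% households at risk of CSE")
        ax.set_title(f"CSE risk by ADI decile — {name}")
        ax.set_xticks(range(1, 11))
        ax.set_ylim(0, 105)
        fig.tight_layout()
        path = outdir / f"decile_{name}.{fmt}"
        fig.savefig(path)
        plt.close(fig)
        paths.append(str(path))
    return paths
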