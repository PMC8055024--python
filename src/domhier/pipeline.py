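"""The two analysis arms over the shared machinery.

Simulated arm: repeated winner-loser simulations of the 14 field group
compositions, per-run beta-binomial regressions of female dominance and
sex-classed aggression on the adult sex ratio, and one-sample t summaries of
the per-run slopes.

Empirical arm: the packaged per-group-period table — rank/unknown-relation
descriptives, grouped-count reconstruction of the female dominance index,
beta-binomial mixed fits with population and group-within-population
intercepts, boundary LRTs and AIC model comparison.  The reconstruction
(successes = round(FDI * n_males * n_females)) is approximate because the
raw field matrices are not available; downstream fits are labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as dio
from .core import GroupComposition
from .domworld import SimParams, run_simulation
from .metrics import summarize_hierarchy
from .stats import (
    BetaBinFit,
    MixtureLRTResult,
    RunCoefficientSummary,
    fit_betabin_mixed,
    fit_betabin_regression,
    mixture_lrt,
    pearson_correlation,
    pseudo_r2_lr,
    summarize_across_runs,
)

__all__ = [
    "ExperimentResult",
    "EmpiricalReport",
    "experiment_params",
    "run_domworld_experiment",
    "reproduce_empirical_analysis",
    "docile_male_check",
    "plot_fdi_vs_sexratio",
]

#: The five cross-group regressions fitted within each simulation run, plus
#: the docile-male check.  (response, regressor, multi-male groups only?)
MODEL_SPECS = {
    "fdi~prop_males": ("fdi", "prop_males", False),
    "mm~prop_males": ("mm", "prop_males", True),
    "fm~prop_males": ("fm", "prop_males", False),
    "fdi~mm_frac": ("fdi", "mm_frac", True),
    "fdi~fm_frac": ("fdi", "fm_frac", False),
}

#: Per-run slopes larger than this in magnitude indicate separation (the
#: likelihood is flat in the coefficient); such fits are excluded from the
#: cross-run summaries and counted as warnings.
SLOPE_ABS_MAX = 100.0


#: Run length used by the repeated-runs experiment.  The winner-loser
#: hierarchy differentiates by diffusion of the dominance values, so the
#: cross-group covariation of female dominance with sex ratio and aggression
#: composition needs long runs to develop; fights are tallied over the last
#: 600 activation periods, after differentiation has built up.
EXPERIMENT_N_PERIODS = 2000
EXPERIMENT_BURN_IN = 1400


def experiment_params(**overrides) -> SimParams:
    """Simulator parameters used by the reproduction experiment.

    Standard per-sex parameters with the calibrated run length documented in
    the methods note; any field can be overridden.
    """
    defaults = dict(
        n_periods=EXPERIMENT_N_PERIODS, burn_in_periods=EXPERIMENT_BURN_IN
    )
    defaults.update(overrides)
    return SimParams().with_overrides(**defaults)


def _simulate_group_row(params, comp, seed) -> dict:
    sim = run_simulation(params, comp, seed)
    summ = summarize_hierarchy(sim.matrix, acts=sim.attacks)
    male = sim.matrix.male_mask()
    acts = sim.attacks
    male_total = int(acts[male].sum())
    female_total = int(acts[~male].sum())
    mm_k = int(acts[np.ix_(male, male)].sum())
    fm_k = int(acts[np.ix_(~male, male)].sum())
    mf_k = int(acts[np.ix_(male, ~male)].sum())
    return {
        "label": comp.label,
        "n_males": comp.n_males,
        "n_females": comp.n_females,
        "prop_males": comp.prop_males,
        "fdi": summ.fdi,
        "fdi_successes": summ.fdi_successes,
        "fdi_total": summ.fdi_total,
        "unknown_proportion": summ.unknown_proportion,
        "mm_frac": summ.mm_fraction,
        "fm_frac": summ.fm_fraction,
        "mm_excluded": summ.mm_excluded,
        "male_acts": male_total,
        "female_acts": female_total,
        "mm_acts": mm_k,
        "fm_acts": fm_k,
        "mf_acts": mf_k,
        "n_fights": int(sim.matrix.counts.sum()),
    }


def _fit_run_models(run_df: pd.DataFrame) -> tuple[dict, list[str]]:
    """Fit the per-run cross-group regressions; returns slopes and warnings."""
    slopes: dict[str, float] = {}
    warnings: list[str] = []
    for model, (response, regressor, multimale_only) in MODEL_SPECS.items():
        df = run_df
        if multimale_only:
            df = df[~df["mm_excluded"]]
        if response == "fdi":
            kk, nn = df["fdi_successes"], df["fdi_total"]
        elif response == "mm":
            kk, nn = df["mm_acts"], df["male_acts"]
        else:
            kk, nn = df["fm_acts"], df["female_acts"]
        keep = np.asarray(nn) > 0
        x = np.asarray(df[regressor], dtype=float)
        keep &= np.isfinite(x)
        kk, nn, x = np.asarray(kk)[keep], np.asarray(nn)[keep], x[keep]
        if len(kk) < 3 or np.std(x) == 0:
            warnings.append(f"{model}: degenerate design, skipped")
            slopes[model] = np.nan
            continue
        X = np.column_stack([np.ones(len(x)), x])
        fit = fit_betabin_regression(kk, nn, X, names=["intercept", regressor])
        slope = fit.coef[1]
        if not fit.converged or abs(slope) > SLOPE_ABS_MAX:
            warnings.append(f"{model}: unstable fit (slope={slope:.3g}), excluded")
            slopes[model] = np.nan
        else:
            slopes[model] = float(slope)
    # docile-male check: male-to-female acts out of all male acts, offset by
    # the expected female share of a male's potential opponents
    df = run_df[~run_df["mm_excluded"]]
    keep = np.asarray(df["male_acts"]) > 0
    df = df[keep]
    if len(df) >= 3:
        off = logit(df["n_females"] / (df["n_adults"] - 1))
        X = np.column_stack([np.ones(len(df)), df["prop_males"]])
        fit = fit_betabin_regression(
            df["mf_acts"], df["male_acts"], X, offset=np.asarray(off),
            names=["intercept", "prop_males"],
        )
        slope = fit.coef[1]
        if not fit.converged or abs(slope) > SLOPE_ABS_MAX:
            warnings.append(f"docile: unstable fit (slope={slope:.3g}), excluded")
            slopes["docile"] = np.nan
        else:
            slopes["docile"] = float(slope)
    else:
        slopes["docile"] = np.nan
        warnings.append("docile: too few usable groups")
    return slopes, warnings


@dataclass
class ExperimentResult:
    """Per-run tables and cross-run slope summaries of the simulated arm."""

    params: SimParams
    seed: int
    n_runs: int
    group_table: pd.DataFrame  # one row per (run, group)
    slope_table: pd.DataFrame  # one row per run, one column per model
    summaries: dict[str, RunCoefficientSummary]
    warnings: list[str] = field(default_factory=list)


def run_domworld_experiment(
    n_runs: int = 40,
    seed: int = 1,
    params: Optional[SimParams] = None,
    compositions: Optional[list[GroupComposition]] = None,
) -> ExperimentResult:
    """Simulate every field composition ``n_runs`` times and fit per-run models.

    Each run simulates all group compositions independently, computes each
    group's hierarchy summary, fits the five beta-binomial regressions (plus
    the docile-male check) across groups, and finally the per-run slopes are
    summarised by one-sample t statistics across runs.
    """
    if params is None:
        params = experiment_params()
    if compositions is None:
        comp_df = dio.load_group_compositions()
        compositions = [
            GroupComposition(int(r.n_males), int(r.n_females))
            for r in comp_df.itertuples()
        ]
    base = np.random.SeedSequence(seed)
    run_seeds = base.spawn(n_runs)
    rows = []
    slope_rows = []
    warnings: list[str] = []
    for run in range(n_runs):
        group_seeds = run_seeds[run].spawn(len(compositions))
        run_rows = []
        for comp, gseed in zip(compositions, group_seeds):
            row = _simulate_group_row(params, comp, gseed)
            row["run"] = run
            row["n_adults"] = comp.n
            run_rows.append(row)
        run_df = pd.DataFrame(run_rows)
        slopes, warns = _fit_run_models(run_df)
        warnings += [f"run {run}: {w}" for w in warns]
        slopes["run"] = run
        slope_rows.append(slopes)
        rows += run_rows
    slope_table = pd.DataFrame(slope_rows).set_index("run")
    summaries = {
        model: summarize_across_runs(slope_table[model].to_numpy())
        for model in slope_table.columns
    }
    return ExperimentResult(
        params=params,
        seed=seed,
        n_runs=n_runs,
        group_table=pd.DataFrame(rows),
        slope_table=slope_table,
        summaries=summaries,
        warnings=warnings,
    )


def docile_male_check(
    mf_acts,
    male_acts,
    frac_female_opponents,
    prop_males,
    mode: str = "offset",
) -> BetaBinFit:
    """Does male-to-female aggression deviate from random-encounter expectation?

    Beta-binomial regression of male-to-female acts out of all male-initiated
    acts on the proportion of males, correcting for the expected female share
    of each male's potential opponents either as a logit offset (default) or
    as a covariate.
    """
    frac = np.asarray(frac_female_opponents, dtype=float)
    keep = (np.asarray(male_acts) > 0) & (frac > 0) & (frac < 1)
    mf = np.asarray(mf_acts)[keep]
    tot = np.asarray(male_acts)[keep]
    pm = np.asarray(prop_males, dtype=float)[keep]
    frac = frac[keep]
    if len(mf) < 3:
        raise ValueError("too few non-degenerate groups for the docile-male check")
    if mode == "offset":
        X = np.column_stack([np.ones(len(mf)), pm])
        return fit_betabin_regression(
            mf, tot, X, offset=logit(frac), names=["intercept", "prop_males"]
        )
    if mode == "covariate":
        X = np.column_stack([np.ones(len(mf)), pm, logit(frac)])
        return fit_betabin_regression(
            mf, tot, X, names=["intercept", "prop_males", "logit_frac_female"]
        )
    raise ValueError(f"unknown mode {mode!r}: expected 'offset' or 'covariate'")


@dataclass
class EmpiricalReport:
    """Analyses of the packaged 14 field group-periods.

    Fits are on grouped counts reconstructed from the rounded published FDI
    values (``successes = round(FDI * n_males * n_females)``) and are
    therefore approximate.
    """

    table: pd.DataFrame
    unknown_vs_adults_r: float
    unknown_vs_adults_p: float
    unknown_vs_adults_rank_r: float
    unknown_vs_adults_rank_p: float
    n_fdi_at_least_half: int
    fit_prop: BetaBinFit  # FDI ~ proportion of males, mixed
    fit_abs: BetaBinFit  # FDI ~ absolute number of males, mixed
    fit_fixed: BetaBinFit  # FDI ~ proportion of males, no random effects
    fit_binom: BetaBinFit  # binomial (no overdispersion) mixed reduced model
    fit_null: BetaBinFit  # intercept-only, no random effects
    fit_null_mixed: BetaBinFit  # intercept-only with random effects
    lrt_dispersion: MixtureLRTResult
    lrt_variance: MixtureLRTResult
    lrt_slope: MixtureLRTResult
    pseudo_r2_vs_null: float
    pseudo_r2_vs_null_mixed: float
    pseudo_r2_rescaled: float
    reconstructed: bool = True


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def reproduce_empirical_analysis() -> EmpiricalReport:
    """Run the full empirical-arm analysis on the packaged group-period table."""
    df = dio.load_dominance_table()
    r, p = pearson_correlation(df["pct_unknown"], df["n_adults"])
    rr, rp = pearson_correlation(df["pct_unknown"], df["n_adults"], rank=True)
    n_high = int(np.sum(df["fdi"] >= 0.5))

    total = (df["n_males"] * df["n_females"]).to_numpy()
    succ = _round_half_away(df["fdi"].to_numpy() * total).astype(int)
    grouping = {
        "population": df["site"].to_numpy(),
        "group": (df["site"] + ":" + df["group"]).to_numpy(),
    }
    ones = np.ones(len(df))
    X_prop = np.column_stack([ones, df["prop_males_exact"]])
    X_abs = np.column_stack([ones, df["n_males"]])
    X_null = ones[:, None]

    fit_prop = fit_betabin_mixed(
        succ, total, X_prop, grouping, names=["intercept", "prop_males"]
    )
    fit_abs = fit_betabin_mixed(
        succ, total, X_abs, grouping, names=["intercept", "n_males"]
    )
    fit_fixed = fit_betabin_regression(
        succ, total, X_prop, names=["intercept", "prop_males"]
    )
    fit_binom = fit_betabin_mixed(
        succ, total, X_prop, grouping, theta_fixed=np.inf,
        names=["intercept", "prop_males"],
    )
    fit_null = fit_betabin_regression(succ, total, X_null, names=["intercept"])
    fit_null_mixed = fit_betabin_mixed(
        succ, total, X_null, grouping, names=["intercept"]
    )

    # overdispersion at the boundary: betabinomial vs binomial, {0, 1} df
    lrt_disp = mixture_lrt(
        fit_prop.loglik, fit_binom.loglik, {0: 0.5, 1: 0.5}, tol=1e-3
    )
    # two variance components at the boundary: {0, 1, 2} df
    lrt_var = mixture_lrt(
        fit_prop.loglik, fit_fixed.loglik, {0: 0.25, 1: 0.5, 2: 0.25}, tol=1e-3
    )
    # the sex-ratio slope itself (interior parameter): plain 1-df LRT
    lrt_slope = mixture_lrt(
        fit_prop.loglik, fit_null_mixed.loglik, {1: 1.0}, tol=1e-3
    )

    n = len(df)
    return EmpiricalReport(
        table=df,
        unknown_vs_adults_r=r,
        unknown_vs_adults_p=p,
        unknown_vs_adults_rank_r=rr,
        unknown_vs_adults_rank_p=rp,
        n_fdi_at_least_half=n_high,
        fit_prop=fit_prop,
        fit_abs=fit_abs,
        fit_fixed=fit_fixed,
        fit_binom=fit_binom,
        fit_null=fit_null,
        fit_null_mixed=fit_null_mixed,
        lrt_dispersion=lrt_disp,
        lrt_variance=lrt_var,
        lrt_slope=lrt_slope,
        pseudo_r2_vs_null=pseudo_r2_lr(fit_prop.loglik, fit_null.loglik, n),
        pseudo_r2_vs_null_mixed=pseudo_r2_lr(fit_prop.loglik, fit_null_mixed.loglik, n),
        pseudo_r2_rescaled=pseudo_r2_lr(
            fit_prop.loglik, fit_null.loglik, n, rescale=True
        ),
    )


def plot_fdi_vs_sexratio(report: EmpiricalReport, path) -> None:
    """Scatter of FDI vs proportion of males with the fitted curve and 95% band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = report.fit_prop
    if fit.cov is None or not np.all(np.isfinite(fit.coef)):
        raise ValueError("no usable fitted model in the report")
    df = report.table
    xs = np.linspace(df["prop_males"].min() - 0.02, df["prop_males"].max() + 0.02, 200)
    G = np.column_stack([np.ones_like(xs), xs])
    eta = G @ fit.coef
    var = np.einsum("ij,jk,ik->i", G, fit.cov, G)
    lo = expit(eta - 1.96 * np.sqrt(var))
    hi = expit(eta + 1.96 * np.sqrt(var))
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.fill_between(xs, lo, hi, alpha=0.25, color="tab:blue", lw=0)
    ax.plot(xs, expit(eta), color="tab:blue")
    ax.scatter(df["prop_males"], df["fdi"], color="black", zorder=3)
    ax.set_xlabel("proportion of males in the group")
    ax.set_ylabel("female dominance index (FDI)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
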