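"""Emergent-trait statistics over simulated phenotypes.

Post-processes batch and mixed-medium simulation outputs into the
population-level summaries the model is used for: growth-regime
classification, BP-BR allometric scaling, rate-yield regression across
substrate classes, group differences in substrate preference, Levins
niche breadth, and variance explained by genomic traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "REGIME_THRESHOLD",
    "classify_regimes",
    "mixture_antimode",
    "bp_br_scaling",
    "rate_yield_regression",
    "preference_differences",
    "levins_niche_breadth",
    "variance_explained",
    "kruskal_dunn",
]

#: boundary between the low and high growth-rate regimes (1/h)
REGIME_THRESHOLD = 0.039


def classify_regimes(
    table: pd.DataFrame,
    threshold: float | None = REGIME_THRESHOLD,
    rate_col: str = "r_realized",
) -> pd.DataFrame:
    """Label each row 'high' or 'low' growth regime.

    The boundary is closed on the high side (r == threshold -> high).
    Passing ``threshold=None`` derives the cut data-driven as the
    antimode of a two-component mixture fit to log growth rates.
    """
    if table.empty:
        raise ValueError("phenotype table is empty")
    cut = threshold if threshold is not None else mixture_antimode(table[rate_col].values)
    out = table.copy()
    out["regime"] = np.where(out[rate_col] >= cut, "high", "low")
    out.attrs["regime_threshold"] = float(cut)
    return out


def mixture_antimode(rates: np.ndarray, seed: int = 0) -> float:
    """Antimode of a 2-component Gaussian mixture on log10 growth rates."""
    x = np.log10(np.asarray(rates, dtype=float))
    x = x[np.isfinite(x)].reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=5).fit(x)
    mu = np.sort(gm.means_.ravel())
    # density minimum between the two component means
    grid = np.linspace(mu[0], mu[1], 512).reshape(-1, 1)
    dens = np.exp(gm.score_samples(grid))
    return float(10 ** grid[int(np.argmin(dens)), 0])


@dataclass(frozen=True)
class ScalingFit:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    t_vs_unity: float
    p_vs_unity: float
    r_squared: float
    n: int


def bp_br_scaling(table: pd.DataFrame, regime: str | None = None) -> ScalingFit:
    """OLS of log10 BP on log10 BR, with a t-test of the slope against 1.

    Disproportional scaling (slope < 1) means respiration grows faster
    than production along the rate axis. Non-positive BP/BR rows are
    dropped with a warning count recorded in the fit's n.
    """
    df = table if regime is None else table[table["regime"] == regime]
    df = df[(df["BP"] > 0) & (df["BR"] > 0)]
    if len(df) < 3:
        raise ValueError("need at least 3 rows with positive BP and BR")
    X = sm.add_constant(np.log10(df["BR"].values))
    fit = sm.OLS(np.log10(df["BP"].values), X).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    ci = fit.conf_int(alpha=0.05)
    if se > 0:
        t_unity = (slope - 1.0) / se
        p_unity = float(2 * stats.t.sf(abs(t_unity), df=fit.df_resid))
    else:
        t_unity, p_unity = (0.0, 1.0) if slope == 1.0 else (np.inf, 0.0)
    return ScalingFit(
        slope=slope,
        intercept=float(fit.params[0]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        t_vs_unity=float(t_unity),
        p_vs_unity=p_unity,
        r_squared=float(fit.rsquared),
        n=len(df),
    )


def rate_yield_regression(
    table: pd.DataFrame, regime: str | None = None, by: str = "substrate_class"
) -> dict:
    """Rate-yield (r vs CUE) regression on substrate-class medians.

    The unit of analysis is the class median, matching how the trade-off
    is summarized across the substrate panel.
    """
    df = table if regime is None else table[table["regime"] == regime]
    med = df.groupby(by)[["r_realized", "CUE"]].median().dropna()
    if len(med) < 2:
        raise ValueError("need at least two substrate-class medians")
    X = sm.add_constant(med["r_realized"].values)
    fit = sm.OLS(med["CUE"].values, X).fit()
    p = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else float("nan")
    r2 = float(fit.rsquared)
    if not np.isfinite(r2):  # zero-variance response: nothing to explain
        r2 = 0.0
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r_squared": r2,
        "p_value": p,
        "n": len(med),
        "medians": med,
    }


def preference_differences(
    ledgers: dict[str, pd.DataFrame], group_of: dict[str, str]
) -> pd.DataFrame:
    """Group differences in relative substrate uptake, in percentage points.

    ``ledgers`` maps consumer id -> per-substrate uptake ledger (from a
    mixed-medium run); ``group_of`` maps consumer id -> response group.
    Per substrate, the group means of the consumed fraction (in %) are
    differenced (first group minus second, alphabetically) and ranked by
    magnitude.
    """
    groups = sorted(set(group_of.values()))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for cid, ledger in ledgers.items():
        g = group_of.get(cid)
        if g is None:
            continue
        for _, row in ledger.iterrows():
            rows.append(
                {
                    "consumer": cid,
                    "group": g,
                    "substrate": row["substrate"],
                    "depletion_pct": 100.0 * row["consumed_fraction"],
                }
            )
    long = pd.DataFrame(rows)
    for g in groups[:2]:
        if (long["group"] == g).sum() == 0:
            raise ValueError(f"group {g!r} has no consumers")
    means = long.pivot_table(
        index="substrate", columns="group", values="depletion_pct", aggfunc="mean"
    )
    out = means.copy()
    out["delta"] = means[groups[0]] - means[groups[1]]
    return out.sort_values("delta", key=np.abs, ascending=False)


def levins_niche_breadth(consumption: np.ndarray) -> float:
    """Levins index B = 1 / sum(p_i^2) on normalized consumption shares.

    Ranges from 1 (perfect specialist) to n (uniform generalist). All-zero
    consumption is undefined and returns NaN.
    """
    p = np.asarray(consumption, dtype=float)
    if np.any(p < 0):
        raise ValueError("consumption proportions must be non-negative")
    total = p.sum()
    if total == 0:
        return float("nan")
    p = p / total
    return float(1.0 / np.sum(p**2))


def variance_explained(
    table: pd.DataFrame,
    response: str = "r_realized",
    predictors: tuple[str, ...] = ("rrn_copies", "genome_size_bp"),
    interaction: bool = True,
) -> dict:
    """OLS r^2 of a phenotype on genomic traits (with optional interaction)."""
    df = table.dropna(subset=[response, *predictors])
    X = df[list(predictors)].astype(float).copy()
    if interaction and len(predictors) == 2:
        X["interaction"] = X.iloc[:, 0] * X.iloc[:, 1]
    X = sm.add_constant(X.values)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return {"r_squared": float("nan"), "rank_deficient": True, "n": len(df)}
    fit = sm.OLS(df[response].astype(float).values, X).fit()
    return {"r_squared": float(fit.rsquared), "rank_deficient": False, "n": len(df)}


def kruskal_dunn(values: pd.Series, groups: pd.Series) -> dict:
    """Kruskal-Wallis across groups plus BH-corrected pairwise rank tests.

    Thin, library-backed utility: the pairwise step uses two-sided
    Mann-Whitney U tests with Benjamini-Hochberg correction.
    """
    labels = sorted(groups.unique())
    samples = [values[groups == g].values for g in labels]
    H, p = stats.kruskal(*samples)
    pairs, pvals = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            _, pw = stats.mannwhitneyu(samples[i], samples[j], alternative="two-sided")
            pairs.append((labels[i], labels[j]))
            pvals.append(pw)
    if pvals:
        adjusted = sm.stats.multipletests(pvals, method="fdr_bh")[1]
    else:
        adjusted = []
    return {
        "H": float(H),
        "p_value": float(p),
        "pairwise": {pair: float(padj) for pair, padj in zip(pairs, adjusted)},
    }
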