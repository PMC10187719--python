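"""Penetrance tables, discordant-sib-pair statistics, sibling score
concordance, and the cohort-level association models.

Penetrance here is the crude proportion affected within a risk stratum
(score quantile bin crossed with APOE-e4 carrier status); the
age-adjusted counterpart lives in :mod:`famprs.cumrisk`.  The discordant
sib-pair statistic is the fraction of affection-discordant pairs in which
the affected sibling carries the strictly higher PRS — 0.5 under
score-disease independence by exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "StratumRule",
    "AssociationResult",
    "stratum_penetrance",
    "discordant_pair_stat",
    "sibling_prs_correlation",
    "percentile_concordance",
    "nagelkerke_r2",
    "fit_ad_association",
    "fit_aao_model",
]


@dataclass(frozen=True)
class StratumRule:
    """A penetrance stratum: a score-bin selector crossed with an APOE
    filter.

    ``prs_bin`` is None (no score restriction) or a pair like
    ("quintile", 5), ("decile", 1); ``apoe`` is "carrier", "noncarrier" or
    "any"; ``scope`` restricts to sibship members when "sibships".
    """

    prs_bin: tuple[str, int] | None = None
    apoe: str = "any"
    scope: str = "everyone"
    label: str = ""

    def mask(self, cohort: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(cohort), dtype=bool)
        if self.prs_bin is not None:
            col, val = self.prs_bin
            if col not in cohort.columns:
                raise KeyError(f"cohort lacks bin column {col!r}")
            m &= cohort[col].to_numpy() == val
        if self.apoe == "carrier":
            m &= cohort["e4"].to_numpy() > 0
        elif self.apoe == "noncarrier":
            m &= cohort["e4"].to_numpy() == 0
        elif self.apoe != "any":
            raise ValueError(f"unknown APOE filter {self.apoe!r}")
        if self.scope == "sibships":
            m &= (cohort["role"] == "sibling").to_numpy()
        return m


def stratum_penetrance(
    cohort: pd.DataFrame, rules: list[StratumRule]
) -> pd.DataFrame:
    """Affected proportion (with counts) in each stratum; an empty stratum
    yields NaN with n = 0."""
    rows = []
    for rule in rules:
        m = rule.mask(cohort)
        n = int(m.sum())
        aff = int(cohort.loc[m, "affected"].sum()) if n else 0
        rows.append(
            {
                "label": rule.label or repr(rule),
                "prs_bin": None if rule.prs_bin is None else f"{rule.prs_bin[0]}{rule.prs_bin[1]}",
                "apoe": rule.apoe,
                "scope": rule.scope,
                "n": n,
                "affected": aff,
                "penetrance": aff / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def discordant_pair_stat(pairs: pd.DataFrame, rule: StratumRule | None = None) -> float:
    """Fraction of discordant pairs whose affected member has the strictly
    higher PRS.

    Stratum membership of a pair follows its higher-PRS member's bin; an
    APOE-stratified rule additionally requires both siblings to share the
    carrier status.  Exact PRS ties are dropped.  Returns NaN when no pair
    qualifies.
    """
    sel = pairs["discordant"].to_numpy(dtype=bool) & ~pairs["prs_tie"].to_numpy(
        dtype=bool
    )
    if rule is not None and rule.prs_bin is not None:
        col, val = rule.prs_bin
        sel &= pairs[f"{col}_higher"].to_numpy() == val
    if rule is not None and rule.apoe == "carrier":
        sel &= (pairs["e4_a"].to_numpy() > 0) & (pairs["e4_b"].to_numpy() > 0)
    elif rule is not None and rule.apoe == "noncarrier":
        sel &= (pairs["e4_a"].to_numpy() == 0) & (pairs["e4_b"].to_numpy() == 0)
    if not sel.any():
        return float("nan")
    return float(pairs.loc[sel, "affected_higher"].mean())


def sibling_prs_correlation(
    pairs: pd.DataFrame, seed: int = 0
) -> tuple[float, float]:
    """Pearson correlation of sibling PRS over pairs, with the within-pair
    ordering randomised (seeded) so neither column is systematically the
    higher scorer.  Returns (r, two-sided p)."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    rng = np.random.default_rng(seed)
    flip = rng.integers(0, 2, size=len(pairs)).astype(bool)
    x = np.where(flip, pairs["prs_b"], pairs["prs_a"]).astype(float)
    y = np.where(flip, pairs["prs_a"], pairs["prs_b"]).astype(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in pair scores; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def percentile_concordance(
    pairs: pd.DataFrame,
    thresholds: tuple[float, ...] = (0.01, 0.05, 0.10, 0.20),
    pct_col: str = "pctile",
) -> dict[float, float]:
    """For each top-p threshold, the fraction of co-siblings also in the
    top p% given the index sibling is, with every qualifying sibling
    serving once as index (both pair orientations).  Percentile ranks are
    cohort-wide, in (0, 1].  NaN when no index sibling qualifies."""
    pa = pairs[f"{pct_col}_a"].to_numpy(dtype=float)
    pb = pairs[f"{pct_col}_b"].to_numpy(dtype=float)
    out = {}
    for p in thresholds:
        cut = 1.0 - p
        idx_a = pa > cut  # a as index
        idx_b = pb > cut
        n = idx_a.sum() + idx_b.sum()
        if n == 0:
            out[p] = float("nan")
            continue
        hits = (pb[idx_a] > cut).sum() + (pa[idx_b] > cut).sum()
        out[p] = float(hits / n)
    return out


@dataclass
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    r2: float
    p_value: float
    n: int
    model: str
    flags: list[str]


def nagelkerke_r2(ll_full: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 of a full vs null log-likelihood."""
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    return float(cox_snell / max_cs)


def fit_ad_association(
    cohort: pd.DataFrame,
    score_col: str = "prs",
    apoe_filter: str = "any",
    covar_cols: tuple[str, ...] = ("age", "sex", "pc1", "pc2", "pc3"),
) -> AssociationResult:
    """Logistic regression of affection on the standardized score plus
    covariates; OR per SD with Wald 95% CI, and Nagelkerke R^2 of the
    score relative to the covariate-only model.

    Complete-case on score and covariates.  Perfect separation falls back
    to an L2-regularised fit (flagged); the R^2 then uses unpenalised
    log-likelihoods evaluated at the regularised estimate.
    """
    df = cohort
    if apoe_filter == "carrier":
        df = df[df["e4"] > 0]
    elif apoe_filter == "noncarrier":
        df = df[df["e4"] == 0]
    cols = [score_col] + [c for c in covar_cols if c in df.columns]
    df = df.dropna(subset=cols)
    y = df["affected"].to_numpy(dtype=float)
    score = df[score_col].to_numpy(dtype=float)
    score = (score - score.mean()) / score.std()
    X_cov = df[[c for c in covar_cols if c in df.columns]].to_numpy(dtype=float)
    X_full = sm.add_constant(np.column_stack([score, X_cov]))
    X_null = sm.add_constant(X_cov)
    flags: list[str] = []
    try:
        fit = sm.Logit(y, X_full).fit(disp=0)
        ll_full = fit.llf
    except Exception:
        fit = sm.Logit(y, X_full).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        ll_full = sm.Logit(y, X_full).loglike(fit.params)
        flags.append("separation_penalized")
    null_fit = sm.Logit(y, X_null).fit(disp=0)
    beta = fit.params[1]
    se = (
        fit.bse[1]
        if hasattr(fit, "bse") and np.isfinite(fit.bse[1])
        else float("nan")
    )
    return AssociationResult(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        r2=nagelkerke_r2(ll_full, null_fit.llf, len(y)),
        p_value=float(2 * sps.norm.sf(abs(beta / se))) if np.isfinite(se) else float("nan"),
        n=len(y),
        model=f"AD ~ {score_col} + " + " + ".join(c for c in covar_cols if c in cohort.columns),
        flags=flags,
    )


def fit_aao_model(
    cases: pd.DataFrame,
    score_col: str = "prs",
    pc_cols: tuple[str, ...] = ("pc1", "pc2", "pc3"),
    quintile_col: str = "quintile",
) -> dict:
    """Least-squares regression of age at onset on the standardized score
    plus principal components, in affected individuals only.

    Returns the per-SD effect in years, its p-value, and mean onset age in
    the highest and lowest score quintile.  Refuses fewer than 10 cases.
    """
    df = cases[cases["affected"].astype(bool)].dropna(
        subset=[score_col, "onset_age"]
    )
    if len(df) < 10:
        raise ValueError(f"need >= 10 affected cases, got {len(df)}")
    score = df[score_col].to_numpy(dtype=float)
    score = (score - score.mean()) / score.std()
    pcs = df[[c for c in pc_cols if c in df.columns]].to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([score, pcs]))
    fit = sm.OLS(df["onset_age"].to_numpy(dtype=float), X).fit()
    out = {
        "effect_years_per_sd": float(fit.params[1]),
        "p_value": float(fit.pvalues[1]),
        "n_cases": len(df),
    }
    if quintile_col in df.columns:
        top = df.loc[df[quintile_col] == 5, "onset_age"]
        bot = df.loc[df[quintile_col] == 1, "onset_age"]
        out["mean_aao_top_quintile"] = float(top.mean()) if len(top) else float("nan")
        out["mean_aao_bottom_quintile"] = float(bot.mean()) if len(bot) else float("nan")
    return out
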