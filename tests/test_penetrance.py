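"""Stratum penetrance, discordant-pair statistics, sibling concordance and
association models, each against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sps

from famprs import scoring
from famprs.penetrance import (
    StratumRule,
    discordant_pair_stat,
    fit_aao_model,
    fit_ad_association,
    percentile_concordance,
    sibling_prs_correlation,
    stratum_penetrance,
)
from famprs.sibpairs import annotate_pairs, sample_one_pair
from famprs.simulate import SimulationConfig, simulate_cohort


def test_stratum_counts_and_conservation(sib_pairs_cohort):
    _, cohort = sib_pairs_cohort
    toy = pd.DataFrame(
        {
            "affected": [True] * 5 + [False] * 3,
            "e4": [1] * 8,
            "role": ["sibling"] * 8,
        }
    )
    tab = stratum_penetrance(toy, [StratumRule(apoe="carrier", label="c")])
    assert tab.loc[0, "penetrance"] == pytest.approx(0.625)
    assert tab.loc[0, "n"] == 8

    rules = [StratumRule(("quintile", k), label=f"q{k}") for k in range(1, 6)]
    tab = stratum_penetrance(cohort, rules)
    # quintile penetrances weighted by sizes reproduce the overall rate
    weighted = (tab["penetrance"] * tab["n"]).sum() / tab["n"].sum()
    assert weighted == pytest.approx(cohort["affected"].mean())
    assert tab["affected"].sum() == cohort["affected"].sum()

    empty = stratum_penetrance(cohort.iloc[:0], rules[:1])
    assert empty.loc[0, "n"] == 0 and np.isnan(empty.loc[0, "penetrance"])


def test_top_quintile_lifetime_penetrance_matches_probit_integral(
    sib_pairs_cohort,
):
    """Unascertained lifetime penetrance in the top score quintile equals
    E[Phi((g - T)/sd_resid)] over the truncated score distribution."""
    cfg, cohort = sib_pairs_cohort
    life = cohort.copy()
    life["affected"] = life["affected_lifetime"]
    tab = stratum_penetrance(
        life, [StratumRule(("quintile", 5), label="top")]
    )
    r2 = cfg.r2_prs
    T = sps.norm.ppf(1 - 0.32)  # lifetime threshold = last band prevalence
    sd = np.sqrt(r2)
    resid = np.sqrt(1 - r2)
    num, _ = integrate.quad(
        lambda g: sps.norm.pdf(g, scale=sd) * sps.norm.cdf((g - T) / resid),
        sps.norm.ppf(0.8) * sd,
        np.inf,
    )
    expect = num / 0.2
    n = tab.loc[0, "n"]
    se = np.sqrt(expect * (1 - expect) / n)
    assert tab.loc[0, "penetrance"] == pytest.approx(expect, abs=3 * se + 0.01)


def test_discordant_stat_toy_and_negation(sib_pairs_cohort):
    toy = pd.DataFrame(
        {
            "discordant": [True] * 3 + [False],
            "prs_tie": [False] * 4,
            "affected_higher": [True, True, False, True],
        }
    )
    assert discordant_pair_stat(toy) == pytest.approx(2 / 3)

    _, cohort = sib_pairs_cohort
    ps = sample_one_pair(cohort, seed=1)
    stat = discordant_pair_stat(ps.pairs)
    neg = cohort.copy()
    neg["prs"] = -neg["prs"]
    ps_neg = sample_one_pair(neg, seed=1)
    assert discordant_pair_stat(ps_neg.pairs) == pytest.approx(1 - stat)
    assert 0 <= stat <= 1


def test_discordant_stat_half_under_independence(sib_pairs_cohort):
    _, cohort = sib_pairs_cohort
    rng = np.random.default_rng(99)
    shuffled = cohort.copy()
    shuffled["prs"] = rng.permutation(shuffled["prs"].to_numpy())
    ps = sample_one_pair(shuffled, seed=2)
    sel = ps.pairs["discordant"] & ~ps.pairs["prs_tie"]
    n = int(sel.sum())
    stat = discordant_pair_stat(ps.pairs)
    se = np.sqrt(0.25 / n)
    assert stat == pytest.approx(0.5, abs=3 * se)

    no_pairs = ps.pairs[ps.pairs["discordant"] & ps.pairs["prs_tie"]]
    assert np.isnan(discordant_pair_stat(no_pairs))


def test_discordant_stat_matches_enumeration_oracle(sib_pairs_cohort):
    """With sibship size 2 every family contributes its only pair, so the
    replicate statistic must equal brute-force enumeration over all
    discordant pairs."""
    _, cohort = sib_pairs_cohort
    ps = sample_one_pair(cohort, seed=3)
    stat = discordant_pair_stat(ps.pairs)
    wide = cohort.set_index("iid")
    count = hits = 0
    for _, grp in cohort.groupby("fid"):
        a, b = grp.iloc[0], grp.iloc[1]
        if a["affected"] != b["affected"] and a["prs"] != b["prs"]:
            count += 1
            aff = a if a["affected"] else b
            una = b if a["affected"] else a
            hits += aff["prs"] > una["prs"]
    assert stat == pytest.approx(hits / count)


def test_sibling_correlation_trivial_and_recovery(sib_pairs_cohort):
    dup = pd.DataFrame({"prs_a": [1.0, 2, 3, 4], "prs_b": [1.0, 2, 3, 4]})
    r, _ = sibling_prs_correlation(dup, seed=0)
    assert r == pytest.approx(1.0)

    rng = np.random.default_rng(1)
    indep = pd.DataFrame(
        {"prs_a": rng.normal(size=800), "prs_b": rng.normal(size=800)}
    )
    r, p = sibling_prs_correlation(indep, seed=0)
    assert abs(r) < 2.58 / np.sqrt(800)  # 99% bound under the null

    _, cohort = sib_pairs_cohort
    ps = sample_one_pair(cohort, seed=4)
    r, p = sibling_prs_correlation(ps.pairs, seed=0)
    se = (1 - 0.25) / np.sqrt(len(ps.pairs))
    assert r == pytest.approx(0.5, abs=3 * se)
    assert p < 1e-10

    with pytest.raises(ValueError):
        sibling_prs_correlation(dup.iloc[:2], seed=0)
    with pytest.raises(ValueError):
        sibling_prs_correlation(
            pd.DataFrame({"prs_a": [1.0] * 5, "prs_b": [1.0] * 5}), seed=0
        )


def bivariate_topfrac_oracle(rho, p):
    """P(co-sib in top p | index in top p) for bivariate normal scores,
    by numerical double integration."""
    c = sps.norm.ppf(1 - p)
    inner = lambda x: sps.norm.pdf(x) * sps.norm.cdf(
        (rho * x - c) / np.sqrt(1 - rho**2)
    )
    num, _ = integrate.quad(inner, c, np.inf)
    return num / p


def test_percentile_concordance_trivial_and_oracle(sib_pairs_cohort):
    same = pd.DataFrame({"pctile_a": [0.999, 0.5], "pctile_b": [0.995, 0.4]})
    out = percentile_concordance(same, thresholds=(0.01,))
    assert out[0.01] == 1.0

    rng = np.random.default_rng(2)
    indep = pd.DataFrame(
        {
            "pctile_a": rng.uniform(size=4000),
            "pctile_b": rng.uniform(size=4000),
        }
    )
    out = percentile_concordance(indep, thresholds=(0.2,))
    assert out[0.2] == pytest.approx(0.2, abs=0.03)

    _, cohort = sib_pairs_cohort
    ps = sample_one_pair(cohort, seed=5)
    out = percentile_concordance(ps.pairs, thresholds=(0.2, 0.05))
    expect = bivariate_topfrac_oracle(0.5, 0.2)
    assert expect == pytest.approx(0.436, abs=0.005)  # sanity on the oracle
    assert out[0.2] == pytest.approx(expect, abs=0.045)
    # enrichment above the independence baseline at every threshold
    assert out[0.05] > 0.05 and out[0.2] > 0.2

    nothing = percentile_concordance(
        pd.DataFrame({"pctile_a": [0.1], "pctile_b": [0.1]}), thresholds=(0.01,)
    )
    assert np.isnan(nothing[0.01])


def _assoc_cohort(seed, n=3000):
    cfg = SimulationConfig(
        n_families=0,
        n_unrelated=n,
        mode="infinitesimal",
        r2_prs=0.068,
        r2_apoe=0.052,
        seed=seed,
    )
    cohort, _ = simulate_cohort(cfg)
    cohort = cohort.copy()
    cohort["prs"] = scoring.standardize(cohort["g_prs"].to_numpy())
    cohort["prs_ad"] = scoring.standardize(
        (cohort["g_prs"] + cohort["g_apoe"]).to_numpy()
    )
    return cohort


def test_association_recovers_risk_and_nests():
    cohort = _assoc_cohort(seed=41)
    fit_prs = fit_ad_association(cohort, "prs")
    fit_ad = fit_ad_association(cohort, "prs_ad")
    assert fit_prs.odds_ratio > 1.1
    assert fit_prs.ci_low < fit_prs.odds_ratio < fit_prs.ci_high
    assert 0 < fit_prs.r2 < 1
    # adding the APOE signal strictly increases both OR and pseudo-R2
    assert fit_ad.odds_ratio > fit_prs.odds_ratio
    assert fit_ad.r2 > fit_prs.r2
    # carrier strata have the expected sample split
    fit_car = fit_ad_association(cohort, "prs", apoe_filter="carrier")
    fit_non = fit_ad_association(cohort, "prs", apoe_filter="noncarrier")
    assert fit_car.n + fit_non.n == fit_prs.n


def test_association_null_coverage():
    rng = np.random.default_rng(7)
    cohort = _assoc_cohort(seed=43, n=500)
    covered = 0
    runs = 100
    for _ in range(runs):
        c = cohort.copy()
        c["prs"] = rng.standard_normal(len(c))  # score carries no signal
        fit = fit_ad_association(c, "prs")
        covered += fit.ci_low <= 1.0 <= fit.ci_high
    assert covered >= 93


def test_aao_model_recovery():
    rng = np.random.default_rng(8)
    n = 400
    score = rng.standard_normal(n)
    onset = 80 - 2.0 * score + rng.normal(0, 3, size=n)
    cases = pd.DataFrame(
        {
            "affected": True,
            "onset_age": onset,
            "prs": score,
            "pc1": rng.standard_normal(n),
            "pc2": rng.standard_normal(n),
            "pc3": rng.standard_normal(n),
        }
    )
    q, _ = scoring.bin_quantiles(score, 5)
    cases["quintile"] = q
    out = fit_aao_model(cases, "prs")
    se_hat = 3 / np.sqrt(n)
    assert out["effect_years_per_sd"] == pytest.approx(-2.0, abs=3 * se_hat)
    assert out["p_value"] < 1e-10
    assert out["mean_aao_top_quintile"] < out["mean_aao_bottom_quintile"]

    with pytest.raises(ValueError):
        fit_aao_model(cases.iloc[:5], "prs")

    null = cases.copy()
    null["onset_age"] = 80 + rng.normal(0, 3, size=n)
    out0 = fit_aao_model(null, "prs")
    assert abs(out0["effect_years_per_sd"]) < 3 * 3 / np.sqrt(n)
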