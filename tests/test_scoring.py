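"""C+T scoring: clumping against a brute-force oracle, score arithmetic,
region exclusion, covariate adjustment, PRS.AD, quantile binning."""

import numpy as np
import pandas as pd
import pytest

from famprs.scoring import (
    APOE_REGION,
    ClumpParams,
    ExclusionRegion,
    adjust_covariates,
    bin_quantiles,
    clump,
    compute_prs,
    make_prs_ad,
    score_pipeline,
    standardize,
)
from famprs.simulate import GenotypePanel


def make_panel(dosages, chrom=None, pos=None, ids=None):
    dosages = np.asarray(dosages, dtype=np.float32)
    n, m = dosages.shape
    snps = pd.DataFrame(
        {
            "snp": ids if ids is not None else [f"s{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "a1": ["A"] * m,
            "a2": ["G"] * m,
            "maf": np.clip(dosages.mean(axis=0) / 2, 0.01, 0.5),
            "block": 0,
            "true_beta": 0.0,
        }
    )
    return GenotypePanel(snps=snps, dosages=dosages, iids=np.array([f"i{k}" for k in range(n)]))


def stats_for(panel, p, beta=None, maf=None):
    m = len(panel.snps)
    return pd.DataFrame(
        {
            "SNP": panel.snps["snp"],
            "CHR": panel.snps["chrom"],
            "BP": panel.snps["pos"],
            "A1": panel.snps["a1"],
            "A2": panel.snps["a2"],
            "BETA": beta if beta is not None else np.ones(m),
            "SE": np.ones(m),
            "P": p,
            "MAF": maf if maf is not None else panel.snps["maf"],
        }
    )


def brute_force_clump(stats, panel, params):
    """Independent greedy reference: explicit pairwise r^2 matrix, ordered
    removal by ascending p."""
    df = stats[(stats["P"] <= params.p_threshold) & (stats["MAF"] >= params.maf_min)]
    df = df.sort_values(["P", "SNP"], kind="mergesort")
    idx = {s: j for j, s in enumerate(panel.snps["snp"])}
    live = [s for s in df["SNP"] if s in idx]
    X = panel.dosages.astype(float)
    R2 = np.corrcoef(X, rowvar=False) ** 2
    pos = panel.snps.set_index("snp")["pos"]
    chrom = panel.snps.set_index("snp")["chrom"]
    retained = []
    while live:
        top = live.pop(0)
        retained.append(top)
        keep = []
        for s in live:
            near = (
                chrom[s] == chrom[top]
                and abs(pos[s] - pos[top]) <= params.window_bp
            )
            if near and R2[idx[s], idx[top]] >= params.r2_max:
                continue
            keep.append(s)
        live = keep
    return sorted(retained)


def test_clump_three_snp_forced_case():
    # r2(1,2) high, r2(1,3) low, all within one window; greedy keeps 1 and 3
    rng = np.random.default_rng(0)
    z1 = rng.normal(size=500)
    z2 = 0.75 * z1 + 0.66 * rng.normal(size=500)  # r ~ 0.75 -> r2 ~ 0.56
    z3 = 0.32 * z1 + 0.95 * rng.normal(size=500)  # r2 ~ 0.1
    dos = np.clip(np.round(np.column_stack([z1, z2, z3]) + 1), 0, 2)
    panel = make_panel(dos)
    stats = stats_for(panel, p=[0.001, 0.01, 0.05])
    retained, report = clump(stats, panel, ClumpParams(window_bp=10_000))
    assert retained == ["s0", "s2"]
    assert report.set_index("snp").loc["s1", "status"] == "removed_ld"
    assert report.set_index("snp").loc["s1", "clumped_by"] == "s0"


def test_clump_uncorrelated_all_retained():
    rng = np.random.default_rng(1)
    panel = make_panel(rng.integers(0, 3, size=(400, 8)))
    stats = stats_for(panel, p=np.full(8, 0.01))
    retained, _ = clump(stats, panel, ClumpParams())
    assert len(retained) == 8


def test_clump_filters_reported():
    rng = np.random.default_rng(2)
    panel = make_panel(rng.integers(0, 3, size=(200, 4)))
    stats = stats_for(panel, p=[0.01, 0.5, 0.01, 0.01], maf=[0.3, 0.3, 0.001, 0.3])
    retained, report = clump(stats, panel, ClumpParams())
    st = report.set_index("snp")["status"]
    assert st["s1"] == "filtered_p" and st["s2"] == "filtered_maf"
    assert set(retained) == {"s0", "s3"}


def test_clump_no_overlap_is_error():
    rng = np.random.default_rng(3)
    panel = make_panel(rng.integers(0, 3, size=(50, 3)))
    stats = stats_for(panel, p=[0.01] * 3).assign(SNP=["x1", "x2", "x3"])
    with pytest.raises(ValueError):
        clump(stats, panel)


@pytest.mark.parametrize("seed", [10, 11, 12])
def test_clump_matches_brute_force_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    n, m = 300, 200
    # blocky correlation so LD removal actually triggers
    latent = rng.normal(size=(n, 40))
    load = latent[:, rng.integers(0, 40, size=m)]
    dos = np.clip(np.round(0.8 * load + rng.normal(size=(n, m)) + 1), 0, 2)
    chrom = np.repeat([str(c) for c in range(1, 5)], m // 4)
    pos = np.tile((np.arange(m // 4) + 1) * 60_000, 4)
    panel = make_panel(dos, chrom=chrom, pos=pos)
    stats = stats_for(panel, p=rng.uniform(0, 0.2, size=m))
    params = ClumpParams(p_threshold=0.1, r2_max=0.2, window_bp=250_000)
    retained, _ = clump(stats, panel, params)
    assert sorted(retained) == brute_force_clump(stats, panel, params)


def test_prs_arithmetic_single_snp():
    panel = make_panel(np.array([[0.0], [1.0], [2.0]]))
    weights = pd.DataFrame(
        {"SNP": ["s0"], "A1": ["A"], "A2": ["G"], "BETA": [np.log(1.5)]}
    )
    scores, rep = compute_prs(panel, weights, exclusion=None)
    assert scores == pytest.approx([0.0, 0.4055, 0.8109], abs=1e-4)
    assert rep["n_used"] == 1


def test_prs_allele_flip_and_unresolvable():
    panel = make_panel(np.array([[0.0, 2.0], [2.0, 0.0]]))
    weights = pd.DataFrame(
        {
            "SNP": ["s0", "s1"],
            "A1": ["G", "C"],  # s0 swapped orientation, s1 unresolvable
            "A2": ["A", "T"],
            "BETA": [1.0, 5.0],
        }
    )
    with pytest.warns(UserWarning):
        scores, rep = compute_prs(panel, weights, exclusion=None)
    # swapped orientation flips the sign: beta * dosage -> -1 * (0, 2)
    assert scores == pytest.approx([0.0, -2.0])
    assert rep["n_dropped_alleles"] == 1


def test_apoe_region_exclusion():
    dos = np.array([[1.0, 2.0], [0.0, 1.0], [2.0, 0.0]])
    panel = make_panel(dos, chrom=["1", "19"], pos=[5_000, 43_000_000])
    weights = pd.DataFrame(
        {"SNP": ["s0", "s1"], "A1": ["A", "A"], "A2": ["G", "G"], "BETA": [1.0, 9.0]}
    )
    scores, rep = compute_prs(panel, weights, exclusion=APOE_REGION)
    assert scores == pytest.approx(dos[:, 0])
    assert rep["n_excluded_region"] == 1
    assert not APOE_REGION.contains(["19"], [42_905_790])[0]
    assert APOE_REGION.contains(["19"], [46_909_393])[0]


def test_prs_matches_double_loop_oracle():
    rng = np.random.default_rng(4)
    dos = rng.integers(0, 3, size=(40, 50)).astype(np.float32)
    panel = make_panel(dos)
    beta = rng.normal(size=50)
    weights = pd.DataFrame(
        {"SNP": panel.snps["snp"], "A1": "A", "A2": "G", "BETA": beta}
    )
    scores, _ = compute_prs(panel, weights, exclusion=None)
    naive = np.zeros(40)
    for i in range(40):
        for j in range(50):
            naive[i] += beta[j] * dos[i, j]
    assert scores == pytest.approx(naive, rel=1e-6)


def test_prs_invariant_to_snp_order():
    rng = np.random.default_rng(5)
    dos = rng.integers(0, 3, size=(30, 20)).astype(np.float32)
    panel = make_panel(dos)
    beta = rng.normal(size=20)
    weights = pd.DataFrame(
        {"SNP": panel.snps["snp"], "A1": "A", "A2": "G", "BETA": beta}
    )
    s1, _ = compute_prs(panel, weights, exclusion=None)
    s2, _ = compute_prs(panel, weights.sample(frac=1, random_state=0), exclusion=None)
    assert s1 == pytest.approx(s2)


def test_adjust_covariates():
    rng = np.random.default_rng(6)
    pcs = rng.normal(size=(200, 3))
    noise = rng.normal(size=200)
    scores = 2.0 + 1.5 * pcs[:, 0] - 0.7 * pcs[:, 2] + noise
    adj = adjust_covariates(scores, pcs)
    assert np.abs(adj @ pcs).max() < 1e-8
    assert adj.mean() == pytest.approx(0, abs=1e-10)
    # zero covariates -> centering only
    centered = adjust_covariates(scores, np.zeros((200, 2)))
    assert centered == pytest.approx(scores - scores.mean())
    # score exactly linear in PC1 -> residual ~ 0
    assert np.abs(adjust_covariates(pcs[:, 0] * 3.0, pcs)).max() < 1e-10


def test_make_prs_ad():
    prs = np.array([0.0, 1.0, -1.0])
    d4 = np.array([2.0, 0.0, 1.0])
    d2 = np.array([0.0, 0.0, 1.0])
    assert make_prs_ad(prs, d4, d2, 0.0, 0.0) == pytest.approx(prs)
    got = make_prs_ad(prs, d4, d2, 0.4, -0.2)
    assert got[0] - prs[0] == pytest.approx(0.8)  # e4 homozygote: +2*beta4
    assert got[2] == pytest.approx(-1.0 + 0.4 - 0.2)
    assert np.isnan(make_prs_ad(prs, np.array([np.nan, 0, 0]), d2, 0.4, -0.2)[0])


def test_bin_quantiles_even_and_ties():
    scores = np.arange(100, dtype=float)
    bins, pct = bin_quantiles(scores, 5)
    assert np.bincount(bins)[1:].tolist() == [20] * 5
    assert pct[-1] == 1.0 and pct[0] == pytest.approx(0.01)
    # all equal: deterministic by id order, sizes still 20
    tied, _ = bin_quantiles(np.zeros(100), 5, ids=np.arange(100))
    assert np.bincount(tied)[1:].tolist() == [20] * 5
    tied2, _ = bin_quantiles(np.zeros(100), 5, ids=np.arange(100))
    assert np.array_equal(tied, tied2)
    with pytest.raises(ValueError):
        bin_quantiles(scores, 1)
    with pytest.raises(ValueError):
        bin_quantiles(scores[:3], 5)


def test_bin_quantiles_matches_sort_oracle():
    rng = np.random.default_rng(7)
    scores = rng.normal(size=237)
    bins, _ = bin_quantiles(scores, 10)
    order = np.argsort(scores, kind="stable")
    expect = np.empty(237, dtype=int)
    for rank, i in enumerate(order):
        expect[i] = (rank * 10) // 237 + 1
    assert np.array_equal(bins, expect)


def test_pipeline_recovers_true_score_when_noise_vanishes(snp_cohort):
    _, cohort, panel, stats, _ = snp_cohort
    # noise-free summary stats: emitted beta equals the true liability beta
    clean = stats.copy()
    clean["BETA"] = panel.snps["true_beta"].to_numpy()
    clean["P"] = np.where(clean["BETA"] != 0, 1e-8, 1.0)
    res = score_pipeline(panel, clean, clump_params=ClumpParams(r2_max=0.999))
    r = np.corrcoef(res.standardized, cohort["g_prs"])[0, 1]
    assert r > 0.95


def test_exclusion_region_validation():
    with pytest.raises(ValueError):
        ExclusionRegion("19", 100, 100)
    with pytest.raises(ValueError):
        ClumpParams(p_threshold=0.0).validate()
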