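import numpy as np
import pytest

from famprs import pipeline, scoring
from famprs.simulate import (
    SimulationConfig,
    generate_summary_stats,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def snp_cohort():
    """Mid-sized SNP-mode cohort with genotypes, summary stats and scores
    attached (unascertained, so population-level checks are unbiased)."""
    cfg = SimulationConfig(
        n_families=300,
        n_unrelated=150,
        n_snps=400,
        sibship_size_distribution={2: 0.4, 3: 0.3, 4: 0.2, 5: 0.1},
        seed=11,
    )
    cohort, panel = simulate_cohort(cfg)
    stats = generate_summary_stats(panel, gwas_n=cfg.gwas_n, seed=12)
    result = scoring.score_pipeline(panel, stats)
    scored = pipeline.attach_scores(cohort, result)
    return cfg, scored, panel, stats, result


@pytest.fixture(scope="session")
def sib_pairs_cohort():
    """Large pure-sibpair cohort (infinitesimal score) for pair statistics."""
    cfg = SimulationConfig(
        n_families=4000,
        n_unrelated=0,
        sibship_size_distribution={2: 1.0},
        mode="infinitesimal",
        r2_prs=0.12,
        r2_apoe=0.0,
        seed=21,
    )
    cohort, _ = simulate_cohort(cfg)
    cohort = cohort.copy()
    cohort["prs"] = cohort["g_prs"]
    q, _ = scoring.bin_quantiles(
        cohort["prs"].to_numpy(), 5, cohort["iid"].to_numpy()
    )
    d, pct = scoring.bin_quantiles(
        cohort["prs"].to_numpy(), 10, cohort["iid"].to_numpy()
    )
    cohort["quintile"] = q
    cohort["decile"] = d
    cohort["pctile"] = pct
    return cfg, cohort
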