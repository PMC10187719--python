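"""Stratum penetrance and discordant-sib-pair tables.

Crude penetrance by score quantile crossed with APOE-e4 status (everyone
vs sibships), and the fraction of affection-discordant sibling pairs in
which the affected sibling carries the higher PRS, under both pairing
strategies with 100 replicates.
"""

import argparse

import pandas as pd
from common import load_scored_cohort, outpath

from famprs.penetrance import discordant_pair_stat, stratum_penetrance
from famprs.pipeline import STRATUM_RULES, _discordant_strata
from famprs.sibpairs import replicate_estimate


def main(seed: int, n_rep: int = 100) -> None:
    cohort = load_scored_cohort()

    t4 = pd.concat(
        [
            stratum_penetrance(cohort, STRATUM_RULES("everyone")).assign(
                scope="everyone"
            ),
            stratum_penetrance(cohort, STRATUM_RULES("sibships")).assign(
                scope="sibships"
            ),
        ],
        ignore_index=True,
    )
    out4 = outpath("penetrance_strata.tsv")
    t4.to_csv(out4, sep="\t", index=False, float_format="%.4f")

    rows = []
    for strategy in ("one_per_family", "max_pairs"):
        for label, rule in _discordant_strata():
            summ = replicate_estimate(
                lambda ps, rule=rule: discordant_pair_stat(ps.pairs, rule),
                cohort,
                strategy=strategy,
                n_rep=n_rep,
                seed=seed,
                name=label,
            )
            rows.append(
                {
                    "stratum": label,
                    "strategy": strategy,
                    "mean": summ.mean,
                    "sd": summ.sd,
                    "n_missing_replicates": summ.n_missing,
                }
            )
    t5 = pd.DataFrame(rows)
    out5 = outpath("discordant_pairs.tsv")
    t5.to_csv(out5, sep="\t", index=False, float_format="%.4f")

    top = t4[(t4["label"] == "PRS in highest quintile") & (t4["scope"] == "everyone")]
    bot = t4[(t4["label"] == "PRS in lowest quintile") & (t4["scope"] == "everyone")]
    print(
        f"penetrance, highest vs lowest PRS quintile: "
        f"{top['penetrance'].iloc[0]:.2f} vs {bot['penetrance'].iloc[0]:.2f}"
    )
    overall = t5[(t5["stratum"] == "Overall") & (t5["strategy"] == "one_per_family")]
    print(
        "discordant pairs where the affected sibling has the higher PRS: "
        f"{overall['mean'].iloc[0]:.2f} ({overall['sd'].iloc[0]:.2f}) "
        "[0.5 would mean no information]"
    )
    print(f"wrote {out4}\nwrote {out5}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2024)
    main(ap.parse_args().seed)
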