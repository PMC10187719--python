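"""Compute the clumping+thresholding PRS from the written cohort files.

Reads the DS-dosage VCF and summary statistics emitted by
01_simulate_cohort.py, clumps (p <= 0.1, r^2 < 0.2, 250 kb), scores with
the APOE region excluded, builds PRS.AD, and writes per-individual scores
with quintile/decile assignments to results/prs_scores.tsv.
"""

import argparse
import os

from common import CLUMP, DATA_DIR, outpath

from famprs import io, scoring


def main(seed: int) -> None:
    panel = io.read_vcf_dosages(os.path.join(DATA_DIR, "genotypes.vcf"))
    stats = io.read_summary_stats(os.path.join(DATA_DIR, "sumstats.tsv"))
    result = scoring.score_pipeline(panel, stats, clump_params=CLUMP)

    frame = result.frame()
    q, _ = scoring.bin_quantiles(result.standardized, 5, result.iids)
    d, pct = scoring.bin_quantiles(result.standardized, 10, result.iids)
    frame["QUINTILE"] = q
    frame["DECILE"] = d
    frame["PCTILE"] = pct
    out = outpath("prs_scores.tsv")
    frame.to_csv(out, sep="\t", index=False, float_format="%.6g")

    rep = result.clump_report["status"].value_counts().to_dict()
    print(f"clump report: {rep}")
    print(f"scored {len(frame)} individuals with {result.n_snps_used} SNPs")
    print(f"wrote {out}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2024)
    main(ap.parse_args().seed)
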