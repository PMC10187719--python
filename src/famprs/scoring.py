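"""Clumping + thresholding polygenic risk scores.

The score pipeline mirrors standard C+T practice: greedy LD clumping of
p-value-ranked summary statistics (p <= 0.1, r^2 < 0.2, 250 kb windows,
MAF >= 0.01 by default), a weighted dosage sum excluding the 2 Mb region
flanking APOE (GRCh38 chr19:42,905,791-46,909,393), residualisation on
principal components, standardisation to unit SD, the PRS.AD augmentation
(adding back the two APOE-coding SNPs rs429358/rs7412), and quantile
binning.  LD r^2 is computed from the analysis genotype panel itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GenotypePanel

__all__ = [
    "ClumpParams",
    "ExclusionRegion",
    "APOE_REGION",
    "PRSResult",
    "clump",
    "compute_prs",
    "adjust_covariates",
    "standardize",
    "make_prs_ad",
    "bin_quantiles",
    "score_pipeline",
]


@dataclass(frozen=True)
class ClumpParams:
    p_threshold: float = 0.1
    r2_max: float = 0.2
    window_bp: int = 250_000
    maf_min: float = 0.01

    def validate(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0,1]")
        if not 0 < self.r2_max < 1:
            raise ValueError("r2_max must be in (0,1)")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0,0.5)")


@dataclass(frozen=True)
class ExclusionRegion:
    chromosome: str
    start: int
    end: int
    build: str = "GRCh38"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("exclusion region start must precede end")

    def contains(self, chrom, pos) -> np.ndarray:
        chrom = np.asarray(chrom, dtype=str)
        pos = np.asarray(pos)
        return (chrom == self.chromosome) & (pos >= self.start) & (pos <= self.end)


#: 2 Mb flanking region around APOE, GRCh38.
APOE_REGION = ExclusionRegion("19", 42_905_791, 46_909_393)


@dataclass
class PRSResult:
    """Per-individual scores plus the clump report for one scoring run."""

    iids: np.ndarray
    raw: np.ndarray
    adjusted: np.ndarray
    standardized: np.ndarray
    prs_ad: np.ndarray | None
    n_snps_used: int
    clump_report: pd.DataFrame

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "IID": self.iids,
                "PRS_RAW": self.raw,
                "PRS_ADJ": self.adjusted,
                "PRS_STD": self.standardized,
            }
        )
        if self.prs_ad is not None:
            df["PRS_AD"] = self.prs_ad
        return df


# ---------------------------------------------------------------------------
# clumping


def clump(
    stats: pd.DataFrame, panel: GenotypePanel, params: ClumpParams | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Greedy LD clumping of summary statistics against the panel.

    SNPs enter if p <= p_threshold and MAF >= maf_min; candidates are
    visited by ascending p (ties broken by SNP id); each retained SNP
    removes every remaining same-chromosome SNP within ``window_bp`` whose
    dosage r^2 with it is >= ``r2_max``.

    Returns the retained SNP ids and a per-SNP report with columns
    snp, status in {retained, removed_ld, filtered_p, filtered_maf,
    not_in_panel}, and clumped_by (index SNP for removed_ld).
    """
    params = params or ClumpParams()
    params.validate()
    panel_idx = {s: j for j, s in enumerate(panel.snps["snp"])}
    report = pd.DataFrame(
        {"snp": stats["SNP"].to_numpy(), "status": "", "clumped_by": ""}
    )
    in_panel = stats["SNP"].map(panel_idx).notna().to_numpy()
    if not in_panel.any():
        raise ValueError("no overlap between summary statistics and panel")
    report.loc[~in_panel, "status"] = "not_in_panel"
    p = stats["P"].to_numpy()
    maf = stats["MAF"].to_numpy()
    report.loc[in_panel & (maf < params.maf_min), "status"] = "filtered_maf"
    elig = in_panel & (maf >= params.maf_min)
    report.loc[elig & (p > params.p_threshold), "status"] = "filtered_p"
    elig &= p <= params.p_threshold

    cand = stats.loc[elig, ["SNP", "CHR", "BP", "P"]].copy()
    cand = cand.sort_values(["P", "SNP"], kind="mergesort").reset_index(drop=True)
    cols = cand["SNP"].map(panel_idx).astype(int).to_numpy()
    X = panel.dosages[:, cols].astype(float)
    X = X - X.mean(axis=0)
    norms = np.sqrt((X**2).sum(axis=0))
    norms[norms == 0] = np.nan

    chrom = cand["CHR"].astype(str).to_numpy()
    bp = cand["BP"].to_numpy()
    alive = np.ones(len(cand), dtype=bool)
    status = np.full(len(cand), "", dtype=object)
    clumped_by = np.full(len(cand), "", dtype=object)
    for i in range(len(cand)):
        if not alive[i]:
            continue
        status[i] = "retained"
        near = (
            alive
            & (np.arange(len(cand)) != i)
            & (chrom == chrom[i])
            & (np.abs(bp - bp[i]) <= params.window_bp)
        )
        if near.any():
            j = np.flatnonzero(near)
            r = (X[:, j].T @ X[:, i]) / (norms[j] * norms[i])
            hit = j[np.nan_to_num(r**2) >= params.r2_max]
            alive[hit] = False
            status[hit] = "removed_ld"
            clumped_by[hit] = cand["SNP"].iloc[i]
    by_snp = dict(zip(cand["SNP"], zip(status, clumped_by)))
    for k, row in report.iterrows():
        if row["snp"] in by_snp and report.at[k, "status"] == "":
            st, cb = by_snp[row["snp"]]
            report.at[k, "status"] = st
            report.at[k, "clumped_by"] = cb
    retained = [s for s, (st, _) in by_snp.items() if st == "retained"]
    retained.sort(key=lambda s: panel_idx[s])
    return retained, report


# ---------------------------------------------------------------------------
# scoring


def compute_prs(
    panel: GenotypePanel,
    weights: pd.DataFrame,
    exclusion: ExclusionRegion | None = APOE_REGION,
) -> tuple[np.ndarray, dict]:
    """Weighted dosage sum over resolvable, non-excluded SNPs.

    ``weights`` needs columns SNP, A1, A2, BETA.  Effect alleles are
    normalised against the panel: matching (A1, A2) uses beta as-is, a
    swapped orientation flips the sign, and an unresolvable allele pair
    drops the SNP with a warning.  Missing dosages contribute the SNP's
    mean dosage.  Returns (scores, report dict).
    """
    snps = panel.snps
    idx = {s: j for j, s in enumerate(snps["snp"])}
    n = panel.dosages.shape[0]
    scores = np.zeros(n)
    used = dropped_allele = excluded = missing = 0
    for _, w in weights.iterrows():
        j = idx.get(w["SNP"])
        if j is None:
            missing += 1
            continue
        row = snps.iloc[j]
        if exclusion is not None and exclusion.contains(
            [str(row["chrom"])], [row["pos"]]
        )[0]:
            excluded += 1
            continue
        if (w["A1"], w["A2"]) == (row["a1"], row["a2"]):
            beta = float(w["BETA"])
        elif (w["A1"], w["A2"]) == (row["a2"], row["a1"]):
            beta = -float(w["BETA"])
        else:
            warnings.warn(
                f"SNP {w['SNP']}: alleles {w['A1']}/{w['A2']} unresolvable "
                f"against panel {row['a1']}/{row['a2']}; dropped"
            )
            dropped_allele += 1
            continue
        d = panel.dosages[:, j].astype(float)
        if np.isnan(d).any():
            d = np.where(np.isnan(d), np.nanmean(d), d)
        scores += beta * d
        used += 1
    report = {
        "n_used": used,
        "n_excluded_region": excluded,
        "n_dropped_alleles": dropped_allele,
        "n_not_in_panel": missing,
    }
    return scores, report


def adjust_covariates(scores: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residual of the least-squares regression of scores on covariates
    (plus intercept); collinear columns are handled by the minimum-norm
    solution.  With no covariates this is plain centering."""
    scores = np.asarray(scores, dtype=float)
    if covariates is None or covariates.size == 0:
        return scores - scores.mean()
    X = np.column_stack([np.ones(len(scores)), np.asarray(covariates, float)])
    coef, *_ = np.linalg.lstsq(X, scores, rcond=None)
    return scores - X @ coef


def standardize(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    sd = scores.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant score")
    return (scores - scores.mean()) / sd


def make_prs_ad(
    prs: np.ndarray,
    d4: np.ndarray,
    d2: np.ndarray,
    beta4: float,
    beta2: float,
) -> np.ndarray:
    """PRS.AD: the APOE-region-free PRS plus the weighted dosages of the
    two APOE-coding SNPs (e4: rs429358; e2: rs7412).  Individuals with a
    missing APOE dosage get NaN."""
    prs = np.asarray(prs, dtype=float)
    d4 = np.asarray(d4, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    out = prs + beta4 * d4 + beta2 * d2
    return out


def bin_quantiles(
    scores: np.ndarray,
    k: int,
    ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Quantile bins 1..k and upper-tail-friendly percentile ranks.

    Ranks are assigned by a stable sort on (score, id) so exact ties break
    deterministically by id; bin sizes differ by at most one.  The
    percentile rank of an individual is (rank + 1) / n with rank 0-based
    ascending, so "top p%" selects percentile rank > 1 - p.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if k < 2:
        raise ValueError("number of bins must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} observations, got {n}")
    if ids is None:
        ids = np.arange(n)
    order = np.lexsort((np.asarray(ids), scores))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    bins = (rank * k) // n + 1
    pct = (rank + 1) / n
    return bins, pct


# ---------------------------------------------------------------------------
# one-call pipeline


def score_pipeline(
    panel: GenotypePanel,
    stats: pd.DataFrame,
    covariates: np.ndarray | None = None,
    clump_params: ClumpParams | None = None,
    exclusion: ExclusionRegion | None = APOE_REGION,
    apoe_snps: tuple[str, str] = ("rs429358", "rs7412"),
) -> PRSResult:
    """Clump -> score (APOE region excluded) -> adjust -> standardize ->
    PRS.AD, returning a :class:`PRSResult`."""
    retained, report = clump(stats, panel, clump_params)
    weights = stats.loc[stats["SNP"].isin(retained), ["SNP", "A1", "A2", "BETA"]]
    raw, score_report = compute_prs(panel, weights, exclusion)
    adjusted = adjust_covariates(raw, covariates)
    std = standardize(adjusted)

    prs_ad = None
    e4_id, e2_id = apoe_snps
    stats_idx = stats.set_index("SNP")
    panel_ids = set(panel.snps["snp"])
    if e4_id in panel_ids and e2_id in panel_ids and {e4_id, e2_id} <= set(
        stats_idx.index
    ):
        prs_ad = make_prs_ad(
            std,
            panel.dosage_of(e4_id),
            panel.dosage_of(e2_id),
            float(stats_idx.at[e4_id, "BETA"]),
            float(stats_idx.at[e2_id, "BETA"]),
        )
    return PRSResult(
        iids=np.asarray(panel.iids),
        raw=raw,
        adjusted=adjusted,
        standardized=std,
        prs_ad=prs_ad,
        n_snps_used=score_report["n_used"],
        clump_report=report,
    )
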