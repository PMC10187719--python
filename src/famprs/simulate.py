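"""Synthetic multiplex-family cohorts with the statistical structure the
downstream penetrance and recurrence analyses assume.

The generator emulates a late-onset Alzheimer's-like family study:

* sibships of configurable size with genotypes produced by Mendelian
  transmission from simulated parental haplotypes (per-SNP sibling dosage
  correlation 0.5 in expectation), plus unrelated singleton cases;
* a polygenic liability component ``g_prs`` built from causal SNP effects
  (or, in ``"infinitesimal"`` mode, from exact Gaussian mid-parent
  segregation), an APOE-like biallelic major locus ``g_apoe`` with e2/e3/e4
  alleles, an optional shared familial residual, and independent noise —
  summing to unit liability variance;
* deterministic onset given liability through an age-declining threshold
  T(band) = probit(1 - K(band)) calibrated to an age-specific cumulative
  prevalence schedule (default 3% / 17% / 32% at 65-74 / 75-84 / 85+);
* noisy GWAS summary statistics over the panel, standing in for an external
  base study.

Everything is deterministic given the master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimulationConfig",
    "GenotypePanel",
    "DEFAULT_SCHEDULE",
    "parse_schedule",
    "simulate_cohort",
    "assign_onset",
    "ascertain_families",
    "generate_summary_stats",
]

#: Age-band cumulative prevalence of disease: band label -> (lo, hi, K).
DEFAULT_SCHEDULE = {"65-74": 0.03, "75-84": 0.17, "85+": 0.32}

# APOE SNP stand-ins (GRCh38 coordinates, inside the excluded region).
APOE_E4_SNP = ("rs429358", "19", 44_908_684)
APOE_E2_SNP = ("rs7412", "19", 44_908_822)


def parse_schedule(schedule: dict[str, float]) -> list[tuple[float, float, float]]:
    """Turn a band-label -> prevalence mapping into (lo, hi, K) triples.

    Labels are ``"lo-hi"`` or ``"lo+"``; an open last band closes at 95
    (the maximum censoring age).  Prevalences must be strictly increasing
    and in (0, 1).
    """
    bands = []
    for label, K in schedule.items():
        if label.endswith("+"):
            lo, hi = float(label[:-1]), 95.0
        else:
            a, b = label.split("-")
            lo, hi = float(a), float(b) + 1.0  # "65-74" covers [65, 75)
        bands.append((lo, hi, float(K)))
    bands.sort()
    ks = [k for _, _, k in bands]
    if not all(0 < k < 1 for k in ks) or any(
        b <= a for a, b in zip(ks, ks[1:])
    ):
        raise ValueError(
            "prevalence schedule must be strictly increasing within (0,1)"
        )
    return bands


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the target study conditions: a PRS explaining 6.8%
    of liability variance (12% jointly with the APOE-like locus), age-band
    prevalences 3/17/32%, 666 multiplex families plus 846 unrelated cases.
    """

    n_families: int = 666
    n_unrelated: int = 846
    sibship_size_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.35, 3: 0.30, 4: 0.20, 5: 0.10, 6: 0.05}
    )
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    r2_prs: float = 0.068
    r2_apoe: float = 0.052
    r2_familial: float = 0.0
    apoe_e4_freq: float = 0.15
    apoe_e2_freq: float = 0.08
    prevalence_schedule: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCHEDULE)
    )
    ascertainment: bool = True
    mode: str = "snp"  # "snp" | "infinitesimal"
    include_parents: bool = False
    ld_block_size: int = 10
    ld_latent_corr: float = 0.7
    causal_fraction: float = 0.3
    gwas_n: int = 100_000
    censor_range: tuple[float, float] = (65.0, 95.0)
    n_pcs: int = 3
    seed: int = 0

    def validate(self) -> None:
        total = self.r2_prs + self.r2_apoe + self.r2_familial
        if total >= 1.0:
            raise ValueError(
                f"liability variance budget exceeds 1 (got {total})"
            )
        if any(v < 0 for v in (self.r2_prs, self.r2_apoe, self.r2_familial)):
            raise ValueError("variance fractions must be non-negative")
        if not (
            0 < self.apoe_e4_freq < 1
            and 0 < self.apoe_e2_freq < 1
            and self.apoe_e4_freq + self.apoe_e2_freq < 1
        ):
            raise ValueError("APOE allele frequencies invalid")
        lo, hi = self.maf_range
        if not 0 < lo < hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if abs(sum(self.sibship_size_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("sibship size distribution must sum to 1")
        if self.mode not in ("snp", "infinitesimal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        parse_schedule(self.prevalence_schedule)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class GenotypePanel:
    """SNP metadata plus an individuals x SNPs dosage matrix in [0, 2].

    ``snps`` columns: snp, chrom, pos, a1 (effect/counted allele), a2, maf,
    block, true_beta (per-dosage liability effect; 0 for non-causal SNPs).
    """

    snps: pd.DataFrame
    dosages: np.ndarray
    iids: np.ndarray

    def dosage_of(self, snp_id: str) -> np.ndarray:
        j = int(np.flatnonzero(self.snps["snp"].to_numpy() == snp_id)[0])
        return self.dosages[:, j]


# ---------------------------------------------------------------------------
# onset model


def assign_onset(
    liability: np.ndarray,
    schedule: dict[str, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Lifetime affection and onset age from liability.

    An individual becomes affected by band b iff liability exceeds
    T(b) = probit(1 - K(b)); the onset age is uniform within the first band
    whose threshold the liability exceeds.  Returns ``(affected, onset_age)``
    with onset NaN for never-affected individuals.
    """
    liability = np.asarray(liability, dtype=float)
    bands = parse_schedule(schedule)
    affected = np.zeros(liability.shape, dtype=bool)
    onset = np.full(liability.shape, np.nan)
    jitter = rng.uniform(size=liability.shape)
    for lo, hi, K in bands:  # increasing K => decreasing threshold
        T = stats.norm.ppf(1.0 - K)
        newly = (liability > T) & ~affected
        onset[newly] = lo + jitter[newly] * (hi - lo)
        affected |= newly
    return affected, onset


# ---------------------------------------------------------------------------
# genotype machinery (snp mode)


def _snp_metadata(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_snps
    n_blocks = int(np.ceil(n / cfg.ld_block_size))
    block = np.repeat(np.arange(n_blocks), cfg.ld_block_size)[:n]
    # blocks tile chromosomes 1..22; 50 kb spacing within a chromosome
    chrom_of_block = (np.arange(n_blocks) % 22) + 1
    chrom = chrom_of_block[block]
    pos = np.zeros(n, dtype=np.int64)
    for c in range(1, 23):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = 1_000_000 + 50_000 * np.arange(idx.size)
    maf = rng.uniform(*cfg.maf_range, size=n)
    alleles = np.array(["A", "C", "G", "T"])
    a_idx = rng.integers(0, 4, size=n)
    a1 = alleles[a_idx]
    a2 = alleles[(a_idx + 1 + rng.integers(0, 3, size=n)) % 4]
    return pd.DataFrame(
        {
            "snp": [f"rs{100000 + i}" for i in range(n)],
            "chrom": chrom.astype(str),
            "pos": pos,
            "a1": a1,
            "a2": a2,
            "maf": maf,
            "block": block,
        }
    )


def _draw_haplotypes(
    n_hap: int, snps: pd.DataFrame, latent_corr: float, rng: np.random.Generator
) -> np.ndarray:
    """Haplotype alleles (n_hap x n_snps, 0/1) with exchangeable within-block
    LD via a shared latent Gaussian factor per block."""
    n_snps = len(snps)
    out = np.empty((n_hap, n_snps), dtype=np.int8)
    thr = stats.norm.ppf(snps["maf"].to_numpy())
    blocks = snps["block"].to_numpy()
    c = np.sqrt(latent_corr)
    s = np.sqrt(1.0 - latent_corr)
    for b in np.unique(blocks):
        cols = np.flatnonzero(blocks == b)
        u = rng.standard_normal((n_hap, 1))
        z = c * u + s * rng.standard_normal((n_hap, cols.size))
        out[:, cols] = (z < thr[cols]).astype(np.int8)
    return out


def _transmit(
    parent_haps: np.ndarray,  # (n_fam, 2, n_snps)
    fam_idx: np.ndarray,  # (n_children,)
    blocks: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One transmitted haplotype per child: an independent uniform choice of
    the parental haplotype per LD block (recombination between blocks only)."""
    n_children = fam_idx.size
    n_snps = parent_haps.shape[2]
    out = np.empty((n_children, n_snps), dtype=np.int8)
    uniq = np.unique(blocks)
    choice = rng.integers(0, 2, size=(n_children, uniq.size))
    for k, b in enumerate(uniq):
        cols = np.flatnonzero(blocks == b)
        out[:, cols] = parent_haps[fam_idx[:, None], choice[:, k, None], cols]
    return out


def _apoe_children(
    pat: np.ndarray, mat: np.ndarray, fam_idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Child APOE alleles: one random allele from each parent. Parent arrays
    are (n_fam, 2) allele codes in {2, 3, 4}."""
    n = fam_idx.size
    a = pat[fam_idx, rng.integers(0, 2, size=n)]
    b = mat[fam_idx, rng.integers(0, 2, size=n)]
    return np.stack([a, b], axis=1)


def _apoe_draw(n: int, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    p = [cfg.apoe_e2_freq, 1 - cfg.apoe_e2_freq - cfg.apoe_e4_freq, cfg.apoe_e4_freq]
    return rng.choice([2, 3, 4], size=(n, 2), p=p)


def _scale_to_variance(x: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
    """Center and rescale so the sample variance equals ``target_var``."""
    x = x - x.mean()
    sd = x.std()
    if sd == 0 or target_var == 0:
        return np.zeros_like(x), 0.0
    f = np.sqrt(target_var) / sd
    return x * f, f


# ---------------------------------------------------------------------------
# main generator


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GenotypePanel | None]:
    """Simulate a family cohort; returns (cohort table, genotype panel).

    The cohort table has one row per phenotyped individual with columns
    fid, iid, father, mother, role, sex, apoe, e4, e2, liability components
    (g_prs, g_apoe, g_fam, env, liability), lifetime and observed affection,
    onset/exam ages, the analysis age (onset if affected else censoring
    age), and simulated principal components pc1..pc_k.

    In ``"infinitesimal"`` mode no genotype panel is produced and ``g_prs``
    comes from exact Gaussian mid-parent segregation (marginal N(0, r2_prs),
    sibling correlation exactly 0.5 in expectation).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ss = rng.spawn(8)
    (rng_fam, rng_geno, rng_apoe, rng_liab, rng_onset, rng_age, rng_pc, _) = ss

    sizes_support = np.array(sorted(config.sibship_size_distribution))
    probs = np.array(
        [config.sibship_size_distribution[k] for k in sizes_support], float
    )
    sib_sizes = rng_fam.choice(sizes_support, size=config.n_families, p=probs)
    n_sibs = int(sib_sizes.sum())
    fam_idx = np.repeat(np.arange(config.n_families), sib_sizes)

    n_unrel = config.n_unrelated
    n_parents = 2 * config.n_families if config.include_parents else 0

    # --- APOE major locus (always an explicit Mendelian locus)
    pat_apoe = _apoe_draw(config.n_families, config, rng_apoe)
    mat_apoe = _apoe_draw(config.n_families, config, rng_apoe)
    sib_apoe = _apoe_children(pat_apoe, mat_apoe, fam_idx, rng_apoe)
    unrel_apoe = _apoe_draw(n_unrel, config, rng_apoe)
    apoe_alleles = [sib_apoe, unrel_apoe]
    if config.include_parents:
        apoe_alleles.append(np.concatenate([pat_apoe, mat_apoe]))
    apoe_alleles = np.concatenate(apoe_alleles)

    # --- identifiers / pedigree
    fids = [f"F{f:05d}" for f in fam_idx]
    iids = [f"F{f:05d}_S{i}" for f, i in zip(fam_idx, _within_index(fam_idx))]
    fathers = [f"F{f:05d}_P0" for f in fam_idx]
    mothers = [f"F{f:05d}_P1" for f in fam_idx]
    roles = ["sibling"] * n_sibs
    fids += [f"U{i:05d}" for i in range(n_unrel)]
    iids += [f"U{i:05d}_I0" for i in range(n_unrel)]
    fathers += ["0"] * n_unrel
    mothers += ["0"] * n_unrel
    roles += ["unrelated"] * n_unrel
    if config.include_parents:
        for p in range(2):
            fids += [f"F{f:05d}" for f in range(config.n_families)]
            iids += [f"F{f:05d}_P{p}" for f in range(config.n_families)]
            fathers += ["0"] * config.n_families
            mothers += ["0"] * config.n_families
            roles += ["parent"] * config.n_families
    n_total = len(iids)

    # --- polygenic score component
    panel: GenotypePanel | None = None
    if config.mode == "snp":
        snps = _snp_metadata(config, rng_geno)
        pat_haps = np.stack(
            [
                _draw_haplotypes(config.n_families, snps, config.ld_latent_corr, rng_geno)
                for _ in range(2)
            ],
            axis=1,
        )
        mat_haps = np.stack(
            [
                _draw_haplotypes(config.n_families, snps, config.ld_latent_corr, rng_geno)
                for _ in range(2)
            ],
            axis=1,
        )
        blocks = snps["block"].to_numpy()
        sib_dos = (
            _transmit(pat_haps, fam_idx, blocks, rng_geno)
            + _transmit(mat_haps, fam_idx, blocks, rng_geno)
        ).astype(np.float32)
        unrel_dos = (
            _draw_haplotypes(n_unrel, snps, config.ld_latent_corr, rng_geno)
            + _draw_haplotypes(n_unrel, snps, config.ld_latent_corr, rng_geno)
        ).astype(np.float32)
        parts = [sib_dos, unrel_dos]
        if config.include_parents:
            parts.append(pat_haps.sum(axis=1).astype(np.float32))
            parts.append(mat_haps.sum(axis=1).astype(np.float32))
        dosages = np.concatenate(parts, axis=0)

        n_causal = max(1, int(round(config.causal_fraction * config.n_snps)))
        causal = rng_liab.choice(config.n_snps, size=n_causal, replace=False)
        raw_beta = np.zeros(config.n_snps)
        raw_beta[causal] = rng_liab.standard_normal(n_causal)
        centered = dosages - dosages.mean(axis=0, keepdims=True)
        g_raw = centered @ raw_beta
        g_prs, f_scale = _scale_to_variance(g_raw, config.r2_prs)
        snps["true_beta"] = raw_beta * f_scale

        # append the two APOE-coding SNPs (dosages of e4 and e2 alleles)
        d4 = (apoe_alleles == 4).sum(axis=1).astype(np.float32)
        d2 = (apoe_alleles == 2).sum(axis=1).astype(np.float32)
        b4, b2 = _apoe_betas(apoe_alleles, config.r2_apoe)
        apoe_meta = pd.DataFrame(
            {
                "snp": [APOE_E4_SNP[0], APOE_E2_SNP[0]],
                "chrom": [APOE_E4_SNP[1], APOE_E2_SNP[1]],
                "pos": [APOE_E4_SNP[2], APOE_E2_SNP[2]],
                "a1": ["C", "T"],
                "a2": ["T", "C"],
                "maf": [config.apoe_e4_freq, config.apoe_e2_freq],
                "block": [-1, -1],
                "true_beta": [b4, b2],
            }
        )
        snps = pd.concat([snps, apoe_meta], ignore_index=True)
        dosages = np.concatenate([dosages, d4[:, None], d2[:, None]], axis=1)
        panel = GenotypePanel(snps=snps, dosages=dosages, iids=np.array(iids))
    else:
        # infinitesimal: exact Gaussian mid-parent segregation of the score
        sd = np.sqrt(config.r2_prs)
        gp = rng_geno.normal(0, sd, size=config.n_families)
        gm = rng_geno.normal(0, sd, size=config.n_families)
        seg = rng_geno.normal(0, sd / np.sqrt(2), size=n_sibs)
        g_sib = 0.5 * (gp[fam_idx] + gm[fam_idx]) + seg
        g_unrel = rng_geno.normal(0, sd, size=n_unrel)
        parts = [g_sib, g_unrel]
        if config.include_parents:
            parts += [gp, gm]
        g_prs = np.concatenate(parts)
        b4, b2 = _apoe_betas(apoe_alleles, config.r2_apoe)

    # --- APOE liability component
    e4 = (apoe_alleles == 4).sum(axis=1)
    e2 = (apoe_alleles == 2).sum(axis=1)
    g_apoe_raw = b4 * e4 + b2 * e2
    g_apoe = g_apoe_raw - g_apoe_raw.mean() if config.r2_apoe > 0 else np.zeros(n_total)

    # --- shared familial residual
    if config.r2_familial > 0:
        sdf = np.sqrt(config.r2_familial)
        fp = rng_liab.normal(0, sdf, size=config.n_families)
        fm = rng_liab.normal(0, sdf, size=config.n_families)
        fam_sib = 0.5 * (fp[fam_idx] + fm[fam_idx]) + rng_liab.normal(
            0, sdf / np.sqrt(2), size=n_sibs
        )
        parts = [fam_sib, rng_liab.normal(0, sdf, size=n_unrel)]
        if config.include_parents:
            parts += [fp, fm]
        g_fam = np.concatenate(parts)
    else:
        g_fam = np.zeros(n_total)

    env_var = 1.0 - config.r2_prs - config.r2_apoe - config.r2_familial
    env = rng_liab.normal(0, np.sqrt(env_var), size=n_total)
    liability = g_prs + g_apoe + g_fam + env

    # --- onset and observation
    affected_life, onset = assign_onset(
        liability, config.prevalence_schedule, rng_onset
    )
    exam = rng_age.uniform(*config.censor_range, size=n_total)
    if config.include_parents:
        is_parent = np.array(roles) == "parent"
        exam[is_parent] = rng_age.uniform(75, 100, size=is_parent.sum())
    affected = affected_life & (onset <= exam)
    age = np.where(affected, onset, exam)

    pcs = rng_pc.standard_normal((n_total, config.n_pcs))
    cohort = pd.DataFrame(
        {
            "fid": fids,
            "iid": iids,
            "father": fathers,
            "mother": mothers,
            "role": roles,
            "sex": rng_age.integers(1, 3, size=n_total),
            "apoe": [
                "".join(str(a) for a in sorted(pair)) for pair in apoe_alleles
            ],
            "e4": e4,
            "e2": e2,
            "g_prs": g_prs,
            "g_apoe": g_apoe,
            "g_fam": g_fam,
            "env": env,
            "liability": liability,
            "affected_lifetime": affected_life,
            "onset_age": onset,
            "exam_age": exam,
            "affected": affected,
            "age": age,
        }
    )
    for k in range(config.n_pcs):
        cohort[f"pc{k + 1}"] = pcs[:, k]
    return cohort, panel


def _within_index(fam_idx: np.ndarray) -> np.ndarray:
    out = np.zeros_like(fam_idx)
    counts: dict[int, int] = {}
    for i, f in enumerate(fam_idx):
        counts[f] = counts.get(f, 0) + 1
        out[i] = counts[f] - 1
    return out


def _apoe_betas(apoe_alleles: np.ndarray, r2_apoe: float) -> tuple[float, float]:
    """Per-allele liability effects of e4 (risk) and e2 (protective, at
    -0.45x the e4 effect) scaled so the locus explains ``r2_apoe``."""
    if r2_apoe == 0:
        return 0.0, 0.0
    e4 = (apoe_alleles == 4).sum(axis=1)
    e2 = (apoe_alleles == 2).sum(axis=1)
    raw = e4 - 0.45 * e2
    sd = raw.std()
    if sd == 0:
        return 0.0, 0.0
    f = np.sqrt(r2_apoe) / sd
    return f, -0.45 * f


# ---------------------------------------------------------------------------
# ascertainment


def ascertain_families(cohort: pd.DataFrame) -> pd.DataFrame:
    """Apply the multiplex ascertainment rule.

    Retains families with at least one affected member with onset after age
    60 and at least one additional affected sibling (i.e. >= 2 affected
    siblings, proband onset > 60).  Unrelated affected singletons are kept
    and flagged via the ``singleton_case`` column rather than dropped;
    unaffected singletons are removed.
    """
    df = cohort
    is_sib = df["role"] == "sibling"
    aff60 = df["affected"] & (df["onset_age"] > 60)
    per_fam = (
        df.loc[is_sib]
        .assign(aff60=aff60[is_sib], aff=df.loc[is_sib, "affected"])
        .groupby("fid")
        .agg(n_aff60=("aff60", "sum"), n_aff=("aff", "sum"))
    )
    keep_fams = per_fam.index[(per_fam["n_aff60"] >= 1) & (per_fam["n_aff"] >= 2)]
    in_kept_family = df["fid"].isin(keep_fams) & (df["role"] != "unrelated")
    singleton_case = (df["role"] == "unrelated") & df["affected"]
    out = df.loc[in_kept_family | singleton_case].copy()
    out["singleton_case"] = singleton_case.loc[out.index]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# summary statistics


def generate_summary_stats(
    panel: GenotypePanel,
    true_effects: np.ndarray | None = None,
    *,
    gwas_n: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy per-SNP association statistics standing in for a base GWAS.

    ``beta = true_beta + N(0, se^2)`` with ``se = 1/sqrt(2 n maf (1-maf))``
    and two-sided normal p-values, so null SNPs give uniform p-values and
    strong effects give sign-consistent estimates.  Columns: SNP CHR BP A1
    A2 BETA SE P MAF.
    """
    snps = panel.snps
    if true_effects is None:
        true_effects = snps["true_beta"].to_numpy()
    true_effects = np.asarray(true_effects, dtype=float)
    if true_effects.shape[0] != len(snps):
        raise ValueError("true_effects misaligned with panel SNP set")
    rng = np.random.default_rng(seed)
    maf = snps["maf"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * gwas_n * maf * (1.0 - maf))
    beta = true_effects + rng.normal(0.0, se)
    z = beta / se
    with np.errstate(over="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "SNP": snps["snp"],
            "CHR": snps["chrom"],
            "BP": snps["pos"],
            "A1": snps["a1"],
            "A2": snps["a2"],
            "BETA": beta,
            "SE": se,
            "P": p,
            "MAF": maf,
        }
    )
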