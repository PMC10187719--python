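"""End-to-end orchestration: simulate -> score -> pair -> analyze -> report.

``run_pipeline`` executes the full synthetic analysis under one master seed
and writes the report tables — association with model-based recurrence,
stratum penetrance, discordant-sib-pair statistics, age-band analytic
recurrence, and empirical sibling recurrence — plus a manifest with a
checksum for every emitted file.  A recurrence-only run skips simulation
entirely and emits just the analytic tables.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cumrisk, io, penetrance, recurrence, scoring, sibpairs
from .simulate import (
    DEFAULT_SCHEDULE,
    SimulationConfig,
    ascertain_families,
    generate_summary_stats,
    simulate_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "attach_scores", "STRATUM_RULES"]


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    clump: scoring.ClumpParams = field(default_factory=scoring.ClumpParams)
    n_rep: int = 100
    n_perm: int = 1000
    n_boot: int = 200
    compare_ages: tuple[float, ...] = (65, 70, 75, 80, 85)
    prevalence_overall: float = 0.13
    recurrence_percentiles: tuple[float, ...] = (0.99, 0.95, 0.90, 0.80)
    run_simulation: bool = True
    run_cumrisk: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**_tupled(raw.pop("simulation", {})))
        cl = scoring.ClumpParams(**raw.pop("clump", {}))
        raw = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        }
        return cls(simulation=sim, clump=cl, **raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, default_flow_style=False)


def _tupled(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if k == "sibship_size_distribution" and isinstance(v, dict):
            out[k] = {int(a): float(b) for a, b in v.items()}
        elif isinstance(v, list):
            out[k] = tuple(v)
        else:
            out[k] = v
    return out


# the stratum grid of the penetrance report
def STRATUM_RULES(scope: str) -> list[penetrance.StratumRule]:
    R = penetrance.StratumRule
    rules = [
        R(None, "carrier", scope, "APOE e4 allele"),
        R(None, "noncarrier", scope, "Non-APOE e4 allele"),
    ]
    for col, top, bottom in (("quintile", 5, 1), ("decile", 10, 1)):
        rules += [
            R((col, top), "any", scope, f"PRS in highest {col}"),
            R((col, bottom), "any", scope, f"PRS in lowest {col}"),
            R((col, top), "carrier", scope, f"APOE e4 carriers, highest {col}"),
            R((col, bottom), "carrier", scope, f"APOE e4 carriers, lowest {col}"),
            R((col, top), "noncarrier", scope, f"APOE e4 non-carriers, highest {col}"),
            R((col, bottom), "noncarrier", scope, f"APOE e4 non-carriers, lowest {col}"),
        ]
    return rules


def attach_scores(
    cohort: pd.DataFrame, result: scoring.PRSResult
) -> pd.DataFrame:
    """Merge a scoring result into a cohort table and add cohort-wide
    quintile/decile bins and percentile ranks of the standardized PRS."""
    frame = result.frame().set_index("IID")
    out = cohort.copy()
    out["prs"] = frame["PRS_STD"].reindex(out["iid"]).to_numpy()
    if "PRS_AD" in frame.columns:
        out["prs_ad"] = frame["PRS_AD"].reindex(out["iid"]).to_numpy()
    keep = out["prs"].notna()
    q, _ = scoring.bin_quantiles(
        out.loc[keep, "prs"].to_numpy(), 5, out.loc[keep, "iid"].to_numpy()
    )
    d, pct = scoring.bin_quantiles(
        out.loc[keep, "prs"].to_numpy(), 10, out.loc[keep, "iid"].to_numpy()
    )
    out.loc[keep, "quintile"] = q
    out.loc[keep, "decile"] = d
    out.loc[keep, "pctile"] = pct
    return out


def _discordant_strata() -> list[tuple[str, penetrance.StratumRule | None]]:
    R = penetrance.StratumRule
    return [
        ("Overall", None),
        ("PRS in highest quintile", R(("quintile", 5))),
        ("PRS in lowest quintile", R(("quintile", 1))),
        ("APOE e4 carriers and highest quintile", R(("quintile", 5), "carrier")),
        ("APOE e4 carriers and lowest quintile", R(("quintile", 1), "carrier")),
        ("APOE e4 non-carriers and highest quintile", R(("quintile", 5), "noncarrier")),
        ("APOE e4 non-carriers and lowest quintile", R(("quintile", 1), "noncarrier")),
        ("PRS in highest decile", R(("decile", 10))),
        ("PRS in lowest decile", R(("decile", 1))),
        ("APOE e4 carriers and highest decile", R(("decile", 10), "carrier")),
        ("APOE e4 carriers and lowest decile", R(("decile", 1), "carrier")),
        ("APOE e4 non-carriers and highest decile", R(("decile", 10), "noncarrier")),
        ("APOE e4 non-carriers and lowest decile", R(("decile", 1), "noncarrier")),
    ]


def run_pipeline(config: RunConfig, out_dir: str) -> dict:
    """Execute all configured stages; returns the manifest dict.

    Every output is a TSV/JSON under ``out_dir``; the manifest lists each
    file with its SHA-256 so reruns can be compared byte-for-byte.
    """
    os.makedirs(out_dir, exist_ok=True)
    files: dict[str, str] = {}
    manifest: dict = {"stages": [], "seed": config.simulation.seed}

    # ---- analytic recurrence tables (no simulation needed)
    r2_prs = config.simulation.r2_prs
    r2_ad = config.simulation.r2_prs + config.simulation.r2_apoe
    t6 = recurrence.recurrence_table(
        dict(config.simulation.prevalence_schedule),
        {"PRS": r2_prs, "PRS.AD": r2_ad},
        config.recurrence_percentiles,
    )
    files["recurrence_by_age"] = _write(t6, out_dir, "recurrence_by_age.tsv")
    manifest["stages"].append("recurrence_analytic")

    if not config.run_simulation:
        manifest["files"] = _checksums(files)
        _dump(manifest, out_dir)
        return manifest

    # ---- simulate
    try:
        cohort, panel = simulate_cohort(config.simulation)
        stats = (
            generate_summary_stats(
                panel,
                gwas_n=config.simulation.gwas_n,
                seed=config.simulation.seed + 1,
            )
            if panel is not None
            else None
        )
        if config.simulation.ascertainment:
            analysis_cohort = ascertain_families(cohort)
        else:
            analysis_cohort = cohort.copy()
        io.write_cohort(analysis_cohort, None, stats, out_dir)
        files["pedigree"] = os.path.join(out_dir, "cohort.fam.tsv")
        if stats is not None:
            files["sumstats"] = os.path.join(out_dir, "sumstats.tsv")
        manifest["stages"].append("simulate")
    except Exception as err:  # pragma: no cover - stage tagging only
        raise RuntimeError(f"stage 'simulate' failed: {err}") from err

    # ---- score
    try:
        if panel is not None:
            covs = None  # PCs are per-individual cohort columns
            result = scoring.score_pipeline(panel, stats, covs, config.clump)
            analysis_cohort = attach_scores(analysis_cohort, result)
            files["scores"] = _write(
                result.frame(), out_dir, "prs_scores.tsv"
            )
        else:
            analysis_cohort = analysis_cohort.copy()
            analysis_cohort["prs"] = scoring.standardize(
                analysis_cohort["g_prs"].to_numpy()
            )
            q, _ = scoring.bin_quantiles(
                analysis_cohort["prs"].to_numpy(), 5, analysis_cohort["iid"].to_numpy()
            )
            d, pct = scoring.bin_quantiles(
                analysis_cohort["prs"].to_numpy(), 10, analysis_cohort["iid"].to_numpy()
            )
            analysis_cohort["quintile"] = q
            analysis_cohort["decile"] = d
            analysis_cohort["pctile"] = pct
        manifest["stages"].append("score")
    except Exception as err:
        raise RuntimeError(f"stage 'score' failed: {err}") from err

    # ---- association + model-based recurrence
    try:
        rows = []
        specs = [("AD ~ PRS + AGE + SEX + PCs", "prs", "any")]
        if "prs_ad" in analysis_cohort.columns:
            specs.append(("AD ~ PRS.AD + AGE + SEX + PCs", "prs_ad", "any"))
        specs += [
            ("AD ~ PRS + AGE + SEX + PCs within APOE e4 carriers", "prs", "carrier"),
            ("AD ~ PRS + AGE + SEX + PCs within APOE e4 non-carriers", "prs", "noncarrier"),
        ]
        for label, col, apoe in specs:
            fit = penetrance.fit_ad_association(analysis_cohort, col, apoe)
            row = {
                "model": label,
                "OR": fit.odds_ratio,
                "CI_low": fit.ci_low,
                "CI_high": fit.ci_high,
                "R2": fit.r2,
                "n": fit.n,
            }
            for q_ in config.recurrence_percentiles:
                r2c = min(max(fit.r2, 0.0), 0.95)
                row[f"recurrence_p{int(round(q_ * 100))}"] = (
                    recurrence.liability_recurrence(
                        config.prevalence_overall, r2c, q_
                    )
                )
            rows.append(row)
        t2 = pd.DataFrame(rows)
        files["association_recurrence"] = _write(
            t2, out_dir, "association_recurrence.tsv"
        )
        manifest["stages"].append("association")
    except Exception as err:
        raise RuntimeError(f"stage 'association' failed: {err}") from err

    # ---- penetrance strata
    try:
        t4_all = penetrance.stratum_penetrance(
            analysis_cohort, STRATUM_RULES("everyone")
        ).assign(scope="everyone")
        t4_sib = penetrance.stratum_penetrance(
            analysis_cohort, STRATUM_RULES("sibships")
        ).assign(scope="sibships")
        t4 = pd.concat([t4_all, t4_sib], ignore_index=True)
        files["penetrance_strata"] = _write(t4, out_dir, "penetrance_strata.tsv")
        manifest["stages"].append("penetrance")
    except Exception as err:
        raise RuntimeError(f"stage 'penetrance' failed: {err}") from err

    # ---- sibling pairs: discordant statistic + empirical recurrence
    try:
        t5_rows, t7_rows = [], []
        for strategy, sname in (
            ("one_per_family", "one_pair_per_family"),
            ("max_pairs", "max_pairs_per_family"),
        ):
            for label, rule in _discordant_strata():
                summ = sibpairs.replicate_estimate(
                    lambda ps, rule=rule: penetrance.discordant_pair_stat(
                        ps.pairs, rule
                    ),
                    analysis_cohort,
                    strategy=strategy,
                    n_rep=config.n_rep,
                    seed=config.simulation.seed + 11,
                    name=label,
                )
                t5_rows.append(
                    {
                        "stratum": label,
                        "strategy": sname,
                        "mean": summ.mean,
                        "sd": summ.sd,
                        "n_missing_replicates": summ.n_missing,
                    }
                )
            for label, rule_name in (
                ("older affected sibling is APOE e4 carrier", "apoe4_carrier"),
                ("older affected sibling is APOE e4 non-carrier", "apoe4_noncarrier"),
                ("older affected sibling in highest PRS quintile", "prs_top_quintile"),
            ):
                summ = sibpairs.replicate_estimate(
                    lambda ps, r=rule_name: recurrence.empirical_recurrence(
                        ps.pairs, r
                    ),
                    analysis_cohort,
                    strategy=strategy,
                    n_rep=config.n_rep,
                    seed=config.simulation.seed + 13,
                    name=label,
                )
                t7_rows.append(
                    {
                        "proband_rule": label,
                        "strategy": sname,
                        "mean": summ.mean,
                        "sd": summ.sd,
                        "n_missing_replicates": summ.n_missing,
                    }
                )
        files["discordant_pairs"] = _write(
            pd.DataFrame(t5_rows), out_dir, "discordant_pairs.tsv"
        )
        files["empirical_recurrence"] = _write(
            pd.DataFrame(t7_rows), out_dir, "empirical_recurrence.tsv"
        )
        manifest["stages"].append("sibpairs")
    except Exception as err:
        raise RuntimeError(f"stage 'sibpairs' failed: {err}") from err

    # ---- age-specific cumulative penetrance + permutation comparison
    if config.run_cumrisk:
        try:
            top = (analysis_cohort["quintile"] == 5).to_numpy()
            bottom = (analysis_cohort["quintile"] == 1).to_numpy()
            curves = []
            for mask, label in ((top, "PRS_top_quintile"), (bottom, "PRS_bottom_quintile")):
                curve = cumrisk.cumulative_penetrance_curve(
                    analysis_cohort,
                    mask,
                    label=label,
                    n_boot=config.n_boot,
                    seed=config.simulation.seed + 17,
                )
                curves.append(curve.frame())
            files["risk_curves"] = _write(
                pd.concat(curves, ignore_index=True), out_dir, "risk_curves.tsv"
            )
            comp = cumrisk.permutation_test(
                analysis_cohort,
                top,
                bottom,
                ages=config.compare_ages,
                n_perm=config.n_perm,
                seed=config.simulation.seed + 19,
                labels=("PRS_top_quintile", "PRS_bottom_quintile"),
            )
            comp_record = {
                "group_a": comp.group_a,
                "group_b": comp.group_b,
                "ages": list(map(float, comp.ages)),
                "observed_diff": list(map(float, comp.observed_diff)),
                "p_values": list(map(float, comp.p_values)),
                "n_perm": comp.n_perm,
            }
            path = os.path.join(out_dir, "cumrisk_comparison.json")
            with open(path, "w") as fh:
                json.dump(comp_record, fh, indent=1, sort_keys=True)
            files["cumrisk_comparison"] = path
            manifest["stages"].append("cumrisk")
        except Exception as err:
            raise RuntimeError(f"stage 'cumrisk' failed: {err}") from err

    manifest["files"] = _checksums(files)
    _dump(manifest, out_dir)
    return manifest


def _write(df: pd.DataFrame, out_dir: str, name: str) -> str:
    path = os.path.join(out_dir, name)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def _checksums(files: dict[str, str]) -> dict[str, dict]:
    out = {}
    for name, path in files.items():
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            h.update(fh.read())
        out[name] = {"path": os.path.basename(path), "sha256": h.hexdigest()}
    return out


def _dump(manifest: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
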