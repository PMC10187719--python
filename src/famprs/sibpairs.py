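"""Replicate sibling-pair datasets.

Two sampling strategies over the genotyped sibships:

* ``one_per_family`` — one uniformly random sibling pair per eligible
  family;
* ``max_pairs`` — a random perfect matching within each sibship, so a
  sibship of size s contributes floor(s/2) individual-disjoint pairs (five
  siblings give two pairs and one left out).

Replicated pair statistics are reported as mean (sample SD) over
``n_rep`` independently seeded replicates (default 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "SibPairSet",
    "ReplicateSummary",
    "eligible_sibships",
    "sample_one_pair",
    "sample_max_pairs",
    "annotate_pairs",
    "replicate_estimate",
]


@dataclass
class SibPairSet:
    """One replicate of individual-disjoint sibling pairs.

    ``pairs`` columns after annotation: fid, iid_a, iid_b plus per-member
    prs/affected/age/e4 columns and derived older/younger, higher/lower-PRS
    and discordance flags.
    """

    replicate: int
    strategy: str
    pairs: pd.DataFrame
    leftover: list[str]

    def validate_disjoint(self) -> None:
        members = pd.concat([self.pairs["iid_a"], self.pairs["iid_b"]])
        if members.duplicated().any():
            raise AssertionError("pair set is not individual-disjoint")


@dataclass
class ReplicateSummary:
    name: str
    values: np.ndarray  # NaN where the statistic was undefined
    n_replicates: int

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values)) if np.isfinite(self.values).any() else float("nan")

    @property
    def sd(self) -> float:
        vals = self.values[np.isfinite(self.values)]
        return float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")

    @property
    def n_missing(self) -> int:
        return int(np.sum(~np.isfinite(self.values)))


def eligible_sibships(
    cohort: pd.DataFrame, prs_col: str = "prs"
) -> dict[str, list[str]]:
    """Families mapped to their pair-eligible siblings (role sibling,
    non-missing PRS and affection), keeping only sibships of size >= 2."""
    df = cohort
    ok = (
        (df["role"] == "sibling")
        & df[prs_col].notna()
        & df["affected"].notna()
    )
    groups: dict[str, list[str]] = {}
    for fid, sub in df.loc[ok].groupby("fid", sort=True):
        iids = sorted(sub["iid"].tolist())
        if len(iids) >= 2:
            groups[fid] = iids
    return groups


def sample_one_pair(
    cohort: pd.DataFrame, seed, prs_col: str = "prs", replicate: int = 0
) -> SibPairSet:
    """One uniformly random sibling pair per eligible family."""
    rng = np.random.default_rng(seed)
    rows = []
    for fid, sibs in eligible_sibships(cohort, prs_col).items():
        a, b = rng.choice(len(sibs), size=2, replace=False)
        rows.append((fid, sibs[a], sibs[b]))
    pairs = pd.DataFrame(rows, columns=["fid", "iid_a", "iid_b"])
    out = SibPairSet(replicate, "one_per_family", pairs, leftover=[])
    return _finalize(out, cohort, prs_col)


def sample_max_pairs(
    cohort: pd.DataFrame, seed, prs_col: str = "prs", replicate: int = 0
) -> SibPairSet:
    """Random perfect matching per sibship: floor(s/2) pairs, each member
    used at most once; the odd sibling out is recorded."""
    rng = np.random.default_rng(seed)
    rows, leftover = [], []
    for fid, sibs in eligible_sibships(cohort, prs_col).items():
        perm = rng.permutation(len(sibs))
        for k in range(len(sibs) // 2):
            rows.append((fid, sibs[perm[2 * k]], sibs[perm[2 * k + 1]]))
        if len(sibs) % 2:
            leftover.append(sibs[perm[-1]])
    pairs = pd.DataFrame(rows, columns=["fid", "iid_a", "iid_b"])
    out = SibPairSet(replicate, "max_pairs", pairs, leftover=leftover)
    return _finalize(out, cohort, prs_col)


def _finalize(ps: SibPairSet, cohort: pd.DataFrame, prs_col: str) -> SibPairSet:
    ps.pairs = annotate_pairs(ps.pairs, cohort, prs_col)
    ps.validate_disjoint()
    return ps


def annotate_pairs(
    pairs: pd.DataFrame, cohort: pd.DataFrame, prs_col: str = "prs"
) -> pd.DataFrame:
    """Attach member attributes and derived orderings to a raw pair table.

    Adds per-member prs/affected/age/e4 (and quantile-bin columns when
    present in the cohort), ``discordant``, an age ordering (older/younger;
    age ties broken by iid so the ordering is deterministic), and a strict
    PRS ordering (``prs_tie`` marks exact ties).
    """
    if pairs.empty:
        return pairs.assign(
            **{
                c: pd.Series(dtype=float)
                for c in (
                    "prs_a", "prs_b", "affected_a", "affected_b",
                    "discordant", "affected_older", "affected_younger",
                    "e4_older", "top_quintile_older",
                )
            }
        )
    extra = [c for c in ("quintile", "decile", "pctile") if c in cohort.columns]
    look = cohort.set_index("iid")[[prs_col, "affected", "age", "e4"] + extra]
    out = pairs.copy()
    for side in ("a", "b"):
        sub = look.loc[out[f"iid_{side}"]].reset_index(drop=True)
        out[f"prs_{side}"] = sub[prs_col].to_numpy()
        out[f"affected_{side}"] = sub["affected"].to_numpy()
        out[f"age_{side}"] = sub["age"].to_numpy()
        out[f"e4_{side}"] = sub["e4"].to_numpy()
        for c in extra:
            out[f"{c}_{side}"] = sub[c].to_numpy()
    out["discordant"] = out["affected_a"] != out["affected_b"]

    # age ordering; ties broken by iid for determinism
    a_older = np.where(
        out["age_a"] == out["age_b"],
        out["iid_a"] > out["iid_b"],
        out["age_a"] > out["age_b"],
    )
    for attr in ["affected", "e4", "prs"] + extra:
        av = out[f"{attr}_a"].to_numpy()
        bv = out[f"{attr}_b"].to_numpy()
        out[f"{attr}_older"] = np.where(a_older, av, bv)
        out[f"{attr}_younger"] = np.where(a_older, bv, av)
    if "quintile_older" in out.columns:
        out["top_quintile_older"] = out["quintile_older"] == 5
    else:
        out["top_quintile_older"] = out["prs_older"] >= np.nanquantile(
            np.concatenate([out["prs_a"], out["prs_b"]]), 0.8
        )

    # strict PRS ordering
    out["prs_tie"] = out["prs_a"] == out["prs_b"]
    a_higher = out["prs_a"] > out["prs_b"]
    for attr in ["affected", "e4"] + extra:
        av = out[f"{attr}_a"].to_numpy()
        bv = out[f"{attr}_b"].to_numpy()
        out[f"{attr}_higher"] = np.where(a_higher, av, bv)
        out[f"{attr}_lower"] = np.where(a_higher, bv, av)
    return out


def replicate_estimate(
    statistic: Callable[[SibPairSet], float],
    cohort: pd.DataFrame,
    strategy: str = "one_per_family",
    n_rep: int = 100,
    seed: int = 0,
    prs_col: str = "prs",
    name: str = "statistic",
) -> ReplicateSummary:
    """Mean (SD) of a pure pair-set statistic over independently seeded
    replicates; a replicate where the statistic is undefined (NaN) is
    recorded as missing, not dropped silently."""
    sampler = {"one_per_family": sample_one_pair, "max_pairs": sample_max_pairs}[
        strategy
    ]
    child_seeds = np.random.SeedSequence(seed).spawn(n_rep)
    values = np.empty(n_rep)
    for r in range(n_rep):
        ps = sampler(cohort, child_seeds[r], prs_col=prs_col, replicate=r)
        values[r] = statistic(ps)
    return ReplicateSummary(name=name, values=values, n_replicates=n_rep)
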