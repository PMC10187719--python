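"""Liability-threshold sibling recurrence risk.

Under the liability-threshold model, disease occurs when a standard-normal
latent liability L exceeds the threshold T = probit(1 - K) set by the
population prevalence K.  A polygenic score explaining a fraction ``r2`` of
the liability variance contributes a component x ~ N(0, r2) of the proband's
liability; the score correlates ``rho`` between a proband and a relative
(0.5 for full siblings under additive inheritance).

Conditioning on a proband whose score lies above the q-th population
percentile, the relative's liability given the proband's score x is
N(rho * x, 1 - rho^2 * r2) — all remaining (non-score) liability variance is
taken to be independent between the pair.  The recurrence risk is then

    R(K, r2, q, rho) = E_x [ Phi( (rho * x - T) / sqrt(1 - rho^2 * r2) ) ]

with the expectation over x ~ N(0, r2) truncated to x > probit(q) * sqrt(r2),
evaluated by adaptive quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "RecurrenceParams",
    "liability_recurrence",
    "recurrence_table",
    "empirical_recurrence",
]


@dataclass(frozen=True)
class RecurrenceParams:
    """Parameters of the liability-threshold recurrence model.

    Attributes
    ----------
    K : float
        Population (or age-band) disease prevalence, in (0, 1).
    r2 : float
        Fraction of liability variance explained by the score, in [0, 1).
    q : float
        Proband score percentile threshold, in (0, 1); e.g. 0.80 for the
        top quintile.
    rho : float
        Score correlation between proband and relative; 0.5 for full
        siblings.
    """

    K: float
    r2: float
    q: float
    rho: float = 0.5

    @property
    def threshold(self) -> float:
        """Liability threshold T = probit(1 - K); recomputed on access."""
        return float(stats.norm.ppf(1.0 - self.K))

    def validate(self) -> None:
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"prevalence K must be in (0,1), got {self.K}")
        if not 0.0 <= self.r2 < 1.0:
            raise ValueError(f"r2 must be in [0,1), got {self.r2}")
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"percentile q must be in (0,1), got {self.q}")
        if self.rho**2 * self.r2 >= 1.0:
            raise ValueError("rho^2 * r2 must be < 1")


def liability_recurrence(
    K: float, r2: float, q: float, rho: float = 0.5, *, abs_tol: float = 1e-9
) -> float:
    """Recurrence risk for a relative of a proband with a high score.

    Probability that a relative (score correlation ``rho``) of a proband
    whose polygenic score exceeds the population ``q`` percentile is
    affected, for prevalence ``K`` and score liability variance ``r2``.

    Returns the risk as a proportion in (0, 1).  With ``r2 == 0`` or
    ``rho == 0`` the score is uninformative and the risk equals ``K``.
    """
    params = RecurrenceParams(K=K, r2=r2, q=q, rho=rho)
    params.validate()
    if r2 == 0.0 or rho == 0.0:
        return float(K)

    T = params.threshold
    sd_x = np.sqrt(r2)
    lower = stats.norm.ppf(q) * sd_x
    resid_sd = np.sqrt(1.0 - rho**2 * r2)

    def integrand(x: float) -> float:
        return stats.norm.pdf(x, scale=sd_x) * stats.norm.cdf(
            (rho * x - T) / resid_sd
        )

    num, _ = integrate.quad(integrand, lower, np.inf, epsabs=abs_tol)
    # mass of the truncated proband distribution is exactly 1 - q
    return float(num / (1.0 - q))


def recurrence_table(
    prevalences: dict[str, float],
    r2_values: dict[str, float],
    percentiles: tuple[float, ...] = (0.99, 0.95, 0.90, 0.80),
    rho: float = 0.5,
) -> pd.DataFrame:
    """Grid of recurrence risks over prevalence bands, scores and percentiles.

    Parameters
    ----------
    prevalences : dict
        Row-band labels mapped to prevalence, e.g.
        ``{"65-74": 0.03, "75-84": 0.17, "85+": 0.32}`` or
        ``{"overall": 0.13}``.
    r2_values : dict
        Score labels mapped to liability variance explained, e.g.
        ``{"PRS": 0.068, "PRS.AD": 0.12}``.
    percentiles : tuple
        Proband percentile thresholds (column order preserved).

    Returns a long-to-wide table with one row per (band, score) and one
    column per percentile, risks as proportions.
    """
    rows = []
    for band, K in prevalences.items():
        for label, r2 in r2_values.items():
            row: dict[str, object] = {
                "age_band": band,
                "prevalence": K,
                "score": label,
                "r2": r2,
            }
            for q in percentiles:
                row[f"p{int(round(q * 100))}"] = liability_recurrence(
                    K, r2, q, rho
                )
            rows.append(row)
    return pd.DataFrame(rows)


def empirical_recurrence(pairs: pd.DataFrame, proband_rule: str) -> float:
    """Observed sibling recurrence given an affected high-risk older sibling.

    Among annotated sibling pairs whose *older* member is affected and
    satisfies ``proband_rule``, returns the fraction of younger siblings who
    are also affected.  ``pairs`` is an annotated pair table from
    :mod:`famprs.sibpairs` (columns ``affected_older``, ``affected_younger``,
    ``e4_older``, ``top_quintile_older``).

    proband_rule : one of ``"apoe4_carrier"``, ``"apoe4_noncarrier"``,
        ``"prs_top_quintile"``.

    Returns NaN when no pair qualifies.
    """
    aff_older = pairs["affected_older"].to_numpy(dtype=bool)
    if proband_rule == "apoe4_carrier":
        sel = aff_older & (pairs["e4_older"].to_numpy() > 0)
    elif proband_rule == "apoe4_noncarrier":
        sel = aff_older & (pairs["e4_older"].to_numpy() == 0)
    elif proband_rule == "prs_top_quintile":
        sel = aff_older & pairs["top_quintile_older"].to_numpy(dtype=bool)
    else:
        raise ValueError(f"unknown proband rule: {proband_rule!r}")
    if not sel.any():
        return float("nan")
    return float(pairs.loc[sel, "affected_younger"].mean())
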