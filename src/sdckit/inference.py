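"""Rank tests for breeding status and randomization tests of assortative mating.

Breeding-status comparison: a two-sided Wilcoxon-Mann-Whitney test on SDC
between confirmed breeders and non-breeders (the W statistic follows the R
convention, i.e. the Mann-Whitney U of the first sample), plus per-group
mean +/- SE summaries.

Assortative mating: the observed mean absolute within-pair difference of an
attribute (age, or age-predicted SDC) is located within its null distribution
under random re-pairing of the observed males and females.  The null interval
is the (2.5th, 97.5th) percentile band of the simulated means; the verdict is
where the observed mean falls relative to that band.  "outside-low" (observed
difference smaller than random) indicates homogamy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .multimodel import ScalingRecord, predict_response

__all__ = [
    "TestResult",
    "RandomizationResult",
    "EXACT_THRESHOLD",
    "wmw_test",
    "signed_rank_test",
    "breeding_comparison",
    "mean_abs_pair_diff",
    "random_pairing_null",
    "predicted_sdc_for_pairs",
]

#: Largest min(n) for which the exact (enumeration) p-value path is used.
EXACT_THRESHOLD = 12


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    statistic: float
    pvalue: float
    method: str                 # "exact" | "normal-approx"
    sidedness: str = "two-sided"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 or math.isnan(self.pvalue)):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class RandomizationResult:
    attribute: str
    observed: float             # observed mean absolute within-pair difference
    null_draws: np.ndarray
    ci: tuple[float, float]     # 2.5th / 97.5th percentiles of the null
    verdict: str                # "inside" | "outside-low" | "outside-high"
    n_sim: int
    seed: int | None


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def wmw_test(
    x: Sequence[float], y: Sequence[float], sides: str = "two-sided"
) -> TestResult:
    """Wilcoxon-Mann-Whitney rank-sum test.

    W is the Mann-Whitney U statistic of ``x`` (rank sum of x minus its
    minimum, midranks for ties).  The exact distribution is used when both
    samples are tie-free and min(n) <= 12; otherwise the normal approximation
    with tie-corrected variance and no continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult("W", x.size * y.size / 2.0, 1.0, "normal-approx", sides, True)
    exact = not _has_ties(pooled) and min(x.size, y.size) <= EXACT_THRESHOLD
    res = stats.mannwhitneyu(
        x, y,
        alternative=sides,
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return TestResult(
        "W", float(res.statistic), float(res.pvalue),
        "exact" if exact else "normal-approx", sides,
    )


def signed_rank_test(differences: Sequence[float], sides: str = "two-sided") -> TestResult:
    """Wilcoxon matched-pairs signed-rank test on paired differences.

    Zero differences are dropped; W is the sum of the midranks of |d| over
    positive differences (R's V).  Exact enumeration when the nonzero |d| are
    tie-free and n <= 12, else normal approximation without continuity
    correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return TestResult("W", 0.0, 1.0, "normal-approx", sides, True)
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    exact = not _has_ties(np.abs(d)) and d.size <= EXACT_THRESHOLD
    alternative = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[sides]
    res = stats.wilcoxon(
        d,
        alternative=alternative,
        method="exact" if exact else "approx",
        correction=False,
        zero_method="wilcox",
    )
    return TestResult("W", w_pos, float(res.pvalue), "exact" if exact else "normal-approx", sides)


def breeding_comparison(
    scores: pd.DataFrame, status: pd.DataFrame, value: str = "sdc"
) -> tuple[TestResult, pd.DataFrame]:
    """Compare SDC between breeders and non-breeders.

    ``scores`` must carry columns id and ``value``; ``status`` columns id and
    breeder (0/1 or bool).  Returns the two-sided WMW result (breeders as the
    first sample) and a per-group mean +/- SE table.
    """
    merged = scores[["id", value]].merge(
        status[["id", "breeder"]].assign(breeder=lambda d: d["breeder"].astype(int)),
        on="id",
    )
    groups = {b: g[value].to_numpy(dtype=float) for b, g in merged.groupby("breeder")}
    if set(groups) != {0, 1}:
        raise ValueError("both breeder and non-breeder groups must be non-empty")
    result = wmw_test(groups[1], groups[0])
    summary = (
        merged.groupby("breeder")[value]
        .agg(n="size", mean="mean", se=lambda v: v.std(ddof=1) / math.sqrt(len(v)))
        .reset_index()
    )
    return result, summary


def mean_abs_pair_diff(pairs: pd.DataFrame, attribute: str) -> float:
    """Mean absolute male-female difference of ``attribute`` across pairs.

    ``pairs`` columns: ``male_<attribute>`` and ``female_<attribute>``.
    """
    if len(pairs) == 0:
        raise ValueError("empty pair list")
    m = pairs[f"male_{attribute}"].to_numpy(dtype=float)
    f = pairs[f"female_{attribute}"].to_numpy(dtype=float)
    if np.isnan(m).any() or np.isnan(f).any():
        raise ValueError(f"missing {attribute} values in pairs")
    return float(np.mean(np.abs(m - f)))


def random_pairing_null(
    pairs: pd.DataFrame,
    attribute: str,
    n_sim: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    permute: str = "female",
) -> RandomizationResult:
    """Randomization test of assortative mating for one attribute.

    Each simulation permutes one sex's attribute vector against the other
    (re-pairing within the observed members; the identity permutation is
    allowed) and records the mean absolute within-pair difference.  The null
    interval is the (2.5th, 97.5th) percentile band (linear interpolation)
    of the ``n_sim`` simulated means; the verdict compares the observed mean
    to the band.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    if n_sim < 100:
        warnings.warn("n_sim < 100: percentile bounds will be unstable", stacklevel=2)
    if rng is None:
        rng = np.random.default_rng(seed)
    m = pairs[f"male_{attribute}"].to_numpy(dtype=float)
    f = pairs[f"female_{attribute}"].to_numpy(dtype=float)
    fixed, shuffled = (m, f) if permute == "female" else (f, m)
    observed = float(np.mean(np.abs(m - f)))
    perms = rng.permuted(np.tile(shuffled, (n_sim, 1)), axis=1)
    draws = np.abs(perms - fixed[None, :]).mean(axis=1)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    if observed < lo:
        verdict = "outside-low"
    elif observed > hi:
        verdict = "outside-high"
    else:
        verdict = "inside"
    return RandomizationResult(
        attribute=attribute, observed=observed, null_draws=draws,
        ci=(float(lo), float(hi)), verdict=verdict, n_sim=n_sim, seed=seed,
    )


def predicted_sdc_for_pairs(
    pairs: pd.DataFrame,
    coefficients: Mapping[str, float],
    scaling: ScalingRecord,
    fixed_date: float = 94.0,
) -> pd.DataFrame:
    """Attach age-predicted SDC to both members of every pair.

    SDC is predicted purely from age through the fitted display model
    (typically the best model, age + age^2 + date) with the date fixed for
    everyone (day 94 = February 3 by default), so the attached score is a
    pure function of age.  Returns a copy of ``pairs`` with ``male_sdc`` and
    ``female_sdc`` columns, ready for :func:`random_pairing_null`.
    """
    out = pairs.copy()
    for side in ("male", "female"):
        ages = out[f"{side}_age"]
        if ages.isna().any():
            raise ValueError(f"missing {side} ages")
        pred = predict_response(coefficients, scaling, ages.to_numpy(dtype=float),
                                fixed_date=fixed_date)
        out[f"{side}_sdc"] = pred["prediction"].to_numpy()
    return out
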