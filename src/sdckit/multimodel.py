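"""AICc-based multimodel inference with zero-method model averaging.

The modelling workflow this module implements is the standard
information-theoretic one for observational behavioral data:

1. standardize every predictor by centering and dividing by **two** standard
   deviations (Gelman's rule), so slopes of numeric and binary predictors are
   directly comparable;
2. generate all hierarchical subsets of a full model, dropping any subset
   that contains a forbidden collinear pair (by default group size and date,
   which covary over a courtship season);
3. fit each candidate by maximum likelihood (gaussian identity or binomial
   logit), rank by AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1);
4. renormalize Akaike weights over the top set (dAICc <= 2) and average
   coefficients with the *zero method* (full average): a term absent from a
   model contributes a coefficient of 0, so averaged effects shrink toward
   zero in proportion to selection uncertainty.

Parameter counting follows the convention that reproduces R's logLik/df:
a gaussian model with p slope terms has k = p + 2 (intercept and residual
variance); a binomial model has k = p + 1.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ethogram import SEX_CODES

__all__ = [
    "ScalingRecord",
    "CandidateModel",
    "TopModelSet",
    "DISPLAY_TERMS",
    "BREEDING_TERMS",
    "standardize",
    "build_predictor_table",
    "generate_model_set",
    "design_matrix",
    "fit_glm",
    "aicc",
    "akaike_weights",
    "rank_models",
    "model_average_zero",
    "selection_table",
    "predict_response",
]

log = logging.getLogger(__name__)

#: Full fixed-effect term list for the display responses (SDC, richness,
#: versatility).  ``age2`` is the quadratic age term; ``:`` marks an
#: interaction of standardized main effects.
DISPLAY_TERMS = (
    "age", "age2", "sex", "group_size", "hour", "date", "year", "age:sex", "date:year",
)

#: Full term list for the breeding-status (binomial) response.
BREEDING_TERMS = ("sdc", "sex", "age", "age2")

#: Collinear pairs excluded from the display model set.
DEFAULT_EXCLUSIONS = (("group_size", "date"),)


# ---------------------------------------------------------------------------
# standardization

@dataclass(frozen=True)
class ScalingRecord:
    """Per-column (mean, sd, min, max) retained for back-transform/prediction."""

    stats: dict[str, tuple[float, float, float, float]]

    def transform_column(self, name: str, values: np.ndarray) -> np.ndarray:
        mean, sd, _, _ = self.stats[name]
        return (np.asarray(values, dtype=float) - mean) / (2.0 * sd)

    def in_fitted_range(self, name: str, values: np.ndarray) -> np.ndarray:
        _, _, lo, hi = self.stats[name]
        v = np.asarray(values, dtype=float)
        return (v >= lo) & (v <= hi)


def standardize(
    table: pd.DataFrame, columns: Sequence[str] | None = None
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Center each column and divide by two (sample) standard deviations.

    After standardization every column has mean 0 and SD 0.5, which puts
    numeric slopes on the same scale as a 0/1 binary contrast.  Binary
    columns are treated by the same rule.  Raises on a constant column.
    """
    columns = list(columns) if columns is not None else list(table.columns)
    out = table.copy()
    stats: dict[str, tuple[float, float, float, float]] = {}
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        if not math.isfinite(sd) or sd == 0.0:
            raise ValueError(f"column {col!r} has zero standard deviation")
        out[col] = (x - mean) / (2.0 * sd)
        stats[col] = (mean, sd, float(x.min()), float(x.max()))
    return out, ScalingRecord(stats=stats)


def build_predictor_table(
    scores: pd.DataFrame, response: str, terms: Sequence[str] | None = None
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Assemble the modelling table from a scored-and-joined cohort table.

    Codes sex F/M as 0/1 and year as 0/1 (first season = 0), squares age
    *before* standardizing, and standardizes every predictor column.  The
    response column is carried through unstandardized.  With ``terms`` given,
    only the main-effect columns those terms need are standardized (an
    interaction pulls in both mains; ``age2`` pulls in ``age``).
    """
    df = scores.copy()
    if "sex" in df.columns and df["sex"].dtype == object:
        df["sex"] = df["sex"].map(SEX_CODES)
    if "year" in df.columns:
        years = sorted(df["year"].unique())
        df["year"] = df["year"].map({y: i for i, y in enumerate(years)})
    if "age" in df.columns:
        df["age2"] = df["age"].astype(float) ** 2
    if terms is None:
        predictors = [
            c for c in ("age", "age2", "sex", "group_size", "hour", "date", "year", "sdc")
            if c in df.columns and c != response
        ]
    else:
        mains: list[str] = []
        for t in terms:
            for part in t.split(":"):
                for col in ([part[:-1], part] if part.endswith("2") else [part]):
                    if col not in mains and col in df.columns:
                        mains.append(col)
        predictors = mains
    table = df[[response] + predictors].astype(float)
    std, scaling = standardize(table, predictors)
    return std, scaling


# ---------------------------------------------------------------------------
# model-set generation

def _requirements(term: str, terms: Sequence[str]) -> list[str]:
    """Marginality: interactions need both mains, a quadratic needs its main."""
    if ":" in term:
        return term.split(":")
    if term.endswith("2") and term[:-1] in terms:
        return [term[:-1]]
    return []


def generate_model_set(
    full_terms: Sequence[str],
    exclusions: Sequence[tuple[str, str]] = DEFAULT_EXCLUSIONS,
    marginality: bool = True,
    max_terms: int | None = None,
) -> list[tuple[str, ...]]:
    """All subsets of ``full_terms`` respecting marginality and exclusions.

    The intercept-only model (empty tuple) is always included.  ``max_terms``
    optionally caps model size (subjects-to-predictors rule of thumb).
    Deterministic order: by size, then term order within the full list.
    """
    full = list(full_terms)
    models: list[tuple[str, ...]] = []
    for r in range(len(full) + 1):
        if max_terms is not None and r > max_terms:
            break
        for subset in itertools.combinations(full, r):
            s = set(subset)
            if marginality and any(
                req not in s for t in subset for req in _requirements(t, full)
            ):
                continue
            if any(a in s and b in s for a, b in exclusions):
                continue
            models.append(subset)
    return models


# ---------------------------------------------------------------------------
# fitting

@dataclass
class CandidateModel:
    """One fitted predictor subset with its information-theoretic bookkeeping."""

    terms: tuple[str, ...]
    family: str
    params: dict[str, float]        # includes "Intercept"
    bse: dict[str, float]
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool = True
    degenerate: bool = False        # gaussian fit with ~zero residual variance
    delta: float = math.nan         # set by rank_models
    weight: float = math.nan        # set by rank_models

    @property
    def label(self) -> str:
        return " + ".join(self.terms) if self.terms else "(intercept)"


@dataclass
class TopModelSet:
    """Models within the dAICc threshold of the best, weights renormalized to 1."""

    models: list[CandidateModel]
    weights: np.ndarray
    threshold: float = 2.0

    def __post_init__(self) -> None:
        total = float(np.sum(self.weights))
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("renormalized weights must sum to 1")


def design_matrix(table: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Intercept + one column per term; interactions are products of mains."""
    X = pd.DataFrame({"Intercept": np.ones(len(table))}, index=table.index)
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            X[term] = table[a].to_numpy() * table[b].to_numpy()
        else:
            X[term] = table[term].to_numpy()
    return X


def fit_glm(
    table: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    family: str = "gaussian",
) -> CandidateModel:
    """Maximum-likelihood fit of one candidate model.

    gaussian: ordinary least squares; the log-likelihood uses the ML residual
    variance, and k counts intercept + slopes + sigma^2.  binomial: logit GLM
    via IRLS; k counts intercept + slopes.  A binomial fit that fails to
    converge (e.g. perfect separation) is returned flagged so the caller can
    drop it from averaging.
    """
    terms = tuple(terms)
    y = table[response].to_numpy(dtype=float)
    X = design_matrix(table, terms)
    n = len(y)
    if family == "gaussian":
        k = len(terms) + 2
    elif family == "binomial":
        k = len(terms) + 1
    else:
        raise ValueError(f"unknown family {family!r}")
    if n <= k:
        raise ValueError(f"n={n} too small for k={k} parameters")

    degenerate = False
    converged = True
    if family == "gaussian":
        res = sm.OLS(y, X).fit()
        ssr = float(res.ssr)
        if ssr <= 1e-12 * max(1.0, float(np.dot(y, y))):
            # perfect fit: the ML variance is ~0 and the likelihood diverges
            degenerate = True
            loglik = math.inf
        else:
            loglik = float(res.llf)
    else:
        try:
            with np.errstate(all="ignore"):
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            loglik = float(res.llf)
            fitted = np.asarray(res.fittedvalues)
            if not res.converged or np.any(np.abs(res.params) > 1e2) or np.any(
                (fitted < 1e-10) | (fitted > 1 - 1e-10)
            ):
                converged = False
                log.warning("binomial fit %s flagged as non-converged (separation?)",
                            " + ".join(terms) or "(intercept)")
        except Exception as exc:  # pragma: no cover - statsmodels failure path
            log.warning("binomial fit %s failed: %s", terms, exc)
            return CandidateModel(
                terms=terms, family=family, params={}, bse={}, loglik=math.nan,
                k=k, n=n, aicc=math.inf, converged=False,
            )

    params = {name: float(v) for name, v in zip(X.columns, np.asarray(res.params))}
    bse = {name: float(v) for name, v in zip(X.columns, np.asarray(res.bse))}
    model_aicc = -math.inf if degenerate else aicc(loglik, k, n)
    return CandidateModel(
        terms=terms, family=family, params=params, bse=bse, loglik=loglik,
        k=k, n=n, aicc=model_aicc, converged=converged, degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# AICc, weights, ranking, averaging

def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1); requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (needs n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """w_i = exp(-d_i/2) / sum_j exp(-d_j/2), d relative to the set minimum."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("empty AICc list")
    delta = a - a.min()
    raw = np.exp(-delta / 2.0)
    return raw / raw.sum()


def rank_models(
    models: Iterable[CandidateModel], delta_threshold: float = 2.0
) -> tuple[list[CandidateModel], TopModelSet]:
    """Rank candidates by AICc and extract the renormalized top set.

    Non-converged fits are excluded (with a warning already logged at fit
    time).  Ties in AICc are broken by fewer parameters, then by term order,
    so the ranking is deterministic.  ``delta`` and ``weight`` (over the full
    converged set) are filled in on each model.
    """
    usable = [m for m in models if m.converged]
    if not usable:
        raise ValueError("no converged models to rank")
    usable.sort(key=lambda m: (m.aicc, m.k, m.terms))
    best = usable[0].aicc
    weights = akaike_weights([m.aicc for m in usable])
    for m, w in zip(usable, weights):
        m.delta = m.aicc - best
        m.weight = float(w)
    top = [m for m in usable if m.delta <= delta_threshold]
    w_top = akaike_weights([m.aicc for m in top])
    return usable, TopModelSet(models=top, weights=w_top, threshold=delta_threshold)


@dataclass(frozen=True)
class AveragedCoefficient:
    """Zero-method averaged estimate for one term."""

    term: str
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    sum_of_weights: float


def model_average_zero(top: TopModelSet, z: float = 1.96) -> pd.DataFrame:
    """Zero-method (full) model averaging over the top set.

    estimate = sum_i w_i * beta_i, with beta_i = 0 where the term is absent;
    unconditional SE = sum_i w_i * sqrt(var_i + (beta_i - estimate)^2),
    likewise with var_i = beta_i = 0 for absent terms; CI = estimate +/- z*SE;
    sum_of_weights = total weight of top models containing the term.
    Returns a table with one row per term (intercept first, then the order of
    first appearance across models).
    """
    terms: list[str] = ["Intercept"]
    for m in top.models:
        for t in m.terms:
            if t not in terms:
                terms.append(t)
    rows = []
    for term in terms:
        betas = np.array([m.params.get(term, 0.0) for m in top.models])
        variances = np.array([m.bse.get(term, 0.0) ** 2 for m in top.models])
        present = np.array([term == "Intercept" or term in m.terms for m in top.models])
        est = float(np.sum(top.weights * betas))
        se = float(np.sum(top.weights * np.sqrt(variances + (betas - est) ** 2)))
        rows.append(
            AveragedCoefficient(
                term=term,
                estimate=est,
                se=se,
                ci_lower=est - z * se,
                ci_upper=est + z * se,
                sum_of_weights=float(np.sum(top.weights[present])),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("term")


def selection_table(models: Sequence[CandidateModel]) -> pd.DataFrame:
    """Model-selection summary: terms, df, logLik, AICc, dAICc, weight."""
    return pd.DataFrame(
        {
            "model": [m.label for m in models],
            "df": [m.k for m in models],
            "logLik": [m.loglik for m in models],
            "AICc": [m.aicc for m in models],
            "dAICc": [m.delta for m in models],
            "weight": [m.weight for m in models],
        }
    )


# ---------------------------------------------------------------------------
# prediction

def predict_response(
    coefficients: Mapping[str, float],
    scaling: ScalingRecord,
    ages: Sequence[float],
    fixed_date: float = 94.0,
    family: str = "gaussian",
) -> pd.DataFrame:
    """Predicted response over an age grid at a fixed date.

    New ages are standardized with the *fitted* scaling record (age and age^2
    as separate columns), combined linearly with the supplied coefficients
    (an averaged-coefficient table's estimates, or one model's params), and
    inverse-logit transformed for a binomial response.  ``fixed_date``
    defaults to day 94 of the season (February 3).  Ages outside the fitted
    range are flagged ``extrapolated``.
    """
    ages = np.asarray(ages, dtype=float)
    cols: dict[str, np.ndarray] = {}
    if "age" in coefficients:
        cols["age"] = scaling.transform_column("age", ages)
    if "age2" in coefficients:
        cols["age2"] = scaling.transform_column("age2", ages ** 2)
    if "date" in coefficients:
        cols["date"] = scaling.transform_column("date", np.full_like(ages, fixed_date))
    eta = np.full(ages.shape, float(coefficients.get("Intercept", 0.0)))
    for term, beta in coefficients.items():
        if term == "Intercept":
            continue
        if term not in cols:
            raise KeyError(
                f"cannot predict from term {term!r}: only age, age2 and date vary "
                "on an age grid (drop other terms or refit the age+age2+date model)"
            )
        eta = eta + beta * cols[term]
    if family == "binomial":
        pred = 1.0 / (1.0 + np.exp(-eta))
    else:
        pred = eta
    extrapolated = ~scaling.in_fitted_range("age", ages)
    return pd.DataFrame({"age": ages, "prediction": pred, "extrapolated": extrapolated})
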