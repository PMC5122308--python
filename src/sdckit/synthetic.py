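"""Synthetic focal-display studies with the structure the pipeline assumes.

The generator emulates a cross-sectional courtship-display study of a
long-lived colonial bird: ~100 focal individuals (half of each sex) observed
once each over a five-minute window during a November-March pairing season,
a latent individual *quality* that is concave in age (rising to a peak near
20 yrs, declining after) and increases over the season, display sequences
whose richness and versatility both rise with quality, a partially observed
breeding outcome linked to SDC, and a sample of mated pairs with tunable
SDC-assortment.

The display sequence itself is a first-order Markov chain over the
nine-posture repertoire: event count ~ Poisson(rate) + 1, a quality-dependent
probability s(q) of switching posture at each step, and a quality-dependent
accessible-posture set of size m(q).  This is a deliberately minimal
stand-in: it produces the joint richness/versatility variation the scoring
and modelling layers consume, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .ethogram import BehavioralSequence, Repertoire
from . import complexity

__all__ = ["GeneratorConfig", "SyntheticStudy", "generate_individuals",
           "generate_sequence", "generate_breeding", "generate_pairs",
           "generate_study", "quality_curve"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the field design: 100 focal individuals (50 F / 50 M),
    male ages 4-34 and female ages 5-37, observation dates over the 152-day
    season (Nov 1 = day 0), display groups of 9-130 birds, a 56-individual
    single-season cohort with known breeding outcome at ~23% prevalence, and
    21 mated pairs.  Quality coefficients place the age peak at 20 yrs and
    make SDC rise over the season; sequence coefficients are set so scored
    richness falls in 2-8, versatility in 2-17 and SDC in 4-136 for the vast
    majority of sequences.
    """

    n_individuals: int = 100
    age_range_male: tuple[int, int] = (4, 34)
    age_range_female: tuple[int, int] = (5, 37)
    date_range: tuple[int, int] = (0, 151)
    hour_range: tuple[float, float] = (8.0, 17.0)
    group_size_range: tuple[int, int] = (9, 130)
    years: tuple[int, int] = (2014, 2015)
    window: float = 300.0

    # latent quality: q = q0 + q_age*age + q_age2*age^2 + q_date*date + N(0, sigma_q)
    q0: float = -0.25
    q_age: float = 0.14
    q_age2: float = -0.0035
    q_date: float = 0.0035
    sigma_q: float = 0.30

    # sequence model: events ~ Poisson(event_rate)+1; switch prob
    # s(q) = expit(logit(s0) + beta_s*q); accessible postures
    # m(q) = clip(2 + round(beta_m*q), 2, 9)
    event_rate: float = 20.0
    s0: float = 0.30
    beta_s: float = 0.70
    beta_m: float = 3.5

    # breeding link: breeder ~ Bernoulli(expit(gamma0 + gamma1 * z(SDC)))
    # over an n_breeding-sized single-season cohort
    gamma0: float = -1.2
    gamma1: float = 1.4
    n_breeding: int = 56

    # pairs: rank-matching on age-predicted SDC with assortment strength rho
    n_pairs: int = 21
    rho: float = 0.9

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2 or self.n_individuals % 2:
            raise ValueError("n_individuals must be an even count >= 2")
        for lo, hi in (self.age_range_male, self.age_range_female,
                       self.date_range, self.group_size_range):
            if lo > hi:
                raise ValueError(f"invalid range ({lo}, {hi})")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.q_age2 >= 0:
            raise ValueError("q_age2 must be negative (concave age profile)")


@dataclass
class SyntheticStudy:
    """One complete generated study (all cross-references resolve by id)."""

    metadata: pd.DataFrame          # id, sex, age, date, hour, group_size, year
    sequences: list[BehavioralSequence]
    quality: pd.Series              # latent quality, indexed by id
    breeding: pd.DataFrame          # id, breeder (single-season cohort)
    pairs: pd.DataFrame             # male_id, male_age, female_id, female_age
    config: GeneratorConfig

    def config_dict(self) -> dict:
        return asdict(self.config)


def quality_curve(age, date, config: GeneratorConfig):
    """Deterministic part of latent quality at a given age and date."""
    age = np.asarray(age, dtype=float)
    return (config.q0 + config.q_age * age + config.q_age2 * age ** 2
            + config.q_date * np.asarray(date, dtype=float))


def generate_individuals(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw the focal cohort and its latent quality.

    Half the cohort is female, half male; ages are uniform on the per-sex
    ranges, dates uniform over the season, hour and group size uniform on
    their observed ranges.  The later season (breeding-monitored year) gets
    ``n_breeding`` individuals, the earlier the rest.  Quality is the concave
    age/date curve plus N(0, sigma_q) noise.
    """
    n = config.n_individuals
    half = n // 2
    ids = [f"F{i:03d}" for i in range(half)] + [f"M{i:03d}" for i in range(half)]
    sex = ["F"] * half + ["M"] * half
    age = np.concatenate([
        rng.integers(config.age_range_female[0], config.age_range_female[1] + 1, half),
        rng.integers(config.age_range_male[0], config.age_range_male[1] + 1, half),
    ])
    date = rng.integers(config.date_range[0], config.date_range[1] + 1, n)
    hour = np.round(rng.uniform(*config.hour_range, n), 2)
    group_size = rng.integers(config.group_size_range[0], config.group_size_range[1] + 1, n)
    n_late = min(config.n_breeding, n)
    year = np.full(n, config.years[0])
    year[rng.choice(n, size=n_late, replace=False)] = config.years[1]
    metadata = pd.DataFrame({
        "id": ids, "sex": sex, "age": age, "date": date, "hour": hour,
        "group_size": group_size, "year": year,
    }).set_index("id", drop=False)
    quality = pd.Series(
        quality_curve(age, date, config) + rng.normal(0.0, config.sigma_q, n),
        index=metadata.index, name="quality",
    )
    return metadata, quality


def switch_probability(q: float, config: GeneratorConfig) -> float:
    return float(expit(logit(config.s0) + config.beta_s * q))


def accessible_count(q: float, config: GeneratorConfig) -> int:
    return int(np.clip(2 + round(config.beta_m * q), 2, 9))


def generate_sequence(
    subject_id: str,
    q: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    repertoire: Repertoire | None = None,
) -> BehavioralSequence:
    """Simulate one focal display sequence for an individual of quality q."""
    rep = repertoire if repertoire is not None else Repertoire.default()
    n_events = int(rng.poisson(config.event_rate)) + 1
    s = switch_probability(q, config)
    m = min(accessible_count(q, config), len(rep))
    accessible = list(rng.choice(rep.labels, size=m, replace=False))
    postures = [accessible[rng.integers(m)]]
    for _ in range(n_events - 1):
        if m > 1 and rng.random() < s:
            alternatives = [p for p in accessible if p != postures[-1]]
            postures.append(alternatives[rng.integers(len(alternatives))])
        else:
            postures.append(postures[-1])
    times = np.sort(rng.uniform(0.0, config.window, n_events))
    # enforce strictly increasing times (duplicate uniform draws are
    # measure-zero but float-possible)
    times = np.maximum.accumulate(times + np.arange(n_events) * 1e-9)
    return BehavioralSequence(
        subject_id=subject_id,
        events=list(zip(times.tolist(), postures)),
        window_length=config.window,
        observed_span=config.window,
    )


def generate_breeding(
    scores: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw breeding status for the monitored single-season cohort.

    The cohort is the later season's individuals (``n_breeding`` of them);
    breeding probability is logistic in SDC standardized by two SDs:
    expit(gamma0 + gamma1 * z), z = (sdc - mean) / (2 sd).
    """
    cohort = scores[scores["year"] == config.years[1]]
    if len(cohort) == 0:
        cohort = scores.sample(n=min(config.n_breeding, len(scores)),
                               random_state=np.random.RandomState(rng.integers(2**31)))
    sdc = cohort["sdc"].to_numpy(dtype=float)
    z = (sdc - sdc.mean()) / (2.0 * sdc.std(ddof=1))
    p = expit(config.gamma0 + config.gamma1 * z)
    breeder = rng.random(len(cohort)) < p
    return pd.DataFrame({"id": cohort["id"].to_numpy(), "breeder": breeder.astype(int)})


def generate_pairs(
    metadata: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Mate males and females with tunable SDC-assortment.

    Both sexes are scored by the deterministic age-quality curve (the
    age-predicted display-complexity proxy, date held fixed at mid-season).
    Matching key per individual = rho * standardized rank + (1 - rho) *
    N(0, 1): rho=1 is exact rank-matching on predicted SDC, rho=0 is uniform
    random pairing.
    """
    males = metadata[metadata["sex"] == "M"]
    females = metadata[metadata["sex"] == "F"]
    if len(males) < config.n_pairs or len(females) < config.n_pairs:
        raise ValueError(
            f"need >= {config.n_pairs} individuals of each sex "
            f"(have {len(males)} M, {len(females)} F)"
        )
    males = males.sample(n=config.n_pairs, random_state=np.random.RandomState(rng.integers(2**31)))
    females = females.sample(n=config.n_pairs, random_state=np.random.RandomState(rng.integers(2**31)))

    def keys(df: pd.DataFrame) -> np.ndarray:
        score = quality_curve(df["age"].to_numpy(), 94.0, config)
        ranks = pd.Series(score).rank(method="first").to_numpy(dtype=float)
        zr = (ranks - ranks.mean()) / ranks.std(ddof=1)
        return config.rho * zr + (1.0 - config.rho) * rng.normal(0.0, 1.0, len(df))

    m_order = np.argsort(keys(males), kind="stable")
    f_order = np.argsort(keys(females), kind="stable")
    males = males.iloc[m_order]
    females = females.iloc[f_order]
    return pd.DataFrame({
        "male_id": males["id"].to_numpy(),
        "male_age": males["age"].to_numpy(),
        "female_id": females["id"].to_numpy(),
        "female_age": females["age"].to_numpy(),
    }).reset_index(drop=True)


def generate_study(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    repertoire: Repertoire | None = None,
) -> SyntheticStudy:
    """Generate a complete study: cohort, sequences, breeding table, pairs.

    Fully deterministic: the same (config, seed) always yields the identical
    study.  ``seed`` overrides ``config.seed`` when given.
    """
    config = config if config is not None else GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rep = repertoire if repertoire is not None else Repertoire.default()
    metadata, quality = generate_individuals(config, rng)
    sequences = [
        generate_sequence(sid, float(quality[sid]), config, rng, rep)
        for sid in metadata.index
    ]
    scores = complexity.score_batch(sequences, metadata, rep)
    breeding = generate_breeding(scores, config, rng)
    pairs = generate_pairs(metadata, config, rng)
    return SyntheticStudy(
        metadata=metadata, sequences=sequences, quality=quality,
        breeding=breeding, pairs=pairs, config=config,
    )
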