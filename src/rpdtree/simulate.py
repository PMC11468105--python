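"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a 1970s urban ageing cohort: ~1000 subjects aged
60–89 at baseline (about half men), followed 35+ years with
near-complete mortality, a survey of typed predictors at baseline, and
a second survey ten years later among the survivors.  Mortality follows
a Gompertz period life table modulated per subject by a hazard ratio

    HR_i = exp( frailty_coef * z_i + sum_j beta_j * x_ij
                + planted threshold / interaction terms )

acting on the annual death probability through the complement power
q_i = 1 - (1 - q)^HR_i, which stays a valid probability for any
HR > 0.  A single shared latent frailty factor z ~ N(0, 1) loads on the
survey variables, making predictors mutually correlated as real health
measures are.

``planted_tree_scenario`` produces cohorts with known tree structure
(a dominant self-rated-health root effect, optionally a second-level
education effect) for split-recovery studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError
from .lifetable import SEXES, LifeTable, generate_gompertz_life_table
from .predictors import PredictorTable, VariableSpec
from .rpd import Subject

__all__ = [
    "SimConfig",
    "default_variable_specs",
    "simulate_cohort",
    "simulate_wave2",
    "planted_tree_scenario",
]


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the cohort generator; same seed, same cohort."""

    n: int = 1056
    baseline_year: int = 1979
    end_of_study_year: int = 2014
    wave2_offset: int = 10
    age_low: int = 60
    age_high: int = 89
    male_share: float = 0.498
    # period life table (year-invariant Gompertz)
    gompertz_alpha_f: float = 2e-5
    gompertz_alpha_m: float = 3.5e-5
    gompertz_beta: float = 0.095
    gompertz_cap: float = 0.7
    # hazard model
    frailty_hazard_coef: float = 0.25
    linear_effects: tuple = (
        ("smoking_years", 0.008),
        ("demanding_functioning", -0.04),
        ("medications", 0.05),
    )
    #: (variable, threshold, log_hr): log_hr applies when value < threshold
    threshold_effects: tuple = (("srh", 2.0, 0.45),)
    #: (conditions, log_hr) with conditions ((variable, "lt"|"ge", threshold), ...)
    interaction_effects: tuple = ()
    # survey realism
    missing_rate: float = 0.02
    wave2_missing_rate: float = 0.03
    # wave-2 transition model (worsening-biased)
    p_worsen: float = 0.35
    p_stay: float = 0.50
    p_improve: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if not (0 <= self.male_share <= 1):
            raise ConfigError("male_share must be in [0, 1]")
        probs = (self.p_worsen, self.p_stay, self.p_improve)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1) > 1e-9:
            raise ConfigError("transition probabilities must be non-negative and sum to 1")
        if self.age_high < self.age_low:
            raise ConfigError("age range must be increasing")


def default_variable_specs() -> dict[str, VariableSpec]:
    """The emulated predictor subset: typed like the field's survey scales.

    Self-rated health (0–4), mobility (0–14), demanding functioning
    (0–12), self-care ADL (0–15) and medication count (0–12) are
    measured at both waves; education, smoking history, a
    musculoskeletal-disease flag, age and sex are baseline-only.
    """
    mk = VariableSpec
    return {
        s.name: s
        for s in [
            mk("srh", "ordinal", "higher_is_better", "both_waves", 0, 4),
            mk("education_years", "continuous", "higher_is_better", "baseline_only", 0, 20),
            mk("smoking_years", "continuous", "higher_is_worse", "baseline_only", 0, 60),
            mk("mobility", "ordinal", "higher_is_better", "both_waves", 0, 14),
            mk("demanding_functioning", "ordinal", "higher_is_better", "both_waves", 0, 12),
            mk("adl", "ordinal", "higher_is_better", "both_waves", 0, 15),
            mk("medications", "ordinal", "higher_is_worse", "both_waves", 0, 12),
            mk("musculoskeletal", "nominal", "undirected", "baseline_only", levels=("no", "yes")),
            mk("age", "continuous", "undirected", "baseline_only", 60, 89),
            mk("sex", "nominal", "undirected", "baseline_only", levels=("f", "m")),
        ]
    }


def _draw_wave1(cfg: SimConfig, rng: np.random.Generator):
    """Latent frailty z plus the correlated survey variables."""
    n = cfg.n
    z = rng.standard_normal(n)
    sex = np.where(rng.random(n) < cfg.male_share, "m", "f")
    age = rng.integers(cfg.age_low, cfg.age_high + 1, size=n)

    def clipround(v, lo, hi):
        return np.clip(np.round(v), lo, hi)

    srh = clipround(2.4 - 0.7 * z + rng.normal(0, 0.8, n), 0, 4)
    education = np.clip(rng.gamma(2.0, 2.5, n) - 0.6 * z, 0, 20).round(1)
    smoker_p = np.where(sex == "m", 0.60, 0.25)
    smoking = np.where(
        rng.random(n) < smoker_p, np.clip(rng.normal(30, 10, n), 1, 60).round(0), 0.0
    )
    mobility = clipround(11 - 2.2 * z + rng.normal(0, 2.0, n), 0, 14)
    demanding = clipround(9 - 2.0 * z + rng.normal(0, 2.0, n), 0, 12)
    adl = clipround(13.5 - 1.8 * z + rng.normal(0, 1.5, n), 0, 15)
    medications = clipround(1.5 + 1.2 * z + rng.normal(0, 1.5, n), 0, 12)
    musculo = np.where(rng.random(n) < 1 / (1 + np.exp(0.6 - 0.5 * z)), "yes", "no")

    df = pd.DataFrame(
        {
            "srh": srh,
            "education_years": education,
            "smoking_years": smoking,
            "mobility": mobility,
            "demanding_functioning": demanding,
            "adl": adl,
            "medications": medications,
            "musculoskeletal": musculo,
            "age": age.astype(float),
            "sex": sex,
        }
    )
    return z, sex, age, df


def _hazard_ratio(cfg: SimConfig, z: np.ndarray, df: pd.DataFrame) -> np.ndarray:
    log_hr = cfg.frailty_hazard_coef * z
    for name, beta in cfg.linear_effects:
        x = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        log_hr = log_hr + beta * (x - np.nanmean(x))
    for name, thr, lhr in cfg.threshold_effects:
        x = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        log_hr = log_hr + lhr * (x < thr)
    for conditions, lhr in cfg.interaction_effects:
        mask = np.ones(len(df), dtype=bool)
        for name, op, thr in conditions:
            x = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
            mask &= (x < thr) if op == "lt" else (x >= thr)
        log_hr = log_hr + lhr * mask
    return np.exp(log_hr)


def _mask_missing(df: pd.DataFrame, rate: float, rng, skip=("age", "sex")) -> pd.DataFrame:
    if rate <= 0:
        return df
    out = df.copy()
    for c in out.columns:
        if c in skip:
            continue
        hit = rng.random(len(out)) < rate
        if out[c].dtype == object:
            out.loc[hit, c] = None
        else:
            out.loc[hit, c] = np.nan
    return out


def build_life_table(cfg: SimConfig, max_age: int | None = None) -> LifeTable:
    """The generator's period life table, covering the cohort's trajectories."""
    hi = max_age or (cfg.age_high + (cfg.end_of_study_year - cfg.baseline_year) + 1)
    return generate_gompertz_life_table(
        cfg.gompertz_alpha_f,
        cfg.gompertz_alpha_m,
        cfg.gompertz_beta,
        (cfg.age_low, hi),
        cap=cfg.gompertz_cap,
    )


def simulate_cohort(
    cfg: SimConfig,
    lt: LifeTable | None = None,
    extend_until_death: bool = False,
) -> tuple[list[Subject], PredictorTable]:
    """Draw one cohort: subjects with vital status plus the wave-1 survey.

    Each subject undergoes yearly Bernoulli death draws with probability
    1 - (1 - q)^HR along their age trajectory; survivors at the end of
    the study are censored (``alive_at_end``) unless
    ``extend_until_death``, which keeps drawing past the study end until
    everyone has died (the table must cover the extended ages — used for
    null studies of the RPD statistic).
    """
    rng = np.random.default_rng(cfg.seed)
    lt = lt or build_life_table(cfg, max_age=None if not extend_until_death else 2000)
    z, sex, age, df = _draw_wave1(cfg, rng)
    hr = _hazard_ratio(cfg, z, df)
    if (hr <= 0).any() or not np.isfinite(hr).all():
        raise ContractError("hazard ratios must be positive and finite")

    n = cfg.n
    sex_idx = np.array([SEXES.index(s) for s in sex])
    death_year = np.full(n, -1)
    alive = np.ones(n, dtype=bool)
    year = cfg.baseline_year
    while alive.any():
        if not extend_until_death and year > cfg.end_of_study_year:
            break
        att_age = age[alive] + (year - cfg.baseline_year)
        q = lt.q_bulk(sex_idx[alive], att_age, np.full(int(alive.sum()), year))
        q_i = 1.0 - np.power(1.0 - q, hr[alive])
        dies = rng.random(int(alive.sum())) < q_i
        idx = np.nonzero(alive)[0]
        death_year[idx[dies]] = year
        alive[idx[dies]] = False
        year += 1

    subjects = []
    for i in range(n):
        dead = death_year[i] >= 0
        subjects.append(
            Subject(
                id=f"s{i:05d}",
                sex=sex[i],
                baseline_age=int(age[i]),
                baseline_year=cfg.baseline_year,
                end_of_study_year=(
                    cfg.end_of_study_year if not extend_until_death else int(death_year.max())
                ),
                death_year=int(death_year[i]) if dead else None,
                alive_at_end=not dead,
            )
        )
    observed = _mask_missing(df, cfg.missing_rate, rng)
    observed.index = pd.Index([s.id for s in subjects], name="id")
    return subjects, PredictorTable(observed, default_variable_specs())


def simulate_wave2(
    subjects: list[Subject], wave1: PredictorTable, cfg: SimConfig
) -> pd.DataFrame:
    """The ten-years-later re-survey: transitioned values for survivors.

    Subjects dead before the wave-2 year get an all-missing row.  Each
    both-waves variable moves by a worsening-biased step (worsen / stay
    / improve with the configured probabilities), clipped to its range.
    """
    rng = np.random.default_rng((cfg.seed + 1000003) % 2**31)
    wave2_year = cfg.baseline_year + cfg.wave2_offset
    surv = np.array(
        [s.death_year is None or s.death_year >= wave2_year for s in subjects]
    )
    eligible = [s for s in wave1.specs.values() if s.waves == "both_waves"]
    out = pd.DataFrame(index=wave1.data.index)
    n = len(wave1.data)
    for spec in eligible:
        w1 = pd.to_numeric(wave1.data[spec.name], errors="coerce").to_numpy(dtype=float)
        move = rng.choice([-1, 0, 1], size=n, p=[cfg.p_worsen, cfg.p_stay, cfg.p_improve])
        span = (spec.maximum - spec.minimum) if spec.maximum is not None else 10
        if spec.kind == "ordinal":
            mag = rng.integers(1, max(2, int(span / 5) + 1), size=n)
        else:
            mag = np.abs(rng.normal(0, span / 10, size=n))
        sign = 1.0 if spec.direction == "higher_is_better" else -1.0
        w2 = w1 + sign * move * mag
        if spec.kind == "ordinal":
            w2 = np.round(w2)
        if spec.minimum is not None:
            w2 = np.clip(w2, spec.minimum, spec.maximum)
        lost = rng.random(n) < cfg.wave2_missing_rate
        w2 = np.where(surv & ~lost, w2, np.nan)
        out[spec.name] = w2
    return out


def null_study_cohort(n: int, seed: int) -> tuple[list[Subject], LifeTable]:
    """Cohort for null studies of the RPD statistic.

    Every subject has hazard ratio 1, death years are drawn from the
    same life table later used to score them, and follow-up continues
    until everyone has died (no censoring).  The table is a fine-grained
    Gompertz with the annual death probability capped at 0.02, chosen
    from the closed-form null expectation
    E[RPD] = (1 - sum dS^2)/2: the annual-discretization deficit is
    about q/4 near the modal death ages, so a 0.02 cap keeps the exact
    mean at 0.495 for every baseline age and sex, well within 0.01 of
    the theoretical 0.50 (a 0.15 cap would not be for baseline ages
    above ~75).
    """
    cfg = SimConfig(
        n=n,
        seed=seed,
        frailty_hazard_coef=0.0,
        linear_effects=(),
        threshold_effects=(),
        missing_rate=0.0,
        gompertz_cap=0.02,
    )
    lt = build_life_table(cfg, max_age=2500)
    subjects, _ = simulate_cohort(cfg, lt, extend_until_death=True)
    return subjects, lt


def planted_tree_scenario(
    level: str, n: int = 1000, seed: int = 0
) -> tuple[list[Subject], PredictorTable, dict]:
    """Cohorts with known tree structure, for split-recovery studies.

    ``root_only`` plants a single dominant effect: poor self-rated
    health (srh < 2) multiplies the hazard by 2.5.  ``two_level`` adds a
    within-branch effect: among subjects with good SRH, nine or more
    years of education roughly halves the hazard — a planted
    second-level split.  All other hazard effects (including frailty)
    are switched off, so the ground truth is exactly the planted
    structure.
    """
    if level not in ("root_only", "two_level"):
        raise ContractError(f"unknown scenario level {level!r}")
    interactions = ()
    if level == "two_level":
        interactions = (
            ((("srh", "ge", 2.0), ("education_years", "ge", 9.0)), -math.log(2.2)),
        )
    cfg = SimConfig(
        n=n,
        seed=seed,
        frailty_hazard_coef=0.0,
        linear_effects=(),
        threshold_effects=(("srh", 2.0, math.log(2.5)),),
        interaction_effects=interactions,
        missing_rate=0.0,
    )
    subjects, wave1 = simulate_cohort(cfg)
    truth = {
        "level": level,
        "root_variable": "srh",
        "root_threshold": 2.0,
        "variables": ["srh"] + (["education_years"] if level == "two_level" else []),
        "hazard_ratios": {"srh_below_2": 2.5}
        | ({"education_ge_9_good_srh": 1 / 2.2} if level == "two_level" else {}),
    }
    return subjects, wave1, truth
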