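"""The realized probability of dying (RPD) and its logit transform.

RPD compares an individual's survival with that of their age- and
sex-matched life-table cohort: it is the product of the annual
survival probabilities (1 - q_i) over the calendar years from baseline
through the year of death, i.e. the fraction of the matched cohort
still alive at the end of the death year.  Values lie in (0, 1]; higher
RPD means shorter survival relative to peers.

Subjects alive at the end of the study receive an imputed RPD: the
cumulative life-table survival from baseline through the final
follow-up year multiplied by 0.50 (half of the still-alive cohort
fraction — the subject will die somewhere in the middle of it).

The analysis outcome is LRPD = ln(RPD / (1 - RPD)), the logit of RPD
(natural logarithm).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError, SchemaError, ValidationError
from .lifetable import SEXES, LifeTable, cumulative_survival, normalize_sex, survival_bulk

__all__ = [
    "Subject",
    "RpdRecord",
    "CohortRpdSummary",
    "compute_rpd",
    "impute_rpd_censored",
    "logit_transform",
    "compute_cohort_rpd",
    "read_cohort_table",
    "write_rpd_records",
]

logger = logging.getLogger(__name__)

#: how the censored-subject imputation reads "probability of survival in
#: the final year": cumulative survival from baseline (default) or the
#: single final-year survival probability.
IMPUTATION_VARIANTS = ("cumulative", "final_year")


@dataclass(frozen=True)
class Subject:
    """One cohort member: identity, demographics and vital status."""

    id: str
    sex: str  # 'f' or 'm'
    baseline_age: int
    baseline_year: int
    end_of_study_year: int
    death_year: int | None = None
    alive_at_end: bool = False

    def __post_init__(self):
        object.__setattr__(self, "sex", normalize_sex(self.sex))
        if (self.death_year is None) == (not self.alive_at_end):
            raise ValidationError(
                f"subject {self.id}: exactly one of death_year / alive_at_end must hold"
            )
        if self.death_year is not None and not (
            self.baseline_year <= self.death_year <= self.end_of_study_year
        ):
            raise ValidationError(
                f"subject {self.id}: death_year {self.death_year} outside "
                f"[{self.baseline_year}, {self.end_of_study_year}]"
            )


@dataclass(frozen=True)
class RpdRecord:
    """Per-subject RPD/LRPD with provenance flags.

    ``lrpd`` is NaN for the degenerate rpd == 1 case (possible only on
    zero-hazard toy tables), which is reported with a warning rather
    than clamped.
    """

    subject_id: str
    rpd: float
    lrpd: float
    imputed: bool
    n_years: int


@dataclass(frozen=True)
class CohortRpdSummary:
    n: int
    n_imputed: int
    mean_rpd: float
    sd_rpd: float
    min_rpd: float
    max_rpd: float
    mean_lrpd: float
    sd_lrpd: float
    min_lrpd: float
    max_lrpd: float


def logit_transform(rpd: float) -> float:
    """ln(p / (1 - p)); strictly increasing on (0, 1), errors at the endpoints."""
    if not 0.0 < rpd < 1.0:
        raise ContractError(f"logit requires 0 < rpd < 1; got {rpd}")
    return math.log(rpd / (1.0 - rpd))


def _finalize(subject_id, rpd, imputed, n_years) -> RpdRecord:
    if 0.0 < rpd < 1.0:
        lrpd = logit_transform(rpd)
    else:
        logger.warning(
            "subject %s: rpd = %g has no finite logit; lrpd set to NaN", subject_id, rpd
        )
        lrpd = float("nan")
    return RpdRecord(subject_id, float(rpd), lrpd, imputed, int(n_years))


def compute_rpd(subject: Subject, lt: LifeTable) -> RpdRecord:
    """RPD for a subject with an observed death year.

    The death year contributes a full annual factor, so
    n = death_year - baseline_year + 1 and RPD is the matched-cohort
    fraction alive at the end of the death year.
    """
    if subject.death_year is None:
        raise ContractError(
            f"subject {subject.id} is alive at end of study; use impute_rpd_censored"
        )
    n = subject.death_year - subject.baseline_year + 1
    rpd = cumulative_survival(lt, subject.sex, subject.baseline_age, subject.baseline_year, n)
    return _finalize(subject.id, rpd, imputed=False, n_years=n)


def impute_rpd_censored(
    subject: Subject, lt: LifeTable, variant: str = "cumulative"
) -> RpdRecord:
    """Imputed RPD for a subject alive at end of study.

    ``cumulative`` (default): RPD = S(baseline .. end-of-study) * 0.50,
    the still-alive cohort fraction halved.  ``final_year``: RPD =
    (1 - q in the final follow-up year) * 0.50, an alternative reading
    of the published rule.
    """
    if subject.death_year is not None:
        raise ContractError(f"subject {subject.id} has a death year; use compute_rpd")
    if variant not in IMPUTATION_VARIANTS:
        raise ContractError(f"unknown imputation variant {variant!r}")
    n = subject.end_of_study_year - subject.baseline_year + 1
    if variant == "cumulative":
        surv = cumulative_survival(
            lt, subject.sex, subject.baseline_age, subject.baseline_year, n
        )
    else:
        final_age = subject.baseline_age + n - 1
        final_year = subject.baseline_year + n - 1
        surv = cumulative_survival(lt, subject.sex, final_age, final_year, 1)
    return _finalize(subject.id, surv * 0.50, imputed=True, n_years=n)


def compute_cohort_rpd(
    subjects: list[Subject],
    lt: LifeTable,
    imputation_variant: str = "cumulative",
) -> tuple[list[RpdRecord], CohortRpdSummary]:
    """RPD records and summary statistics for a whole cohort.

    Any per-subject failure is collected and re-raised with the subject
    ids — partial results are never returned silently.  Period-only
    tables take a vectorized path (identical results, useful for the
    100k-subject null simulations).
    """
    if not subjects:
        raise ContractError("empty cohort")
    if imputation_variant not in IMPUTATION_VARIANTS:
        raise ContractError(f"unknown imputation variant {imputation_variant!r}")

    if lt.period_only and imputation_variant == "cumulative":
        records = _cohort_rpd_vectorized(subjects, lt)
    else:
        records, errors = [], []
        for s in subjects:
            try:
                if s.death_year is not None:
                    records.append(compute_rpd(s, lt))
                else:
                    records.append(impute_rpd_censored(s, lt, imputation_variant))
            except Exception as exc:  # noqa: BLE001 - collected and re-raised
                errors.append(f"{s.id}: {exc}")
        if errors:
            raise ValidationError(
                "RPD computation failed for %d subject(s): %s"
                % (len(errors), "; ".join(errors[:10]))
            )
    return records, summarize_rpd(records)


def _cohort_rpd_vectorized(subjects: list[Subject], lt: LifeTable) -> list[RpdRecord]:
    sex_idx = np.array([SEXES.index(s.sex) for s in subjects])
    age0 = np.array([s.baseline_age for s in subjects])
    dead = np.array([s.death_year is not None for s in subjects])
    last_year = np.array(
        [s.death_year if s.death_year is not None else s.end_of_study_year for s in subjects]
    )
    year0 = np.array([s.baseline_year for s in subjects])
    n_years = last_year - year0 + 1
    surv = survival_bulk(lt, sex_idx, age0, year0, n_years)
    rpd = np.where(dead, surv, surv * 0.50)
    return [
        _finalize(s.id, r, imputed=not d, n_years=n)
        for s, r, d, n in zip(subjects, rpd, dead, n_years)
    ]


def summarize_rpd(records: list[RpdRecord]) -> CohortRpdSummary:
    rpd = np.array([r.rpd for r in records])
    lrpd = np.array([r.lrpd for r in records])
    finite = np.isfinite(lrpd)
    if not finite.all():
        logger.warning(
            "%d subject(s) with rpd in {0, 1} excluded from LRPD summary", int((~finite).sum())
        )
    lv = lrpd[finite] if finite.any() else np.array([np.nan])
    return CohortRpdSummary(
        n=len(records),
        n_imputed=sum(r.imputed for r in records),
        mean_rpd=float(rpd.mean()),
        sd_rpd=float(rpd.std(ddof=0)),
        min_rpd=float(rpd.min()),
        max_rpd=float(rpd.max()),
        mean_lrpd=float(lv.mean()),
        sd_lrpd=float(lv.std(ddof=0)),
        min_lrpd=float(lv.min()),
        max_lrpd=float(lv.max()),
    )


# -- cohort file IO -------------------------------------------------------

_COHORT_COLS = ("id", "sex", "baseline_age", "baseline_year")


def read_cohort_table(
    path, end_of_study_year: int | None = None, delimiter: str | None = None
) -> tuple[list[Subject], pd.DataFrame]:
    """Read a cohort CSV/TSV into subjects plus a predictor frame.

    Required columns: id, sex, baseline_age, baseline_year, death_year
    (empty = alive at end).  ``end_of_study_year`` may instead be a
    column.  All remaining columns are returned untouched as the
    predictor frame, indexed by subject id in file order.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    missing = [c for c in _COHORT_COLS if c not in df.columns]
    if missing or ("death_year" not in df.columns):
        raise SchemaError(f"cohort file lacks columns: {missing + ['death_year'] if missing else ['death_year']}")
    if end_of_study_year is None:
        if "end_of_study_year" not in df.columns:
            raise SchemaError(
                "end_of_study_year must be given as an argument or a column"
            )
        eos = df["end_of_study_year"].astype(int)
    else:
        eos = pd.Series(int(end_of_study_year), index=df.index)
    subjects = []
    for i, row in df.iterrows():
        dy = row["death_year"]
        dead = pd.notna(dy)
        subjects.append(
            Subject(
                id=str(row["id"]),
                sex=row["sex"],
                baseline_age=int(row["baseline_age"]),
                baseline_year=int(row["baseline_year"]),
                end_of_study_year=int(eos[i]),
                death_year=int(dy) if dead else None,
                alive_at_end=not dead,
            )
        )
    reserved = set(_COHORT_COLS) | {"death_year", "end_of_study_year"}
    predictors = df[[c for c in df.columns if c not in reserved]].copy()
    predictors.index = pd.Index([s.id for s in subjects], name="id")
    return subjects, predictors


def write_rpd_records(records: list[RpdRecord], path) -> None:
    pd.DataFrame(
        {
            "id": [r.subject_id for r in records],
            "rpd": [r.rpd for r in records],
            "lrpd": [r.lrpd for r in records],
            "imputed": [r.imputed for r in records],
            "n_years": [r.n_years for r in records],
        }
    ).to_csv(path, index=False)
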