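"""Period life tables of annual death probabilities q(sex, age, calendar year).

The life table supplies the annual probabilities of dying that the RPD
(realized probability of dying) statistic multiplies along a subject's
age trajectory.  Tables are either calendar-year-specific (one q per
(sex, age, year)) or *period-only* (a single table applied to every
calendar year); a ``period_only`` flag governs dispatch.

Attained age advances exactly one year per calendar year from baseline:
the i-th follow-up year uses q(sex, baseline_age + i - 1,
baseline_year + i - 1).  Queries outside the declared age/year ranges
are hard errors — no extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError, SchemaError, TableLookupError, ValidationError

__all__ = [
    "LifeTable",
    "read_life_table",
    "write_life_table",
    "death_prob",
    "cumulative_survival",
    "generate_gompertz_life_table",
]

#: canonical sex codes; index into the first axis of ``LifeTable.q``
SEXES = ("f", "m")

_SEX_ALIASES = {
    "f": "f", "female": "f", "fem": "f", "w": "f",
    "m": "m", "male": "m",
}


def normalize_sex(value) -> str:
    """Map a sex label ('f', 'female', 'M', ...) to the canonical 'f'/'m'."""
    key = str(value).strip().lower()
    try:
        return _SEX_ALIASES[key]
    except KeyError:
        raise ValidationError(f"unrecognized sex code {value!r}") from None


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities indexed by sex, integer age and calendar year.

    Parameters
    ----------
    q
        Array of shape ``(2, n_ages, n_years)``; axis 0 is sex in the
        order ('f', 'm'), axis 1 ages ``min_age..max_age`` contiguously,
        axis 2 calendar years.  When ``period_only`` the year axis has
        length one and applies to all calendar years.
    min_age, max_age
        Inclusive attained-age range.
    min_year, max_year
        Inclusive calendar-year range; ``None`` when ``period_only``.
    """

    q: np.ndarray
    min_age: int
    max_age: int
    min_year: int | None
    max_year: int | None
    period_only: bool
    _log_surv: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 3 or q.shape[0] != 2:
            raise ValidationError(f"q must have shape (2, n_ages, n_years); got {q.shape}")
        if q.shape[1] != self.max_age - self.min_age + 1:
            raise ValidationError("age axis length does not match declared age range")
        if self.period_only:
            if q.shape[2] != 1:
                raise ValidationError("period-only table must have a single year slice")
        else:
            if self.min_year is None or self.max_year is None:
                raise ValidationError("year range required for a year-specific table")
            if q.shape[2] != self.max_year - self.min_year + 1:
                raise ValidationError("year axis length does not match declared year range")
        if np.isnan(q).any():
            raise ValidationError("life table has gaps: some (sex, age, year) cells are missing")
        if (q < 0).any() or (q > 1).any():
            raise ValidationError("every q must satisfy 0 <= q <= 1")
        object.__setattr__(self, "q", q)

    # -- indexing helpers -------------------------------------------------

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.min_age, self.max_age + 1)

    def _age_index(self, age) -> int:
        if age < self.min_age or age > self.max_age:
            raise TableLookupError(
                f"age {age} outside table range [{self.min_age}, {self.max_age}]"
            )
        return int(age) - self.min_age

    def _year_index(self, year) -> int:
        if self.period_only:
            return 0
        if year is None:
            raise TableLookupError("year required for a year-specific life table")
        if year < self.min_year or year > self.max_year:
            raise TableLookupError(
                f"calendar year {year} outside table range [{self.min_year}, {self.max_year}]"
            )
        return int(year) - self.min_year

    # -- vectorized access (internal fast paths) --------------------------

    def q_bulk(self, sex_idx: np.ndarray, ages: np.ndarray, years: np.ndarray | None) -> np.ndarray:
        """Vectorized q lookup; raises if any key is out of range."""
        ages = np.asarray(ages)
        if ages.min() < self.min_age or ages.max() > self.max_age:
            bad = ages[(ages < self.min_age) | (ages > self.max_age)][0]
            raise TableLookupError(
                f"age {bad} outside table range [{self.min_age}, {self.max_age}]"
            )
        if self.period_only:
            yidx = np.zeros(len(ages), dtype=int)
        else:
            years = np.asarray(years)
            if years.min() < self.min_year or years.max() > self.max_year:
                bad = years[(years < self.min_year) | (years > self.max_year)][0]
                raise TableLookupError(
                    f"calendar year {bad} outside table range [{self.min_year}, {self.max_year}]"
                )
            yidx = years - self.min_year
        return self.q[sex_idx, ages - self.min_age, yidx]

    def _log_survival_prefix(self, sex_idx: int) -> np.ndarray:
        """Per-sex prefix sums of log(1 - q) over ages (period-only tables).

        Entry j is sum of log(1 - q) for ages min_age..min_age+j-1, with a
        leading zero, so cumulative survival over [a0, a0+n-1] is
        exp(L[a0+n-min_age] - L[a0-min_age]).
        """
        if sex_idx not in self._log_surv:
            with np.errstate(divide="ignore"):
                logs = np.log1p(-self.q[sex_idx, :, 0])
            self._log_surv[sex_idx] = np.concatenate([[0.0], np.cumsum(logs)])
        return self._log_surv[sex_idx]


# -- operations -----------------------------------------------------------


def death_prob(lt: LifeTable, sex, age: int, year: int | None = None) -> float:
    """The stored q for (sex, age, year); the year is ignored for period-only tables."""
    s = SEXES.index(normalize_sex(sex))
    return float(lt.q[s, lt._age_index(age), lt._year_index(year)])


def cumulative_survival(
    lt: LifeTable, sex, baseline_age: int, baseline_year: int | None, n_years: int
) -> float:
    """Probability of surviving ``n_years`` consecutive calendar years.

    Returns the product of (1 - q_i) for i = 1..n_years along the
    trajectory (baseline_age + i - 1, baseline_year + i - 1); 1.0 when
    ``n_years`` is 0.
    """
    if n_years < 0:
        raise ContractError("n_years must be >= 0")
    s = SEXES.index(normalize_sex(sex))
    prod = 1.0
    for i in range(int(n_years)):
        a = lt._age_index(baseline_age + i)
        y = lt._year_index(None if lt.period_only else baseline_year + i)
        prod *= 1.0 - lt.q[s, a, y]
    return prod


def survival_bulk(
    lt: LifeTable,
    sex_idx: np.ndarray,
    baseline_age: np.ndarray,
    baseline_year: np.ndarray | None,
    n_years: np.ndarray,
) -> np.ndarray:
    """Vectorized cumulative survival for many subjects.

    Period-only tables use per-sex log-survival prefix sums (O(1) per
    subject); year-specific tables fall back to the per-subject product.
    Agrees with :func:`cumulative_survival` to floating-point rounding.
    """
    sex_idx = np.asarray(sex_idx, dtype=int)
    baseline_age = np.asarray(baseline_age, dtype=int)
    n_years = np.asarray(n_years, dtype=int)
    if (n_years < 0).any():
        raise ContractError("n_years must be >= 0")
    if lt.period_only:
        last_age = baseline_age + n_years - 1
        live = n_years > 0
        if live.any():
            amin, amax = baseline_age[live].min(), last_age[live].max()
            if amin < lt.min_age or amax > lt.max_age:
                raise TableLookupError(
                    f"trajectory ages [{amin}, {amax}] leave table range "
                    f"[{lt.min_age}, {lt.max_age}]"
                )
        out = np.ones(len(sex_idx))
        for s in (0, 1):
            mask = live & (sex_idx == s)
            if not mask.any():
                continue
            L = lt._log_survival_prefix(s)
            lo = baseline_age[mask] - lt.min_age
            hi = lo + n_years[mask]
            out[mask] = np.exp(L[hi] - L[lo])
        return out
    baseline_year = np.asarray(baseline_year, dtype=int)
    return np.array(
        [
            cumulative_survival(lt, SEXES[s], a, y, n)
            for s, a, y, n in zip(sex_idx, baseline_age, baseline_year, n_years)
        ]
    )


def generate_gompertz_life_table(
    alpha_f: float,
    alpha_m: float,
    beta: float,
    age_range: tuple[int, int],
    year_range: tuple[int, int] | None = None,
    cap: float = 1.0,
) -> LifeTable:
    """Synthetic Gompertz table: q(sex, a) = min(cap, alpha_sex * exp(beta * a)).

    Year-invariant; when ``year_range`` is given the same period is
    replicated over the declared calendar years, otherwise the table is
    period-only.
    """
    if alpha_f <= 0 or alpha_m <= 0 or beta <= 0:
        raise ConfigError("Gompertz alpha and beta must be positive")
    if not 0 < cap <= 1:
        raise ConfigError("cap must be in (0, 1]")
    lo, hi = int(age_range[0]), int(age_range[1])
    if hi < lo:
        raise ConfigError("age_range must be increasing")
    ages = np.arange(lo, hi + 1)
    qs = np.stack(
        [np.minimum(cap, alpha * np.exp(beta * ages)) for alpha in (alpha_f, alpha_m)]
    )
    if year_range is None:
        q = qs[:, :, None]
        return LifeTable(q, lo, hi, None, None, period_only=True)
    y0, y1 = int(year_range[0]), int(year_range[1])
    if y1 < y0:
        raise ConfigError("year_range must be increasing")
    q = np.repeat(qs[:, :, None], y1 - y0 + 1, axis=2)
    return LifeTable(q, lo, hi, y0, y1, period_only=False)


# -- text IO --------------------------------------------------------------

_CANONICAL_COLS = ("sex", "age", "year", "qx")


def _resolve_columns(columns, dialect):
    """Map canonical names to actual file columns (case-insensitive)."""
    lower = {c.lower(): c for c in columns}
    resolved = {}
    dialect = dict(dialect or {})
    for canon in _CANONICAL_COLS:
        if canon in dialect:
            name = dialect[canon]
            if name is not None and name not in columns:
                raise SchemaError(f"dialect maps {canon!r} to missing column {name!r}")
            resolved[canon] = name
        else:
            aliases = [canon] if canon != "qx" else ["qx", "q", "prob", "death_prob"]
            resolved[canon] = next((lower[a] for a in aliases if a in lower), None)
    for required in ("sex", "age", "qx"):
        if resolved[required] is None:
            raise SchemaError(
                f"life-table file lacks a column for {required!r} "
                f"(available: {list(columns)})"
            )
    return resolved


def read_life_table(path, dialect: dict | None = None, delimiter: str | None = None) -> LifeTable:
    """Read a delimited life-table file into a validated :class:`LifeTable`.

    The file must have a header row with columns resolvable to sex, age,
    qx and optionally year (``dialect`` maps canonical names to the
    file's, e.g. ``{"age": "Age", "qx": "qx"}`` for HMD-style exports).
    A file without a year column yields a period-only table.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"life-table file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    cols = _resolve_columns(df.columns, dialect)
    has_year = cols["year"] is not None

    sex = df[cols["sex"]].map(normalize_sex)
    age = pd.to_numeric(df[cols["age"]], errors="raise").astype(int)
    q = pd.to_numeric(df[cols["qx"]], errors="coerce")
    if q.isna().any():
        row = int(q.index[q.isna()][0])
        raise ValidationError(f"row {row}: q value {df[cols['qx']][row]!r} is not a number")
    bad = (q < 0) | (q > 1)
    if bad.any():
        row = int(q.index[bad][0])
        raise ValidationError(
            f"row {row}: q = {q[row]} outside [0, 1] "
            f"(sex={sex[row]}, age={age[row]})"
        )
    keys = pd.DataFrame({"sex": sex, "age": age})
    if has_year:
        keys["year"] = pd.to_numeric(df[cols["year"]], errors="raise").astype(int)
    dup = keys.duplicated()
    if dup.any():
        row = int(keys.index[dup][0])
        raise ValidationError(f"row {row}: duplicate key {tuple(keys.iloc[row])}")

    min_age, max_age = int(age.min()), int(age.max())
    n_ages = max_age - min_age + 1
    if has_year:
        min_year, max_year = int(keys["year"].min()), int(keys["year"].max())
        n_years = max_year - min_year + 1
    else:
        min_year = max_year = None
        n_years = 1
    arr = np.full((2, n_ages, n_years), np.nan)
    sidx = sex.map({"f": 0, "m": 1}).to_numpy()
    yidx = (keys["year"].to_numpy() - min_year) if has_year else np.zeros(len(df), dtype=int)
    arr[sidx, age.to_numpy() - min_age, yidx] = q.to_numpy()
    if np.isnan(arr).any():
        s, a, y = (int(v[0]) for v in np.nonzero(np.isnan(arr)))
        where = f"sex={SEXES[s]}, age={a + min_age}"
        if has_year:
            where += f", year={y + min_year}"
        raise ValidationError(f"non-contiguous table: missing entry for ({where})")
    return LifeTable(arr, min_age, max_age, min_year, max_year, period_only=not has_year)


def write_life_table(lt: LifeTable, path, delimiter: str = ",") -> None:
    """Write the table back out (sex, age, [year], qx; 10 significant digits)."""
    rows = []
    for s, sex in enumerate(SEXES):
        for ai, a in enumerate(lt.ages):
            for yi in range(lt.q.shape[2]):
                rec = {"sex": sex, "age": a}
                if not lt.period_only:
                    rec["year"] = lt.min_year + yi
                rec["qx"] = f"{lt.q[s, ai, yi]:.10g}"
                rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
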