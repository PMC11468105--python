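"""RPD computation, censoring imputation and the logit transform."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpdtree import (
    ContractError,
    LifeTable,
    compute_cohort_rpd,
    compute_rpd,
    impute_rpd_censored,
    logit_transform,
)
from tests.conftest import make_subject


def period_table(qs, min_age=60):
    """Period-only table with the given per-age q for both sexes."""
    q = np.tile(np.asarray(qs, dtype=float)[None, :, None], (2, 1, 1))
    return LifeTable(q, min_age, min_age + len(qs) - 1, None, None, period_only=True)


class TestComputeRpd:
    def test_worked_example(self, worked_example_table, worked_example_subject):
        rec = compute_rpd(worked_example_subject, worked_example_table)
        assert rec.rpd == pytest.approx(0.80, abs=1e-12)
        assert rec.n_years == 2
        assert not rec.imputed
        assert rec.lrpd == pytest.approx(math.log(4), abs=1e-9)

    def test_zero_hazard_gives_one(self):
        lt = period_table([0.0] * 10)
        rec = compute_rpd(make_subject(age=60, year=2000, death=2004), lt)
        assert rec.rpd == 1.0
        assert math.isnan(rec.lrpd)  # reported unrepresentable, not clamped

    def test_constant_half(self):
        lt = period_table([0.5] * 10)
        rec = compute_rpd(make_subject(age=60, year=2000, death=2002), lt)
        assert rec.rpd == pytest.approx(0.125)
        assert rec.n_years == 3

    def test_death_in_baseline_year_is_one_factor(self):
        lt = period_table([0.2] * 5)
        rec = compute_rpd(make_subject(age=60, year=2000, death=2000), lt)
        assert rec.n_years == 1
        assert rec.rpd == pytest.approx(0.8)

    def test_alive_subject_rejected(self):
        lt = period_table([0.1] * 5)
        with pytest.raises(ContractError, match="impute"):
            compute_rpd(make_subject(death=None), lt)

    def test_agrees_with_yearly_product_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            qs = rng.uniform(0, 0.4, size=30)
            lt = period_table(qs)
            age0 = int(rng.integers(60, 75))
            dy = int(rng.integers(0, 10))
            s = make_subject(age=age0, year=2000, death=2000 + dy, end=2015)
            expected = 1.0
            for i in range(dy + 1):
                expected *= 1 - qs[age0 - 60 + i]
            assert compute_rpd(s, lt).rpd == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_in_death_year(self):
        lt = period_table(np.linspace(0.05, 0.4, 20))
        rpds = [
            compute_rpd(make_subject(age=60, year=2000, death=2000 + d, end=2015), lt).rpd
            for d in range(10)
        ]
        assert all(a > b for a, b in zip(rpds, rpds[1:]))


class TestImputation:
    def test_cumulative_times_half(self):
        # hand-multiplied 5-year product
        qs = [0.1, 0.2, 0.05, 0.3, 0.15]
        lt = period_table(qs)
        s = make_subject(age=60, year=2000, death=None, end=2004)
        rec = impute_rpd_censored(s, lt)
        hand = (1 - 0.1) * (1 - 0.2) * (1 - 0.05) * (1 - 0.3) * (1 - 0.15)
        assert rec.rpd == pytest.approx(hand * 0.5, rel=1e-12)
        assert rec.imputed and rec.n_years == 5

    def test_zero_hazard_gives_half(self):
        lt = period_table([0.0] * 10)
        rec = impute_rpd_censored(make_subject(age=60, year=2000, death=None, end=2005), lt)
        assert rec.rpd == 0.5

    def test_below_same_trajectory_final_year_death(self):
        lt = period_table([0.1] * 10)
        alive = impute_rpd_censored(make_subject(age=60, year=2000, death=None, end=2005), lt)
        dead = compute_rpd(make_subject(age=60, year=2000, death=2005, end=2005), lt)
        assert alive.rpd < dead.rpd

    def test_final_year_variant(self):
        qs = [0.1, 0.2, 0.05, 0.3, 0.15]
        lt = period_table(qs)
        s = make_subject(age=60, year=2000, death=None, end=2004)
        rec = impute_rpd_censored(s, lt, variant="final_year")
        assert rec.rpd == pytest.approx((1 - 0.15) * 0.5, rel=1e-12)

    def test_dead_subject_rejected(self):
        lt = period_table([0.1] * 5)
        with pytest.raises(ContractError):
            impute_rpd_censored(make_subject(death=2002, year=2000, age=60), lt)


class TestLogit:
    def test_symmetry_point(self):
        assert logit_transform(0.5) == 0.0

    def test_closed_form(self):
        assert logit_transform(0.8) == pytest.approx(math.log(4), rel=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(deadline=None, derandomize=True)
    def test_antisymmetry(self, p):
        assert logit_transform(p) == pytest.approx(-logit_transform(1 - p), abs=1e-9)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.1])
    def test_domain_errors(self, p):
        with pytest.raises(ContractError):
            logit_transform(p)


class TestCohort:
    def test_singleton_summary(self):
        lt = period_table([0.2] * 5)
        recs, summ = compute_cohort_rpd([make_subject(age=60, year=2000, death=2001)], lt)
        assert summ.n == 1
        assert summ.mean_rpd == pytest.approx(recs[0].rpd)
        assert summ.sd_rpd == 0.0

    def test_replication_invariance(self):
        lt = period_table(np.linspace(0.05, 0.3, 15))
        subjects = [
            make_subject(sid=f"a{i}", age=60 + i, year=2000, death=2000 + i, end=2010)
            for i in range(5)
        ]
        doubled = subjects + [
            make_subject(sid=f"b{i}", age=60 + i, year=2000, death=2000 + i, end=2010)
            for i in range(5)
        ]
        _, s1 = compute_cohort_rpd(subjects, lt)
        _, s2 = compute_cohort_rpd(doubled, lt)
        assert s1.mean_rpd == pytest.approx(s2.mean_rpd)
        assert s1.sd_rpd == pytest.approx(s2.sd_rpd)

    def test_mixed_dead_and_censored(self):
        lt = period_table([0.1] * 12)
        subjects = [
            make_subject(sid="d", age=60, year=2000, death=2003, end=2009),
            make_subject(sid="c", age=60, year=2000, death=None, end=2009),
        ]
        recs, summ = compute_cohort_rpd(subjects, lt)
        assert summ.n_imputed == 1
        by_id = {r.subject_id: r for r in recs}
        assert by_id["c"].imputed and not by_id["d"].imputed
        assert by_id["c"].rpd == pytest.approx(0.9**10 * 0.5, rel=1e-12)

    def test_vectorized_matches_scalar_path(self):
        # period-only cohorts take a prefix-sum fast path; must agree
        lt = period_table(np.linspace(0.02, 0.35, 40))
        rng = np.random.default_rng(5)
        subjects = []
        for i in range(60):
            age = int(rng.integers(60, 80))
            dead = rng.random() < 0.9
            dy = 2000 + int(rng.integers(0, 15)) if dead else None
            subjects.append(
                make_subject(sid=f"s{i}", sex="fm"[i % 2], age=age, year=2000, death=dy, end=2014)
            )
        recs, _ = compute_cohort_rpd(subjects, lt)
        for r, s in zip(recs, subjects):
            if s.death_year is not None:
                ref = compute_rpd(s, lt)
            else:
                ref = impute_rpd_censored(s, lt)
            assert r.rpd == pytest.approx(ref.rpd, rel=1e-12)
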