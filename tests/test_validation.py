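import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brisk.errors import InputError, UndefinedStatisticError
from brisk.validation import (
    DEFAULT_AGE_BANDS,
    FIVE_YEAR_SCHEME,
    LIFETIME_SCHEME,
    CalibrationBand,
    CalibrationResult,
    ReclassificationTable,
    ScoredSubject,
    auc,
    build_reclass_table,
    calibration_eo,
    categorize,
    delong_compare,
    nri,
    or_per_sd,
    proportion_above,
)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation paths)
# ---------------------------------------------------------------------------


def brute_auc(cases, controls):
    total = 0.0
    for x in cases:
        for y in controls:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(cases) * len(controls))


def brute_nri_arm(matrix):
    up = down = n = 0
    k = len(matrix)
    for i in range(k):
        for j in range(k):
            c = matrix[i][j]
            n += c
            if j > i:
                up += c
            elif j < i:
                down += c
    return up, down, n


def brute_delong(xo, xn, yo, yn):
    """Placement values by explicit pair counting, covariance by hand."""

    def psi(a, b):
        return 1.0 if a > b else (0.5 if a == b else 0.0)

    m, n = len(xo), len(yo)
    out = {}
    for tag, (x, y) in {"o": (xo, yo), "n": (xn, yn)}.items():
        v10 = np.array([np.mean([psi(xi, yj) for yj in y]) for xi in x])
        v01 = np.array([np.mean([psi(xi, yj) for xi in x]) for yj in y])
        out[tag] = (v10.mean(), v10, v01)
    s10 = np.cov(np.vstack([out["o"][1], out["n"][1]]), ddof=1)
    s01 = np.cov(np.vstack([out["o"][2], out["n"][2]]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    return out["o"][0], out["n"][0], var


# ---------------------------------------------------------------------------
# Categorization
# ---------------------------------------------------------------------------


class TestCategorize:
    @pytest.mark.parametrize(
        "risk, scheme, label",
        [
            (0.0167, FIVE_YEAR_SCHEME, ">= 1.67 to < 3%"),
            (0.0099, FIVE_YEAR_SCHEME, "< 1%"),
            (0.01, FIVE_YEAR_SCHEME, ">= 1 to < 1.67%"),
            (0.20, LIFETIME_SCHEME, ">= 20 to < 25%"),
            (0.25, LIFETIME_SCHEME, ">= 25%"),
            (0.0, LIFETIME_SCHEME, "< 6%"),
        ],
    )
    def test_left_closed_intervals(self, risk, scheme, label):
        assert scheme.labels[categorize(risk, scheme)] == label

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(x=st.floats(0, 1), y=st.floats(0, 1))
    def test_monotone(self, x, y):
        lo, hi = sorted([x, y])
        assert categorize(lo, FIVE_YEAR_SCHEME) <= categorize(hi, FIVE_YEAR_SCHEME)

    def test_out_of_range_risk_rejected(self):
        with pytest.raises(InputError):
            categorize(1.5, FIVE_YEAR_SCHEME)


# ---------------------------------------------------------------------------
# Reclassification tables and NRI
# ---------------------------------------------------------------------------


def subject(i, case, old, new):
    return ScoredSubject(
        id=str(i), is_case=case, age=60.0, scores={"old": old, "new": new}
    )


class TestReclassTable:
    def test_concentrated_cell(self):
        subs = [subject(i, False, 0.005, 0.02) for i in range(3)]
        t = build_reclass_table(subs, "old", "new", FIVE_YEAR_SCHEME)
        assert t.controls[0, 2] == 3 and t.controls.sum() == 3
        assert t.cases.sum() == 0

    def test_totals_conserved_and_matches_brute_force(self, rng):
        subs = [
            subject(i, bool(rng.integers(2)), float(rng.random() * 0.05), float(rng.random() * 0.05))
            for i in range(50)
        ]
        t = build_reclass_table(subs, "old", "new", FIVE_YEAR_SCHEME)
        assert t.n_cases + t.n_controls == 50
        k = FIVE_YEAR_SCHEME.n_categories
        expect_cases = np.zeros((k, k), dtype=int)
        expect_ctrls = np.zeros((k, k), dtype=int)
        for s in subs:
            i = categorize(s.scores["old"], FIVE_YEAR_SCHEME)
            j = categorize(s.scores["new"], FIVE_YEAR_SCHEME)
            (expect_cases if s.is_case else expect_ctrls)[i, j] += 1
        assert np.array_equal(t.cases, expect_cases)
        assert np.array_equal(t.controls, expect_ctrls)

    def test_missing_score_raises_unless_dropped(self):
        s = ScoredSubject(id="x", is_case=True, age=60.0, scores={"old": 0.02})
        with pytest.raises(InputError, match="missing score"):
            build_reclass_table([s], "old", "new", FIVE_YEAR_SCHEME)
        t = build_reclass_table([s], "old", "new", FIVE_YEAR_SCHEME, drop_missing=True)
        assert t.cases.sum() == 0


class TestNri:
    def test_diagonal_table_is_null(self):
        m = np.diag([5, 6, 7, 8]).astype(np.int64)
        t = ReclassificationTable(m, m, FIVE_YEAR_SCHEME)
        r = nri(t)
        assert r.overall == 0.0 and r.case_improvement == 0.0

    def test_identities(self, rng):
        m1 = rng.integers(0, 30, size=(4, 4))
        m2 = rng.integers(0, 30, size=(4, 4))
        r = nri(ReclassificationTable(m1, m2, FIVE_YEAR_SCHEME))
        assert r.overall == pytest.approx(
            r.case_improvement + r.control_improvement, abs=1e-12
        )
        assert r.se_overall**2 == pytest.approx(
            r.se_case**2 + r.se_control**2, abs=1e-12
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        cells=st.lists(st.integers(0, 40), min_size=32, max_size=32),
    )
    def test_matches_brute_force_enumeration(self, cells):
        m1 = np.array(cells[:16], dtype=np.int64).reshape(4, 4) + np.eye(4, dtype=np.int64)
        m2 = np.array(cells[16:], dtype=np.int64).reshape(4, 4) + np.eye(4, dtype=np.int64)
        r = nri(ReclassificationTable(m1, m2, FIVE_YEAR_SCHEME))
        uc, dc, n_c = brute_nri_arm(m1.tolist())
        uk, dk, n_k = brute_nri_arm(m2.tolist())
        assert r.case_improvement == pytest.approx((uc - dc) / n_c, abs=1e-15)
        assert r.control_improvement == pytest.approx(-(uk - dk) / n_k, abs=1e-15)
        p_u, p_d = uc / n_c, dc / n_c
        assert r.se_case == pytest.approx(
            math.sqrt((p_u + p_d - (p_u - p_d) ** 2) / n_c), abs=1e-15
        )

    def test_empty_arm_rejected(self):
        z = np.zeros((4, 4), dtype=np.int64)
        m = np.ones((4, 4), dtype=np.int64)
        with pytest.raises(UndefinedStatisticError):
            nri(ReclassificationTable(m, z, FIVE_YEAR_SCHEME))


class TestProportionAbove:
    def test_rows_and_columns(self):
        cases = np.array([[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1], [0, 0, 0, 4]], dtype=np.int64)
        t = ReclassificationTable(cases, cases, FIVE_YEAR_SCHEME)
        # new model (columns) at/above 1.67%: col 2 + col 3 = 2 + 5
        assert proportion_above(t, 0.0167, "case", "new") == pytest.approx(7 / 10)
        # old model (rows) at/above 3%: bottom row
        assert proportion_above(t, 0.03, "case", "old") == pytest.approx(4 / 10)

    def test_non_edge_threshold_rejected(self):
        t = ReclassificationTable(
            np.ones((4, 4), dtype=np.int64), np.ones((4, 4), dtype=np.int64), FIVE_YEAR_SCHEME
        )
        with pytest.raises(InputError, match="edge"):
            proportion_above(t, 0.02, "case", "new")


# ---------------------------------------------------------------------------
# AUC / DeLong
# ---------------------------------------------------------------------------


class TestAuc:
    def test_complete_separation(self):
        assert auc([2, 3], [1]).auc == 1.0

    def test_identical_arms_give_half(self):
        assert auc([1, 2, 3], [1, 2, 3]).auc == 0.5

    def test_hand_example(self):
        assert auc([1, 3], [2, 4]).auc == 0.25

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        cases=st.lists(st.integers(0, 10), min_size=1, max_size=60),
        controls=st.lists(st.integers(0, 10), min_size=1, max_size=60),
    )
    def test_equals_exhaustive_pair_counting(self, cases, controls):
        assert auc(cases, controls).auc == pytest.approx(
            brute_auc(cases, controls), abs=1e-12
        )

    def test_empty_arm_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            auc([], [1.0])


class TestDelong:
    def test_identical_models_null(self):
        x = [0.1, 0.4, 0.35, 0.8]
        y = [0.05, 0.3, 0.2]
        r = delong_compare(x, x, y, y)
        assert r.chi2 == 0.0 and r.p_value == 1.0

    def test_reported_aucs_match_auc_function(self, rng):
        xo, xn = rng.random(20), rng.random(20)
        yo, yn = rng.random(30), rng.random(30)
        r = delong_compare(xo, xn, yo, yn)
        assert r.auc_old == pytest.approx(auc(xo, yo).auc, abs=1e-12)
        assert r.auc_new == pytest.approx(auc(xn, yn).auc, abs=1e-12)

    def test_variance_matches_placement_oracle(self, rng):
        for _ in range(5):
            xo, xn = rng.random(10), rng.random(10)
            yo, yn = rng.random(12), rng.random(12)
            r = delong_compare(xo, xn, yo, yn)
            a_o, a_n, var = brute_delong(xo, xn, yo, yn)
            assert r.auc_old == pytest.approx(a_o, abs=1e-10)
            assert r.var_delta == pytest.approx(var, abs=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        xo, xn = rng.random(25), rng.random(25)
        yo, yn = rng.random(40), rng.random(40)
        r1 = delong_compare(xo, xn, yo, yn)
        f = lambda v: np.log(np.asarray(v) + 1.0) ** 3
        r2 = delong_compare(f(xo), f(xn), f(yo), f(yn))
        assert r1.chi2 == pytest.approx(r2.chi2, rel=1e-9)

    def test_unpaired_input_rejected(self):
        with pytest.raises(InputError):
            delong_compare([1, 2], [1], [3, 4], [3, 4])


# ---------------------------------------------------------------------------
# OR per SD
# ---------------------------------------------------------------------------


class TestOrPerSd:
    def test_null_association_covers_one(self, rng):
        scores = rng.random(2000)
        status = rng.integers(0, 2, 2000).astype(bool)
        r = or_per_sd(scores, status)
        assert r.ci_low < 1.0 < r.ci_high

    def test_scale_invariance(self, rng):
        scores = rng.random(500)
        status = scores + rng.normal(0, 0.5, 500) > 0.7
        r1 = or_per_sd(scores, status)
        r2 = or_per_sd(scores * 10, status)
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio, rel=1e-6)

    def test_recovers_designed_log_odds(self, rng):
        """Logistic data with per-unit log-OR beta: estimated OR per control
        SD should sit within 2 SE of exp(beta * sd_controls)."""
        beta, n = 0.8, 8000
        x = rng.normal(0, 1.0, n)
        p = 1 / (1 + np.exp(-(-0.5 + beta * x)))
        y = rng.random(n) < p
        r = or_per_sd(x, y)
        sd = np.std(x[~y], ddof=1)
        target = math.exp(beta * sd)
        log_se = (math.log(r.ci_high) - math.log(r.ci_low)) / (2 * 1.96)
        assert abs(math.log(r.odds_ratio) - math.log(target)) < 2 * log_se

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            or_per_sd([1.0, 2.0], [True, True])
        with pytest.raises(UndefinedStatisticError):
            or_per_sd([1.0, 1.0, 2.0], [False, False, True])


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


class TestCalibration:
    def make_controls(self, rng, n=400):
        return [
            ScoredSubject(
                id=str(i),
                is_case=False,
                age=float(rng.uniform(40, 79)),
                scores={"m": float(rng.uniform(0.005, 0.05))},
            )
            for i in range(n)
        ]

    def pop_risk(self):
        return {label: 0.02 for label, _, _ in DEFAULT_AGE_BANDS}

    def test_observed_equals_expected_gives_unit_ratio(self):
        bands = [CalibrationBand("a", 10, 5.0, 5.0), CalibrationBand("b", 20, 7.5, 7.5)]
        assert CalibrationResult.from_bands(bands).ratio == 1.0

    def test_totals_are_column_sums(self, rng):
        res = calibration_eo(self.make_controls(rng), "m", self.pop_risk())
        assert res.expected == pytest.approx(sum(b.expected for b in res.bands))
        assert res.observed == pytest.approx(sum(b.observed for b in res.bands))
        assert res.ratio == pytest.approx(res.expected / res.observed)

    def test_permutation_invariant(self, rng):
        controls = self.make_controls(rng)
        r1 = calibration_eo(controls, "m", self.pop_risk())
        r2 = calibration_eo(list(reversed(controls)), "m", self.pop_risk())
        assert r1.ratio == r2.ratio and r1.ci_low == r2.ci_low

    def test_ci_symmetric_in_log_space(self, rng):
        res = calibration_eo(self.make_controls(rng), "m", self.pop_risk())
        assert res.ci_low * res.ci_high == pytest.approx(res.ratio**2, rel=1e-9)

    def test_empty_band_skipped_with_warning(self, rng):
        controls = [s for s in self.make_controls(rng) if s.age >= 50]
        with pytest.warns(UserWarning, match="empty"):
            res = calibration_eo(controls, "m", self.pop_risk())
        assert all(b.label not in ("< 45", "45-49") for b in res.bands)

    def test_median_not_mean(self, rng):
        """A single extreme score in a band must not move the expected count
        (the band median is robust to the right tail)."""
        controls = self.make_controls(rng, n=100)
        res1 = calibration_eo(controls, "m", self.pop_risk())
        controls[0].scores["m"] = 0.9  # one outlier
        res2 = calibration_eo(controls, "m", self.pop_risk())
        assert abs(res1.expected - res2.expected) < 1.0
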