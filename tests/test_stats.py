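"""Onset/precedence rules, Pearson chi-square and the two-way ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from betasleep.errors import (
    DegenerateTableError,
    DesignError,
    InputSizeError,
    JoinError,
)
from betasleep.io import ClaspingRecord
from betasleep.stats import (
    beta_onset_age,
    chi_square_2x2,
    precedence_summary,
    presence_contingency,
    two_way_anova,
)


class TestBetaOnset:
    @pytest.mark.parametrize(
        "sessions,expected",
        [
            ([(9, False), (13, False), (17, True), (22, True)], 17.0),
            ([(9, False), (13, False)], None),
            ([(9, True), (13, False), (17, True)], 9.0),  # first detection, no persistence
        ],
    )
    def test_first_detection_rule(self, sessions, expected):
        assert beta_onset_age(sessions) == expected

    def test_empty_and_unordered_inputs_rejected(self):
        with pytest.raises(InputSizeError):
            beta_onset_age([])
        with pytest.raises(InputSizeError):
            beta_onset_age([(13, False), (9, True)])


class TestPrecedence:
    def test_hand_computed_example(self):
        onsets = {"a": 10.0, "b": 12.0}
        clasping = [
            ClaspingRecord("a", [(10, False), (16, True)]),
            ClaspingRecord("b", [(12, False), (20, True)]),
        ]
        summary = precedence_summary(onsets, clasping)
        assert list(summary.per_mouse["precedence_weeks"]) == [6.0, 8.0]
        assert summary.mean_weeks == 7.0
        assert summary.n_beta_first == 2 and summary.n_clasp_first == 0

    def test_ties_count_as_neither(self):
        onsets = {"a": 10.0, "b": 14.0}
        clasping = [
            ClaspingRecord("a", [(10, True)]),
            ClaspingRecord("b", [(14, True)]),
        ]
        summary = precedence_summary(onsets, clasping)
        assert summary.mean_weeks == 0.0
        assert summary.n_beta_first == 0 and summary.n_clasp_first == 0
        assert summary.n_tied == 2

    def test_missing_clasping_record_raises(self):
        with pytest.raises(JoinError):
            precedence_summary({"a": 10.0}, [])

    def test_mouse_without_beta_is_listed_but_excluded(self):
        onsets = {"a": 10.0, "b": None}
        clasping = [ClaspingRecord("a", [(16, True)])]
        summary = precedence_summary(onsets, clasping)
        assert len(summary.per_mouse) == 2
        assert summary.per_mouse["precedence_weeks"].notna().sum() == 1


class TestChiSquare:
    def test_genotype_split_gives_eighteen(self):
        stat, df, p = chi_square_2x2([[10, 0], [0, 8]])
        assert stat == 18.0
        assert df == 1
        assert p < 1e-4

    def test_independence_gives_zero(self):
        stat, _, p = chi_square_2x2([[5, 5], [5, 5]])
        assert stat == 0.0 and p == 1.0

    def test_hand_formula_example(self):
        stat, _, _ = chi_square_2x2([[6, 4], [2, 8]])
        assert np.isclose(stat, 10.0 / 3.0)

    def test_matches_scipy_without_correction(self, rng):
        for _ in range(20):
            table = rng.integers(1, 30, size=(2, 2))
            stat, _, p = chi_square_2x2(table)
            ref = sstats.chi2_contingency(table, correction=False)
            assert np.isclose(stat, ref.statistic)
            assert np.isclose(p, ref.pvalue)

    def test_invariant_to_transposition_and_swaps(self):
        t = np.array([[7, 3], [2, 9]])
        base = chi_square_2x2(t)[0]
        assert np.isclose(chi_square_2x2(t.T)[0], base)
        assert np.isclose(chi_square_2x2(t[::-1])[0], base)
        assert np.isclose(chi_square_2x2(t[:, ::-1])[0], base)

    def test_zero_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            chi_square_2x2([[0, 0], [3, 4]])


def _rss(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def anova_by_model_comparison(y, a, b):
    """Independent oracle: Type II SS via nested least-squares fits."""
    y = np.asarray(y, dtype=float)
    A = pd.get_dummies(pd.Series(a), drop_first=True).to_numpy(dtype=float)
    B = pd.get_dummies(pd.Series(b), drop_first=True).to_numpy(dtype=float)
    AB = np.column_stack([A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])])
    ones = np.ones((len(y), 1))
    rss_b = _rss(y, np.column_stack([ones, B]))
    rss_a = _rss(y, np.column_stack([ones, A]))
    rss_ab = _rss(y, np.column_stack([ones, A, B]))
    rss_full = _rss(y, np.column_stack([ones, A, B, AB]))
    df_a, df_b = A.shape[1], B.shape[1]
    df_int = AB.shape[1]
    df_resid = len(y) - (1 + df_a + df_b + df_int)
    mse = rss_full / df_resid
    out = {}
    for name, ss, df in [
        ("a", rss_b - rss_ab, df_a),
        ("b", rss_a - rss_ab, df_b),
        ("a:b", rss_ab - rss_full, df_int),
    ]:
        out[name] = {"ss": ss, "F": (ss / df) / mse, "df": df, "df_resid": df_resid}
    return out


class TestTwoWayAnova:
    def test_constant_response_gives_zero_f(self):
        table = two_way_anova([1.0] * 8, ["x", "y"] * 4, ["u", "u", "v", "v"] * 2)
        assert np.all(table["F"] == 0.0)
        assert np.all(table["p"] == 1.0)

    def test_balanced_toy_matches_hand_sums_of_squares(self):
        # 2x2 with n = 3 per cell: closed-form balanced decomposition
        cells = {
            ("g1", "s1"): [1.0, 2.0, 3.0],
            ("g1", "s2"): [4.0, 5.0, 6.0],
            ("g2", "s1"): [3.0, 4.0, 5.0],
            ("g2", "s2"): [9.0, 10.0, 11.0],
        }
        y, a, b = [], [], []
        for (ga, sb), vals in cells.items():
            y += vals
            a += [ga] * 3
            b += [sb] * 3
        y = np.array(y)
        grand = y.mean()
        mean_a = {g: y[np.array(a) == g].mean() for g in ("g1", "g2")}
        mean_b = {s: y[np.array(b) == s].mean() for s in ("s1", "s2")}
        ss_a = sum(6 * (mean_a[g] - grand) ** 2 for g in mean_a)
        ss_b = sum(6 * (mean_b[s] - grand) ** 2 for s in mean_b)
        cell_means = {k: np.mean(v) for k, v in cells.items()}
        ss_cells = sum(3 * (m - grand) ** 2 for m in cell_means.values())
        ss_int = ss_cells - ss_a - ss_b
        ss_err = sum(((np.array(v) - cell_means[k]) ** 2).sum() for k, v in cells.items())
        table = two_way_anova(y, a, b, names=("geno", "state"))
        assert np.isclose(table.loc["geno", "sum_sq"], ss_a, atol=1e-10)
        assert np.isclose(table.loc["state", "sum_sq"], ss_b, atol=1e-10)
        assert np.isclose(table.loc["geno:state", "sum_sq"], ss_int, atol=1e-10)
        assert np.isclose(table.loc["geno", "F"], (ss_a / 1) / (ss_err / 8), atol=1e-10)

    def test_matches_model_comparison_oracle_unbalanced(self, rng):
        n = 60
        a = rng.choice(["g1", "g2"], size=n, p=[0.6, 0.4])
        b = rng.choice(["s1", "s2", "s3"], size=n)
        # make sure every cell is occupied
        a[:6] = ["g1", "g1", "g1", "g2", "g2", "g2"]
        b[:6] = ["s1", "s2", "s3", "s1", "s2", "s3"]
        y = rng.standard_normal(n) + (a == "g2") * 0.8 + (b == "s3") * 0.5
        table = two_way_anova(y, a, b, names=("a", "b"))
        oracle = anova_by_model_comparison(y, a, b)
        for eff, key in [("a", "a"), ("b", "b"), ("a:b", "a:b")]:
            assert np.isclose(table.loc[eff, "sum_sq"], oracle[key]["ss"], rtol=1e-10)
            assert np.isclose(table.loc[eff, "F"], oracle[key]["F"], rtol=1e-10)
            assert table.loc[eff, "df1"] == oracle[key]["df"]
            assert table.loc[eff, "df2"] == oracle[key]["df_resid"]

    def test_type_two_equals_balanced_sequential(self):
        # on a balanced design Type II coincides with the sequential
        # (Type I) decomposition, whichever factor enters first
        rng = np.random.default_rng(3)
        a = np.repeat(["g1", "g2"], 12)
        b = np.tile(np.repeat(["s1", "s2", "s3"], 4), 2)
        y = rng.standard_normal(24) + (a == "g2") * 1.0
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = pd.DataFrame({"y": y, "a": a, "b": b})
        seq = sm.stats.anova_lm(smf.ols("y ~ C(a) * C(b)", df).fit(), typ=1)
        table = two_way_anova(y, a, b, names=("a", "b"))
        assert np.isclose(table.loc["a", "sum_sq"], seq.loc["C(a)", "sum_sq"], rtol=1e-10)
        assert np.isclose(table.loc["b", "sum_sq"], seq.loc["C(b)", "sum_sq"], rtol=1e-10)

    def test_empty_cell_raises(self):
        a = ["g1", "g1", "g2", "g2"]
        b = ["s1", "s1", "s2", "s2"]  # cells (g1,s2), (g2,s1) empty
        with pytest.raises(DesignError):
            two_way_anova([1.0, 2.0, 3.0, 4.0], a, b)


class TestPresenceContingency:
    def test_any_session_marks_mouse_positive(self):
        table = presence_contingency(
            pd.DataFrame(
                {
                    "mouse_id": ["a", "a", "b", "c"],
                    "genotype": ["R6/1", "R6/1", "R6/1", "WT"],
                    "beta_present": [False, True, False, False],
                }
            )
        )
        assert table.tolist() == [[1, 1], [0, 1]]
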