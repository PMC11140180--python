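"""Repeated-measures ANOVA, Bonferroni pairwise tests and letters."""

import math

import numpy as np
import pandas as pd
import pytest

from placentamri.stats import (
    bin_time_series,
    bonferroni_pairwise,
    compact_letters,
    paired_t,
    rm_anova,
    summarize_cohort,
)


def _long(values: np.ndarray, states=("basal", "TAD1", "TAD2")) -> pd.DataFrame:
    n, k = values.shape
    rows = [
        {"animal_id": f"a{i}", "state": states[j], "variable": "y",
         "value": values[i, j]}
        for i in range(n) for j in range(k)
    ]
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_two_condition_f_equals_paired_t_squared(self, rng):
        x = rng.normal(10, 2, 8)
        y = x + rng.normal(0.5, 1, 8)
        table = _long(np.column_stack([x, y]), states=("basal", "TAD1"))
        res = rm_anova(table, "y")
        t = paired_t(x, y)
        assert res.f == pytest.approx(t.t**2, abs=1e-10)
        assert res.p == pytest.approx(t.p, abs=1e-12)

    def test_all_identical_values_degenerate(self):
        res = rm_anova(_long(np.full((5, 3), 7.0)), "y")
        assert res.degenerate and math.isnan(res.p)
        assert res.ss_error == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_sums_of_squares(self):
        # 4 animals x 3 states; SS terms computed by literal arithmetic
        y = np.array([
            [10.0, 12.0, 11.0],
            [14.0, 15.0, 16.0],
            [9.0, 11.0, 13.0],
            [12.0, 14.0, 12.0],
        ])
        grand = y.sum() / 12.0
        ss_cond = 4 * sum((y[:, j].mean() - grand) ** 2 for j in range(3))
        ss_subj = 3 * sum((y[i, :].mean() - grand) ** 2 for i in range(4))
        ss_tot = sum((y[i, j] - grand) ** 2 for i in range(4) for j in range(3))
        ss_err = ss_tot - ss_cond - ss_subj
        f_hand = (ss_cond / 2) / (ss_err / 6)
        res = rm_anova(_long(y), "y")
        assert res.ss_condition == pytest.approx(ss_cond, rel=1e-12)
        assert res.ss_subject == pytest.approx(ss_subj, rel=1e-12)
        assert res.ss_error == pytest.approx(ss_err, rel=1e-12)
        assert res.f == pytest.approx(f_hand, rel=1e-12)
        assert (res.df1, res.df2) == (2, 6)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = rng.normal(50, 5, (7, 3)) + rng.normal(0, 3, (7, 1))
        table = _long(y)
        mine = rm_anova(table, "y")
        ref = pingouin.rm_anova(
            data=table, dv="value", within="state", subject="animal_id"
        )
        assert mine.f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-8)
        assert mine.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_invariant_to_per_animal_constant(self, rng):
        y = rng.normal(0, 1, (6, 3))
        shifted = y + rng.normal(0, 10, (6, 1))
        assert rm_anova(_long(y), "y").f == pytest.approx(
            rm_anova(_long(shifted), "y").f, rel=1e-9
        )

    def test_incomplete_animal_dropped_with_warning(self, rng):
        table = _long(rng.normal(0, 1, (4, 3)))
        table = table[~((table.animal_id == "a0") & (table.state == "TAD2"))]
        with pytest.warns(UserWarning, match="incomplete"):
            res = rm_anova(table, "y")
        assert res.df2 == 2 * 2  # 3 animals remain


class TestPairedT:
    def test_six_pair_fixture_matches_hand_formula(self):
        x = np.array([5.1, 6.2, 5.8, 7.0, 6.5, 5.9])
        y = np.array([4.8, 6.4, 5.2, 6.1, 6.0, 5.5])
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(6))
        res = paired_t(x, y)
        assert res.t == pytest.approx(t_hand, rel=1e-12)
        assert res.df == 5 and not res.degenerate

    def test_equal_samples_degenerate_zero_t(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t(x, x)
        assert res.degenerate and res.t == 0.0 and res.p == 1.0

    def test_constant_nonzero_difference_infinite_t(self):
        x = np.array([1.0, 2.0, 3.0])
        res = paired_t(x + 0.5, x)
        assert res.degenerate and math.isinf(res.t) and res.p == 0.0


class TestBonferroni:
    def test_identical_paired_samples_adjust_to_one(self):
        y = np.tile([[1.0, 1.0, 1.0]], (5, 1)) + np.arange(5)[:, None]
        pw = bonferroni_pairwise(_long(y), "y")
        assert (pw["p_adj"] == 1.0).all()

    def test_multiplicative_adjustment_and_cap(self, rng):
        y = rng.normal(0, 1, (7, 3))
        pw = bonferroni_pairwise(_long(y), "y")
        assert len(pw) == 3
        for _, r in pw.iterrows():
            assert r["p_adj"] == pytest.approx(min(1.0, 3 * r["p_raw"]), rel=1e-12)
            assert r["p_adj"] >= r["p_raw"]  # never below raw


class TestCompactLetters:
    STATES = ("basal", "TAD1", "TAD2")

    def _pw(self, sig_pairs):
        rows = []
        from itertools import combinations

        for a, b in combinations(self.STATES, 2):
            p = 0.001 if {a, b} in sig_pairs else 0.9
            rows.append({"state_a": a, "state_b": b, "p_adj": p})
        return pd.DataFrame(rows)

    def test_no_differences_single_letter(self):
        letters = compact_letters(self.STATES, self._pw([]))
        assert set(letters.values()) == {"a"}

    def test_one_state_distinct(self):
        letters = compact_letters(
            self.STATES, self._pw([{"basal", "TAD2"}, {"TAD1", "TAD2"}])
        )
        assert letters["basal"] == letters["TAD1"]
        assert set(letters["TAD2"]) & set(letters["basal"]) == set()

    def test_all_distinct(self):
        sig = [{"basal", "TAD1"}, {"basal", "TAD2"}, {"TAD1", "TAD2"}]
        letters = compact_letters(self.STATES, self._pw(sig))
        assert len({v for v in letters.values()}) == 3

    def test_chain_pattern_shares_middle(self):
        # basal != TAD2 but TAD1 indistinguishable from both
        letters = compact_letters(self.STATES, self._pw([{"basal", "TAD2"}]))
        assert set(letters["basal"]) & set(letters["TAD2"]) == set()
        assert set(letters["TAD1"]) & set(letters["basal"])
        assert set(letters["TAD1"]) & set(letters["TAD2"])


class TestSummarize:
    def test_zero_effect_shares_one_letter(self):
        # fixed layout with state means equal and ample within-animal spread
        jitter = np.array([
            [0.4, -0.7, 0.3], [-0.5, 0.6, -0.1], [0.2, 0.1, -0.3],
            [-0.6, -0.2, 0.8], [0.7, 0.3, -1.0], [-0.2, -0.5, 0.7],
            [0.0, 0.4, -0.4],
        ])
        base = np.linspace(45, 55, 7)[:, None]
        rows = [
            {"animal_id": f"a{i}", "state": s, "y": (base + jitter)[i, j]}
            for i in range(7) for j, s in enumerate(self_states())
        ]
        df = pd.DataFrame(rows)
        rep = summarize_cohort(df, ["y"])
        row = rep.iloc[0]
        assert row["letter_basal"] == row["letter_TAD1"] == row["letter_TAD2"]

    def test_injected_effect_gets_distinct_letter(self, rng):
        rows = []
        for i in range(7):
            base = rng.normal(50, 5)
            for s in self_states():
                shift = 10.0 if s == "TAD2" else 0.0
                rows.append({"animal_id": f"a{i}", "state": s,
                             "y": base + shift + rng.normal(0, 1)})
        rep = summarize_cohort(pd.DataFrame(rows), ["y"])
        row = rep.iloc[0]
        assert row["p"] < 0.05
        assert set(row["letter_TAD2"]) & set(row["letter_basal"]) == set()

    def test_report_layout(self, rng):
        rows = [
            {"animal_id": f"a{i}", "state": s, "y": rng.normal(), "z": rng.normal()}
            for i in range(4) for s in self_states()
        ]
        rep = summarize_cohort(pd.DataFrame(rows), ["y", "z"])
        expected_cols = {"variable", "F", "df1", "df2", "p", "degenerate"}
        for s in self_states():
            expected_cols |= {f"mean_{s}", f"sd_{s}", f"letter_{s}"}
        assert set(rep.columns) == expected_cols
        assert list(rep["variable"]) == ["y", "z"]


def self_states():
    return ("basal", "TAD1", "TAD2")


def test_bin_time_series_five_minute_averages():
    t = np.array([0.0, 1.0, 4.9, 5.0, 7.5, 12.0])
    v = np.array([1.0, 2.0, 3.0, 10.0, 20.0, 7.0])
    out = bin_time_series(t, v, 5.0)
    assert list(out["bin_start_min"]) == [0.0, 5.0, 10.0]
    assert out["value"].tolist() == [2.0, 15.0, 7.0]
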