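"""Survival statistics, summary-cell ANOVA and the published table arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from germsoma import (
    SummaryCell,
    SurvivalCohort,
    anova2_from_raw,
    anova2_from_summary,
    chi2_score_test,
    copas_normalize,
    holm_sidak_adjust,
    kinetic_slope,
    km_estimate,
    logrank_pair,
    percent_extension,
)
from germsoma.datasets import (
    extension_cells,
    lifespan_anova_cells,
    load_lifespan_table,
    load_stress_table,
)
from germsoma.phenotype import median_survival


def _cohort(times_a, events_a, times_b=None, events_b=None):
    frames = [
        pd.DataFrame({"time_days": times_a, "event": events_a, "group": "a"})
    ]
    if times_b is not None:
        frames.append(
            pd.DataFrame({"time_days": times_b, "event": events_b, "group": "b"})
        )
    return SurvivalCohort(pd.concat(frames, ignore_index=True))


class TestKaplanMeier:
    def test_three_uncensored_deaths(self):
        km = km_estimate(_cohort([1.0, 2.0, 3.0], [True] * 3), "a")
        assert km.loc[1.0, "S"] == pytest.approx(2.0 / 3.0)
        assert km.loc[2.0, "S"] == pytest.approx(1.0 / 3.0)
        assert km.loc[3.0, "S"] == pytest.approx(0.0)

    def test_all_censored_survival_stays_one(self):
        km = km_estimate(_cohort([2.0, 4.0, 6.0], [False] * 3), "a")
        assert np.allclose(km["S"], 1.0)

    def test_censoring_product_limit_by_hand(self):
        """Times [1, 2+, 3, 4]: S = 3/4 after t=1, then 3/4 * 1/2 = 3/8
        after t=3 (risk set shrank to 2), then 0 after t=4."""
        km = km_estimate(_cohort([1.0, 2.0, 3.0, 4.0], [True, False, True, True]), "a")
        assert km.loc[1.0, "S"] == pytest.approx(0.75)
        assert km.loc[3.0, "S"] == pytest.approx(0.375)
        assert km.loc[4.0, "S"] == pytest.approx(0.0)

    def test_median_survival(self):
        cohort = _cohort([1.0, 2.0, 3.0, 4.0, 5.0], [True] * 5)
        assert median_survival(cohort, "a") == pytest.approx(3.0)

    def test_bad_cohort_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            _cohort([0.0, 1.0], [True, True])
        with pytest.raises(ValueError, match="missing column"):
            SurvivalCohort(pd.DataFrame({"time_days": [1.0], "group": ["a"]}))


class TestLogrank:
    def test_identical_groups_give_chi2_zero(self):
        cohort = _cohort(
            [1.0, 2.0, 3.0], [True] * 3, [1.0, 2.0, 3.0], [True] * 3
        )
        chi2, p = logrank_pair(cohort, "a", "b")
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_permutation_oracle(self):
        """Asymptotic log-rank p against a 10,000-draw label-permutation
        reference on a 40-animal cohort (agreement tolerance 0.05 chosen
        before running)."""
        rng = np.random.default_rng(12)
        ta = rng.gamma(16.0, 1.0, 20)
        tb = rng.gamma(16.0, 1.25, 20)
        cohort = _cohort(ta, [True] * 20, tb, [True] * 20)
        chi2_obs, p_asym = logrank_pair(cohort, "a", "b")

        def _hand_chi2(times, labels):
            # O-E log-rank with hypergeometric variance, all deaths observed
            order = np.argsort(times)
            t_s, g_s = times[order], labels[order]
            uniq = np.unique(t_s)
            o_minus_e, var = 0.0, 0.0
            for u in uniq:
                at_risk = t_s >= u
                n = at_risk.sum()
                n1 = (at_risk & g_s).sum()
                d = (t_s == u).sum()
                d1 = ((t_s == u) & g_s).sum()
                o_minus_e += d1 - d * n1 / n
                if n > 1:
                    var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
            return o_minus_e**2 / var

        times = np.concatenate([ta, tb])
        labels = np.arange(40) < 20
        assert _hand_chi2(times, labels) == pytest.approx(chi2_obs, rel=1e-6)
        perm_rng = np.random.default_rng(13)
        count = 0
        for _ in range(10_000):
            count += _hand_chi2(times, perm_rng.permutation(labels)) >= chi2_obs
        p_perm = count / 10_000
        assert abs(p_perm - p_asym) < 0.05

    def test_no_events_rejected(self):
        cohort = _cohort([1.0, 2.0], [False] * 2, [1.0, 2.0], [False] * 2)
        with pytest.raises(ValueError, match="events"):
            logrank_pair(cohort, "a", "b")


class TestPercentExtension:
    def test_hand_examples(self):
        assert percent_extension(19.94, 15.40) == pytest.approx(29.48)
        assert percent_extension(22.46, 13.99) == pytest.approx(60.54)
        assert percent_extension(10.0, 10.0) == 0.0
        assert percent_extension(5.0, 10.0) == -50.0

    def test_nonpositive_means_rejected(self):
        with pytest.raises(ValueError):
            percent_extension(0.0, 10.0)
        with pytest.raises(ValueError):
            percent_extension(10.0, 0.0)

    @given(st.floats(0.5, 100.0), st.floats(0.5, 100.0))
    def test_inverts_the_ratio(self, a, b):
        e = percent_extension(a, b)
        assert a / b == pytest.approx(1.0 + e / 100.0, abs=0.005 / 100.0 + 1e-12)

    @pytest.mark.parametrize("loader", [load_lifespan_table, load_stress_table])
    def test_published_extensions_recompute(self, loader):
        """Every printed percent extension is reproduced from its printed
        means up to propagated rounding error: the means carry +/-0.005
        each and the printed extension another +/-0.005."""
        cells = extension_cells(loader())
        assert len(cells) > 0
        for _, row in cells.iterrows():
            a, b = row["mean"], row["control_mean"]
            recomputed = percent_extension(a, b)
            bound = 100.0 * 0.005 * (1.0 + a / b) / b + 0.005 + 1e-9
            assert abs(recomputed - row["printed_extension"]) <= bound, (
                row["set"],
                row["strain"],
                recomputed,
            )


class TestSummaryAnova:
    @staticmethod
    def _grid(means, sem=0.5, n=10):
        return [[SummaryCell(m, sem, n) for m in row] for row in means]

    def test_equal_means_give_zero_f(self):
        res = anova2_from_summary(self._grid([[5.0, 5.0], [5.0, 5.0]]))
        assert res.f_a == res.f_b == res.f_interaction == 0.0
        assert res.p_a == res.p_b == res.p_interaction == pytest.approx(1.0)

    def test_additive_means_give_zero_interaction(self):
        # rows add 0/2, columns add 0/3: no interaction term
        res = anova2_from_summary(self._grid([[10.0, 13.0], [12.0, 15.0]]))
        assert res.f_interaction == pytest.approx(0.0, abs=1e-20)
        assert res.f_a > 0 and res.f_b > 0

    def test_degrees_of_freedom(self):
        res = anova2_from_summary(self._grid([[10.0, 13.0], [12.0, 20.0]], n=7))
        assert (res.df_a, res.df_b, res.df_interaction) == (1, 1, 1)
        assert res.df_error == 4 * 6

    def test_matches_raw_data_anova_when_balanced(self):
        """Summary-cell reconstruction equals statsmodels' raw two-way
        ANOVA on a balanced design (independent oracle)."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(14)
        rows = []
        effects = {("lo", "x"): 10.0, ("lo", "y"): 12.0, ("hi", "x"): 15.0, ("hi", "y"): 13.0}
        for (la, lb), mu in effects.items():
            for v in rng.normal(mu, 1.0, 8):
                rows.append({"value": v, "a": la, "b": lb})
        df = pd.DataFrame(rows)
        ours = anova2_from_raw(df)
        fit = ols("value ~ C(a) * C(b)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        assert ours.f_a == pytest.approx(ref.loc["C(a)", "F"], rel=1e-8)
        assert ours.f_b == pytest.approx(ref.loc["C(b)", "F"], rel=1e-8)
        assert ours.f_interaction == pytest.approx(
            ref.loc["C(a):C(b)", "F"], rel=1e-8
        )
        assert ours.p_interaction == pytest.approx(
            ref.loc["C(a):C(b)", "PR(>F)"], rel=1e-6
        )

    def test_published_lifespan_grid_shapes(self):
        for set_id in ("C1", "#1", "#2", "#3", "C2", "#4", "#5"):
            grid = lifespan_anova_cells(set_id)
            res = anova2_from_summary(grid)
            assert res.df_interaction == 1
            assert np.isfinite(res.p_interaction)

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            anova2_from_summary([[SummaryCell(1.0, 0.1, 5)]])


class TestHolmSidak:
    def test_hand_example(self):
        adj = holm_sidak_adjust([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - (1 - 0.01) ** 2)
        assert adj[1] == pytest.approx(0.04)

    def test_single_p_unchanged(self):
        assert holm_sidak_adjust([0.03])[0] == pytest.approx(0.03)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_matches_stepdown_formula(self, plist):
        """Independent oracle: literal step-down Sidak with monotone
        enforcement."""
        p = np.asarray(plist)
        m = len(p)
        order = np.argsort(p)
        adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
        adj_sorted = np.maximum.accumulate(adj_sorted)
        oracle = np.empty(m)
        oracle[order] = np.minimum(adj_sorted, 1.0)
        assert np.allclose(holm_sidak_adjust(p), oracle, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak_adjust([0.5, 1.5])


class TestChi2ScoreTest:
    def test_identical_rows_not_significant(self):
        chi2, p = chi2_score_test(np.array([[30, 20, 10], [30, 20, 10]]))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_separation_value(self):
        chi2, _ = chi2_score_test(np.array([[10, 0], [0, 10]]))
        assert chi2 == pytest.approx(20.0)

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(15)
        table = rng.integers(5, 50, size=(2, 3)).astype(float)
        chi2, _ = chi2_score_test(table)
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        assert chi2 == pytest.approx(((table - expected) ** 2 / expected).sum())

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            chi2_score_test(np.array([[1, 2, 3]]))
        with pytest.raises(ValueError, match="marginal"):
            chi2_score_test(np.array([[1, 0], [2, 0]]))


class TestSmallHelpers:
    def test_copas_ratio(self):
        assert copas_normalize(1000.0, 200.0) == 5.0
        assert np.allclose(copas_normalize([10, 20], [5, 5]), [2.0, 4.0])
        with pytest.raises(ValueError, match="positive"):
            copas_normalize(10.0, 0.0)

    def test_kinetic_slope_linear_trace(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        assert kinetic_slope(t, 2 * t + 1) == pytest.approx(2.0)
        with pytest.raises(ValueError, match="3 time points"):
            kinetic_slope([0, 1], [0, 1])
        with pytest.raises(ValueError, match="constant"):
            kinetic_slope([1, 1, 1], [0, 1, 2])

    def test_summary_cell_validation(self):
        cell = SummaryCell(mean=15.0, sem=0.5, n=100)
        assert cell.variance == pytest.approx(25.0)
        with pytest.raises(ValueError):
            SummaryCell(mean=-1.0, sem=0.5, n=10)
        with pytest.raises(ValueError):
            SummaryCell(mean=1.0, sem=0.5, n=1)
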