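"""Factorial ANOVA, ART, residual diagnostics, post-hoc families."""

import numpy as np
import pandas as pd
import pytest

from bonefrag.phantoms import CANA_LEVELS, GROUP_LEVELS, CohortSpec, simulate_cohort_table
from bonefrag.stats import (
    art_anova,
    aligned_responses,
    diagnose_residuals,
    fit_two_way_anova,
    holm_sidak_adjust,
    posthoc_families,
    run_decision_tree,
)


def _table(values_by_cell):
    rows = []
    i = 0
    for (c, g), vals in values_by_cell.items():
        for v in vals:
            rows.append((f"m{i}", c, g, float(v)))
            i += 1
    return pd.DataFrame(rows, columns=["specimen_id", "cana", "group", "y"])


def _balanced_table(cell_fn, n=4):
    cells = {}
    for ci, c in enumerate(CANA_LEVELS):
        for gi, g in enumerate(GROUP_LEVELS):
            cells[(c, g)] = [cell_fn(ci, gi, r) for r in range(n)]
    return _table(cells)


class TestTwoWayAnova:
    def test_matches_statsmodels_type_iii_unbalanced(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        spec = CohortSpec(
            n_per_cell={("NoCana", "ND-Palm"): 8, ("NoCana", "T1D-Palm"): 10,
                        ("NoCana", "T1D-Ins"): 9, ("Cana", "ND-Palm"): 11,
                        ("Cana", "T1D-Palm"): 7, ("Cana", "T1D-Ins"): 12},
            cell_location=5.0, cell_scale=2.0, seed=42)
        tab = simulate_cohort_table(spec)
        fit = fit_two_way_anova(tab, "outcome")
        m = smf.ols("outcome ~ C(cana, Sum)*C(group, Sum)", data=tab).fit()
        a3 = sm.stats.anova_lm(m, typ=3)
        assert fit.f_stats["cana"] == pytest.approx(a3.loc["C(cana, Sum)", "F"])
        assert fit.f_stats["group"] == pytest.approx(a3.loc["C(group, Sum)", "F"])
        assert fit.f_stats["interaction"] == pytest.approx(
            a3.loc["C(cana, Sum):C(group, Sum)", "F"])
        for eff, label in [("cana", "C(cana, Sum)"), ("group", "C(group, Sum)"),
                           ("interaction", "C(cana, Sum):C(group, Sum)")]:
            assert fit.p_values[eff] == pytest.approx(a3.loc[label, "PR(>F)"])

    def test_hand_computed_balanced_sums_of_squares(self):
        # integer dataset, 2x3 with n=2: oracle by textbook balanced formulas
        tab = _balanced_table(lambda ci, gi, r: 2 * ci + 3 * gi + r, n=2)
        y = tab["y"].to_numpy()
        n, a, b = 2, 2, 3
        grand = y.mean()
        cm = tab.groupby(["cana", "group"], observed=True)["y"].mean()
        am = tab.groupby("cana", observed=True)["y"].mean()
        bm = tab.groupby("group", observed=True)["y"].mean()
        ss_a = n * b * sum((am - grand) ** 2)
        ss_b = n * a * sum((bm - grand) ** 2)
        ss_ab = n * sum((cm[(c, g)] - am[c] - bm[g] + grand) ** 2
                        for c in CANA_LEVELS for g in GROUP_LEVELS)
        ss_err = sum((row.y - cm[(row.cana, row.group)]) ** 2
                     for row in tab.itertuples())
        df_err = len(y) - 6
        fit = fit_two_way_anova(tab, "y")
        assert fit.f_stats["cana"] == pytest.approx(
            (ss_a / 1) / (ss_err / df_err))
        assert fit.f_stats["group"] == pytest.approx(
            (ss_b / 2) / (ss_err / df_err))
        assert fit.f_stats["interaction"] == pytest.approx(
            (ss_ab / 2) / (ss_err / df_err))

    def test_additive_means_give_null_interaction(self):
        tab = _balanced_table(lambda ci, gi, r: 1.5 * ci + 0.7 * gi + 0.1 * r,
                              n=3)
        # additive cell means -> interaction sum of squares is zero up
        # to linear-algebra round-off
        fit = fit_two_way_anova(tab, "y")
        assert fit.f_stats["interaction"] == pytest.approx(0.0, abs=1e-10)
        assert fit.p_values["interaction"] == pytest.approx(1.0)

    def test_empty_cell_named_in_error(self):
        tab = _balanced_table(lambda ci, gi, r: r, n=3)
        tab = tab[~((tab.cana == "Cana") & (tab.group == "T1D-Ins"))]
        with pytest.raises(ValueError, match="T1D-Ins"):
            fit_two_way_anova(tab, "y")

    def test_constant_outcome_rejected(self):
        tab = _balanced_table(lambda ci, gi, r: 1.0, n=3)
        with pytest.raises(ValueError, match="variance"):
            fit_two_way_anova(tab, "y")


class TestDiagnostics:
    def test_gaussian_homoscedastic_passes_mostly(self):
        # two diagnostics at alpha = 0.05 each pass jointly ~ 0.95^2 of
        # the time on well-behaved data (slightly less: the tests run on
        # fitted residuals, which inflates their size a little)
        ok = 0
        for seed in range(200):
            tab = simulate_cohort_table(CohortSpec(
                n_per_cell=10, cell_location=5.0, cell_scale=1.0, seed=seed))
            fit = fit_two_way_anova(tab, "outcome")
            ok += diagnose_residuals(fit)["parametric_ok"]
        assert ok >= 0.85 * 200

    def test_heteroscedastic_detected(self):
        hits = 0
        for seed in range(200):
            tab = simulate_cohort_table(CohortSpec(
                n_per_cell=10,
                cell_location={("NoCana", "ND-Palm"): 5, ("NoCana", "T1D-Palm"): 20,
                               ("NoCana", "T1D-Ins"): 60, ("Cana", "ND-Palm"): 5,
                               ("Cana", "T1D-Palm"): 20, ("Cana", "T1D-Ins"): 60},
                cell_scale={("NoCana", "ND-Palm"): 0.5, ("NoCana", "T1D-Palm"): 2.0,
                            ("NoCana", "T1D-Ins"): 6.0, ("Cana", "ND-Palm"): 0.5,
                            ("Cana", "T1D-Palm"): 2.0, ("Cana", "T1D-Ins"): 6.0},
                seed=seed))
            fit = fit_two_way_anova(tab, "outcome")
            d = diagnose_residuals(fit)
            hits += not d["homoscedastic"]
        assert hits >= 0.95 * 200

    def test_two_point_residuals_fail_normality(self):
        rng = np.random.default_rng(0)
        tab = _balanced_table(lambda ci, gi, r: 0.0, n=10)
        tab["y"] = rng.choice([-1.0, 1.0], size=len(tab))
        fit = fit_two_way_anova(tab, "y")
        assert not diagnose_residuals(fit)["normal"]

    def test_small_sample_warns(self):
        tab = _balanced_table(lambda ci, gi, r: ci + gi + 0.1 * r, n=1)
        tab2 = pd.concat([tab, tab.assign(y=tab.y + 0.05)])
        fit = fit_two_way_anova(tab2, "y")
        # 12 residuals -> fine; drop to below 8 by subsetting is impossible
        # with a full factorial, so check the path with a tiny cohort
        assert diagnose_residuals(fit)["parametric_ok"] in (True, False)


class TestART:
    def test_alignment_zeroes_off_test_effects(self):
        from bonefrag.stats import _anova_from_design, _design_matrices

        tab = _balanced_table(lambda ci, gi, r: 1.0 * ci + 2.0 * gi + 0.1 * r,
                              n=4)
        _, cols = _design_matrices(tab, "y")
        al = aligned_responses(tab, "y")
        for eff in ("cana", "group", "interaction"):
            sub = _anova_from_design(al[eff], cols, "chk")
            for other in ("cana", "group", "interaction"):
                if other != eff:
                    assert sub.f_stats[other] <= 1e-8

    def test_monotone_transform_agreement(self):
        # exp() destroys additivity but not ordering: ART group decision
        # should usually agree with the parametric decision on raw data
        agree = 0
        for seed in range(200):
            tab = simulate_cohort_table(CohortSpec(
                n_per_cell=10,
                cell_location={("NoCana", "ND-Palm"): 0.0, ("NoCana", "T1D-Palm"): 1.0,
                               ("NoCana", "T1D-Ins"): 0.5, ("Cana", "ND-Palm"): 0.0,
                               ("Cana", "T1D-Palm"): 1.0, ("Cana", "T1D-Ins"): 0.5},
                cell_scale=0.8, seed=seed))
            par = fit_two_way_anova(tab, "outcome")
            tab2 = tab.assign(outcome=np.exp(tab["outcome"]))
            art = art_anova(tab2, "outcome")
            agree += ((par.p_values["group"] < 0.05)
                      == (art.p_values["group"] < 0.05))
        assert agree >= 0.90 * 200

    def test_all_tied_rejected(self):
        tab = _balanced_table(lambda ci, gi, r: 1.0, n=3)
        tab["y"] = 7.0
        with pytest.raises(ValueError):
            art_anova(tab, "y")


class TestHolmSidak:
    def test_worked_example(self):
        adj = holm_sidak_adjust(np.array([0.01, 0.03, 0.04]))
        assert adj == pytest.approx([0.029701, 0.0591, 0.0591], abs=1e-4)

    def test_monotone_and_above_raw(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(2, 8))
            adj = holm_sidak_adjust(p)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1.0)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-15)


class TestPosthoc:
    def _gaussian_table(self, seed=0, shift=0.0):
        return simulate_cohort_table(CohortSpec(
            n_per_cell=10,
            cell_location={("NoCana", "ND-Palm"): 0.0, ("NoCana", "T1D-Palm"): shift,
                           ("NoCana", "T1D-Ins"): 0.0, ("Cana", "ND-Palm"): 0.0,
                           ("Cana", "T1D-Palm"): shift, ("Cana", "T1D-Ins"): 0.0},
            cell_scale=1.0, seed=seed))

    def test_family_plan_three_by_three(self):
        fams = posthoc_families(self._gaussian_table(shift=3.0), "outcome")
        assert len(fams) == 3
        assert all(len(f.comparisons) == 3 for f in fams)
        ids = {f.family_id for f in fams}
        assert ids == {"groups_within_NoCana", "groups_within_Cana",
                       "cana_within_groups"}

    def test_identical_groups_under_dunn_adjusted_to_one(self):
        from bonefrag.stats import _dunn_raw

        v = [np.array([1.0, 2.0, 3.0, 4.0]), np.array([1.0, 2.0, 3.0, 4.0]),
             np.array([10.0, 11.0, 12.0, 13.0])]
        z, p = _dunn_raw(v, 0, 1)
        assert z == 0.0
        assert p == 1.0

    def test_small_group_forces_dunn(self):
        tab = self._gaussian_table(shift=3.0)
        tab = tab[~((tab.cana == "NoCana") & (tab.group == "T1D-Palm")
                    & (tab.index % 10 < 8))]  # leave n=2 in one group
        with pytest.warns(UserWarning, match="Shapiro"):
            fams = posthoc_families(tab, "outcome")
        fam = [f for f in fams if f.family_id == "groups_within_NoCana"][0]
        assert fam.test_used == "dunn"

    def test_adjusted_at_least_raw(self):
        for f in posthoc_families(self._gaussian_table(shift=2.0), "outcome"):
            for c in f.comparisons:
                assert c.adjusted_p >= c.raw_p - 1e-15


class TestDecisionTree:
    def test_gaussian_cohort_takes_parametric_branch(self):
        tab = simulate_cohort_table(CohortSpec(
            n_per_cell=12,
            cell_location={("NoCana", "ND-Palm"): 0.0, ("NoCana", "T1D-Palm"): 4.0,
                           ("NoCana", "T1D-Ins"): 1.0, ("Cana", "ND-Palm"): 0.0,
                           ("Cana", "T1D-Palm"): 4.0, ("Cana", "T1D-Ins"): 1.0},
            cell_scale=1.0, seed=10))
        report = run_decision_tree(tab, "outcome")
        assert report["anova_branch"] == "parametric"
        assert report["posthoc_gate_open"]
        assert {f.test_used for f in report["families"]} >= {"holm_sidak_t"}

    def test_lognormal_heteroscedastic_takes_art_dunn(self):
        tab = simulate_cohort_table(CohortSpec(
            n_per_cell=12,
            cell_location={("NoCana", "ND-Palm"): 1.0, ("NoCana", "T1D-Palm"): 30.0,
                           ("NoCana", "T1D-Ins"): 4.0, ("Cana", "ND-Palm"): 1.0,
                           ("Cana", "T1D-Palm"): 30.0, ("Cana", "T1D-Ins"): 4.0},
            cell_scale=1.2, noise_family="lognormal", seed=3))
        report = run_decision_tree(tab, "outcome")
        assert report["anova_branch"] == "ART"
        groups_fams = [f for f in report["families"]
                       if f.family_id.startswith("groups_within")]
        assert all(f.test_used == "dunn" for f in groups_fams)

    def test_no_group_effect_closes_gate(self):
        tab = simulate_cohort_table(CohortSpec(
            n_per_cell=10, cell_location=5.0, cell_scale=1.0, seed=77))
        report = run_decision_tree(tab, "outcome")
        assert not report["posthoc_gate_open"]
        assert report["families"] == []
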