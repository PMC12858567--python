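"""Factorial statistics for two-factor (pretreatment x glucose group) cohorts.

The decision tree mirrors common practice for small-animal endpoint
outcomes:

1. two-way ANOVA (2 x 3 with interaction, Type III sums of squares on
   sum-to-zero contrasts, safe for mild imbalance);
2. residual diagnostics — Anderson-Darling normality on the residuals
   and a Spearman rank correlation of |residual| against fitted values
   (heteroscedasticity);
3. if either diagnostic fails, the aligned-rank-transform (ART) ANOVA
   replaces the parametric fit: for each effect the response is aligned
   by stripping every other estimated effect, mid-ranked, refit, and
   only the effect under test is read from that fit;
4. when the glucose-group or interaction effect is significant,
   pre-declared post-hoc families are tested: the three group contrasts
   within each pretreatment level (two families) and the pretreatment
   contrast within each group (one family).  Each family uses
   Holm-Sidak step-down t tests when every involved group passes
   Shapiro-Wilk normality and Brown-Forsythe variance homogeneity, and
   Dunn's joint-rank z tests (same step-down family size) otherwise.

The module's ANOVA core is plain linear algebra (verified against
statsmodels' Type III ANOVA in the test suite) so Monte-Carlo
calibration runs stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phantoms import CANA_LEVELS, GROUP_LEVELS

__all__ = [
    "FactorialFit",
    "PosthocComparison",
    "PosthocFamily",
    "fit_two_way_anova",
    "diagnose_residuals",
    "art_anova",
    "holm_sidak_adjust",
    "posthoc_families",
    "run_decision_tree",
]

EFFECTS = ("cana", "group", "interaction")


@dataclass
class FactorialFit:
    """Two-way factorial fit: per-effect F statistics and p-values."""

    f_stats: dict
    p_values: dict
    df: dict
    residuals: np.ndarray
    fitted: np.ndarray
    method_used: str  # "parametric" | "ART"
    cell_means: pd.Series | None = None


@dataclass
class PosthocComparison:
    pair: tuple[str, str]
    raw_p: float
    adjusted_p: float
    statistic: float
    test_used: str  # "holm_sidak_t" | "dunn"


@dataclass
class PosthocFamily:
    family_id: str
    comparisons: list
    test_used: str
    family_alpha: float = 0.05
    gates: dict = field(default_factory=dict)


def _design_matrices(table: pd.DataFrame, outcome: str):
    """Sum-to-zero coded design: intercept | cana | group(2) | interaction(2)."""
    y = table[outcome].to_numpy(dtype=float)
    cana = table["cana"].to_numpy()
    group = table["group"].to_numpy()
    for lev, col, name in ((CANA_LEVELS, cana, "cana"), (GROUP_LEVELS, group, "group")):
        unknown = set(col) - set(lev)
        if unknown:
            raise ValueError(f"unknown {name} level(s): {unknown}")
    # empty-cell check
    counts = table.groupby(["cana", "group"], observed=True).size()
    for c in CANA_LEVELS:
        for g in GROUP_LEVELS:
            if counts.get((c, g), 0) == 0:
                raise ValueError(f"empty design cell: ({c}, {g})")
    if np.ptp(y) == 0:
        raise ValueError("constant outcome: zero variance")

    a = np.where(cana == CANA_LEVELS[0], 1.0, -1.0)  # sum-to-zero, 2 levels
    g1 = np.select([group == GROUP_LEVELS[0], group == GROUP_LEVELS[2]], [1.0, -1.0], 0.0)
    g2 = np.select([group == GROUP_LEVELS[1], group == GROUP_LEVELS[2]], [1.0, -1.0], 0.0)
    cols = {
        "intercept": np.ones_like(y),
        "cana": a,
        "group": np.column_stack([g1, g2]),
        "interaction": np.column_stack([a * g1, a * g2]),
    }
    return y, cols


def _sse(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r), beta


def _anova_from_design(y, cols, method_label):
    x_full = np.column_stack([cols["intercept"], cols["cana"],
                              cols["group"], cols["interaction"]])
    n = len(y)
    df_resid = n - x_full.shape[1]
    if df_resid <= 0:
        raise ValueError("not enough observations for the full factorial model")
    beta, *_ = np.linalg.lstsq(x_full, y, rcond=None)
    fitted = x_full @ beta
    resid = y - fitted
    sse_full = float(resid @ resid)
    f_stats, p_values, dfs = {}, {}, {}
    for eff in EFFECTS:
        drop = [k for k in ("intercept", "cana", "group", "interaction") if k != eff]
        x_red = np.column_stack([cols[k] for k in drop])
        sse_red, _ = _sse(x_red, y)
        df_eff = cols[eff].shape[1] if cols[eff].ndim == 2 else 1
        ms_eff = (sse_red - sse_full) / df_eff
        ms_err = sse_full / df_resid
        f = ms_eff / ms_err if ms_err > 0 else np.inf
        f_stats[eff] = float(max(f, 0.0))
        p_values[eff] = float(sps.f.sf(max(f, 0.0), df_eff, df_resid))
        dfs[eff] = (df_eff, df_resid)
    return FactorialFit(f_stats, p_values, dfs, resid, fitted, method_label)


def fit_two_way_anova(table: pd.DataFrame, outcome: str) -> FactorialFit:
    """Parametric 2x3 factorial ANOVA with interaction.

    Type III sums of squares on sum-to-zero contrasts: each effect is
    tested by the SSE increase from dropping its columns from the full
    model, which is imbalance-safe.  Residuals and fitted values are
    retained for the diagnostics stage.
    """
    y, cols = _design_matrices(table, outcome)
    fit = _anova_from_design(y, cols, "parametric")
    fit.cell_means = table.groupby(["cana", "group"], observed=True)[outcome].mean()
    return fit


def diagnose_residuals(fit: FactorialFit, alpha: float = 0.05) -> dict:
    """Residual diagnostics gating the parametric branch.

    Anderson-Darling normality on the residuals, and Spearman rank
    correlation of |residual| versus fitted (heteroscedasticity).
    ``parametric_ok`` iff both are non-significant at ``alpha``.
    """
    from statsmodels.stats.diagnostic import normal_ad

    resid = fit.residuals
    out = {"alpha": alpha}
    if len(resid) < 8:
        import warnings

        warnings.warn("fewer than 8 residuals: diagnostics unreliable")
        out["unreliable"] = True
    ad_stat, ad_p = normal_ad(resid)
    rho, sp_p = sps.spearmanr(fit.fitted, np.abs(resid))
    out.update(anderson_darling={"statistic": float(ad_stat), "p": float(ad_p)},
               spearman={"rho": float(rho), "p": float(sp_p)},
               normal=bool(ad_p >= alpha), homoscedastic=bool(sp_p >= alpha))
    out["parametric_ok"] = out["normal"] and out["homoscedastic"]
    return out


def _midrank(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def art_anova(table: pd.DataFrame, outcome: str) -> FactorialFit:
    """Aligned-rank-transform factorial ANOVA.

    For each effect, the response is aligned by subtracting every
    estimated effect except the one under test (cell-mean
    decomposition, unweighted means), mid-ranked, and refit with the
    full factorial model; only the aligned-for effect is read from each
    of the three fits.  Correctness check: on each aligned (pre-rank)
    response the F statistics of the two other effects are exactly 0.
    """
    y, cols = _design_matrices(table, outcome)
    if np.ptp(_midrank(y)) == 0:
        raise ValueError("degenerate ranks: all outcome values tied")
    aligned_by_effect = aligned_responses(table, outcome)

    f_stats, p_values, dfs = {}, {}, {}
    last_fit = None
    for eff in EFFECTS:
        ranked = _midrank(aligned_by_effect[eff])
        sub = _anova_from_design(ranked, cols, "ART")
        f_stats[eff] = sub.f_stats[eff]
        p_values[eff] = sub.p_values[eff]
        dfs[eff] = sub.df[eff]
        last_fit = sub
    fit = FactorialFit(f_stats, p_values, dfs, last_fit.residuals,
                       last_fit.fitted, "ART")
    fit.cell_means = table.groupby(["cana", "group"], observed=True)[outcome].mean()
    return fit


def aligned_responses(table: pd.DataFrame, outcome: str) -> dict:
    """Aligned (pre-rank) responses per effect — exposed for the ART
    correctness check that off-test effects carry zero F."""
    y, _ = _design_matrices(table, outcome)
    art = {}
    cana = table["cana"].to_numpy()
    group = table["group"].to_numpy()
    cell_mean = {(c, g): y[(cana == c) & (group == g)].mean()
                 for c in CANA_LEVELS for g in GROUP_LEVELS}
    mu = np.mean(list(cell_mean.values()))
    a_eff = {c: np.mean([cell_mean[(c, g)] for g in GROUP_LEVELS]) - mu for c in CANA_LEVELS}
    b_eff = {g: np.mean([cell_mean[(c, g)] for c in CANA_LEVELS]) - mu for g in GROUP_LEVELS}
    ab_eff = {(c, g): cell_mean[(c, g)] - mu - a_eff[c] - b_eff[g]
              for c in CANA_LEVELS for g in GROUP_LEVELS}
    cell_of = np.array([cell_mean[(c, g)] for c, g in zip(cana, group)])
    resid = y - cell_of
    est = {
        "cana": np.array([a_eff[c] for c in cana]),
        "group": np.array([b_eff[g] for g in group]),
        "interaction": np.array([ab_eff[(c, g)] for c, g in zip(cana, group)]),
    }
    for eff in EFFECTS:
        art[eff] = resid + est[eff]
    return art


# ---------------------------------------------------------------------------
# post-hoc machinery
# ---------------------------------------------------------------------------

def holm_sidak_adjust(raw_p: np.ndarray) -> np.ndarray:
    """Holm-Sidak step-down adjustment.

    Sorted ascending, adjusted p_(i) = 1 - (1 - p_(i))^(m - i + 1),
    enforced monotone non-decreasing; returned in the input order.
    """
    p = np.asarray(raw_p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty_like(p)
    out[order] = adj_sorted
    return out


def _dunn_raw(values: list[np.ndarray], i: int, j: int) -> tuple[float, float]:
    """Dunn's joint-rank z test for groups i, j among the family's groups.

    Mid-ranks over the pooled family sample with the standard tie
    correction of the rank variance.
    """
    pooled = np.concatenate(values)
    ranks = _midrank(pooled)
    n_tot = len(pooled)
    bounds = np.cumsum([0] + [len(v) for v in values])
    mean_ranks = [ranks[bounds[k]:bounds[k + 1]].mean() for k in range(len(values))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_tot - 1))
    var = (n_tot * (n_tot + 1) / 12.0 - tie_term) * (1.0 / len(values[i]) + 1.0 / len(values[j]))
    if var <= 0:
        return 0.0, 1.0
    z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def _gates(values: list[np.ndarray], alpha: float = 0.05) -> dict:
    """Shapiro-Wilk per group + Brown-Forsythe homogeneity across groups."""
    gates = {"alpha": alpha}
    sw_ps = []
    forced = False
    for v in values:
        if len(v) < 3:
            forced = True
            sw_ps.append(np.nan)
            continue
        sw_ps.append(float(sps.shapiro(v).pvalue))
    bf_p = float(sps.levene(*values, center="median").pvalue)
    gates["shapiro_p"] = sw_ps
    gates["brown_forsythe_p"] = bf_p
    if forced:
        import warnings

        warnings.warn("group with n < 3: Shapiro-Wilk impossible, forcing Dunn")
        gates["forced_nonparametric"] = True
        gates["parametric"] = False
    else:
        gates["parametric"] = all(p >= alpha for p in sw_ps) and bf_p >= alpha
    return gates


def _family(values_by_label: dict, family_id: str, alpha: float) -> PosthocFamily:
    labels = list(values_by_label)
    values = [np.asarray(values_by_label[k], dtype=float) for k in labels]
    gates = _gates(values, alpha)
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    raws, stats_ = [], []
    if gates["parametric"]:
        test_used = "holm_sidak_t"
        for i, j in pairs:
            t, p = sps.ttest_ind(values[i], values[j], equal_var=True)
            raws.append(float(p))
            stats_.append(float(t))
    else:
        test_used = "dunn"
        for i, j in pairs:
            z, p = _dunn_raw(values, i, j)
            raws.append(p)
            stats_.append(z)
    adj = holm_sidak_adjust(np.array(raws))
    comparisons = [
        PosthocComparison(pair=(labels[i], labels[j]), raw_p=raws[k],
                          adjusted_p=float(adj[k]), statistic=stats_[k],
                          test_used=test_used)
        for k, (i, j) in enumerate(pairs)
    ]
    return PosthocFamily(family_id=family_id, comparisons=comparisons,
                         test_used=test_used, family_alpha=alpha, gates=gates)


def posthoc_families(table: pd.DataFrame, outcome: str,
                     alpha: float = 0.05) -> list[PosthocFamily]:
    """The study's three pre-declared comparison families.

    Two families of the three glucose-group contrasts (one within each
    pretreatment level) and one family of the pretreatment contrast
    within each glucose group — three comparisons per family.
    """
    families = []
    for c in CANA_LEVELS:
        sub = table[table["cana"] == c]
        values = {g: sub.loc[sub["group"] == g, outcome].to_numpy()
                  for g in GROUP_LEVELS}
        families.append(_family(values, f"groups_within_{c}", alpha))
    # pretreatment contrasts within each glucose group: 3 two-group
    # comparisons adjusted together as one family of size 3
    raws, stats_, pair_labels, tests = [], [], [], []
    gates_all = {}
    for g in GROUP_LEVELS:
        sub = table[table["group"] == g]
        values = {c: sub.loc[sub["cana"] == c, outcome].to_numpy()
                  for c in CANA_LEVELS}
        vlist = [values[c] for c in CANA_LEVELS]
        gates = _gates(vlist, alpha)
        gates_all[g] = gates
        if gates["parametric"]:
            t, p = sps.ttest_ind(*vlist, equal_var=True)
            tests.append("holm_sidak_t")
            stats_.append(float(t))
        else:
            z, p = _dunn_raw(vlist, 0, 1)
            tests.append("dunn")
            stats_.append(z)
        raws.append(float(p))
        pair_labels.append((f"{CANA_LEVELS[0]}|{g}", f"{CANA_LEVELS[1]}|{g}"))
    adj = holm_sidak_adjust(np.array(raws))
    comps = [PosthocComparison(pair=pair_labels[k], raw_p=raws[k],
                               adjusted_p=float(adj[k]), statistic=stats_[k],
                               test_used=tests[k])
             for k in range(len(raws))]
    families.append(PosthocFamily(family_id="cana_within_groups",
                                  comparisons=comps,
                                  test_used=",".join(sorted(set(tests))),
                                  family_alpha=alpha, gates=gates_all))
    return families


def run_decision_tree(table: pd.DataFrame, outcome: str,
                      alpha: float = 0.05, diag_alpha: float = 0.05) -> dict:
    """Full endpoint-outcome analysis with branch bookkeeping.

    Parametric fit -> residual diagnostics -> (ART on violation) ->
    post-hoc families, gated on a significant glucose-group or
    interaction effect.  The report records every branch taken.
    """
    fit = fit_two_way_anova(table, outcome)
    diag = diagnose_residuals(fit, alpha=diag_alpha)
    branch = "parametric"
    if not diag["parametric_ok"]:
        fit = art_anova(table, outcome)
        branch = "ART"
    gate_open = (fit.p_values["group"] < alpha
                 or fit.p_values["interaction"] < alpha)
    families = posthoc_families(table, outcome, alpha) if gate_open else []
    return {
        "outcome": outcome,
        "anova_branch": branch,
        "f_stats": fit.f_stats,
        "p_values": fit.p_values,
        "diagnostics": diag,
        "posthoc_gate_open": bool(gate_open),
        "families": families,
        "fit": fit,
    }
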