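"""Inference layer: mixed ANOVA against independent oracles, GG epsilon,
contrasts, Tukey comparisons, and within-subject CIs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tests.oracles import gg_epsilon_eigen_oracle, projection_anova_oracle
from turntap import stats


def long_table(Y, groups=None, within_names=("A", "B"), level_counts=(2, 4)):
    """units x cells matrix -> long format (cells ordered factor-major)."""
    rows = []
    cells = [()]
    for lc in level_counts:
        cells = [c + (lvl,) for c in cells for lvl in range(lc)]
    for i in range(Y.shape[0]):
        for j, cell in enumerate(cells):
            row = {"pair_id": f"u{i:03d}", "value": Y[i, j]}
            for name, lvl in zip(within_names, cell):
                row[name] = f"{name.lower()}{lvl + 1}"
            if groups is not None:
                row["grp"] = groups[i]
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

def test_two_level_within_f_equals_squared_paired_t(rng):
    Y = rng.normal(0, 1, (10, 2))
    tab = long_table(Y, within_names=("A",), level_counts=(2,))
    res = {r.effect: r for r in stats.mixed_anova(tab, "value", ["A"], None, "pair_id")}
    t, p = sps.ttest_rel(Y[:, 0], Y[:, 1])
    assert res["A"].F == pytest.approx(t ** 2)
    assert res["A"].p == pytest.approx(p)


def test_matches_projection_oracle_on_random_balanced_2x2x4(rng):
    """F, dfs and ges agree with a brute-force projection decomposition."""
    n_per = 6
    Y = rng.normal(0, 1, (2 * n_per, 8)) + rng.normal(0, 1, (2 * n_per, 1))
    groups = ["g1"] * n_per + ["g2"] * n_per
    tab = long_table(Y, groups)
    res = stats.mixed_anova(tab, "value", ["A", "B"], ["grp"], "pair_id")
    oracle = projection_anova_oracle(Y, groups, [2, 4])
    name_map = {"grp": "P", "A": "w0", "grp:A": "P:w0", "B": "w1",
                "grp:B": "P:w1", "A:B": "w0:w1", "grp:A:B": "P:w0:w1"}
    assert len(res) == 7
    for r in res:
        F, d1, d2, ges = oracle[name_map[r.effect]]
        assert r.F == pytest.approx(F, abs=1e-8)
        assert (r.df_num_raw, r.df_den_raw) == (d1, d2)
        assert r.ges == pytest.approx(ges, abs=1e-8)


def test_matches_pingouin_mixed_anova(rng):
    """Independent cross-check: F statistics agree with pingouin for a
    one-within x one-between design."""
    pg = pytest.importorskip("pingouin")
    Y = rng.normal(0, 1, (12, 4)) @ np.diag([1.0, 2.0, 0.5, 1.5])
    groups = ["g1"] * 6 + ["g2"] * 6
    tab = long_table(Y, groups, within_names=("B",), level_counts=(4,))
    res = {r.effect: r for r in stats.mixed_anova(tab, "value", ["B"], ["grp"],
                                                  "pair_id")}
    ref = pg.mixed_anova(data=tab, dv="value", within="B", subject="pair_id",
                         between="grp")
    by_src = {row["Source"]: row for _, row in ref.iterrows()}
    assert res["grp"].F == pytest.approx(by_src["grp"]["F"])
    assert res["B"].F == pytest.approx(by_src["B"]["F"])
    assert res["grp:B"].F == pytest.approx(by_src["Interaction"]["F"])


def test_epsilon_near_one_under_compound_symmetry(rng):
    eps = []
    for _ in range(60):
        Y = rng.normal(0, 1, (40, 4)) + 2.0 * rng.normal(0, 1, (40, 1))
        tab = long_table(Y, within_names=("B",), level_counts=(4,))
        res = {r.effect: r for r in stats.mixed_anova(tab, "value", ["B"],
                                                      None, "pair_id")}
        eps.append(res["B"].epsilon_gg)
    assert np.mean(eps) > 0.9


def test_ges_invariant_to_affine_rescaling(rng):
    Y = rng.normal(0, 1, (8, 8))
    tab = long_table(Y)
    res1 = stats.mixed_anova(tab, "value", ["A", "B"], None, "pair_id")
    tab2 = tab.assign(value=tab["value"] * 3.2 + 40.0)
    res2 = stats.mixed_anova(tab2, "value", ["A", "B"], None, "pair_id")
    for r1, r2 in zip(res1, res2):
        assert r1.ges == pytest.approx(r2.ges)
        assert r1.F == pytest.approx(r2.F)


def test_missing_cell_and_missing_unit_column_errors(rng):
    Y = rng.normal(0, 1, (6, 8))
    tab = long_table(Y)
    with pytest.raises(ValueError, match="unit column"):
        stats.mixed_anova(tab, "value", ["A", "B"], None, "unit")
    with pytest.raises(ValueError, match="not complete"):
        stats.mixed_anova(tab.iloc[:-1], "value", ["A", "B"], None, "pair_id")


# ---------------------------------------------------------------------------
# Greenhouse-Geisser epsilon
# ---------------------------------------------------------------------------

def test_gg_epsilon_bounds_and_oracle(rng):
    k = 4
    # compound symmetry -> 1
    cs = 0.5 * np.eye(k) + 0.5 * np.ones((k, k))
    assert stats.gg_epsilon(cs) == pytest.approx(1.0)
    # rank-1 (maximally non-spherical) -> 1/(k-1)
    v = rng.normal(0, 1, k)
    v = v - v.mean()  # ensure variation survives centering on one axis only
    assert stats.gg_epsilon(np.outer(v, v)) == pytest.approx(1 / (k - 1))
    # random PSD vs eigenvalue-formula oracle
    for _ in range(10):
        A = rng.normal(0, 1, (k, k))
        S = A @ A.T
        assert stats.gg_epsilon(S) == pytest.approx(gg_epsilon_eigen_oracle(S))


def test_gg_epsilon_input_validation():
    with pytest.raises(ValueError, match="square"):
        stats.gg_epsilon(np.ones((2, 3)))
    with pytest.raises(ValueError, match="positive semi-definite"):
        stats.gg_epsilon(np.array([[1.0, 2.0], [2.0, 1.0]]))


# ---------------------------------------------------------------------------
# linear contrasts
# ---------------------------------------------------------------------------

def _block_table(values_by_unit_task):
    rows = []
    for (unit, task), vals in values_by_unit_task.items():
        for b, v in enumerate(vals, start=1):
            rows.append({"pair_id": unit, "task": task, "block": b, "value": v})
    return pd.DataFrame(rows)


def test_linear_contrast_sign_and_null():
    declining = _block_table({(f"u{i}", "Individual"): [8.0 - i * 0.1 - b
                                                        for b in range(4)]
                              for i in range(6)})
    c = stats.linear_block_contrast(declining, "Individual")
    assert c.estimate < 0 and c.t < 0 and c.df == 5
    flat = _block_table({(f"u{i}", "Joint"): [5.0 + 0.01 * i] * 4 for i in range(6)})
    c0 = stats.linear_block_contrast(flat, "Joint")
    assert c0.estimate == pytest.approx(0.0, abs=1e-12)


def test_planted_learning_slope_recovered_at_twelve_units(rng):
    tabs = {}
    for i in range(12):
        base = rng.normal(6, 0.5)
        tabs[(f"u{i:02d}", "Joint")] = [base - 0.5 * b + rng.normal(0, 0.2)
                                        for b in range(4)]
    c = stats.linear_block_contrast(_block_table(tabs), "Joint")
    assert c.estimate < 0 and c.p < 0.01


def test_interaction_contrast_conventions(rng):
    # identical task trajectories -> zero estimate
    same = {}
    for i in range(8):
        traj = [6.0 - 0.3 * b + 0.05 * i for b in range(4)]
        same[(f"u{i}", "Individual")] = traj
        same[(f"u{i}", "Joint")] = traj
    c = stats.interaction_contrast(_block_table(same))
    assert c.estimate == pytest.approx(0.0, abs=1e-12)
    # steeper joint decline -> positive t
    steeper = {}
    for i in range(8):
        steeper[(f"u{i}", "Individual")] = [6.0 - 0.1 * b + rng.normal(0, 0.05)
                                            for b in range(4)]
        steeper[(f"u{i}", "Joint")] = [7.0 - 0.8 * b + rng.normal(0, 0.05)
                                       for b in range(4)]
    c = stats.interaction_contrast(_block_table(steeper))
    assert c.t > 0 and c.p < 0.01


def test_interaction_contrast_equals_two_step_oracle(rng):
    tabs = {}
    for i in range(10):
        for task in ("Individual", "Joint"):
            tabs[(f"u{i:02d}", task)] = list(rng.normal(5, 1, 4))
    tab = _block_table(tabs)
    c = stats.interaction_contrast(tab)
    w = np.array([-3.0, -1.0, 1.0, 3.0])
    diffs = [np.dot(tabs[(f"u{i:02d}", "Individual")], w)
             - np.dot(tabs[(f"u{i:02d}", "Joint")], w) for i in range(10)]
    t, p = sps.ttest_1samp(diffs, 0.0)
    assert c.estimate == pytest.approx(np.mean(diffs))
    assert c.t == pytest.approx(t) and c.p == pytest.approx(p)


# ---------------------------------------------------------------------------
# Tukey pairwise
# ---------------------------------------------------------------------------

def test_two_level_tukey_equals_paired_t(rng):
    rows = []
    for i in range(10):
        for task, mu in [("Individual", 4.0), ("Joint", 5.0)]:
            rows.append({"pair_id": f"u{i}", "task": task,
                         "value": rng.normal(mu, 1)})
    tab = pd.DataFrame(rows)
    res = stats.tukey_pairwise(tab, factor="task")
    assert len(res) == 1
    wide = tab.pivot(index="pair_id", columns="task", values="value")
    t, p = sps.ttest_rel(wide["Individual"], wide["Joint"])
    assert res[0].t == pytest.approx(t)
    assert res[0].p == pytest.approx(p)


def test_planted_task_gap_significant_in_every_block(rng):
    rows = []
    for i in range(12):
        for b in range(1, 5):
            rows.append({"pair_id": f"u{i}", "task": "Individual", "block": b,
                         "value": rng.normal(4, 0.3)})
            rows.append({"pair_id": f"u{i}", "task": "Joint", "block": b,
                         "value": rng.normal(5.5, 0.3)})
    res = stats.tukey_pairwise(pd.DataFrame(rows), factor="task", by="block")
    assert len(res) == 4
    assert all(c.p < 0.001 for c in res)


def test_tukey_familywise_error_controlled_under_null(rng):
    """With 4 levels and no true differences the family-wise rejection rate
    stays at or below the nominal 0.05 (studentized-range calibration)."""
    k, n, reps = 4, 12, 600
    crit = sps.studentized_range.ppf(0.95, k, n - 1)
    fw = 0
    for _ in range(reps):
        Y = rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
        qmax = 0.0
        for i in range(k):
            for j in range(i + 1, k):
                d = Y[:, i] - Y[:, j]
                t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
                qmax = max(qmax, abs(t) * np.sqrt(2))
        fw += qmax > crit
    rate = fw / reps
    assert rate <= 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / reps)


# ---------------------------------------------------------------------------
# within-subject confidence intervals
# ---------------------------------------------------------------------------

def test_offsets_between_units_do_not_widen_intervals(rng):
    rows = []
    profile = [4.0, 5.0, 6.0, 5.5]
    for i in range(10):
        offset = rng.normal(0, 50)
        for b, v in enumerate(profile, start=1):
            rows.append({"pair_id": f"u{i}", "block": b, "value": v + offset})
    ci = stats.within_subject_ci(pd.DataFrame(rows), dv="value",
                                 within_cells=["block"])
    widths = ci["ci_hi"] - ci["ci_lo"]
    assert (widths < 1e-9).all()
    # cell means keep the shared between-unit offset; differences match
    got = ci.sort_values("block")["mean"].to_numpy()
    assert np.allclose(got - got[0], np.array(profile) - profile[0], atol=1e-9)


def test_single_cell_errors():
    tab = pd.DataFrame({"pair_id": ["u1", "u2"], "block": [1, 1],
                        "value": [1.0, 2.0]})
    with pytest.raises(ValueError, match="J=1"):
        stats.within_subject_ci(tab, dv="value", within_cells=["block"])


def test_hand_computed_two_unit_example():
    tab = pd.DataFrame([
        {"pair_id": "u1", "block": 1, "value": 1.0},
        {"pair_id": "u1", "block": 2, "value": 3.0},
        {"pair_id": "u2", "block": 1, "value": 5.0},
        {"pair_id": "u2", "block": 2, "value": 8.0},
    ])
    ci = stats.within_subject_ci(tab, dv="value", within_cells=["block"])
    # centered scores: u1 [3.25, 5.25], u2 [2.75, 5.75]; cell SDs 0.35355...
    # Morey factor sqrt(2); half-width = t(.975, 1) * sd * sqrt(2) / sqrt(2)
    half = sps.t.ppf(0.975, 1) * 0.35355339059327373
    row1 = ci[ci["block"] == 1].iloc[0]
    assert row1["mean"] == pytest.approx(3.0)
    assert row1["ci_hi"] - row1["ci_lo"] == pytest.approx(2 * half)


# ---------------------------------------------------------------------------
# robustness harness
# ---------------------------------------------------------------------------

def test_significance_pattern_consistent_under_log_transform(study1_analysis):
    """ANOVAs on log-transformed accuracy/CV agree with the raw runs on
    which effects are significant (positive measures, multiplicative noise)."""
    table = study1_analysis["measures"]
    for measure in ("accuracy_pct", "cv"):
        sub = table[table["measure"] == measure].copy()
        raw = stats.mixed_anova(sub, "value", ["task", "block"],
                                ["predictability"], "pair_id")
        sub["value"] = np.log(sub["value"])
        logged = stats.mixed_anova(sub, "value", ["task", "block"],
                                   ["predictability"], "pair_id")
        for r1, r2 in zip(raw, logged):
            if min(r1.p, r2.p) < 0.01 and max(r1.p, r2.p) > 0.10:
                raise AssertionError(
                    f"{measure}/{r1.effect}: raw p={r1.p:.4g} vs log p={r2.p:.4g}")
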