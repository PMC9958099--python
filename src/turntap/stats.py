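"""Inference for balanced mixed factorial repeated-measures designs.

The estimator targets the design family of dyadic learning experiments:
every unit (pair) measured in every within-subject cell (e.g. Task x
Learning Block x Lag), optionally split by one between-subject factor
(e.g. Pitch Predictability or Study).  For such balanced complete designs
Type-III and Type-I sums of squares coincide, and every effect can be
computed exactly from orthonormal contrast transforms of the unit x cell
score matrix:

* for each within effect *w*, the score matrix is projected onto the
  Kronecker product of orthonormal factor contrasts (for factors in *w*)
  and unit-norm averaging vectors (for the rest); sums of squares of the
  transformed scores give the effect, its between-group interaction, and
  the stratum error term;
* the Greenhouse-Geisser epsilon of each within stratum comes from the
  pooled covariance of the transformed scores,
  ``eps = tr(S)^2 / (d * tr(S^2))``, and multiplies the raw degrees of
  freedom of every effect tested against that stratum (applied always, not
  gated on a sphericity pretest);
* generalized eta squared is ``SS_effect / (SS_effect + sum of all error
  SS)`` across every stratum, the convention of standard repeated-measures
  ANOVA software.

Follow-ups: linear contrasts across blocks with orthogonal polynomial
weights (-3, -1, 1, 3), contrast-of-contrasts between tasks, Tukey-corrected
pairwise comparisons using within-unit (multivariate, per-comparison error)
differences and the studentized-range distribution, and Cousineau-Morey
within-subject confidence intervals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

LINEAR_WEIGHTS_4 = np.array([-3.0, -1.0, 1.0, 3.0])


@dataclass
class AnovaResult:
    """One effect line: F-test with GG-adjusted dfs and generalized eta squared."""

    effect: str
    df_num: float          # GG-adjusted (fractional) numerator df
    df_den: float          # GG-adjusted denominator df
    F: float
    p: float
    ges: float
    epsilon_gg: float
    df_num_raw: int
    df_den_raw: int
    ss_effect: float
    ss_error: float


@dataclass
class ContrastResult:
    """A single linear contrast or pairwise comparison."""

    name: str
    estimate: float
    t: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# Mixed factorial ANOVA
# ---------------------------------------------------------------------------

def _orthonormal_basis(n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """(averaging vector of unit norm, orthonormal contrast matrix) for a factor."""
    seed = np.column_stack([np.ones(n_levels), np.eye(n_levels)[:, :-1]])
    q, _ = np.linalg.qr(seed)
    u = q[:, :1] * np.sign(q[0, 0])   # 1/sqrt(l) averaging vector
    c = q[:, 1:]                      # orthonormal complement (contrasts)
    return u, c


def _pivot(table: pd.DataFrame, dv: str, within: list[str], unit: str,
           levels: dict[str, list]) -> tuple[pd.DataFrame, list]:
    cells = pd.MultiIndex.from_product([levels[f] for f in within], names=within)
    wide = table.pivot_table(index=unit, columns=within, values=dv, aggfunc="mean")
    if len(within) == 1:
        wide = wide.reindex(columns=levels[within[0]])
    else:
        wide = wide.reindex(columns=cells)
    if wide.isna().any().any():
        missing = wide.isna().stack(future_stack=True)
        where = missing[missing].index[0]
        raise ValueError(f"design not complete: unit/cell {where} has no observation")
    counts = table.groupby([unit] + within, observed=True)[dv].count()
    if (counts != 1).any():
        raise ValueError("expected exactly one observation per unit x within cell; "
                         "aggregate trials before the ANOVA")
    return wide, list(wide.index)


def mixed_anova(table: pd.DataFrame, dv: str, within: list[str],
                between: list[str] | None, unit: str) -> list[AnovaResult]:
    """Balanced mixed factorial repeated-measures ANOVA (Type-III SS).

    ``table`` is long format with one row per unit x within-cell.  At most
    one between-subject factor is supported (the scope of the target
    designs); between-group sizes may differ (with a warning).  Every within
    effect's p-value uses GG-corrected degrees of freedom.
    """
    between = list(between or [])
    if len(between) > 1:
        raise NotImplementedError("at most one between-subject factor is supported")
    if unit not in table.columns:
        raise ValueError(f"unit column {unit!r} absent from table")
    for col in [dv] + within + between:
        if col not in table.columns:
            raise ValueError(f"column {col!r} absent from table")

    levels = {f: sorted(table[f].unique()) for f in within}
    wide, units = _pivot(table, dv, within, unit, levels)
    Y = wide.to_numpy(dtype=float)
    N = Y.shape[0]

    if between:
        bmap = table.groupby(unit)[between[0]].agg(lambda s: s.unique())
        if any(len(v) != 1 for v in bmap):
            raise ValueError("between-subject factor varies within a unit")
        glabels = np.array([bmap.loc[u][0] for u in units])
        gnames = sorted(pd.unique(glabels))
        gindex = [np.flatnonzero(glabels == g) for g in gnames]
        sizes = {g: len(ix) for g, ix in zip(gnames, gindex)}
        if len(set(sizes.values())) > 1:
            warnings.warn(f"unequal between-group sizes: {sizes}")
    else:
        gnames = ["_all_"]
        gindex = [np.arange(N)]
    G = len(gnames)
    if N - G < 1:
        raise ValueError("need more units than between-group levels")

    bases = {f: _orthonormal_basis(len(levels[f])) for f in within}
    results: list[AnovaResult] = []
    error_ss_total = 0.0
    pending: list[tuple] = []

    # between-subject stratum (unit-mean scores)
    u_all = np.ones((1, 1))
    for f in within:
        u_all = np.kron(u_all, bases[f][0])
    # Type-III SS use unweighted group means; n_h (harmonic mean group size)
    # replaces the per-group n, exact under balance.
    n_h = G / sum(1.0 / len(ix) for ix in gindex)
    z0 = (Y @ u_all).ravel()
    gmeans0 = np.array([z0[ix].mean() for ix in gindex])
    ss_err0 = float(sum(np.sum((z0[ix] - m) ** 2) for ix, m in zip(gindex, gmeans0)))
    error_ss_total += ss_err0
    if between:
        ss_b = float(n_h * np.sum((gmeans0 - gmeans0.mean()) ** 2))
        pending.append((between[0], ss_b, G - 1, ss_err0, N - G, 1.0))

    # within strata: one per nonempty subset of within factors
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            M = np.ones((1, 1))
            for f in within:
                M = np.kron(M, bases[f][1] if f in combo else bases[f][0])
            Z = Y @ M                       # N x d
            d = Z.shape[1]
            gmeans = np.vstack([Z[ix].mean(axis=0) for ix in gindex])
            umean = gmeans.mean(axis=0)     # unweighted mean of group means
            ss_w = float(n_h * G * np.sum(umean ** 2))
            ss_bw = float(n_h * np.sum((gmeans - umean) ** 2))
            resid = np.vstack([Z[ix] - gm for ix, gm in zip(gindex, gmeans)])
            ss_err = float(np.sum(resid ** 2))
            error_ss_total += ss_err
            S = resid.T @ resid / (N - G)   # pooled covariance in contrast space
            tr = float(np.trace(S))
            tr2 = float(np.trace(S @ S))
            eps = 1.0 if d == 1 or tr2 <= 0 else min(1.0, max(1.0 / d, tr * tr / (d * tr2)))
            name = ":".join(combo)
            pending.append((name, ss_w, d, ss_err, (N - G) * d, eps))
            if between:
                pending.append((f"{between[0]}:{name}", ss_bw, (G - 1) * d,
                                ss_err, (N - G) * d, eps))

    for name, ss, df1, ss_err, df2, eps in pending:
        ms_eff = ss / df1
        ms_err = ss_err / df2
        F = ms_eff / ms_err if ms_err > 0 else np.inf
        p = float(sps.f.sf(F, df1 * eps, df2 * eps))
        ges = ss / (ss + error_ss_total) if (ss + error_ss_total) > 0 else 0.0
        results.append(AnovaResult(
            effect=name, df_num=df1 * eps, df_den=df2 * eps, F=float(F), p=p,
            ges=float(ges), epsilon_gg=float(eps), df_num_raw=df1, df_den_raw=df2,
            ss_effect=float(ss), ss_error=float(ss_err)))
    return results


def anova_frame(results: list[AnovaResult]) -> pd.DataFrame:
    """Tabular view of ANOVA results in reporting field order."""
    return pd.DataFrame([{
        "effect": r.effect, "df_num": r.df_num, "df_den": r.df_den,
        "F": r.F, "p": r.p, "ges": r.ges, "epsilon_gg": r.epsilon_gg,
        "df_num_raw": r.df_num_raw, "df_den_raw": r.df_den_raw,
    } for r in results])


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k covariance of within-cell scores.

    ``eps = tr(CSC)^2 / ((k-1) tr((CSC)^2))`` with C the centering projector,
    clamped to [1/(k-1), 1].  Equals 1 under compound symmetry and reaches
    the lower bound for a rank-1 (maximally non-spherical) covariance.
    """
    S = np.asarray(cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need at least 2 within cells")
    eigvals = np.linalg.eigvalsh((S + S.T) / 2)
    if eigvals[0] < -1e-8 * max(1.0, abs(eigvals[-1])):
        raise ValueError("covariance is not positive semi-definite")
    C = np.eye(k) - np.ones((k, k)) / k
    A = C @ S @ C
    tr = float(np.trace(A))
    tr2 = float(np.trace(A @ A))
    if tr2 <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / (k - 1), tr * tr / ((k - 1) * tr2))))


# ---------------------------------------------------------------------------
# Follow-up contrasts
# ---------------------------------------------------------------------------

def _unit_scores(table: pd.DataFrame, dv: str, unit: str, level_col: str,
                 levels: list, weights: np.ndarray) -> pd.Series:
    wide = table.pivot_table(index=unit, columns=level_col, values=dv, aggfunc="mean")
    wide = wide.reindex(columns=levels)
    if wide.isna().any().any():
        raise ValueError(f"incomplete data over {level_col} levels {levels}")
    return wide @ weights


def linear_block_contrast(table: pd.DataFrame, task: str, dv: str = "value",
                          unit: str = "pair_id", block_col: str = "block",
                          weights: np.ndarray = LINEAR_WEIGHTS_4) -> ContrastResult:
    """Linear trend across learning blocks within one task.

    Per-unit score = sum of block means weighted by the orthogonal linear
    weights (-3, -1, 1, 3); a one-sample t-test of the scores against zero.
    Negative estimates mean the measure decreased (improved) across blocks.
    """
    sub = table[table["task"] == task]
    blocks = sorted(sub[block_col].unique())
    if len(blocks) != len(weights):
        raise ValueError(f"expected {len(weights)} block levels, got {blocks}")
    scores = _unit_scores(sub, dv, unit, block_col, blocks, np.asarray(weights, float))
    if len(scores) < 2:
        raise ValueError("need at least 2 units")
    t, p = sps.ttest_1samp(scores, 0.0)
    return ContrastResult(name=f"linear block trend ({task})",
                          estimate=float(scores.mean()), t=float(t),
                          df=len(scores) - 1, p=float(p))


def interaction_contrast(table: pd.DataFrame, dv: str = "value",
                         unit: str = "pair_id", block_col: str = "block",
                         weights: np.ndarray = LINEAR_WEIGHTS_4) -> ContrastResult:
    """Contrast of linear block contrasts between tasks (Individual - Joint).

    A positive t indicates a steeper decline (stronger learning trend) in the
    Joint than the Individual task.
    """
    per_task = {}
    for task in ("Individual", "Joint"):
        sub = table[table["task"] == task]
        if sub.empty:
            raise ValueError(f"task {task!r} missing from table")
        blocks = sorted(sub[block_col].unique())
        per_task[task] = _unit_scores(sub, dv, unit, block_col, blocks,
                                      np.asarray(weights, float))
    diff = (per_task["Individual"] - per_task["Joint"]).dropna()
    if len(diff) != len(per_task["Individual"]) or len(diff) != len(per_task["Joint"]):
        raise ValueError("a task is missing for some unit")
    t, p = sps.ttest_1samp(diff, 0.0)
    return ContrastResult(name="linear block trend: Individual - Joint",
                          estimate=float(diff.mean()), t=float(t),
                          df=len(diff) - 1, p=float(p))


def tukey_pairwise(table: pd.DataFrame, factor: str, by: str | None = None,
                   dv: str = "value", unit: str = "pair_id") -> list[ContrastResult]:
    """All pairwise within-unit comparisons of ``factor`` levels, Tukey-corrected.

    Each comparison uses its own paired-difference error (the multivariate
    formulation, robust to sphericity violations); the p-value comes from
    the studentized-range distribution with k = number of factor levels.
    """
    results: list[ContrastResult] = []
    by_levels = sorted(table[by].unique()) if by else [None]
    for b in by_levels:
        sub = table if b is None else table[table[by] == b]
        levels = sorted(sub[factor].unique())
        k = len(levels)
        if k < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels, got {levels}")
        wide = sub.pivot_table(index=unit, columns=factor, values=dv, aggfunc="mean")
        wide = wide.reindex(columns=levels).dropna()
        n = len(wide)
        for l1, l2 in itertools.combinations(levels, 2):
            d = wide[l1] - wide[l2]
            se = d.std(ddof=1) / np.sqrt(n)
            t = d.mean() / se if se > 0 else np.inf
            # Tukey HSD: q = |t| * sqrt(2) against the studentized range
            p = float(sps.studentized_range.sf(abs(t) * np.sqrt(2), k, n - 1))
            if k == 2:  # single comparison: plain paired t
                p = float(2 * sps.t.sf(abs(t), n - 1))
            tag = f"{factor} {l1} - {l2}" + (f" | {by}={b}" if b is not None else "")
            results.append(ContrastResult(name=tag, estimate=float(d.mean()),
                                          t=float(t), df=n - 1, p=p))
    return results


def within_subject_ci(table: pd.DataFrame, dv: str, within_cells: list[str],
                      unit: str = "pair_id", level: float = 0.95) -> pd.DataFrame:
    """Cousineau-Morey within-subject confidence intervals per design cell.

    Scores are subject-centered (each unit's mean removed, grand mean added)
    so between-unit offsets do not inflate the intervals, then the per-cell
    SD is multiplied by the Morey bias correction sqrt(J/(J-1)) for J within
    cells, and a t-based interval formed.
    """
    cells = table.groupby(within_cells, observed=True)
    J = cells.ngroups
    if J < 2:
        raise ValueError("within-subject CI undefined for a single cell (J=1)")
    counts = table.groupby([unit], observed=True)[dv].count()
    if counts.nunique() != 1 or counts.iloc[0] != J:
        raise ValueError("incomplete within data: every unit must appear in every cell")
    unit_means = table.groupby(unit)[dv].transform("mean")
    grand = table[dv].mean()
    centered = table[dv] - unit_means + grand
    work = table[within_cells].copy()
    work["_c"] = centered
    morey = np.sqrt(J / (J - 1))
    out = []
    for key, grp in work.groupby(within_cells, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        m = grp["_c"].mean()
        half = sps.t.ppf((1 + level) / 2, n - 1) * grp["_c"].std(ddof=1) * morey / np.sqrt(n)
        out.append(dict(zip(within_cells, key),
                        mean=float(table.loc[grp.index, dv].mean()),
                        ci_lo=float(m - half), ci_hi=float(m + half)))
    return pd.DataFrame(out)
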