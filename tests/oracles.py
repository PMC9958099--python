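"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the ANOVA oracle builds
the classical balanced decomposition by sequential orthogonal projection of
raw dummy design matrices; the outlier oracle re-evaluates the scaled-MAD
rule with explicit loops.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def projection_anova_oracle(Y: np.ndarray, groups: list[str],
                            level_counts: list[int]) -> dict[str, tuple]:
    """Balanced mixed ANOVA by sequential orthogonal projection.

    ``Y`` is units x cells with cells ordered factor-major in the order of
    ``level_counts`` (within factors); ``groups`` assigns each unit to a
    between level.  Returns {effect: (F, df_num, df_den, ges)} with effects
    named 'P', 'W0', 'P:W0', 'W1', 'P:W1', 'W0:W1', 'P:W0:W1' (for two
    within factors) etc.

    Each raw dummy block (grand mean, between, each within effect and its
    between interaction, then subject and subject-by-within blocks) is
    orthogonalized against everything before it; squared projections of the
    response give the sums of squares, SVD rank gives the df.  Under balance
    this equals the Type-III decomposition.
    """
    n_units = Y.shape[0]
    n_within = len(level_counts)
    y = Y.ravel()
    cells = [()]
    for lc in level_counts:
        cells = [c + (lvl,) for c in cells for lvl in range(lc)]
    rows = [(i, groups[i]) + c for i in range(n_units) for c in cells]
    cols = ["s", "p"] + [f"w{j}" for j in range(n_within)]
    df = pd.DataFrame(rows, columns=cols)

    def dummies(keys: list[str]) -> np.ndarray:
        codes = df.groupby(keys, sort=True).ngroup().to_numpy()
        return np.eye(codes.max() + 1)[codes]

    import itertools
    wnames = [f"w{j}" for j in range(n_within)]
    subsets = []
    for r in range(1, n_within + 1):
        subsets.extend(itertools.combinations(wnames, r))

    blocks: list[tuple[str, list[str]]] = [("mu", []), ("P", ["p"])]
    for sub in subsets:
        blocks.append((":".join(sub), list(sub)))
        blocks.append(("P:" + ":".join(sub), ["p"] + list(sub)))
    blocks.append(("S", ["s"]))
    for sub in subsets:
        blocks.append(("S:" + ":".join(sub), ["s"] + list(sub)))

    ss: dict[str, float] = {}
    dfs: dict[str, int] = {}
    Q = np.zeros((len(df), 0))
    for name, keys in blocks:
        X = np.ones((len(df), 1)) if not keys else dummies(keys)
        if Q.shape[1]:
            X = X - Q @ (Q.T @ X)
        u, sv, _ = np.linalg.svd(X, full_matrices=False)
        keep = sv > 1e-8 * (sv[0] if sv[0] > 0 else 1.0)
        q = u[:, keep]
        ss[name] = float(np.sum((q.T @ y) ** 2))
        dfs[name] = int(keep.sum())
        Q = np.hstack([Q, q])

    err_total = ss["S"] + sum(ss["S:" + ":".join(sub)] for sub in subsets)
    out: dict[str, tuple] = {}
    pairs = [("P", "S")]
    for sub in subsets:
        w = ":".join(sub)
        pairs += [(w, "S:" + w), ("P:" + w, "S:" + w)]
    for eff, err in pairs:
        F = (ss[eff] / dfs[eff]) / (ss[err] / dfs[err])
        out[eff] = (F, dfs[eff], dfs[err], ss[eff] / (ss[eff] + err_total))
    return out


def mad_outlier_oracle(values: np.ndarray, criterion: float = 3.0,
                       scale: float = 1.4826) -> np.ndarray:
    """Explicit-loop evaluation of the scaled-MAD outlier rule."""
    values = list(map(float, values))
    srt = sorted(values)
    n = len(srt)
    med = (srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2)
    devs = sorted(abs(v - med) for v in values)
    mad = (devs[n // 2] if n % 2 else (devs[n // 2 - 1] + devs[n // 2]) / 2)
    return np.array([abs(v - med) > criterion * scale * mad for v in values])


def gg_epsilon_eigen_oracle(cov: np.ndarray) -> float:
    """GG epsilon via the eigenvalues of the doubly centered covariance."""
    k = cov.shape[0]
    C = np.eye(k) - np.ones((k, k)) / k
    lam = np.linalg.eigvalsh(C @ cov @ C)
    lam = lam[lam > 1e-12 * max(1.0, lam.max())]
    eps = lam.sum() ** 2 / ((k - 1) * np.sum(lam ** 2))
    return float(min(1.0, max(1.0 / (k - 1), eps)))
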