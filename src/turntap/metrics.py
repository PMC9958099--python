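"""Dependent measures: ITI accuracy, precision, lag autocorrelations, and
ITI-contrast profiles, plus trial -> block -> unit aggregation.

Accuracy is mean absolute percent deviation from the 500 ms target interval,
``mean(|target - ITI| / target) * 100``.  Precision is the coefficient of
variation ``SD(ITI)/mean(ITI)`` per trial.  Rhythmicity is captured by the
sample autocorrelation of the linearly detrended series at lags 1, 2 and 4
— lag 1 indexes long-short alternation, lags 2 and 4 the turn interval and
full turn cycle of an A-A-B-B schedule — and by ITI contrasts, a per-position
code of whether the direction of durational change between successive ITIs
matches the trial's first change (1), opposes it (0), or is absent (0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from turntap.preprocess import detrend_linear

TARGET_MS = 500.0
DEFAULT_LAGS = (1, 2, 4)
SIGN_TOL_MS = 0.5  # durational changes below MIDI timing resolution count as "no change"

MEASURES = ("accuracy_pct", "cv", "acf_lag1", "acf_lag2", "acf_lag4")


def accuracy_pct(itis: np.ndarray, target_ms: float = TARGET_MS) -> float:
    """Mean absolute percent deviation from the target interval (NaN-aware)."""
    x = np.asarray(itis, dtype=float)
    if np.all(np.isnan(x)) or len(x) == 0:
        raise ValueError("accuracy undefined: no non-missing ITIs")
    return float(np.nanmean(np.abs(target_ms - x) / target_ms) * 100.0)


def cv_iti(itis: np.ndarray, ddof: int = 1) -> float:
    """Coefficient of variation SD/mean of a trial's non-missing ITIs.

    Sample SD (N-1 denominator) by default; configurable via ``ddof``.
    """
    x = np.asarray(itis, dtype=float)
    n = int(np.sum(~np.isnan(x)))
    if n < 2:
        raise ValueError(f"CV needs >= 2 non-missing ITIs, got {n}")
    return float(np.nanstd(x, ddof=ddof) / np.nanmean(x))


def acf_at_lags(itis: np.ndarray, lags: tuple[int, ...] = DEFAULT_LAGS,
                detrend: bool = True, unbiased: bool = False) -> dict[int, float]:
    """Sample autocorrelation of the (detrended, mean-removed) ITI series.

    ``r_k = sum_{t<=N-k} x_t x_{t+k} / sum_t x_t^2`` — the biased
    (divide-by-N) estimator standard in econometrics toolboxes, which keeps
    every r_k in [-1, 1].  ``unbiased=True`` rescales each numerator term by
    N/(N-k).  Outlier ITIs must be retained upstream: the estimator assumes
    an unbroken series.
    """
    x = np.asarray(itis, dtype=float)
    if np.any(np.isnan(x)):
        raise ValueError("autocorrelation requires a complete (outlier-retained) series")
    if len(x) < max(lags) + 2:
        raise ValueError(f"series of length {len(x)} too short for lag {max(lags)}")
    if detrend:
        x = detrend_linear(x)
    x = x - x.mean()
    denom = float(np.sum(x * x))
    n = len(x)
    # a (near-)constant input leaves only detrending round-off; treat the
    # series as having zero variance rather than correlating noise
    scale = float(np.max(np.abs(np.asarray(itis, dtype=float)))) or 1.0
    if denom <= n * (1e-9 * scale) ** 2:
        return {k: 0.0 for k in lags}
    out: dict[int, float] = {}
    for k in lags:
        num = float(np.sum(x[:-k] * x[k:]))
        if unbiased:
            num *= n / (n - k)
        out[k] = num / denom if denom > 0 else 0.0
    return out


def _change_sign(d: float, tol: float) -> int:
    if abs(d) < tol:
        return 0
    return 1 if d > 0 else -1


def trial_contrasts(itis: np.ndarray, sign_tol_ms: float = SIGN_TOL_MS) -> np.ndarray:
    """Code the direction of durational change between successive ITIs.

    With ``d_k = ITI_{k+1} - ITI_k``: the first contrast is 1 by definition;
    each later position is 1 if its change has the same sign as the trial's
    reference direction, 0 if opposite, and 0.5 if there is no change.  The
    reference direction is sign(d_1), or — when d_1 itself is a tie — the
    first nonzero change; a trial with no durational change at all codes 0.5
    everywhere after the first position.
    """
    x = np.asarray(itis, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need >= 3 ITIs for contrasts, got {len(x)}")
    d = np.diff(x)
    signs = np.array([_change_sign(v, sign_tol_ms) for v in d])
    nonzero = signs[signs != 0]
    ref = int(nonzero[0]) if len(nonzero) else 0
    out = np.empty(len(d), dtype=float)
    out[0] = 1.0
    for k in range(1, len(d)):
        if signs[k] == 0 or ref == 0:
            out[k] = 0.5
        else:
            out[k] = 1.0 if signs[k] == ref else 0.0
    return out


@dataclass
class ContrastProfile:
    """Mean ITI-contrast per sequence position with distance to the
    perfect-rhythmicity exemplar (the alternating 1,0,1,0,... profile of a
    series with lag-1 autocorrelation magnitude 1)."""

    positions: np.ndarray     # 1-based contrast positions
    mean_contrast: np.ndarray
    exemplar: np.ndarray
    distance: np.ndarray      # elementwise |mean - exemplar| (Manhattan)
    n_trials: int

    def reported(self) -> pd.DataFrame:
        """Positions 2..end — position 1 is the defined constant 1."""
        df = pd.DataFrame({
            "position": self.positions, "mean_contrast": self.mean_contrast,
            "exemplar": self.exemplar, "distance": self.distance,
        })
        return df[df["position"] >= 2].reset_index(drop=True)


def contrast_profile(trial_contrast_vectors: list[np.ndarray]) -> ContrastProfile:
    """Average contrast vectors across trials and compare to the exemplar."""
    if not trial_contrast_vectors:
        raise ValueError("need at least one trial")
    lengths = {len(v) for v in trial_contrast_vectors}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent trial contrast lengths: {sorted(lengths)}")
    stack = np.vstack(trial_contrast_vectors)
    mean = stack.mean(axis=0)
    npos = stack.shape[1]
    exemplar = np.array([1.0 if k % 2 == 0 else 0.0 for k in range(npos)])
    return ContrastProfile(
        positions=np.arange(1, npos + 1),
        mean_contrast=mean,
        exemplar=exemplar,
        distance=np.abs(mean - exemplar),
        n_trials=stack.shape[0],
    )


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Two-stage aggregation of trial-level measures to the analysis unit.

    ``records`` is long-format with columns pair_id, subject_id, task, block,
    predictability, trial_index, measure, value.  Trial values are averaged
    within each producing unit x task x block cell, then Individual partner
    means are averaged within pair, so one row per pair x task x block x
    measure remains (the pair is the grouping unit throughout the inference
    layer).  Averaging is NaN-aware; an empty cell is an error naming the
    cell.
    """
    required = {"pair_id", "subject_id", "task", "block", "predictability",
                "trial_index", "measure", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")

    # stage 1: trials -> producing-unit block means
    unit_cols = ["pair_id", "subject_id", "task", "block", "predictability", "measure"]
    stage1 = (records.groupby(unit_cols, dropna=False)["value"]
              .mean().reset_index())

    # stage 2: Individual partners -> pair mean; Joint rows pass through
    pair_cols = ["pair_id", "task", "block", "predictability", "measure"]
    out = stage1.groupby(pair_cols, dropna=False)["value"].mean().reset_index()

    bad = out[out["value"].isna()]
    if not bad.empty:
        cell = bad.iloc[0]
        raise ValueError(
            f"no surviving trial values for cell pair={cell.pair_id} "
            f"task={cell.task} block={cell.block} measure={cell.measure}")
    return out
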