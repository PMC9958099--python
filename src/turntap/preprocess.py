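"""From keystroke streams to validated, outlier-annotated ITI series.

Stages, in the order the pipeline applies them:

1. :func:`compute_itis` — successive differences of tap onsets, with a
   per-interval *resolver* label recording which performer(s) produced each
   interval ("A"/"B" within a turn, "AB" across a turn transition).
2. :func:`validate_turn_pattern` / :func:`exclude_trials` — Joint trials in
   which the pair broke the instructed turn schedule (strict A-B alternation
   or the A-A-B-B cycle) are excluded, as are trials flagged during
   acquisition.
3. :func:`flag_outliers` — ITIs pooled per producing unit (subject for
   Individual, pair for Joint) and task across all blocks form one
   distribution; values more than 3 *scaled* median absolute deviations from
   its median are flagged.  The scale factor 1.4826 makes the MAD a
   consistent estimator of the SD under normality.
4. :func:`apply_mask_for_measure` — accuracy/precision computations skip
   flagged ITIs (replaced by NaN); autocorrelation and contrast computations
   keep the raw series intact, because they depend on unbroken serial
   structure.
5. :func:`detrend_linear` — removes a least-squares linear trend, so slow
   tempo drift does not masquerade as long-lag autocorrelation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from turntap.types import TapEvent, Trial, TrialMeta

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # normal-consistency factor for the scaled MAD
MAD_CRITERION = 3.0

ACCURACY_LIKE = ("accuracy", "precision")
SERIAL_LIKE = ("autocorrelation", "contrast")


@dataclass
class ITISeries:
    """Per-trial ordered inter-tap intervals with outlier annotations."""

    meta: TrialMeta
    itis_ms: np.ndarray
    resolver: list[str]
    outlier_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.itis_ms = np.asarray(self.itis_ms, dtype=float)
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros(len(self.itis_ms), dtype=bool)
        self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        if len(self.outlier_mask) != len(self.itis_ms):
            raise ValueError("outlier mask length must match series length")
        if len(self.resolver) != len(self.itis_ms):
            raise ValueError("resolver length must match series length")
        if np.any(self.itis_ms <= 0):
            raise ValueError(f"trial {self.meta.key}: non-positive ITI "
                             "(simultaneous or duplicate events)")


def compute_itis(events: list[TapEvent], meta: TrialMeta) -> ITISeries:
    """Successive onset differences for one trial.

    ``itis_ms[k] = time[k+1] - time[k]``; ``resolver[k]`` is the producing
    performer when taps k and k+1 share one, else "AB".  A 16-tap trial
    yields 15 intervals.
    """
    if len(events) < 2:
        raise ValueError(f"trial {meta.key}: need at least 2 events to form an ITI")
    times = np.array([e.time_ms for e in events], dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError(f"trial {meta.key}: events not sorted by time")
    itis = np.diff(times)
    resolver = [
        a.performer if a.performer == b.performer else "AB"
        for a, b in zip(events, events[1:])
    ]
    return ITISeries(meta=meta, itis_ms=itis, resolver=resolver)


def turn_template(turn_pattern: str, starting_performer: str, n_taps: int) -> list[str]:
    """Expected performer of each tap under a turn schedule."""
    other = "B" if starting_performer == "A" else "A"
    if turn_pattern == "AB":
        cycle = [starting_performer, other]
    elif turn_pattern == "AABB":
        cycle = [starting_performer, starting_performer, other, other]
    else:
        raise ValueError(f"turn validation not applicable to pattern {turn_pattern!r}")
    return [cycle[i % len(cycle)] for i in range(n_taps)]


def validate_turn_pattern(events: list[TapEvent], turn_pattern: str,
                          starting_performer: str | None = None) -> tuple[bool, int | None]:
    """Check a Joint event stream against its instructed turn schedule.

    Returns ``(valid, first_violation_index)``.  When ``starting_performer``
    is None (starts were counterbalanced and may be unrecorded) the template
    is rooted at the observed first tap.
    """
    observed = [e.performer for e in events]
    start = starting_performer if starting_performer is not None else observed[0]
    template = turn_template(turn_pattern, start, len(observed))
    for i, (got, want) in enumerate(zip(observed, template)):
        if got != want:
            return False, i
    return True, None


def exclude_trials(dataset: list[Trial],
                   strict_start: bool = True) -> tuple[list[Trial], pd.DataFrame]:
    """Drop invalid trials; return the retained dataset and an exclusion report.

    Removed: any trial with ``flagged_online``, and Joint trials whose
    performer sequence violates the instructed turn pattern.  The report
    counts exclusions per pair and task with reasons.  With
    ``strict_start=False`` either starting performer is accepted.
    """
    kept: list[Trial] = []
    records: list[dict] = []
    for trial in dataset:
        meta = trial.meta
        reason = None
        if meta.flagged_online:
            reason = "flagged_online"
        elif meta.task == "Joint":
            start = meta.starting_performer if strict_start else None
            valid, idx = validate_turn_pattern(trial.events, meta.turn_pattern, start)
            if not valid:
                reason = f"turn_violation_at_{idx}"
        if reason is None:
            kept.append(trial)
        else:
            logger.info("excluding trial %s: %s", meta.key, reason)
            records.append({"pair_id": meta.pair_id, "task": meta.task,
                            "block": meta.block, "trial_index": meta.trial_index,
                            "subject_id": meta.subject_id, "reason": reason})
    report = pd.DataFrame(records, columns=["pair_id", "task", "block",
                                            "trial_index", "subject_id", "reason"])
    return kept, report


def _pooling_key(meta: TrialMeta) -> tuple:
    # within-subject for Individual, within-pair for Joint
    if meta.task == "Individual":
        return (meta.pair_id, meta.subject_id, meta.task)
    return (meta.pair_id, None, meta.task)


def scaled_mad_outliers(values: np.ndarray, criterion: float = MAD_CRITERION,
                        scale: float = MAD_SCALE) -> np.ndarray:
    """Boolean mask of values strictly more than ``criterion`` scaled MADs
    from the median.  With MAD = 0 every value unequal to the median is
    flagged (the threshold degenerates to zero)."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    return np.abs(values - med) > criterion * scale * mad


def flag_outliers(series_list: list[ITISeries], criterion: float = MAD_CRITERION,
                  scale: float = MAD_SCALE) -> list[ITISeries]:
    """Fill every series' outlier mask from its unit x task pooled distribution.

    ITIs are aggregated across all blocks and trials of a producing unit
    (subject for Individual, pair for Joint) within task; the scaled-MAD rule
    is applied once to that pooled distribution and the mask written back to
    each trial.  Pooling is a pure function of the group, so processing order
    cannot change the result.  Masks are modified in place and the list is
    returned for convenience.
    """
    groups: dict[tuple, list[ITISeries]] = {}
    for s in series_list:
        groups.setdefault(_pooling_key(s.meta), []).append(s)
    for key, members in groups.items():
        pooled = np.concatenate([s.itis_ms for s in members])
        if len(pooled) < 3:
            raise ValueError(f"unit {key}: pooled ITI distribution too small "
                             f"({len(pooled)} values) for outlier detection")
        mask = scaled_mad_outliers(pooled, criterion=criterion, scale=scale)
        pos = 0
        for s in members:
            n = len(s.itis_ms)
            s.outlier_mask = mask[pos:pos + n].copy()
            if s.outlier_mask.any():
                logger.info("trial %s: %d outlier ITI(s) flagged",
                            s.meta.key, int(s.outlier_mask.sum()))
            pos += n
    return series_list


def apply_mask_for_measure(series: ITISeries, measure_kind: str) -> np.ndarray:
    """Working copy of a trial's ITIs appropriate to a measure.

    Accuracy/precision: flagged ITIs become NaN and downstream averaging is
    NaN-aware.  Autocorrelation/contrast: the raw series is returned intact,
    preserving serial dependencies.
    """
    if measure_kind in ACCURACY_LIKE:
        out = series.itis_ms.astype(float).copy()
        out[series.outlier_mask] = np.nan
        if np.all(np.isnan(out)):
            logger.warning("trial %s: all ITIs flagged; contributes nothing to %s",
                           series.meta.key, measure_kind)
        return out
    if measure_kind in SERIAL_LIKE:
        return series.itis_ms.astype(float).copy()
    raise ValueError(f"unknown measure kind {measure_kind!r}")


def detrend_linear(itis: np.ndarray) -> np.ndarray:
    """Remove the ordinary-least-squares line of ITI on position index.

    The result has zero mean and zero linear component; applying the
    operation twice is a no-op (projection idempotence).
    """
    x = np.asarray(itis, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need >= 3 intervals to detrend, got {len(x)}")
    idx = np.arange(len(x), dtype=float)
    slope, intercept = np.polyfit(idx, x, 1)
    return x - (slope * idx + intercept)
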