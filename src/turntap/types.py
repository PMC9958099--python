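"""Core domain types: keystroke events and trial metadata."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

PERFORMERS = ("A", "B")
TASKS = ("Individual", "Joint")
TURN_PATTERNS = ("SOLO", "AB", "AABB")
PREDICTABILITY = ("Predictable", "Random", "NA")


@dataclass(frozen=True)
class TapEvent:
    """One keystroke: onset time (ms from trial start), MIDI pitch/velocity,
    and which performer produced it."""

    time_ms: float
    pitch: int
    velocity: int
    performer: str

    def __post_init__(self) -> None:
        if self.time_ms < 0:
            raise ValueError(f"time_ms must be >= 0, got {self.time_ms}")
        if not 0 <= self.pitch <= 127:
            raise ValueError(f"pitch must be in 0..127, got {self.pitch}")
        if not 0 <= self.velocity <= 127:
            raise ValueError(f"velocity must be in 0..127, got {self.velocity}")
        if self.performer not in PERFORMERS:
            raise ValueError(f"performer must be one of {PERFORMERS}, got {self.performer!r}")


@dataclass(frozen=True)
class TrialMeta:
    """Identity and design-cell metadata for one test trial.

    ``subject_id`` identifies the tapping partner for Individual (solo)
    trials and is None for Joint trials, where the pair is the producing
    unit.  ``flagged_online`` marks trials the experimenter flagged during
    acquisition (technical error, instructions not followed).
    """

    pair_id: str
    subject_id: str | None
    task: str
    block: int
    trial_index: int
    predictability: str = "NA"
    turn_pattern: str = "SOLO"
    starting_performer: str = "A"
    flagged_online: bool = False

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task label {self.task!r}")
        if self.turn_pattern not in TURN_PATTERNS:
            raise ValueError(f"unknown turn pattern {self.turn_pattern!r}")
        if self.predictability not in PREDICTABILITY:
            raise ValueError(f"unknown predictability {self.predictability!r}")
        if not 1 <= self.block:
            raise ValueError(f"block must be >= 1, got {self.block}")
        if self.trial_index < 1:
            raise ValueError(f"trial_index must be >= 1, got {self.trial_index}")
        if self.starting_performer not in PERFORMERS:
            raise ValueError(f"starting_performer must be A or B")
        if self.task == "Individual":
            if self.turn_pattern != "SOLO":
                raise ValueError("Individual trials must have turn_pattern SOLO")
            if self.subject_id is None:
                raise ValueError("Individual trials require a subject_id")
        else:
            if self.turn_pattern == "SOLO":
                raise ValueError("Joint trials require turn_pattern AB or AABB")

    @property
    def key(self) -> tuple:
        """Hashable identity of the trial within a dataset."""
        return (self.pair_id, self.subject_id, self.task, self.block, self.trial_index)


@dataclass
class Trial:
    """A trial: metadata plus its time-ordered keystroke events."""

    meta: TrialMeta
    events: list[TapEvent] = field(default_factory=list)

    def validate(self) -> None:
        times = [e.time_ms for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"trial {self.meta.key}: events not sorted by time")


META_FIELDS = [f.name for f in fields(TrialMeta)]
EVENT_FIELDS = [f.name for f in fields(TapEvent)]
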