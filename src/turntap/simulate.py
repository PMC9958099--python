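"""Synthetic dyadic-tapping generator and stimulus-sequence algorithms.

The tapping model is the two-level timekeeper-plus-motor account of paced
tapping with first-order phase correction: tap onsets are

    t_{n+1} = t_n + T_n + M_{n+1} - M_n - alpha * (I_{n-1} - target) + drift

with central timekeeper intervals ``T ~ N(mu, sigma_t^2)`` and peripheral
motor delays ``M ~ N(0, sigma_m^2)``.  Without correction or drift this
implies ITI variance ``sigma_t^2 + 2 sigma_m^2`` and lag-1 autocovariance
``-sigma_m^2`` — the motor-noise signature of slightly negative lag-1
autocorrelation in solo tapping.

Joint trials run the same recurrence on the single merged tap stream: each
tap is produced by the scheduled partner's timekeeper relative to the
previous tap (whoever made it), with that partner's motor delay, and phase
correction toward the cued 500 ms target.  A between-partner tempo mismatch
(mu_A != mu_B) then produces alternating short-long intervals under an
A-B schedule (negative lag-1 autocorrelation) and a period-4 interval
pattern under A-A-B-B (positive lag-4 autocorrelation) — the rhythmicity
signatures of turn-taking.  Rare outlier taps are modeled as hesitations: a
delayed onset that lengthens exactly one interval.  Block-wise learning
scales the noise SDs and the tempo mismatch down across learning blocks.

Stimulus sequences: two pre-composed predictable pentatonic melodies
(original and retrograde) and a random generator that draws uniform
scale-degree sequences and prunes those with immediate pitch repeats or
incomplete scale coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from turntap.preprocess import turn_template
from turntap.types import TapEvent, Trial, TrialMeta

TARGET_MS = 500.0
N_TAPS = 16

# scale degree (1..5) -> MIDI pitch, C-major pentatonic
DEGREE_TO_MIDI = {1: 60, 2: 62, 3: 64, 4: 67, 5: 69}
PENTATONIC = tuple(DEGREE_TO_MIDI.values())

# C4 D4 E4 A4 G4 E4 D4 C4 D4 E4 G4 E4 D4 E4 D4 C4
_PREDICTABLE = (60, 62, 64, 69, 67, 64, 62, 60, 62, 64, 67, 64, 62, 64, 62, 60)


@dataclass(frozen=True)
class PitchSequence:
    """A 16-note pentatonic stimulus sequence."""

    pitches: tuple[int, ...]
    kind: str  # "Predictable" | "Random"

    def __post_init__(self) -> None:
        if len(self.pitches) != N_TAPS:
            raise ValueError(f"sequence must have {N_TAPS} pitches")
        if any(p not in PENTATONIC for p in self.pitches):
            raise ValueError("pitches must come from the C-major pentatonic set")


def predictable_sequences() -> tuple[PitchSequence, PitchSequence]:
    """The pre-composed predictable melody and its retrograde."""
    original = PitchSequence(pitches=_PREDICTABLE, kind="Predictable")
    retro = PitchSequence(pitches=tuple(reversed(_PREDICTABLE)), kind="Predictable")
    return original, retro


def analytic_survivor_rate(n_positions: int = N_TAPS, n_symbols: int = 5) -> float:
    """Probability that a uniform random degree sequence survives pruning.

    Inclusion-exclusion over the alphabet: the number of length-L sequences
    over exactly <= j symbols with no immediate repeat is j*(j-1)^(L-1), so
    the count with no repeat AND full coverage is
    sum_j (-1)^(s-j) C(s,j) j (j-1)^(L-1), divided by s^L candidates.
    (The additional note-by-note rejection against the two fixed predictable
    melodies removes at most 2 specific sequences and is negligible.)
    """
    s, L = n_symbols, n_positions
    count = sum((-1) ** (s - j) * math.comb(s, j) * j * (j - 1) ** (L - 1)
                for j in range(1, s + 1))
    return count / s ** L


def generate_random_sequences(n_candidates: int = 10_000,
                              seed: int | np.random.Generator | None = None
                              ) -> list[PitchSequence]:
    """Draw uniform pentatonic degree sequences and prune.

    Pruning removes sequences with the same pitch twice in a row, sequences
    missing any of the five scale degrees, and (note-by-note) any sequence
    identical to either pre-composed predictable melody.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    degrees = rng.integers(1, 6, size=(n_candidates, N_TAPS))
    no_repeat = np.all(degrees[:, 1:] != degrees[:, :-1], axis=1)
    full_cover = np.array([len(np.unique(row)) == 5 for row in degrees])
    forbidden = {p.pitches for p in predictable_sequences()}
    out = []
    for row in degrees[no_repeat & full_cover]:
        pitches = tuple(DEGREE_TO_MIDI[int(d)] for d in row)
        if pitches in forbidden:
            continue
        out.append(PitchSequence(pitches=pitches, kind="Random"))
    return out


# ---------------------------------------------------------------------------
# Tapping model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimekeeperParams:
    """Two-level timing parameters for one performer.

    mu_ms: mean timekeeper interval (the performer's natural tempo);
    sigma_t_ms / sigma_m_ms: timekeeper and motor-delay noise SDs;
    alpha: first-order phase-correction gain toward the cued target;
    drift_ms_per_tap: linear period drift; outlier_rate / outlier_shift_ms:
    probability and size of hesitation outliers (one lengthened interval).
    """

    mu_ms: float = TARGET_MS
    sigma_t_ms: float = 20.0
    sigma_m_ms: float = 10.0
    alpha: float = 0.15
    drift_ms_per_tap: float = 0.3
    outlier_rate: float = 0.02
    outlier_shift_ms: float = 250.0

    def __post_init__(self) -> None:
        if self.mu_ms <= 0:
            raise ValueError("mu_ms must be positive")
        if self.sigma_t_ms < 0 or self.sigma_m_ms < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must be in [0, 1)")

    def scaled(self, mult: float, target_ms: float = TARGET_MS) -> "TimekeeperParams":
        """Learning: shrink noise and tempo mismatch by a block multiplier."""
        return replace(self,
                       mu_ms=target_ms + (self.mu_ms - target_ms) * mult,
                       sigma_t_ms=self.sigma_t_ms * mult,
                       sigma_m_ms=self.sigma_m_ms * mult)


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic turn-taking experiment.

    The defaults are the study conditions of the target design: 16-tap
    trials at a 500 ms cued interval, 9 test trials in each of 4 learning
    blocks, Individual (solo) and Joint production, with block multipliers
    shrinking noise and tempo mismatch across blocks (learning).
    ``tempo_sd_ms`` is the between-subject SD of natural-tempo offsets from
    the target; ``transition_offset_ms`` is an extra duration on Joint
    between-turn intervals (handing over a turn takes slightly longer than
    continuing one's own).
    """

    n_pairs: int = 12
    turn_pattern: str = "AB"
    predictability: str = "split"   # "split" (study 1) | "random_only" (study 2)
    n_taps: int = N_TAPS
    n_trials: int = 9
    n_blocks: int = 4
    target_ms: float = TARGET_MS
    learning_schedule: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7)
    tempo_sd_ms: float = 25.0
    transition_offset_ms: float = 10.0
    base_params: TimekeeperParams = field(default_factory=TimekeeperParams)
    seed: int = 0
    # planted defects for pipeline testing: trial keys (pair_id, task, block,
    # trial_index) for turn violations; outlier plants add (interval_index, shift)
    planted_violations: list[tuple] = field(default_factory=list)
    planted_outliers: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_taps < 4:
            raise ValueError("need at least 4 taps per trial")
        if len(self.learning_schedule) != self.n_blocks:
            raise ValueError("learning_schedule must have one multiplier per block")
        sched = self.learning_schedule
        if any(m <= 0 for m in sched) or any(b > a for a, b in zip(sched, sched[1:])):
            raise ValueError("schedule multipliers must be positive and non-increasing")
        if self.turn_pattern not in ("AB", "AABB"):
            raise ValueError("turn_pattern must be AB or AABB")
        if self.predictability not in ("split", "random_only"):
            raise ValueError("predictability must be 'split' or 'random_only'")


def _intervals(producers: list[TimekeeperParams],
               motor_params: list[TimekeeperParams], performer_of: list[str],
               n_taps: int, target_ms: float, rng: np.random.Generator,
               transition_offset_ms: float = 0.0,
               planted_outliers: list[tuple[int, float]] | None = None) -> np.ndarray:
    """Core recurrence over the merged tap stream.

    ``producers[k]`` supplies the timekeeper for the interval ending at tap
    k+1; ``motor_params[k]`` supplies the motor-delay SD of tap k's own
    performer.
    """
    motor = np.array([rng.normal(0.0, motor_params[k].sigma_m_ms)
                      for k in range(n_taps)])
    plants = dict(planted_outliers or [])
    itis = np.empty(n_taps - 1)
    prev_iti = target_ms
    for k in range(n_taps - 1):
        p = producers[k]
        t_k = rng.normal(p.mu_ms, p.sigma_t_ms)
        if rng.random() < p.outlier_rate:
            t_k += p.outlier_shift_ms   # hesitation: one lengthened interval
        if k in plants:
            t_k += plants[k]
        iti = (t_k + motor[k + 1] - motor[k]
               - p.alpha * (prev_iti - target_ms)
               + p.drift_ms_per_tap * k)
        if performer_of[k + 1] != performer_of[k]:
            iti += transition_offset_ms
        itis[k] = iti
        prev_iti = iti
    if np.any(itis <= 0):  # pathological parameterizations only
        raise ValueError("simulated non-positive ITI; reduce noise or outlier shift")
    return itis


def _events_from_itis(itis: np.ndarray, performer_of: list[str],
                      pitches: tuple[int, ...], rng: np.random.Generator) -> list[TapEvent]:
    onsets = np.concatenate([[0.0], np.cumsum(itis)])
    velocities = rng.integers(60, 101, size=len(onsets))
    return [TapEvent(time_ms=float(t), pitch=int(pitches[i % len(pitches)]),
                     velocity=int(velocities[i]), performer=performer_of[i])
            for i, t in enumerate(onsets)]


def simulate_individual_trial(params: TimekeeperParams, rng: np.random.Generator,
                              n_taps: int = N_TAPS, target_ms: float = TARGET_MS,
                              performer: str = "A",
                              pitches: tuple[int, ...] | None = None,
                              planted_outliers: list[tuple[int, float]] | None = None
                              ) -> list[TapEvent]:
    """One solo trial: a single performer's two-level timekeeper stream."""
    if pitches is None:
        pitches = _PREDICTABLE
    performer_of = [performer] * n_taps
    itis = _intervals([params] * (n_taps - 1), [params] * n_taps, performer_of,
                      n_taps, target_ms, rng, planted_outliers=planted_outliers)
    return _events_from_itis(itis, performer_of, pitches, rng)


def simulate_joint_trial(params_a: TimekeeperParams, params_b: TimekeeperParams,
                         turn_pattern: str, rng: np.random.Generator,
                         n_taps: int = N_TAPS, target_ms: float = TARGET_MS,
                         starting_performer: str = "A",
                         transition_offset_ms: float = 0.0,
                         pitches: tuple[int, ...] | None = None,
                         planted_outliers: list[tuple[int, float]] | None = None
                         ) -> list[TapEvent]:
    """One joint trial on the merged stream under an AB or AABB schedule."""
    if pitches is None:
        pitches = _PREDICTABLE
    performer_of = turn_template(turn_pattern, starting_performer, n_taps)
    by = {"A": params_a, "B": params_b}
    producers = [by[performer_of[k + 1]] for k in range(n_taps - 1)]
    motor_params = [by[lab] for lab in performer_of]
    itis = _intervals(producers, motor_params, performer_of, n_taps, target_ms,
                      rng, transition_offset_ms=transition_offset_ms,
                      planted_outliers=planted_outliers)
    return _events_from_itis(itis, performer_of, pitches, rng)


def _draw_subject_params(config: SimulationConfig, rng: np.random.Generator
                         ) -> TimekeeperParams:
    offset = rng.normal(0.0, config.tempo_sd_ms)
    return replace(config.base_params, mu_ms=config.target_ms + offset)


def simulate_experiment(config: SimulationConfig
                        ) -> tuple[list[Trial], dict]:
    """Generate a full synthetic experiment.

    For each pair: two solo streams (one per partner) and one joint stream,
    ``n_trials`` trials per block, block multipliers applied to noise and
    tempo mismatch, starting performer alternating across blocks.  Returns
    the dataset and a plant manifest recording exactly which trials carry
    deliberate turn-pattern violations / outlier ITIs (ground truth for
    pipeline testing).  Identical config (including seed) reproduces the
    dataset exactly.
    """
    rng = np.random.default_rng(config.seed)
    violations = {tuple(v) for v in config.planted_violations}
    outlier_plants: dict[tuple, list[tuple[int, float]]] = {}
    for plant in config.planted_outliers:
        key, spec = tuple(plant[:4]), (int(plant[4]), float(plant[5]))
        outlier_plants.setdefault(key, []).append(spec)
    manifest = {"violations": sorted(violations),
                "outliers": sorted((k, *s) for k, specs in outlier_plants.items()
                                   for s in specs),
                "seed": config.seed}

    sequences = {"Predictable": predictable_sequences()[0], "Random": None}
    dataset: list[Trial] = []
    for p in range(config.n_pairs):
        pair_id = f"pair{p + 1:02d}"
        if config.predictability == "split":
            pred = "Predictable" if p < config.n_pairs // 2 else "Random"
        else:
            pred = "Random"
        partner = {"A": _draw_subject_params(config, rng),
                   "B": _draw_subject_params(config, rng)}
        for block in range(1, config.n_blocks + 1):
            mult = config.learning_schedule[block - 1]
            scaled = {lab: prm.scaled(mult, config.target_ms)
                      for lab, prm in partner.items()}
            start = "A" if block % 2 == 1 else "B"
            for trial_index in range(1, config.n_trials + 1):
                if pred == "Predictable":
                    pitches = sequences["Predictable"].pitches
                else:
                    pitches = tuple(rng.choice(PENTATONIC, size=config.n_taps))
                # solo trials, one per partner
                for lab in ("A", "B"):
                    meta = TrialMeta(
                        pair_id=pair_id, subject_id=f"{pair_id}{lab}",
                        task="Individual", block=block, trial_index=trial_index,
                        predictability=pred, turn_pattern="SOLO",
                        starting_performer=lab,
                        flagged_online=(pair_id, "Individual", block,
                                        trial_index) in violations and lab == "A")
                    key = (pair_id, "Individual", block, trial_index)
                    events = simulate_individual_trial(
                        scaled[lab], rng, n_taps=config.n_taps,
                        target_ms=config.target_ms, performer=lab, pitches=pitches,
                        planted_outliers=outlier_plants.get(key) if lab == "A" else None)
                    dataset.append(Trial(meta=meta, events=events))
                # joint trial
                key = (pair_id, "Joint", block, trial_index)
                meta = TrialMeta(
                    pair_id=pair_id, subject_id=None, task="Joint", block=block,
                    trial_index=trial_index, predictability=pred,
                    turn_pattern=config.turn_pattern, starting_performer=start,
                    flagged_online=False)
                events = simulate_joint_trial(
                    scaled["A"], scaled["B"], config.turn_pattern, rng,
                    n_taps=config.n_taps, target_ms=config.target_ms,
                    starting_performer=start,
                    transition_offset_ms=config.transition_offset_ms,
                    pitches=pitches, planted_outliers=outlier_plants.get(key))
                if key in violations:
                    events = _break_turn_pattern(events)
                dataset.append(Trial(meta=meta, events=events))
    return dataset, manifest


def _break_turn_pattern(events: list[TapEvent]) -> list[TapEvent]:
    """Plant a turn violation: swap the performer labels of taps 2 and 3."""
    out = list(events)
    for i, j in [(2, 3)]:
        out[i] = replace(out[i], performer=events[j].performer)
        out[j] = replace(out[j], performer=events[i].performer)
    return out


# ---------------------------------------------------------------------------
# Two-level model moment estimator (simulator recovery oracle)
# ---------------------------------------------------------------------------

def wk_estimate(itis: np.ndarray) -> tuple[float, float]:
    """Moment estimate of (sigma_t^2, sigma_m^2) from one uncoupled solo series.

    Uses the autocovariance identities gamma_0 = sigma_t^2 + 2 sigma_m^2 and
    gamma_1 = -sigma_m^2; negative moment solutions clamp to zero.
    """
    x = np.asarray(itis, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 intervals")
    g0, g1 = _gammas([x - x.mean()])
    return max(0.0, g0 + 2 * g1), max(0.0, -g1)


def wk_estimate_pooled(series: list[np.ndarray]) -> tuple[float, float]:
    """Pooled moment estimate across many independent trials of one performer.

    Deviations are taken from the grand mean across trials (per-trial mean
    removal would bias gamma_1 downward at 15 intervals per trial), and
    per-lag sums use unbiased denominators.
    """
    arrs = [np.asarray(s, dtype=float) for s in series]
    grand = np.mean(np.concatenate(arrs))
    g0, g1 = _gammas([a - grand for a in arrs])
    return max(0.0, g0 + 2 * g1), max(0.0, -g1)


def _gammas(centered: list[np.ndarray]) -> tuple[float, float]:
    g0 = float(np.mean([np.mean(x * x) for x in centered]))
    g1 = float(np.mean([np.mean(x[:-1] * x[1:]) for x in centered]))
    return g0, g1
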