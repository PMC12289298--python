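"""Adaptive emotion-bias task engine and the processing-speed outcome.

The task shows an emotional face (neutral, happy, sad or angry) with a
superimposed arrow for 300 ms; the participant reports the arrow direction
within an adaptive response window. On neutral trials the window follows a
weighted up-down staircase (-33 ms after a correct response, +100 ms after an
incorrect one), which holds long-run accuracy near the weighted equilibrium
step_up / (step_up + step_down) = 100/133 ~ 75.2%. Non-neutral trials inherit
the window of the most recent neutral trial.

Processing speed, the task's outcome, is log10(1 / mean RT in seconds):
larger values mean faster responding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "EMOTIONS",
    "TrialRecord",
    "StaircaseState",
    "PsychometricObserver",
    "build_schedule",
    "update_window",
    "run_observer",
    "processing_speed",
]

EMOTIONS = ("neutral", "happy", "sad", "angry")

N_TRIALS = 144
N_BLOCKS = 3
TRIALS_PER_EMOTION_PER_BLOCK = 12

#: Staircase defaults: initial/ceiling window is the task's 1-second response
#: window; floor is the 300 ms stimulus duration.
STEP_DOWN_MS = 33.0
STEP_UP_MS = 100.0
WINDOW_FLOOR_MS = 300.0
WINDOW_CEILING_MS = 1000.0
WINDOW_START_MS = 1000.0


@dataclass(frozen=True)
class TrialRecord:
    """One emotion-bias trial."""

    trial_index: int
    block: int  # 1-3
    emotion: str
    face_sex: str  # "male" | "female"
    field: str  # "upper" | "lower"
    arrow_direction: str  # "left" | "right"
    response_window_ms: float | None = None
    rt_ms: float | None = None
    correct: bool | None = None

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.emotion!r}")
        if self.rt_ms is not None and self.rt_ms <= 0:
            raise ValueError("RT must be positive when present")


@dataclass(frozen=True)
class StaircaseState:
    """Current response window plus the staircase's step and bound settings."""

    window_ms: float = WINDOW_START_MS
    step_down_ms: float = STEP_DOWN_MS
    step_up_ms: float = STEP_UP_MS
    floor_ms: float = WINDOW_FLOOR_MS
    ceiling_ms: float = WINDOW_CEILING_MS

    def __post_init__(self) -> None:
        if not (self.floor_ms <= self.window_ms <= self.ceiling_ms):
            raise ValueError("window must lie in [floor, ceiling]")
        if self.step_down_ms <= 0 or self.step_up_ms <= 0:
            raise ValueError("steps must be positive")

    @property
    def equilibrium_accuracy(self) -> float:
        """Long-run accuracy at which up and down drifts balance."""
        return self.step_up_ms / (self.step_up_ms + self.step_down_ms)


def build_schedule(seed, n_trials: int = N_TRIALS, n_blocks: int = N_BLOCKS) -> list:
    """Build a counterbalanced, seed-randomized trial schedule.

    144 trials in 3 equipartitioned blocks by default; within each block every
    emotion appears on 12 trials and face sex, visual field and arrow
    direction are each split evenly (and evenly within every emotion cell).
    Trial order within a block is shuffled by the seed.
    """
    if n_trials % n_blocks:
        raise ValueError("n_trials must divide evenly into blocks")
    per_block = n_trials // n_blocks
    if per_block % (2 * len(EMOTIONS)):
        raise ValueError("block size must balance emotions with an even trial count each")
    per_emotion = per_block // len(EMOTIONS)

    def balanced(rng, options, n):
        # n/2 of each option, independently shuffled within the emotion cell
        col = np.repeat(options, n // 2)
        return col[rng.permutation(n)]

    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    index = 0
    for block in range(1, n_blocks + 1):
        cells = []
        for emotion in EMOTIONS:
            sexes = balanced(rng, ["male", "female"], per_emotion)
            fields = balanced(rng, ["upper", "lower"], per_emotion)
            arrows = balanced(rng, ["left", "right"], per_emotion)
            cells.extend(
                (emotion, sexes[i], fields[i], arrows[i]) for i in range(per_emotion)
            )
        for cell_idx in rng.permutation(len(cells)):
            emotion, sex, fld, arrow = cells[cell_idx]
            trials.append(TrialRecord(index, block, emotion, sex, fld, arrow))
            index += 1
    return trials


def update_window(state: StaircaseState, emotion: str, correct: bool) -> StaircaseState:
    """Advance the staircase after one trial.

    Neutral correct: window - step_down, clamped at floor. Neutral incorrect:
    window + step_up, clamped at ceiling. Non-neutral trials leave the window
    unchanged (they follow the preceding neutral trial's window).
    """
    if emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion {emotion!r}")
    if emotion != "neutral":
        return state
    if correct:
        new = max(state.floor_ms, state.window_ms - state.step_down_ms)
    else:
        new = min(state.ceiling_ms, state.window_ms + state.step_up_ms)
    return replace(state, window_ms=new)


@dataclass(frozen=True)
class PsychometricObserver:
    """Simulated participant: accuracy vs response window plus an RT model.

    Accuracy is a logistic function of the window rising from chance (0.5 on
    a two-alternative arrow judgement) to ``lapse``-limited ceiling:

        P(correct | w) = 0.5 + (0.5 - lapse) / (1 + exp(-(w - threshold)/slope))

    which is monotone nondecreasing in the window. RTs are lognormal with
    median ``rt_median_s`` and log-SD ``rt_sigma``; a draw exceeding the
    response window is an omission (no RT, scored incorrect).
    """

    threshold_ms: float = 600.0
    slope_ms: float = 50.0
    lapse: float = 0.02
    rt_median_s: float = 0.55
    rt_sigma: float = 0.25

    def p_correct(self, window_ms) -> np.ndarray:
        w = np.asarray(window_ms, dtype=float)
        p = 0.5 + (0.5 - self.lapse) / (1.0 + np.exp(-(w - self.threshold_ms) / self.slope_ms))
        return p

    def draw_rt_s(self, rng: np.random.Generator) -> float:
        return float(self.rt_median_s * math.exp(self.rt_sigma * rng.standard_normal()))


def run_observer(schedule, observer: PsychometricObserver, seed) -> list:
    """Run a psychometric observer through a schedule, evolving the staircase.

    Each trial is scored correct with the observer's window-dependent
    probability; an RT is drawn from the observer's RT model and responses
    slower than the window become omissions (incorrect, RT absent). The
    window evolves per :func:`update_window`; trials before the first neutral
    trial inherit the initial window.
    """
    rng = np.random.default_rng(seed)
    state = StaircaseState()
    completed: list[TrialRecord] = []
    for trial in schedule:
        window = state.window_ms
        rt_s = observer.draw_rt_s(rng)
        if rt_s * 1000.0 > window:
            correct, rt_ms = False, None  # omission
        else:
            correct = bool(rng.random() < observer.p_correct(window))
            rt_ms = rt_s * 1000.0
        completed.append(
            replace(trial, response_window_ms=window, rt_ms=rt_ms, correct=correct)
        )
        state = update_window(state, trial.emotion, correct)
    return completed


def processing_speed(trials, emotion: str | None = None, correct_only: bool = True) -> float:
    """Processing speed log10(1 / mean RT in seconds) over qualifying trials.

    Qualifying trials have a recorded RT, match the emotion filter (``None``
    keeps all emotions) and, with ``correct_only`` (the default), were
    answered correctly. Strictly decreasing in mean RT; larger = faster.

    Raises ``ValueError`` when no trial qualifies.
    """
    rts = [
        t.rt_ms
        for t in trials
        if t.rt_ms is not None
        and (emotion is None or t.emotion == emotion)
        and (not correct_only or t.correct)
    ]
    if not rts:
        raise ValueError("no qualifying trials with an RT")
    mean_rt_s = float(np.mean(rts)) / 1000.0
    return float(np.log10(1.0 / mean_rt_s))
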