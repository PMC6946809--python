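"""Trial scheduling for the concept-learning task.

Each of the three problems is learned over 4 functional runs of 32 trials
(8 stimuli x 4 repetitions per run). Trial order is pseudo-randomized in
sub-blocks of 16 trials such that every stimulus appears exactly twice per
sub-block. A trial is: stimulus (3.5 s) -> jittered fixation (0.5-4.5 s) ->
feedback (2 s) -> jittered inter-trial fixation. Jitters are uniform over
the stated windows, discretized to 0.5 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .problems import CODES, PROBLEMS, ProblemBank

N_RUNS = 4
TRIALS_PER_RUN = 32
SUBBLOCK = 16

TRIAL_COLUMNS = [
    "participant",
    "problem",
    "problem_position",
    "run",
    "trial_index",
    "stimulus_code",
    "repetition",
    "onset_s",
    "stim_duration_s",
    "feedback_onset_s",
    "feedback_duration_s",
    "response_onset_s",
    "response",
    "true_class",
    "correct",
    "problem_order",
]


class SchedulingError(RuntimeError):
    """Raised when no event timing fits within the requested run length."""


@dataclass(frozen=True)
class TimingSpec:
    """Event timing parameters (seconds).

    The post-feedback delay window defaults to the 2-6 s inter-trial
    fixation; jitters are drawn uniformly on a 0.5 s grid.
    """

    stim_duration: float = 3.5
    feedback_duration: float = 2.0
    isi_window: tuple[float, float] = (0.5, 4.5)
    iti_window: tuple[float, float] = (2.0, 6.0)
    jitter_step: float = 0.5
    run_length: float = 388.0


def _jitter_grid(window: tuple[float, float], step: float) -> np.ndarray:
    lo, hi = window
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def _run_order(rng: np.random.Generator) -> list[str]:
    """32-trial order: two 16-trial sub-blocks, each stimulus twice per sub-block."""
    order: list[str] = []
    for _ in range(TRIALS_PER_RUN // SUBBLOCK):
        block = list(CODES) * (SUBBLOCK // len(CODES))
        rng.shuffle(block)
        order.extend(block)
    return order


def _run_onsets(rng: np.random.Generator, timing: TimingSpec, max_attempts: int = 200):
    isi_grid = _jitter_grid(timing.isi_window, timing.jitter_step)
    iti_grid = _jitter_grid(timing.iti_window, timing.jitter_step)
    for _ in range(max_attempts):
        isis = rng.choice(isi_grid, size=TRIALS_PER_RUN)
        itis = rng.choice(iti_grid, size=TRIALS_PER_RUN)
        onsets = np.empty(TRIALS_PER_RUN)
        fb_onsets = np.empty(TRIALS_PER_RUN)
        t = 0.0
        for i in range(TRIALS_PER_RUN):
            onsets[i] = t
            fb_onsets[i] = t + timing.stim_duration + isis[i]
            t = fb_onsets[i] + timing.feedback_duration + itis[i]
        if t <= timing.run_length:
            return onsets, fb_onsets
    raise SchedulingError(
        f"could not fit {TRIALS_PER_RUN} trials in {timing.run_length} s "
        f"after {max_attempts} attempts"
    )


def make_trial_schedule(
    bank: ProblemBank,
    problem_order: tuple[str, str, str] = ("high", "low", "medium"),
    seed: int = 0,
    participant: str = "sub-01",
    timing: TimingSpec | None = None,
) -> pd.DataFrame:
    """Generate a full 3-problem trial schedule (responses left empty).

    The default problem order reflects the study design: the high-complexity
    problem first, low and medium counterbalanced across participants.
    """
    if sorted(problem_order) != sorted(PROBLEMS):
        raise ValueError(f"problem_order must cover {PROBLEMS}, got {problem_order}")
    timing = timing or TimingSpec()
    rng = np.random.default_rng(seed)
    rows = []
    order_label = "-".join(problem_order)
    for pos, problem in enumerate(problem_order, start=1):
        seen: dict[str, int] = {c: 0 for c in CODES}
        for run in range(1, N_RUNS + 1):
            codes = _run_order(rng)
            onsets, fb_onsets = _run_onsets(rng, timing)
            for i, code in enumerate(codes):
                seen[code] += 1
                rows.append(
                    {
                        "participant": participant,
                        "problem": problem,
                        "problem_position": pos,
                        "run": run,
                        "trial_index": i + 1,
                        "stimulus_code": code,
                        "repetition": seen[code],
                        "onset_s": onsets[i],
                        "stim_duration_s": timing.stim_duration,
                        "feedback_onset_s": fb_onsets[i],
                        "feedback_duration_s": timing.feedback_duration,
                        "response_onset_s": np.nan,
                        "response": pd.NA,
                        "true_class": bank.true_class(code, problem),
                        "correct": pd.NA,
                        "problem_order": order_label,
                    }
                )
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["response"] = df["response"].astype("string")
    df["correct"] = df["correct"].astype("boolean")
    return df
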