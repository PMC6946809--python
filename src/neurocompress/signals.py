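"""Synthetic trial-wise activation patterns and forward-modeled BOLD.

Stands in for the study's raw fMRI data. Each (problem, run) yields a
32-trial x voxel pattern matrix built as a low-rank signal plus isotropic
Gaussian noise:

* the noise-free ensemble has exactly ``intrinsic_rank`` dimensions
  (orthonormal, variance-balanced score axes times orthonormal voxel axes),
  so the downstream PCA dimensionality is controlled by construction;
* the two category means are separated by ``category_separation`` (in units
  of the per-axis signal SD) along the leading signal axis;
* one additional axis per problem-relevant attribute carries that
  attribute's binary contrast, mirroring the idea that compression reflects
  goal-relevant feature coding.

Default rank and separation schedules emulate the study conditions: the
intrinsic dimensionality falls across learning blocks fastest for the
low-complexity problem, and category separation grows over blocks most for
low complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .problems import ProblemBank
from .schedule import N_RUNS, TRIALS_PER_RUN

COMPLEXITY_LEVEL = {"low": 1, "medium": 2, "high": 3}

RELEVANT_ATTRIBUTES = {"low": (0,), "medium": (1, 2), "high": (0, 1, 2)}


def default_rank_schedule(problem: str, block: int) -> int:
    """Intrinsic dimensionality per (problem, learning block).

    Starts at 12 for every problem and declines linearly to 4 x complexity
    level by block 4 (low -> 4, medium -> 8, high -> 12), so the block slope
    is steepest for the low-complexity problem.
    """
    c = COMPLEXITY_LEVEL[problem]
    return int(round(12 + (block - 1) / 3.0 * (4 * c - 12)))


def default_separation_schedule(problem: str, block: int) -> float:
    """Category separation growing over blocks, most for low complexity."""
    c = COMPLEXITY_LEVEL[problem]
    return 0.15 * block * (4 - c)


@dataclass(frozen=True)
class SignalSpec:
    """Generative parameters of the synthetic pattern ensembles."""

    intrinsic_rank: Callable[[str, int], int] = default_rank_schedule
    category_separation: Callable[[str, int], float] = default_separation_schedule
    attr_amplitude: float = 0.8  # binary-contrast amplitude on attribute axes
    signal_sd: float = 1.0  # per-axis SD of the low-rank signal
    noise_sd: float = 0.3  # i.i.d. voxel noise SD
    seed: int = 0


def constant_spec(
    rank: int, separation: float = 0.0, attr_amplitude: float = 0.0, **kw
) -> SignalSpec:
    """A SignalSpec with rank and separation fixed across problems/blocks."""
    return SignalSpec(
        intrinsic_rank=lambda p, b: rank,
        category_separation=lambda p, b: separation,
        attr_amplitude=attr_amplitude,
        **kw,
    )


@dataclass
class BetaSeries:
    """Trial x voxel parameter estimates for one (problem, run)."""

    data: np.ndarray  # (n_trials, n_voxels), voxels in mask order
    mask: np.ndarray  # 3-D boolean
    affine: np.ndarray
    participant: str
    problem: str
    run: int
    trials: pd.DataFrame | None = None  # per-trial metadata, ordered as rows

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def to_volume(self) -> np.ndarray:
        """4-D array (x, y, z, trial) with NaN outside the mask."""
        vol = np.full(self.mask.shape + (self.n_trials,), np.nan)
        vol[self.mask, :] = self.data.T
        return vol


def spherical_mask(shape=(20, 20, 20), radius: float | None = None) -> np.ndarray:
    """Ellipsoidal (spherical by default) mask centered in a small volume."""
    shape = tuple(shape)
    if radius is None:
        radius = min(shape) / 2.0 - 1.0
    center = (np.array(shape) - 1) / 2.0
    grid = np.indices(shape)
    dist2 = sum((grid[i] - center[i]) ** 2 for i in range(3))
    return dist2 <= radius**2


def _run_rng(seed: int, problem: str, run: int) -> np.random.Generator:
    return np.random.default_rng([seed, COMPLEXITY_LEVEL[problem], run])


def simulate_beta_series(
    trials: pd.DataFrame,
    spec: SignalSpec,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> list[BetaSeries]:
    """Generate one BetaSeries per (problem, run) of a participant schedule.

    With ``noise_sd = 0`` the voxel-centered pattern matrix of a run has
    numerical rank exactly ``intrinsic_rank(problem, run)``.
    """
    mask = spherical_mask() if mask is None else np.asarray(mask, dtype=bool)
    affine = np.eye(4) if affine is None else affine
    n_voxels = int(mask.sum())
    out = []
    for (problem, run), grp in trials.groupby(["problem", "run"], sort=False):
        grp = grp.sort_values("trial_index")
        n = len(grp)
        r = int(spec.intrinsic_rank(problem, int(run)))
        if not 1 <= r <= n:
            raise ValueError(f"intrinsic_rank {r} outside [1, {n}]")
        sep = float(spec.category_separation(problem, int(run)))
        rng = _run_rng(spec.seed, problem, int(run))

        # orthonormal, column-centered score axes -> equal signal variance
        g = rng.standard_normal((n, r))
        g -= g.mean(axis=0)
        q, _ = np.linalg.qr(g)
        scores = q * np.sqrt(n - 1)  # unit variance per axis

        y = np.where(grp["true_class"].to_numpy() == "A", 0.5, -0.5)
        scores[:, 0] = scores[:, 0] + sep * y
        bits = np.array(
            [[int(c) for c in code] for code in grp["stimulus_code"]], dtype=float
        )
        for j, attr in enumerate(RELEVANT_ATTRIBUTES[problem]):
            axis = 1 + j
            if axis < r:
                scores[:, axis] += spec.attr_amplitude * (bits[:, attr] - 0.5)
        # total per-voxel signal variance = signal_sd**2 independent of rank
        scores *= spec.signal_sd * np.sqrt(n_voxels / r)

        vdirs, _ = np.linalg.qr(rng.standard_normal((n_voxels, r)))
        data = scores @ vdirs.T
        if spec.noise_sd > 0:
            data = data + spec.noise_sd * rng.standard_normal((n, n_voxels))
        out.append(
            BetaSeries(
                data=data,
                mask=mask,
                affine=affine,
                participant=str(grp["participant"].iloc[0]),
                problem=problem,
                run=int(run),
                trials=grp.reset_index(drop=True),
            )
        )
    return out


def simulate_bold(
    trials: pd.DataFrame,
    betas: BetaSeries,
    tr: float = 2.0,
    run_length_s: float = 388.0,
    hrf_spec=None,
    noise_sd: float = 0.0,
    feedback_amplitude: float = 1.0,
    response_amplitude: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Forward-model one run of BOLD (volumes x voxels) from trial betas.

    Each trial contributes its beta pattern times the convolved 3.5 s
    stimulus boxcar; feedback and response events add seeded random nuisance
    patterns with the amplitudes given, plus optional Gaussian noise.
    """
    from .glm import HRFSpec, _convolved_regressor, hrf_kernel

    if tr <= 0:
        raise ValueError("TR must be positive")
    hrf_spec = hrf_spec or HRFSpec()
    hrf = hrf_kernel(hrf_spec)
    dt = 0.1
    trials = trials.sort_values("trial_index")
    ends = trials["feedback_onset_s"] + trials["feedback_duration_s"]
    if (ends > run_length_s).any():
        raise ValueError("run length does not accommodate all events")
    n_vols = int(np.floor(run_length_s / tr + 1e-9))
    n_vox = betas.data.shape[1]
    rng = np.random.default_rng(seed)
    bold = np.zeros((n_vols, n_vox))
    for row, (_, ev) in enumerate(trials.iterrows()):
        reg = _convolved_regressor(
            [ev["onset_s"]], [ev["stim_duration_s"]], run_length_s, tr, hrf, dt
        )
        bold += np.outer(reg, betas.data[row])

    correct = trials["correct"].fillna(False).astype(bool).to_numpy()
    for sel in (correct, ~correct):
        if sel.any():
            reg = _convolved_regressor(
                trials.loc[sel, "feedback_onset_s"],
                trials.loc[sel, "feedback_duration_s"],
                run_length_s, tr, hrf, dt,
            )
            bold += feedback_amplitude * np.outer(reg, rng.standard_normal(n_vox))
    responded = trials["response"].notna().to_numpy() & np.isfinite(
        trials["response_onset_s"].to_numpy(dtype=float)
    )
    for label in ("A", "B"):
        sel = responded & (trials["response"] == label).to_numpy()
        if sel.any():
            reg = _convolved_regressor(
                trials.loc[sel, "response_onset_s"],
                np.zeros(int(sel.sum())),
                run_length_s, tr, hrf, dt,
            )
            bold += response_amplitude * np.outer(reg, rng.standard_normal(n_vox))
    if noise_sd > 0:
        bold += noise_sd * rng.standard_normal(bold.shape)
    return bold
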