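"""Single-trial activation estimates via the least-squares-separate GLM.

Each trial's activation pattern is estimated from run-wise BOLD with its own
ordinary-least-squares model: one regressor for the trial of interest (3.5 s
boxcar convolved with a canonical double-gamma hemodynamic response), one
regressor pooling all other stimulus events, separate regressors for correct
and incorrect feedback (2 s boxcars), impulse regressors for the two
response buttons, six motion parameters and an intercept. The beta of the
trial-of-interest regressor, collected across trials, forms the beta series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

#: regressor labels of one LS-S design, in column order
DESIGN_COLUMNS = [
    "trial_of_interest",
    "other_trials",
    "feedback_correct",
    "feedback_incorrect",
    "response_A",
    "response_B",
    *[f"motion{i + 1}" for i in range(6)],
    "intercept",
]


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma hemodynamic response (SPM-convention defaults).

    With unit dispersions the positive lobe is a gamma density with shape
    ``peak_delay`` whose mode sits at ``peak_delay - 1`` = 5 s.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0

    def validate(self) -> None:
        if min(self.peak_delay, self.undershoot_delay) <= 1.0:
            raise ValueError("gamma delays must exceed 1 for a causal kernel")
        if min(self.peak_dispersion, self.undershoot_dispersion) <= 0:
            raise ValueError("dispersions must be positive")


def hrf_kernel(spec: HRFSpec | None = None, dt: float = 0.1) -> np.ndarray:
    """Sampled double-gamma kernel on a ``dt`` grid, normalized to peak 1."""
    spec = spec or HRFSpec()
    spec.validate()
    if dt <= 0:
        raise ValueError("sampling interval must be positive")
    t = np.arange(0.0, spec.duration + dt / 2, dt)
    peak = gamma_dist.pdf(
        t, spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion
    )
    under = gamma_dist.pdf(
        t,
        spec.undershoot_delay / spec.undershoot_dispersion,
        scale=spec.undershoot_dispersion,
    )
    h = peak - spec.undershoot_ratio * under
    return h / h.max()


def _convolved_regressor(
    onsets, durations, run_length_s: float, tr: float, hrf: np.ndarray, dt: float
) -> np.ndarray:
    """Boxcar (impulse when duration == 0) convolved with the HRF, sampled at
    volume acquisition times 0, TR, 2 TR, ..."""
    n_vols = int(np.floor(run_length_s / tr + 1e-9))
    n_fine = int(np.ceil(run_length_s / dt)) + 1
    fine = np.zeros(n_fine)
    for onset, dur in zip(np.atleast_1d(onsets), np.atleast_1d(durations)):
        i0 = int(round(onset / dt))
        if dur > 0:
            i1 = min(int(round((onset + dur) / dt)), n_fine)
            fine[i0:i1] = 1.0
        else:
            fine[i0] = 1.0 / dt  # unit-area impulse
    conv = np.convolve(fine, hrf)[:n_fine] * dt
    vol_idx = np.round(np.arange(n_vols) * tr / dt).astype(int)
    return conv[vol_idx]


def stimulus_regressors(
    events: pd.DataFrame,
    run_length_s: float,
    tr: float,
    hrf_spec: HRFSpec | None = None,
    dt: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial convolved stimulus regressors.

    Returns (volumes x trials matrix, trial_index order).
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    ends = events["feedback_onset_s"] + events["feedback_duration_s"]
    if (ends > run_length_s).any():
        raise ValueError("events extend beyond the end of the run")
    hrf = hrf_kernel(hrf_spec, dt)
    ev = events.sort_values("trial_index")
    cols = [
        _convolved_regressor(
            [row["onset_s"]], [row["stim_duration_s"]], run_length_s, tr, hrf, dt
        )
        for _, row in ev.iterrows()
    ]
    return np.column_stack(cols), ev["trial_index"].to_numpy()


def nuisance_regressors(
    events: pd.DataFrame,
    run_length_s: float,
    tr: float,
    hrf_spec: HRFSpec | None = None,
    motion: np.ndarray | None = None,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Feedback, response, motion and intercept regressors of one run."""
    hrf = hrf_kernel(hrf_spec, dt)
    n_vols = int(np.floor(run_length_s / tr + 1e-9))
    cols = {}
    correct = events["correct"].fillna(False).astype(bool).to_numpy()
    for name, sel in [("feedback_correct", correct), ("feedback_incorrect", ~correct)]:
        cols[name] = _convolved_regressor(
            events.loc[sel, "feedback_onset_s"],
            events.loc[sel, "feedback_duration_s"],
            run_length_s, tr, hrf, dt,
        )
    responded = events["response"].notna().to_numpy() & np.isfinite(
        events["response_onset_s"].to_numpy(dtype=float)
    )
    for name, label in [("response_A", "A"), ("response_B", "B")]:
        sel = responded & (events["response"] == label).to_numpy()
        cols[name] = _convolved_regressor(
            events.loc[sel, "response_onset_s"],
            np.zeros(int(sel.sum())),
            run_length_s, tr, hrf, dt,
        )
    if motion is None:
        motion = np.zeros((n_vols, 6))
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (n_vols, 6):
        raise ValueError(f"motion must be ({n_vols}, 6), got {motion.shape}")
    for i in range(6):
        cols[f"motion{i + 1}"] = motion[:, i]
    cols["intercept"] = np.ones(n_vols)
    return pd.DataFrame(cols, columns=DESIGN_COLUMNS[2:])


def build_design(
    events: pd.DataFrame,
    run_length_s: float,
    tr: float,
    target_trial: int,
    hrf_spec: HRFSpec | None = None,
    motion: np.ndarray | None = None,
    dt: float = 0.1,
) -> pd.DataFrame:
    """LS-S design matrix for one target trial of one run.

    ``events`` needs columns onset_s, stim_duration_s, feedback_onset_s,
    feedback_duration_s, trial_index, correct, response, response_onset_s.
    Rows = volumes (run_length_s / TR), columns = :data:`DESIGN_COLUMNS`.
    """
    trial_regs, order = stimulus_regressors(events, run_length_s, tr, hrf_spec, dt)
    if target_trial not in order:
        raise ValueError(f"target trial {target_trial} not in events")
    is_target = order == target_trial
    nuisance = nuisance_regressors(events, run_length_s, tr, hrf_spec, motion, dt)
    cols = {
        "trial_of_interest": trial_regs[:, is_target].sum(axis=1),
        "other_trials": trial_regs[:, ~is_target].sum(axis=1),
    }
    for name in nuisance.columns:
        cols[name] = nuisance[name].to_numpy()
    return pd.DataFrame(cols, columns=DESIGN_COLUMNS)


def lss_from_design(
    trial_regs: np.ndarray, nuisance: np.ndarray, bold: np.ndarray
) -> np.ndarray:
    """Least-squares-separate solve given per-trial regressors.

    For each trial, fits OLS with [that trial's regressor, the summed other
    trials, nuisance columns] and collects the first coefficient.
    """
    n_trials = trial_regs.shape[1]
    betas = np.empty((n_trials, bold.shape[1]))
    total = trial_regs.sum(axis=1)
    for i in range(n_trials):
        X = np.column_stack([trial_regs[:, i], total - trial_regs[:, i], nuisance])
        nonzero = np.flatnonzero(np.abs(X).sum(axis=0) > 0)
        rank = np.linalg.matrix_rank(X[:, nonzero])
        if rank < len(nonzero):
            warnings.warn(
                f"rank-deficient design for trial {i + 1} "
                f"(rank {rank} < {len(nonzero)} non-empty regressors); "
                "using pseudo-inverse",
                RuntimeWarning,
                stacklevel=2,
            )
        coef, *_ = np.linalg.lstsq(X, bold, rcond=None)
        betas[i] = coef[0]
    return betas


def lsa_from_design(
    trial_regs: np.ndarray, nuisance: np.ndarray, bold: np.ndarray
) -> np.ndarray:
    """Single-GLM (least-squares-all) trial estimates: every trial gets its
    own regressor in one joint model."""
    X = np.column_stack([trial_regs, nuisance])
    coef, *_ = np.linalg.lstsq(X, bold, rcond=None)
    return coef[: trial_regs.shape[1]]


def highpass_detrend(bold: np.ndarray, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Remove linear trend and slow drifts (discrete cosine basis up to the
    cutoff period) from a volumes x voxels array."""
    n = bold.shape[0]
    t = np.arange(n)
    k_max = int(np.floor(2.0 * n * tr / cutoff_s))
    basis = [np.ones(n), t - t.mean()]
    for k in range(1, k_max + 1):
        basis.append(np.cos(np.pi * k * (2 * t + 1) / (2 * n)))
    X = np.column_stack(basis)
    beta, *_ = np.linalg.lstsq(X, bold, rcond=None)
    resid = bold - X @ beta
    return resid + bold.mean(axis=0)  # keep the mean level


def lss_estimate(
    bold: np.ndarray,
    events: pd.DataFrame,
    tr: float,
    run_length_s: float | None = None,
    hrf_spec: HRFSpec | None = None,
    motion: np.ndarray | None = None,
    dt: float = 0.1,
) -> np.ndarray:
    """Least-squares-separate beta series for one run.

    ``bold`` is volumes x voxels. Returns trials x voxels, rows ordered by
    ``trial_index``. Rank-deficient designs fall back to the pseudo-inverse
    solution with a warning.
    """
    bold = np.asarray(bold, dtype=float)
    if run_length_s is None:
        run_length_s = bold.shape[0] * tr
    trial_regs, _ = stimulus_regressors(events, run_length_s, tr, hrf_spec, dt)
    if trial_regs.shape[0] != bold.shape[0]:
        raise ValueError(
            f"design has {trial_regs.shape[0]} rows but BOLD has "
            f"{bold.shape[0]} volumes"
        )
    nuisance = nuisance_regressors(
        events, run_length_s, tr, hrf_spec, motion, dt
    ).to_numpy()
    return lss_from_design(trial_regs, nuisance, bold)
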