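"""SUSTAIN clustering model of supervised category learning.

SUSTAIN represents category knowledge as clusters in stimulus space. Each
binary attribute is encoded as a one-hot pair, and a per-attribute tuning
``lambda_i`` acts as a receptive field: a cluster's activation is the
attention-weighted similarity

    act_j = sum_i lambda_i**gamma * exp(-lambda_i * mu_ij) / sum_i lambda_i**gamma

where ``mu_ij`` is half the city-block distance between the stimulus and
cluster ``j`` on attribute ``i`` and ``gamma`` is the attentional-focus
exponent. Clusters compete via lateral inhibition with exponent ``beta``
(winner-take-all output), category evidence is the winner's association
weights scaled by its inhibited output, and responses follow an exponential
(Luce) choice rule with consistency ``d``.

Learning is supervised: a new cluster is recruited at the stimulus when the
winning cluster predicts the wrong category or is activated below the
recruitment threshold ``tau_h``; otherwise the winner moves toward the
stimulus, its association weights follow a humble-teacher delta rule, and
the tunings ``lambda_i`` take a receptive-field gradient step, all at
learning rate ``eta``.

The model runs generatively (sampling responses) and in likelihood mode
(probability of reproducing a participant's responses trial-by-trial, with
model state carrying over between problems in the experienced order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .problems import CODES, ProblemBank

N_ATTR = 3
N_VALUES = 2
CATEGORIES = ("A", "B")

#: probability floor applied per trial in the likelihood (avoids -inf)
PROB_FLOOR = 1e-6

#: fitting bounds for (gamma, beta_inh, eta, d, tau_h)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "gamma": (0.0, 20.0),
    "beta_inh": (0.0, 20.0),
    "eta": (0.0, 1.0),
    "d": (0.0, 30.0),
    "tau_h": (0.0, 1.0),
}

PARAM_NAMES = tuple(DEFAULT_BOUNDS)


@dataclass(frozen=True)
class SustainParams:
    """The five free parameters of the supervised model."""

    gamma: float = 8.96  # attentional focus exponent (>= 0)
    beta_inh: float = 1.51  # cluster-competition (lateral inhibition) exponent
    eta: float = 0.08  # learning rate in [0, 1]
    d: float = 17.04  # decision consistency (>= 0)
    tau_h: float = 0.11  # cluster-recruitment activation threshold in [0, 1]

    def validate(self, bounds: dict[str, tuple[float, float]] | None = None) -> None:
        bounds = bounds or DEFAULT_BOUNDS
        for name, (lo, hi) in bounds.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"parameter {name}={v} outside bounds [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, x) -> "SustainParams":
        return cls(**{n: float(v) for n, v in zip(PARAM_NAMES, x)})


@dataclass
class SustainState:
    """Mutable model state: cluster positions, association weights, tunings."""

    positions: np.ndarray = field(
        default_factory=lambda: np.empty((0, N_ATTR, N_VALUES))
    )
    assoc: np.ndarray = field(default_factory=lambda: np.empty((0, len(CATEGORIES))))
    lambdas: np.ndarray = field(default_factory=lambda: np.ones(N_ATTR))

    @property
    def n_clusters(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SustainState":
        return SustainState(
            self.positions.copy(), self.assoc.copy(), self.lambdas.copy()
        )


# one-hot encodings of the 8 stimulus codes, indexed by code
_ENCODINGS = {}
for _code in CODES:
    _e = np.zeros((N_ATTR, N_VALUES))
    for _i, _c in enumerate(_code):
        _e[_i, int(_c)] = 1.0
    _ENCODINGS[_code] = _e


def encode_stimulus(code: str) -> np.ndarray:
    """Per-attribute one-hot representation of a 3-bit stimulus code."""
    try:
        return _ENCODINGS[code].copy()
    except KeyError:
        raise ValueError(f"malformed stimulus code {code!r}") from None


def cluster_activation(
    state: SustainState, stim: np.ndarray, gamma: float
) -> np.ndarray:
    """Receptive-field activation of every cluster for a stimulus.

    Returns an empty array when the state holds no clusters (the caller
    handles recruitment).
    """
    if state.n_clusters == 0:
        return np.empty(0)
    lam = state.lambdas
    mu = 0.5 * np.abs(state.positions - stim).sum(axis=2)  # (n_clusters, n_attr)
    w = np.power(lam, gamma)
    wsum = w.sum()
    if wsum <= 0.0:  # degenerate all-zero tunings: fall back to equal weights
        w = np.ones(N_ATTR)
        wsum = float(N_ATTR)
    return (w * np.exp(-lam * mu)).sum(axis=1) / wsum


def _argmax_latest(act: np.ndarray) -> int:
    """Index of the maximal activation; exact ties go to the most recently
    recruited cluster, so a fresh cluster can out-compete a stale one sitting
    at the same position (matters when class rules change between problems)."""
    n = len(act)
    return n - 1 - int(np.argmax(act[::-1]))


def _winner_output(act: np.ndarray, winner: int, beta_inh: float) -> float:
    """Lateral-inhibition output of the winning cluster."""
    powed = np.power(act, beta_inh)
    denom = powed.sum()
    if denom <= 0.0:
        return 0.0
    return float(powed[winner] / denom * act[winner])


def choice_probabilities(
    state: SustainState, stim: np.ndarray, params: SustainParams
) -> np.ndarray:
    """P(A), P(B) under the consistency-scaled choice rule.

    With no clusters (or d = 0) the model responds at chance.
    """
    if state.n_clusters == 0:
        return np.array([0.5, 0.5])
    act = cluster_activation(state, stim, params.gamma)
    winner = _argmax_latest(act)
    out = _winner_output(act, winner, params.beta_inh)
    evidence = params.d * state.assoc[winner] * out
    evidence = evidence - evidence.max()
    e = np.exp(evidence)
    return e / e.sum()


def learn_trial(
    state: SustainState,
    stim: np.ndarray,
    true_class: str,
    params: SustainParams,
) -> tuple[SustainState, bool]:
    """One supervised learning update; returns (new state, recruited flag).

    Recruitment occurs on the first trial ever, when the winning cluster
    predicts the wrong category, or when its activation falls below tau_h.
    Updates (position, association weights, tunings) apply to the winner
    only, using pre-update quantities.
    """
    state = state.copy()
    true_idx = CATEGORIES.index(true_class)
    other_idx = 1 - true_idx
    recruited = False

    if state.n_clusters == 0:
        winner = _recruit(state, stim)
        recruited = True
    else:
        act = cluster_activation(state, stim, params.gamma)
        winner = _argmax_latest(act)
        a = state.assoc[winner]
        mispredicts = a[true_idx] < a[other_idx]
        if mispredicts or act[winner] < params.tau_h:
            winner = _recruit(state, stim)
            recruited = True

    act = cluster_activation(state, stim, params.gamma)
    out = _winner_output(act, winner, params.beta_inh)
    c_out = state.assoc[winner] * out

    # humble teacher: no error signal once output is beyond the target
    target = np.empty(len(CATEGORIES))
    target[true_idx] = max(c_out[true_idx], 1.0)
    target[other_idx] = min(c_out[other_idx], -1.0)

    eta = params.eta
    mu_w = 0.5 * np.abs(state.positions[winner] - stim).sum(axis=1)
    lam = state.lambdas
    state.lambdas = np.maximum(lam + eta * np.exp(-lam * mu_w) * (1.0 - lam * mu_w), 0.0)
    state.assoc[winner] = state.assoc[winner] + eta * (target - c_out) * out
    state.positions[winner] = state.positions[winner] + eta * (
        stim - state.positions[winner]
    )
    return state, recruited


def _recruit(state: SustainState, stim: np.ndarray) -> int:
    state.positions = np.concatenate([state.positions, stim[None]], axis=0)
    state.assoc = np.concatenate(
        [state.assoc, np.zeros((1, len(CATEGORIES)))], axis=0
    )
    return state.n_clusters - 1


# ---------------------------------------------------------------------------
# fast internal trial loop (mutates arrays in place; used by likelihood,
# replay and generative simulation, which must agree exactly)
# ---------------------------------------------------------------------------


class _FastState:
    __slots__ = ("positions", "assoc", "lambdas", "n")

    def __init__(self, capacity: int, init: SustainState | None = None):
        base = init.n_clusters if init is not None else 0
        self.positions = np.empty((base + capacity, N_ATTR, N_VALUES))
        self.assoc = np.zeros((base + capacity, len(CATEGORIES)))
        self.lambdas = np.ones(N_ATTR)
        self.n = base
        if init is not None and base:
            self.positions[:base] = init.positions
            self.assoc[:base] = init.assoc
        if init is not None:
            self.lambdas = init.lambdas.copy()

    def freeze(self) -> SustainState:
        return SustainState(
            self.positions[: self.n].copy(),
            self.assoc[: self.n].copy(),
            self.lambdas.copy(),
        )


def _step(
    fs: _FastState,
    rep: np.ndarray,
    true_idx: int,
    gamma: float,
    beta_inh: float,
    eta: float,
    d: float,
    tau_h: float,
    learn: bool = True,
) -> float:
    """Advance one trial; returns P(respond A) before learning."""
    n = fs.n
    lam = fs.lambdas
    if n == 0:
        p_a = 0.5
        winner = -1
        act = None
    else:
        mu = 0.5 * np.abs(fs.positions[:n] - rep).sum(axis=2)
        w = lam**gamma
        wsum = w.sum()
        if wsum <= 0.0:
            w = np.ones(N_ATTR)
            wsum = N_ATTR
        act = (w * np.exp(-lam * mu)).sum(axis=1) / wsum
        winner = _argmax_latest(act)
        powed = act**beta_inh
        denom = powed.sum()
        out = powed[winner] / denom * act[winner] if denom > 0 else 0.0
        c_a = fs.assoc[winner, 0] * out
        c_b = fs.assoc[winner, 1] * out
        p_a = 1.0 / (1.0 + math.exp(-d * (c_a - c_b)))
    if not learn:
        return p_a

    recruited = False
    if n == 0:
        recruited = True
    else:
        a = fs.assoc[winner]
        if a[true_idx] < a[1 - true_idx] or act[winner] < tau_h:
            recruited = True
    if recruited:
        fs.positions[fs.n] = rep
        fs.assoc[fs.n] = 0.0
        winner = fs.n
        fs.n += 1
        n = fs.n
        mu = 0.5 * np.abs(fs.positions[:n] - rep).sum(axis=2)
        w = lam**gamma
        wsum = w.sum()
        if wsum <= 0.0:
            w = np.ones(N_ATTR)
            wsum = N_ATTR
        act = (w * np.exp(-lam * mu)).sum(axis=1) / wsum

    powed = act**beta_inh
    denom = powed.sum()
    out = powed[winner] / denom * act[winner] if denom > 0 else 0.0
    c_out = fs.assoc[winner] * out
    t0 = max(c_out[0], 1.0) if true_idx == 0 else min(c_out[0], -1.0)
    t1 = max(c_out[1], 1.0) if true_idx == 1 else min(c_out[1], -1.0)

    mu_w = mu[winner]
    fs.lambdas = np.maximum(lam + eta * np.exp(-lam * mu_w) * (1.0 - lam * mu_w), 0.0)
    fs.assoc[winner, 0] += eta * (t0 - c_out[0]) * out
    fs.assoc[winner, 1] += eta * (t1 - c_out[1]) * out
    fs.positions[winner] += eta * (rep - fs.positions[winner])
    return p_a


try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False


def _core_loop_py(enc, true_idx, gamma, beta_inh, eta, d, tau_h):
    """Reference trial loop built on :func:`_step`.

    Returns (p_a per trial before learning, lambda trajectory after each
    trial). Responses never feed back into learning (feedback is shown on
    every trial), so the loop is response-independent.
    """
    T = enc.shape[0]
    fs = _FastState(T, None)
    p_a = np.empty(T)
    lam_traj = np.empty((T, N_ATTR))
    for i in range(T):
        p_a[i] = _step(fs, enc[i], true_idx[i], gamma, beta_inh, eta, d, tau_h)
        lam_traj[i] = fs.lambdas
    return p_a, lam_traj


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _core_loop_jit(enc, true_idx, gamma, beta_inh, eta, d, tau_h):
        T = enc.shape[0]
        pos = np.zeros((T, 3, 2))
        assoc = np.zeros((T, 2))
        lam = np.ones(3)
        p_a = np.empty(T)
        lam_traj = np.empty((T, 3))
        act = np.empty(T)
        mu = np.zeros((T, 3))
        n = 0
        for t in range(T):
            stim = enc[t]
            ti = true_idx[t]
            win = -1
            if n > 0:
                wsum = 0.0
                w = np.empty(3)
                for i in range(3):
                    w[i] = lam[i] ** gamma
                    wsum += w[i]
                if wsum <= 0.0:
                    for i in range(3):
                        w[i] = 1.0
                    wsum = 3.0
                best = -1.0
                for j in range(n):
                    a = 0.0
                    for i in range(3):
                        m = 0.5 * (
                            abs(pos[j, i, 0] - stim[i, 0])
                            + abs(pos[j, i, 1] - stim[i, 1])
                        )
                        mu[j, i] = m
                        a += w[i] * math.exp(-lam[i] * m)
                    a /= wsum
                    act[j] = a
                    if a >= best:  # ties -> most recently recruited
                        best = a
                        win = j
                den = 0.0
                for j in range(n):
                    den += act[j] ** beta_inh
                out = act[win] ** beta_inh / den * act[win] if den > 0.0 else 0.0
                ca = assoc[win, 0] * out
                cb = assoc[win, 1] * out
                pa = 1.0 / (1.0 + math.exp(-d * (ca - cb)))
            else:
                pa = 0.5
            p_a[t] = pa

            recruit = False
            if n == 0:
                recruit = True
            elif assoc[win, ti] < assoc[win, 1 - ti] or act[win] < tau_h:
                recruit = True
            if recruit:
                for i in range(3):
                    pos[n, i, 0] = stim[i, 0]
                    pos[n, i, 1] = stim[i, 1]
                    mu[n, i] = 0.0
                assoc[n, 0] = 0.0
                assoc[n, 1] = 0.0
                act[n] = 1.0
                win = n
                n += 1
            den = 0.0
            for j in range(n):
                den += act[j] ** beta_inh
            out = act[win] ** beta_inh / den * act[win] if den > 0.0 else 0.0
            c0 = assoc[win, 0] * out
            c1 = assoc[win, 1] * out
            t0 = max(c0, 1.0) if ti == 0 else min(c0, -1.0)
            t1 = max(c1, 1.0) if ti == 1 else min(c1, -1.0)
            for i in range(3):
                m = mu[win, i]
                nl = lam[i] + eta * math.exp(-lam[i] * m) * (1.0 - lam[i] * m)
                lam[i] = nl if nl > 0.0 else 0.0
            assoc[win, 0] += eta * (t0 - c0) * out
            assoc[win, 1] += eta * (t1 - c1) * out
            for i in range(3):
                pos[win, i, 0] += eta * (stim[i, 0] - pos[win, i, 0])
                pos[win, i, 1] += eta * (stim[i, 1] - pos[win, i, 1])
            lam_traj[t, 0] = lam[0]
            lam_traj[t, 1] = lam[1]
            lam_traj[t, 2] = lam[2]
        return p_a, lam_traj


def _core_loop(trials: pd.DataFrame, params: SustainParams):
    """Choice probabilities P(A) and lambda trajectory over a trial table."""
    enc = np.stack([_ENCODINGS[c] for c in trials["stimulus_code"]])
    true_idx = np.array(
        [CATEGORIES.index(c) for c in trials["true_class"]], dtype=np.int64
    )
    g, b, e, d, t = params.as_array()
    fn = _core_loop_jit if _HAVE_NUMBA else _core_loop_py
    return fn(enc, true_idx, g, b, e, d, t)


def _check_ordered(trials: pd.DataFrame) -> pd.DataFrame:
    key = trials[["problem_position", "run", "trial_index"]].to_numpy()
    if not (np.diff(key @ np.array([10_000, 100, 1])) > 0).all():
        raise ValueError(
            "trials must be ordered by (problem_position, run, trial_index) "
            "as experienced"
        )
    return trials


def _prep_arrays(trials: pd.DataFrame):
    reps = [_ENCODINGS[c] for c in trials["stimulus_code"]]
    true_idx = np.array([CATEGORIES.index(c) for c in trials["true_class"]])
    resp = np.full(len(trials), -1)
    mask = trials["response"].notna().to_numpy()
    resp[mask] = [CATEGORIES.index(r) for r in trials["response"][mask]]
    return reps, true_idx, resp


def negative_log_likelihood(
    params: SustainParams,
    trials: pd.DataFrame,
    init_state: SustainState | None = None,
) -> float:
    """-sum log P(model emits the participant's response), state carried
    across problems in the experienced order; unresponded trials excluded
    from the likelihood but still drive learning (feedback was shown)."""
    trials = _check_ordered(trials)
    _, true_idx, resp = _prep_arrays(trials)
    if init_state is None:
        p_a, _ = _core_loop(trials, params)
    else:
        reps = [_ENCODINGS[c] for c in trials["stimulus_code"]]
        g, b, e, d, t = params.as_array()
        fs = _FastState(len(trials), init_state)
        p_a = np.array(
            [_step(fs, rep, true_idx[i], g, b, e, d, t) for i, rep in enumerate(reps)]
        )
    mask = resp >= 0
    p = np.where(resp[mask] == 0, p_a[mask], 1.0 - p_a[mask])
    return float(-np.log(np.maximum(p, PROB_FLOOR)).sum())


def replay_attention(
    params: SustainParams,
    trials: pd.DataFrame,
    init_state: SustainState | None = None,
) -> pd.DataFrame:
    """Replay the experienced trial order at fixed parameters, extracting the
    attention tunings lambda_i after every trial."""
    trials = _check_ordered(trials)
    if init_state is None:
        _, lams = _core_loop(trials, params)
    else:
        reps, true_idx, _ = _prep_arrays(trials)
        g, b, e, d, t = params.as_array()
        fs = _FastState(len(trials), init_state)
        lams = np.empty((len(trials), N_ATTR))
        for i, rep in enumerate(reps):
            _step(fs, rep, true_idx[i], g, b, e, d, t)
            lams[i] = fs.lambdas
    out = trials[["participant", "problem", "problem_position", "run", "trial_index"]].copy()
    for i in range(N_ATTR):
        out[f"lambda{i + 1}"] = lams[:, i]
    return out


def simulate_learner(
    schedule: pd.DataFrame,
    params: SustainParams,
    seed: int = 0,
    rt_window: tuple[float, float] = (0.5, 3.0),
) -> pd.DataFrame:
    """Fill a schedule's responses by running the model generatively.

    Responses are sampled from the choice probabilities; state carries over
    between problems in the scheduled order. Response onsets are drawn
    uniformly within ``rt_window`` seconds after stimulus onset.
    """
    params.validate()
    schedule = _check_ordered(schedule)
    _, true_idx, _ = _prep_arrays(schedule)
    rng = np.random.default_rng(seed)
    p_a, _ = _core_loop(schedule, params)
    responses = (rng.random(len(schedule)) >= p_a).astype(int)
    out = schedule.copy()
    out["response"] = pd.array([CATEGORIES[r] for r in responses], dtype="string")
    out["correct"] = pd.array(
        [r == ti for r, ti in zip(responses, true_idx)], dtype="boolean"
    )
    out["response_onset_s"] = out["onset_s"] + rng.uniform(
        rt_window[0], rt_window[1], size=len(out)
    )
    return out


@dataclass
class FitResult:
    params: SustainParams
    neg_log_likelihood: float
    choice_probabilities: np.ndarray  # per responded trial, P(participant's response)
    attention_trajectory: pd.DataFrame
    seed: int
    n_iterations: int
    converged: bool
    bounds: dict[str, tuple[float, float]]


def _per_trial_response_probs(params, trials) -> np.ndarray:
    _, _, resp = _prep_arrays(trials)
    p_a, _ = _core_loop(trials, params)
    mask = resp >= 0
    return np.where(resp[mask] == 0, p_a[mask], 1.0 - p_a[mask])


def fit_participant(
    trials: pd.DataFrame,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    maxiter: int = 300,
    popsize: int = 15,
    tol: float = 0.01,
    polish: bool = True,
) -> FitResult:
    """Maximum-likelihood fit of the five parameters by differential evolution.

    The attention trajectory is obtained by replaying the participant's trial
    order at the best-fitting parameters.
    """
    bounds = bounds or DEFAULT_BOUNDS
    trials = _check_ordered(trials)
    enc = np.stack([_ENCODINGS[c] for c in trials["stimulus_code"]])
    _, true_idx, resp = _prep_arrays(trials)
    mask = resp >= 0
    resp_a = resp[mask] == 0
    fn = _core_loop_jit if _HAVE_NUMBA else _core_loop_py

    def objective(x):
        p_a, _ = fn(enc, true_idx, x[0], x[1], x[2], x[3], x[4])
        p = np.where(resp_a, p_a[mask], 1.0 - p_a[mask])
        return float(-np.log(np.maximum(p, PROB_FLOOR)).sum())

    result = differential_evolution(
        objective,
        bounds=[bounds[n] for n in PARAM_NAMES],
        seed=seed,
        maxiter=maxiter,
        popsize=popsize,
        tol=tol,
        polish=polish,
        init="sobol",
    )
    best = SustainParams.from_array(result.x)
    return FitResult(
        params=best,
        neg_log_likelihood=float(result.fun),
        choice_probabilities=_per_trial_response_probs(best, trials),
        attention_trajectory=replay_attention(best, trials),
        seed=seed,
        n_iterations=int(result.nit),
        converged=bool(result.success),
        bounds=bounds,
    )
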