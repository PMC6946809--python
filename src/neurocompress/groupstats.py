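"""Group-level inference on compression maps and behavior.

All models are linear mixed-effects regressions with participant random
intercepts, problem complexity coded numerically 1 (low) / 2 (medium) /
3 (high) and learning block 1-4, so the block x complexity interaction is a
single coefficient. The voxel-wise map saves the Wald t-statistic of that
interaction; clusters are extracted with second-nearest-neighbor
(faces + edges) connectivity under a two-sided voxel threshold.
Trial-by-trial accuracy is modeled with a fixed-effects logistic regression
(participant intercepts as dummies) and likelihood-ratio chi-square tests
per effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
import statsmodels.api as sm

from .signals import COMPLEXITY_LEVEL


def _interaction_design(meta: pd.DataFrame, extra: list[str]) -> pd.DataFrame:
    block = meta["block"].to_numpy(dtype=float)
    comp = meta["complexity"].to_numpy(dtype=float)
    cols = {
        "intercept": np.ones(len(meta)),
        "block": block,
        "complexity": comp,
        "block:complexity": block * comp,
    }
    for name in extra:
        cols[name] = meta[name].to_numpy(dtype=float)
    return pd.DataFrame(cols)


def _fit_mixedlm(model: sm.MixedLM):
    """Fit with the default optimizer, falling back to derivative-free
    methods when a near-zero random-effect variance makes the score
    singular."""
    last_err = None
    for method in (None, "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if method is None:
                    return model.fit(reml=True)
                return model.fit(method=method, reml=True)
        except (np.linalg.LinAlgError, ValueError) as err:
            last_err = err
    raise last_err


def add_complexity(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["complexity"] = out["problem"].map(COMPLEXITY_LEVEL)
    return out


def fit_mixed_interaction(
    df: pd.DataFrame,
    outcome: str,
    covariates: list[str] = ("accuracy",),
    include_interaction: bool = True,
) -> pd.DataFrame:
    """Mixed model ``outcome ~ block * complexity + covariates`` with a
    participant random intercept; returns a coefficient table.

    With ``include_interaction=False`` the model drops the product term and
    the block/complexity rows give marginal (main-effect) slopes.
    """
    exog = _interaction_design(df, list(covariates))
    if not include_interaction:
        exog = exog.drop(columns="block:complexity")
    names = list(exog.columns)
    model = sm.MixedLM(
        df[outcome].to_numpy(dtype=float),
        exog,
        groups=df["participant"].to_numpy(),
    )
    fit = _fit_mixedlm(model)
    fe = fit.fe_params
    bse = fit.bse_fe
    tvals = fe / bse
    ci = fit.conf_int().loc[names]
    return pd.DataFrame(
        {
            "coef": fe,
            "se": bse,
            "t": tvals,
            "p": fit.pvalues.loc[names],
            "ci_low": ci[0],
            "ci_high": ci[1],
        },
        index=names,
    )


@dataclass
class StatMap:
    """Voxel-wise interaction statistics from the mixed-effects maps."""

    t: np.ndarray  # 3-D t of block:complexity, NaN where unfit
    coef: np.ndarray  # 3-D interaction coefficient
    mask: np.ndarray
    df_resid: float
    n_failed: int


def voxelwise_interaction_map(
    maps: np.ndarray,
    meta: pd.DataFrame,
    mask: np.ndarray,
    covariates: list[str] = ("accuracy",),
    min_participants: int = 5,
) -> StatMap:
    """Fit the block x complexity mixed model at every in-mask voxel.

    ``maps`` is (n_observations, x, y, z) aligned with ``meta`` rows
    (participant, block, complexity, covariates). Voxels with any undefined
    observation or a singular fit are left NaN.
    """
    if maps.shape[0] != len(meta):
        raise ValueError("map stack and metadata are misaligned")
    if meta["participant"].nunique() < min_participants:
        raise ValueError(f"need at least {min_participants} participants")
    exog = _interaction_design(meta, list(covariates))
    names = list(exog.columns)
    idx = names.index("block:complexity")
    groups = meta["participant"].to_numpy()
    tvol = np.full(mask.shape, np.nan)
    cvol = np.full(mask.shape, np.nan)
    n_failed = 0
    centers = np.argwhere(mask)
    for c in centers:
        y = maps[(slice(None), *c)]
        if not np.isfinite(y).all():
            continue
        try:
            fit = _fit_mixedlm(sm.MixedLM(y, exog, groups=groups))
            tvol[tuple(c)] = fit.fe_params.iloc[idx] / fit.bse_fe.iloc[idx]
            cvol[tuple(c)] = fit.fe_params.iloc[idx]
        except (np.linalg.LinAlgError, ValueError):
            n_failed += 1
    df_resid = float(len(meta) - exog.shape[1])
    return StatMap(t=tvol, coef=cvol, mask=mask, df_resid=df_resid, n_failed=n_failed)


def cluster_extract(
    stat: StatMap | np.ndarray,
    voxel_p: float = 0.001,
    extent: int = 1,
    df_resid: float | None = None,
    connectivity: int = 2,
) -> pd.DataFrame:
    """Two-sided suprathreshold clusters with faces+edges connectivity.

    Returns a table (cluster_id, sign, size, peak_t, peak_x/y/z) of clusters
    with at least ``extent`` voxels, largest first.
    """
    if isinstance(stat, StatMap):
        tmap = stat.t
        df_resid = stat.df_resid if df_resid is None else df_resid
    else:
        tmap = np.asarray(stat, dtype=float)
        if df_resid is None:
            raise ValueError("df_resid required when passing a bare t volume")
    if voxel_p <= 0 or extent <= 0:
        raise ValueError("voxel_p and extent must be positive")
    t_crit = stats.t.ppf(1.0 - voxel_p / 2.0, df_resid)
    structure = ndimage.generate_binary_structure(3, connectivity)
    rows = []
    for sign in (1, -1):
        supra = np.nan_to_num(tmap * sign) > t_crit
        labeled, n = ndimage.label(supra, structure=structure)
        for lab in range(1, n + 1):
            vox = np.argwhere(labeled == lab)
            size = len(vox)
            if size < extent:
                continue
            tv = tmap[labeled == lab]
            peak_i = np.argmax(tv * sign)
            rows.append(
                {
                    "sign": sign,
                    "size": size,
                    "peak_t": float(tv[peak_i]),
                    "peak_x": int(vox[peak_i, 0]),
                    "peak_y": int(vox[peak_i, 1]),
                    "peak_z": int(vox[peak_i, 2]),
                }
            )
    out = pd.DataFrame(
        rows, columns=["sign", "size", "peak_t", "peak_x", "peak_y", "peak_z"]
    ).sort_values("size", ascending=False, ignore_index=True)
    out.insert(0, "cluster_id", np.arange(1, len(out) + 1))
    return out


def _order_covariate(trials: pd.DataFrame) -> pd.Series:
    """Counterbalance indicator: 0 when low precedes medium, else 1."""
    def per_participant(grp):
        pos = grp.groupby("problem")["problem_position"].first()
        return 0.0 if pos["low"] < pos["medium"] else 1.0

    order = trials.groupby("participant").apply(per_participant, include_groups=False)
    return trials["participant"].map(order)


def behavioral_learning_regression(trials: pd.DataFrame) -> pd.DataFrame:
    """Trial-by-trial accuracy ~ repetition * complexity + order, participant
    intercepts, likelihood-ratio chi-square per fixed effect.

    Only responded trials enter. Returns a table (effect, chi2, df, p).
    """
    df = trials[trials["response"].notna()].copy()
    df["complexity"] = df["problem"].map(COMPLEXITY_LEVEL).astype(float)
    df["acc"] = df["correct"].astype(float)
    df["order"] = _order_covariate(df).to_numpy()
    dummies = pd.get_dummies(df["participant"], drop_first=False, dtype=float)

    def design(effects: list[str], with_dummies: bool = True) -> np.ndarray:
        cols = [dummies.to_numpy()] if with_dummies else []
        for eff in effects:
            if eff == "repetition:complexity":
                cols.append((df["repetition"] * df["complexity"]).to_numpy()[:, None])
            elif eff == "intercept":
                cols.append(np.ones((len(df), 1)))
            else:
                cols.append(df[eff].to_numpy(dtype=float)[:, None])
        return np.hstack(cols)

    mains = ["repetition", "complexity"]

    def llf(effects, with_dummies=True):
        X = design(effects, with_dummies)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(df["acc"].to_numpy(), X).fit(disp=0, maxiter=200)
        if not np.isfinite(fit.llf):
            raise RuntimeError("logistic fit failed (possible separation)")
        return fit.llf

    # type-II style: main effects tested against the main-effects model,
    # the interaction against the main-effects model augmented with it
    ll_mains = llf(mains)
    rows = []
    for eff in mains:
        chi2 = 2.0 * (ll_mains - llf([e for e in mains if e != eff]))
        rows.append({"effect": eff, "chi2": chi2})
    chi2_int = 2.0 * (llf(mains + ["repetition:complexity"]) - ll_mains)
    rows.append({"effect": "repetition:complexity", "chi2": chi2_int})
    # order varies between participants only, so it is collinear with the
    # participant intercepts; test it in a pooled model without them
    pooled = ["intercept", "repetition", "complexity", "order"]
    chi2_order = 2.0 * (
        llf(pooled, with_dummies=False)
        - llf([e for e in pooled if e != "order"], with_dummies=False)
    )
    rows.append({"effect": "order", "chi2": chi2_order})
    out = pd.DataFrame(rows)
    out["df"] = 1
    out["p"] = stats.chi2.sf(np.maximum(out["chi2"], 0.0), 1)
    return out


def learning_curves(trials: pd.DataFrame, block_size: int = 16) -> pd.DataFrame:
    """Mean accuracy over consecutive ``block_size``-trial behavioral blocks,
    per (participant, problem)."""
    rows = []
    for (part, prob), grp in trials.groupby(["participant", "problem"], sort=False):
        grp = grp.sort_values(["run", "trial_index"])
        acc = grp["correct"].astype(float).to_numpy()
        if len(acc) % block_size:
            raise ValueError(
                f"block size {block_size} does not divide {len(acc)} trials"
            )
        means = acc.reshape(-1, block_size).mean(axis=1)
        for b, m in enumerate(means, start=1):
            rows.append(
                {
                    "participant": part,
                    "problem": prob,
                    "block": b,
                    "accuracy": float(m),
                }
            )
    return pd.DataFrame(rows)


def compression_attention_regression(
    neural: pd.DataFrame,
    attention: pd.DataFrame,
    covariates: list[str] = ("accuracy", "order"),
) -> dict:
    """Mixed model of attention compression on neural compression.

    Tables join on (participant, problem, block); ``neural`` carries a
    ``neural_compression`` column, ``attention`` an ``attention_compression``
    column plus covariates. Returns the coefficient, 95% interval and p for
    the neural predictor, the full coefficient table, and partial residuals
    of both measures with block/complexity/covariates regressed out.
    """
    keys = ["participant", "problem", "block"]
    df = attention.merge(neural, on=keys, how="inner", validate="one_to_one")
    if len(df) == 0:
        raise ValueError("no overlapping (participant, problem, block) rows")
    if len(df) < len(attention) or len(df) < len(neural):
        raise ValueError("tables do not fully align on (participant, problem, block)")
    df = add_complexity(df)

    exog = _interaction_design(df, list(covariates))
    exog["neural_compression"] = df["neural_compression"].to_numpy(dtype=float)
    names = list(exog.columns)
    model = sm.MixedLM(
        df["attention_compression"].to_numpy(dtype=float),
        exog,
        groups=df["participant"].to_numpy(),
    )
    fit = _fit_mixedlm(model)
    ci = fit.conf_int().loc["neural_compression"]
    table = pd.DataFrame(
        {"coef": fit.fe_params, "se": fit.bse_fe, "p": fit.pvalues.loc[names]},
        index=names,
    )

    # partial residuals: regress each measure on everything but the other
    base = _interaction_design(df, list(covariates)).to_numpy()
    def residualize(col):
        y = df[col].to_numpy(dtype=float)
        b, *_ = np.linalg.lstsq(base, y, rcond=None)
        return y - base @ b

    partial = df[keys].copy()
    partial["neural_partial"] = residualize("neural_compression")
    partial["attention_partial"] = residualize("attention_compression")
    return {
        "coef": float(fit.fe_params.loc["neural_compression"]),
        "ci": (float(ci[0]), float(ci[1])),
        "p": float(fit.pvalues.loc["neural_compression"]),
        "table": table,
        "partial_residuals": partial,
    }
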