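"""End-to-end orchestration: simulate -> fit -> compress -> discriminate -> stats.

The pipeline runs at the pattern level: trial-wise activation patterns are
generated directly (the forward BOLD model and LS-S estimation are exercised
by their own module and tests, and are bypassed here, as the two routes are
equivalent by the round-trip property). Every stage writes under its own
subdirectory and a manifest records seeds and configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import attention as attn
from . import compression as comp
from . import dataio, discrimination, groupstats, schedule, signals, sustain
from .problems import PROBLEMS, make_problem_bank

log = logging.getLogger("neurocompress")


@dataclass
class PipelineConfig:
    seed: int = 0
    n_participants: int = 23
    volume_shape: tuple[int, int, int] = (20, 20, 20)
    mask_radius: float | None = None
    noise_sd: float = 0.3
    generating_params: dict = field(
        default_factory=lambda: asdict(sustain.SustainParams())
    )
    # differential-evolution budget for the fitting stage
    de_maxiter: int = 40
    de_popsize: int = 6
    searchlight_radius: float = 4.0
    min_sphere_voxels: int = 10
    var_threshold: float = 0.9
    voxel_p: float = 0.001
    cluster_extent: int = 10
    problems: tuple[str, ...] = PROBLEMS  # subset filter for the stats stage
    n_perm: int = 999

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        cfg = cls(**raw)
        cfg.volume_shape = tuple(cfg.volume_shape)
        cfg.problems = tuple(cfg.problems)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _participant_ids(n: int) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(n)]


def _problem_order(i: int) -> tuple[str, str, str]:
    # high always first; low/medium counterbalanced across participants
    return ("high", "low", "medium") if i % 2 == 0 else ("high", "medium", "low")


def simulate_stage(cfg: PipelineConfig, outdir: Path) -> None:
    data_dir = outdir / "data"
    spec = signals.SignalSpec(noise_sd=cfg.noise_sd, seed=cfg.seed)
    mask = signals.spherical_mask(cfg.volume_shape, cfg.mask_radius)
    params = sustain.SustainParams(**cfg.generating_params)
    for i, pid in enumerate(_participant_ids(cfg.n_participants)):
        bank = make_problem_bank(seed=cfg.seed * 1000 + i, randomize_feature_mapping=True)
        sched = schedule.make_trial_schedule(
            bank, _problem_order(i), seed=cfg.seed * 1000 + i, participant=pid
        )
        trials = sustain.simulate_learner(sched, params, seed=cfg.seed * 1000 + i)
        pspec = signals.SignalSpec(
            noise_sd=cfg.noise_sd, seed=(cfg.seed * 1000 + i) % 2**31
        )
        betas = signals.simulate_beta_series(trials, pspec, mask)
        dataio.write_dataset(
            data_dir / pid, trials, betas, config={"seed": cfg.seed, "participant": pid}
        )


def fit_stage(cfg: PipelineConfig, outdir: Path) -> None:
    fits_dir = outdir / "fits"
    fits_dir.mkdir(parents=True, exist_ok=True)
    for pid in _participant_ids(cfg.n_participants):
        trials, _ = dataio.read_dataset(outdir / "data" / pid)
        result = sustain.fit_participant(
            trials,
            seed=cfg.seed,
            maxiter=cfg.de_maxiter,
            popsize=cfg.de_popsize,
        )
        (fits_dir / f"{pid}_fit.json").write_text(
            json.dumps(
                {
                    "params": asdict(result.params),
                    "neg_log_likelihood": result.neg_log_likelihood,
                    "seed": result.seed,
                    "n_iterations": result.n_iterations,
                    "converged": result.converged,
                    "bounds": result.bounds,
                },
                indent=2,
            )
        )
        result.attention_trajectory.to_csv(
            fits_dir / f"{pid}_attention.tsv", sep="\t", index=False
        )


def compress_stage(cfg: PipelineConfig, outdir: Path) -> None:
    import nibabel as nib

    maps_dir = outdir / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    spec = comp.SearchlightSpec(
        radius=cfg.searchlight_radius,
        min_sphere_voxels=cfg.min_sphere_voxels,
        var_threshold=cfg.var_threshold,
    )
    members = None
    rows = []
    for pid in _participant_ids(cfg.n_participants):
        trials, betas = dataio.read_dataset(outdir / "data" / pid)
        for bs in betas:
            if members is None:
                members = comp._sphere_members(
                    bs.mask, comp.sphere_offsets(spec.radius)
                )
            cmap = comp.searchlight_compression(bs, spec, members=members)
            name = f"{pid}_{bs.problem}_block-{bs.run}_compression.nii.gz"
            nib.save(nib.Nifti1Image(cmap.compression, bs.affine), maps_dir / name)
            rows.append(
                {
                    "participant": pid,
                    "problem": bs.problem,
                    "block": bs.run,
                    "neural_compression": float(np.nanmean(cmap.compression)),
                }
            )
    pd.DataFrame(rows).to_csv(maps_dir / "mean_compression.tsv", sep="\t", index=False)


def discriminate_stage(cfg: PipelineConfig, outdir: Path) -> None:
    disc_dir = outdir / "discrimination"
    disc_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid in _participant_ids(cfg.n_participants):
        trials, betas = dataio.read_dataset(outdir / "data" / pid)
        for bs in betas:
            res = comp.pca_k(bs.data, cfg.var_threshold)
            labels = bs.trials["true_class"].to_numpy()
            d = discrimination.pc_category_discrimination(res, labels)
            rows.append(
                {
                    "participant": pid,
                    "problem": bs.problem,
                    "block": bs.run,
                    "score": d.score,
                    "k": d.k,
                }
            )
    pd.DataFrame(rows).to_csv(disc_dir / "scores.tsv", sep="\t", index=False)


def stats_stage(cfg: PipelineConfig, outdir: Path) -> None:
    import nibabel as nib

    stats_dir = outdir / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    pids = _participant_ids(cfg.n_participants)

    all_trials = pd.concat(
        [dataio.read_dataset(outdir / "data" / pid)[0] for pid in pids],
        ignore_index=True,
    )
    curves = groupstats.learning_curves(all_trials)
    curves.to_csv(stats_dir / "learning_curves.tsv", sep="\t", index=False)
    behav = groupstats.behavioral_learning_regression(all_trials)
    behav.to_csv(stats_dir / "behavioral_regression.tsv", sep="\t", index=False)

    # per (participant, problem, run) accuracy covariate and order covariate
    acc = (
        all_trials.assign(acc=all_trials["correct"].astype(float))
        .groupby(["participant", "problem", "run"], as_index=False)["acc"]
        .mean()
        .rename(columns={"run": "block", "acc": "accuracy"})
    )
    order = groupstats._order_covariate(all_trials)
    order_map = all_trials.assign(order=order.to_numpy()).groupby("participant")[
        "order"
    ].first()

    mean_comp = pd.read_csv(outdir / "maps" / "mean_compression.tsv", sep="\t")
    mean_comp = mean_comp[mean_comp["problem"].isin(cfg.problems)]
    neural = mean_comp.merge(acc, on=["participant", "problem", "block"])
    neural["order"] = neural["participant"].map(order_map)
    neural = groupstats.add_complexity(neural)
    table = groupstats.fit_mixed_interaction(
        neural, "neural_compression", covariates=["accuracy"]
    )
    table.to_csv(stats_dir / "compression_interaction.tsv", sep="\t")

    # voxel-wise map and clusters
    mask_img = nib.load(outdir / "data" / pids[0] / "mask.nii.gz")
    mask = np.asarray(mask_img.dataobj).astype(bool)
    stack, meta_rows = [], []
    for pid in pids:
        for problem in cfg.problems:
            for run in range(1, schedule.N_RUNS + 1):
                name = f"{pid}_{problem}_block-{run}_compression.nii.gz"
                stack.append(np.asarray(nib.load(outdir / "maps" / name).dataobj))
                meta_rows.append(
                    {"participant": pid, "problem": problem, "block": run}
                )
    meta = groupstats.add_complexity(pd.DataFrame(meta_rows))
    meta = meta.merge(acc, on=["participant", "problem", "block"], validate="one_to_one")
    stat = groupstats.voxelwise_interaction_map(
        np.stack(stack), meta, mask, covariates=["accuracy"]
    )
    nib.save(nib.Nifti1Image(stat.t, mask_img.affine), stats_dir / "interaction_t.nii.gz")
    clusters = groupstats.cluster_extract(
        stat, voxel_p=cfg.voxel_p, extent=cfg.cluster_extent
    )
    clusters.to_csv(stats_dir / "clusters.tsv", sep="\t", index=False)

    # attention compression from the fitted trajectories
    att_rows = []
    for pid in pids:
        traj = pd.read_csv(outdir / "fits" / f"{pid}_attention.tsv", sep="\t")
        att_rows.append(attn.blockwise_attention_compression(traj))
    att = pd.concat(att_rows, ignore_index=True)
    att = att[att["problem"].isin(cfg.problems)]
    att = att.merge(acc, on=["participant", "problem", "block"])
    att["order"] = att["participant"].map(order_map)
    att = groupstats.add_complexity(att)
    att.to_csv(stats_dir / "attention_compression.tsv", sep="\t", index=False)
    att_table = groupstats.fit_mixed_interaction(
        att, "attention_compression", covariates=["accuracy"]
    )
    att_table.to_csv(stats_dir / "attention_interaction.tsv", sep="\t")

    reg = groupstats.compression_attention_regression(
        neural[["participant", "problem", "block", "neural_compression"]],
        att[
            [
                "participant",
                "problem",
                "block",
                "attention_compression",
                "accuracy",
                "order",
            ]
        ],
    )
    reg["table"].to_csv(stats_dir / "attention_on_neural.tsv", sep="\t")
    reg["partial_residuals"].to_csv(
        stats_dir / "partial_residuals.tsv", sep="\t", index=False
    )

    # discrimination regression
    disc = pd.read_csv(outdir / "discrimination" / "scores.tsv", sep="\t")
    disc = disc[disc["problem"].isin(cfg.problems)]
    disc = disc.merge(acc, on=["participant", "problem", "block"])
    disc = groupstats.add_complexity(disc)
    disc_table = groupstats.fit_mixed_interaction(
        disc, "score", covariates=["accuracy"]
    )
    disc_table.to_csv(stats_dir / "discrimination_interaction.tsv", sep="\t")


STAGES = {
    "simulate": simulate_stage,
    "fit": fit_stage,
    "compress": compress_stage,
    "discriminate": discriminate_stage,
    "stats": stats_stage,
}


def run(cfg: PipelineConfig, outdir, stages: list[str] | None = None) -> Path:
    """Run the pipeline stages in order, writing a manifest at the end."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or list(STAGES)
    manifest = {"config": asdict(cfg), "stages": {}}
    for name in stages:
        t0 = time.time()
        log.info("stage %s starting", name)
        try:
            STAGES[name](cfg, outdir)
        except Exception as err:  # preserve partial outputs, tag the stage
            manifest["stages"][name] = {"status": "failed", "error": str(err)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise StageError(name, err) from err
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.time() - t0, 3),
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
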