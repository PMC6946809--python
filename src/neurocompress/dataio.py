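"""On-disk layout: NIfTI beta series, BIDS-style events tables, JSON config.

Beta series are written as 4-D NIfTI (one volume per trial) alongside a 3-D
mask; trials as tab-separated events files with onset/duration columns in
seconds; generation parameters as a JSON snapshot.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .signals import BetaSeries

EVENTS_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "participant",
    "problem",
    "problem_position",
    "run",
    "trial_index",
    "stimulus",
    "response",
    "correct",
    "true_class",
    "problem_order",
]


def events_frame(trials: pd.DataFrame) -> pd.DataFrame:
    """BIDS-events-like view of a trial table (one row per stimulus event)."""
    ev = pd.DataFrame(
        {
            "onset": trials["onset_s"],
            "duration": trials["stim_duration_s"],
            "trial_type": "stimulus",
            "participant": trials["participant"],
            "problem": trials["problem"],
            "problem_position": trials["problem_position"],
            "run": trials["run"],
            "trial_index": trials["trial_index"],
            "stimulus": trials["stimulus_code"],
            "response": trials["response"],
            "correct": trials["correct"],
            "true_class": trials["true_class"],
            "problem_order": trials["problem_order"],
        }
    )
    return ev[EVENTS_COLUMNS]


def write_dataset(
    directory,
    trials: pd.DataFrame,
    beta_series: list[BetaSeries],
    config: dict | None = None,
) -> Path:
    """Write one participant's trials, beta series and mask under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trials.to_csv(directory / "trials.tsv", sep="\t", index=False)
    events_frame(trials).to_csv(directory / "events.tsv", sep="\t", index=False)
    if beta_series:
        mask = beta_series[0].mask
        affine = beta_series[0].affine
        nib.save(
            nib.Nifti1Image(mask.astype(np.uint8), affine),
            directory / "mask.nii.gz",
        )
        for bs in beta_series:
            img = nib.Nifti1Image(bs.to_volume().astype(np.float64), bs.affine)
            name = f"{bs.participant}_{bs.problem}_run-{bs.run}_betas.nii.gz"
            nib.save(img, directory / name)
    if config is not None:
        (directory / "config.json").write_text(json.dumps(config, indent=2, default=str))
    return directory


def read_dataset(directory) -> tuple[pd.DataFrame, list[BetaSeries]]:
    """Read back a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    trials = pd.read_csv(
        directory / "trials.tsv",
        sep="\t",
        dtype={"stimulus_code": str, "response": "string"},
    )
    trials["correct"] = trials["correct"].astype("boolean")
    mask_path = directory / "mask.nii.gz"
    series: list[BetaSeries] = []
    if mask_path.exists():
        mask_img = nib.load(mask_path)
        mask = np.asarray(mask_img.dataobj).astype(bool)
        affine = mask_img.affine
        for path in sorted(directory.glob("*_betas.nii.gz")):
            participant, problem, run_part, _ = path.name.split("_")
            run = int(run_part.split("-")[1])
            vol = np.asarray(nib.load(path).dataobj)
            data = vol[mask, :].T
            sub = trials[
                (trials["problem"] == problem) & (trials["run"] == run)
            ].sort_values("trial_index")
            series.append(
                BetaSeries(
                    data=data,
                    mask=mask,
                    affine=affine,
                    participant=participant,
                    problem=problem,
                    run=run,
                    trials=sub.reset_index(drop=True),
                )
            )
    return trials, series
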