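"""Category discrimination carried by the retained principal components.

For the k PCs kept by the compression criterion, each trial's loading is its
projection onto the PC axis. The discrimination score is the absolute
difference between category-mean loadings on each PC, weighted by that PC's
explained-variance ratio and summed:

    score = sum_p evr_p * | mean(loading_p | A) - mean(loading_p | B) |

A score of 0 means both categories load identically on every retained PC;
larger scores mean the compressed solution separates the categories. A
label-permutation null calibrates the score against chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compression import CompressionResult


@dataclass
class DiscriminationResult:
    score: float
    per_pc_contributions: np.ndarray  # (k,)
    k: int
    labels: np.ndarray


def _score(pc_scores: np.ndarray, evr: np.ndarray, is_a: np.ndarray) -> float:
    diff = np.abs(pc_scores[is_a].mean(axis=0) - pc_scores[~is_a].mean(axis=0))
    return float((evr * diff).sum())


def pc_category_discrimination(
    comp: CompressionResult, labels
) -> DiscriminationResult:
    """Explained-variance-weighted category separation of PC loadings."""
    labels = np.asarray(labels)
    if len(labels) != comp.n:
        raise ValueError(f"{len(labels)} labels for {comp.n} trials")
    is_a = labels == "A"
    if is_a.all() or not is_a.any():
        raise ValueError("both categories must be present")
    evr = comp.explained_variance_ratios[: comp.k]
    diff = np.abs(
        comp.pc_scores[is_a].mean(axis=0) - comp.pc_scores[~is_a].mean(axis=0)
    )
    contributions = evr * diff
    return DiscriminationResult(
        score=float(contributions.sum()),
        per_pc_contributions=contributions,
        k=comp.k,
        labels=labels,
    )


def permutation_null(
    comp: CompressionResult,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Null distribution of the score under label permutations.

    Permutations preserve class counts. Returns (null scores, empirical p)
    with p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    labels = np.asarray(labels)
    observed = pc_category_discrimination(comp, labels).score
    evr = comp.explained_variance_ratios[: comp.k]
    rng = np.random.default_rng(seed)
    is_a = labels == "A"
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _score(comp.pc_scores, evr, rng.permutation(is_a))
    p = (1.0 + (null >= observed).sum()) / (1.0 + n_perm)
    return null, float(p)
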