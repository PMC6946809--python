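"""Attention-compression index from model-derived attention tunings.

The per-attribute tunings ``lambda_i`` extracted from the learning model are
normalized to a probability distribution ``a`` over the three stimulus
dimensions. Dispersion of attention is the Shannon entropy

    entropy = -sum_i a_i log2 a_i        (0 * log 0 = 0)

and the attention-compression index rescales it to

    attention_compression = 1 - entropy / log2(3)

which ranges from 0 (unselective: uniform attention) to 1 (fully selective:
all weight on one dimension).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MAX_ENTROPY_BITS = float(np.log2(3.0))


def normalize_attention(lambdas) -> np.ndarray:
    """Scale non-negative tunings to sum to 1."""
    lam = np.asarray(lambdas, dtype=float)
    if lam.ndim != 1 or lam.size != 3:
        raise ValueError("expected 3 attention tunings")
    if (lam < 0).any():
        raise ValueError("attention tunings must be non-negative")
    total = lam.sum()
    if total <= 0:
        raise ValueError("attention tunings are all zero; cannot normalize")
    return lam / total


def attention_entropy(a) -> float:
    """Shannon entropy (bits) of normalized attention weights."""
    a = np.asarray(a, dtype=float)
    nz = a[a > 0]
    return float(-(nz * np.log2(nz)).sum())


def attention_compression(a) -> float:
    """1 - entropy/log2(3): 0 at uniform attention, 1 at one-hot attention."""
    return 1.0 - attention_entropy(a) / MAX_ENTROPY_BITS


def trialwise_compression(trajectory: pd.DataFrame) -> pd.Series:
    """Attention compression for every row of a lambda trajectory table."""
    lams = trajectory[["lambda1", "lambda2", "lambda3"]].to_numpy()
    out = np.empty(len(lams))
    for i, lam in enumerate(lams):
        out[i] = attention_compression(normalize_attention(lam))
    return pd.Series(out, index=trajectory.index, name="attention_compression")


def blockwise_attention_compression(
    trajectory: pd.DataFrame, n_blocks: int = 4
) -> pd.DataFrame:
    """Average per-trial attention compression within each learning block.

    The trajectory must carry ``problem`` and ``run`` columns; the learning
    block for attention is the functional run. Raises if any (problem,
    block) cell up to ``n_blocks`` is missing.
    """
    traj = trajectory.copy()
    traj["attention_compression"] = trialwise_compression(traj)
    traj["block"] = traj["run"]
    out = (
        traj.groupby(["participant", "problem", "block"], as_index=False)[
            "attention_compression"
        ]
        .mean()
        .sort_values(["participant", "problem", "block"], ignore_index=True)
    )
    counts = out.groupby(["participant", "problem"])["block"].count()
    if (counts != n_blocks).any():
        raise ValueError(f"expected {n_blocks} blocks per problem, got\n{counts}")
    return out
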