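"""PCA neural compression and its searchlight mapping.

For a trial x voxel pattern matrix, voxel-wise mean-centering followed by
SVD yields explained-variance ratios; ``k`` is the smallest number of
principal components whose cumulative ratio reaches the variance criterion
(90% by default) and the compression score is

    compression = 1 - k / n

with ``n`` the number of trials (32 per learning block). The score is
mapped over the brain by evaluating it on every sphere of a voxel-radius
searchlight (radius 4 by default, 257 in-sphere voxels when untruncated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import BetaSeries

#: tolerance used when comparing cumulative variance ratios to the criterion
_CUM_TOL = 1e-12


@dataclass
class CompressionResult:
    k: int
    n: int
    compression: float
    explained_variance_ratios: np.ndarray  # all min(n, v) ratios, descending
    pc_scores: np.ndarray  # (n, k) projections of centered trials
    degenerate: bool = False  # zero-variance input, k = 1 by convention


def _k_from_variances(variances: np.ndarray, var_threshold: float) -> int:
    total = variances.sum()
    if total <= 0:
        return 1
    cum = np.cumsum(variances) / total
    return int(np.searchsorted(cum, var_threshold - _CUM_TOL) + 1)


def _gram_variances(Xc: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of Xc Xc^T (= squared singular values of Xc).

    Both the standalone PCA and the searchlight derive k from this one
    routine so their component counts agree bit-for-bit.
    """
    ev = np.linalg.eigvalsh(Xc @ Xc.T)[::-1]
    return np.maximum(ev, 0.0)


def pca_k(patterns: np.ndarray, var_threshold: float = 0.9) -> CompressionResult:
    """Compression of an n x v pattern matrix at the variance criterion.

    Patterns are mean-centered per voxel (column) across trials; no variance
    scaling. A zero-variance matrix returns k = 1 flagged as degenerate.
    """
    X = np.asarray(patterns, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError(f"need an n x v matrix with n >= 2, got shape {X.shape}")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    var = _gram_variances(Xc)[: min(X.shape)]
    total = var.sum()
    if total <= 0:
        return CompressionResult(
            k=1,
            n=n,
            compression=1.0 - 1.0 / n,
            explained_variance_ratios=np.zeros_like(var),
            pc_scores=np.zeros((n, 1)),
            degenerate=True,
        )
    k = _k_from_variances(var, var_threshold)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    return CompressionResult(
        k=k,
        n=n,
        compression=1.0 - k / n,
        explained_variance_ratios=var / total,
        pc_scores=u[:, :k] * s[:k],
    )


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer lattice offsets within Euclidean distance ``radius`` of the
    center (center included); 257 offsets at radius 4."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


@dataclass(frozen=True)
class SearchlightSpec:
    radius: float = 4.0
    min_sphere_voxels: int = 10
    var_threshold: float = 0.9


@dataclass
class CompressionMap:
    """Searchlight compression of one (participant, problem, block)."""

    compression: np.ndarray  # 3-D, NaN outside evaluated centers
    k: np.ndarray  # 3-D int counts, 0 outside
    sphere_size: np.ndarray  # 3-D int counts, 0 outside
    mask: np.ndarray
    affine: np.ndarray
    participant: str
    problem: str
    run: int


def _sphere_members(mask: np.ndarray, offsets: np.ndarray) -> list[np.ndarray]:
    """Flat in-mask voxel indices of each center's (truncated) sphere.

    Returned in the order of in-mask centers (C-order scan of the mask);
    indices refer to columns of the mask-flattened pattern matrix.
    """
    shape = mask.shape
    centers = np.argwhere(mask)
    # map from flat volume index to in-mask column index
    flat_to_col = -np.ones(mask.size, dtype=np.int64)
    flat_to_col[np.flatnonzero(mask.ravel())] = np.arange(int(mask.sum()))
    members = []
    for c in centers:
        pts = c + offsets
        ok = ((pts >= 0) & (pts < shape)).all(axis=1)
        pts = pts[ok]
        flat = np.ravel_multi_index((pts[:, 0], pts[:, 1], pts[:, 2]), shape)
        cols = flat_to_col[flat]
        members.append(cols[cols >= 0])
    return members


def searchlight_compression(
    beta: BetaSeries,
    spec: SearchlightSpec | None = None,
    members: list[np.ndarray] | None = None,
) -> CompressionMap:
    """Map the compression score over all in-mask sphere centers.

    Spheres are truncated to in-mask voxels; centers whose truncated sphere
    holds fewer than ``min_sphere_voxels`` voxels are left undefined (NaN).
    Precomputed ``members`` (from :func:`_sphere_members`) may be supplied
    when many runs share one mask.
    """
    spec = spec or SearchlightSpec()
    mask = beta.mask
    if not mask.any():
        raise ValueError("mask contains no voxels")
    if members is None:
        members = _sphere_members(mask, sphere_offsets(spec.radius))
    centers = np.argwhere(mask)
    n = beta.data.shape[0]
    comp = np.full(mask.shape, np.nan)
    kmap = np.zeros(mask.shape, dtype=int)
    szmap = np.zeros(mask.shape, dtype=int)
    X = beta.data
    for c, cols in zip(centers, members):
        sz = len(cols)
        szmap[tuple(c)] = sz
        if sz < spec.min_sphere_voxels:
            continue
        sub = X[:, cols]
        sub = sub - sub.mean(axis=0)
        k = _k_from_variances(_gram_variances(sub), spec.var_threshold)
        kmap[tuple(c)] = k
        comp[tuple(c)] = 1.0 - k / n
    return CompressionMap(
        compression=comp,
        k=kmap,
        sphere_size=szmap,
        mask=mask,
        affine=beta.affine,
        participant=beta.participant,
        problem=beta.problem,
        run=beta.run,
    )


def roi_mean_activation(beta: BetaSeries, roi_mask: np.ndarray) -> float:
    """Mean beta over ROI voxels and trials of one run (univariate control)."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != beta.mask.shape:
        raise ValueError("ROI mask shape does not match the beta mask")
    cols = roi_mask[beta.mask]
    if not cols.any():
        raise ValueError("ROI contains no in-mask voxels")
    return float(beta.data[:, cols].mean())
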