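"""White-matter-hyperintensity segmentation from T2 FLAIR.

The segmenter reproduces a three-step recipe: (1) z-normalise FLAIR
intensities to the mean and SD of a cerebellar white-matter reference
region, (2) run a two-class fuzzy c-means (FCM) on the 1-D normalised
intensities of cerebral voxels to get a soft "high intensity" membership
per voxel, (3) call a voxel WMH when its high-intensity membership strictly
exceeds a threshold (default 0.75).

FCM here is deliberately one-dimensional and unregularised: each voxel is
classified by intensity alone.  Centroids are initialised at the 10th and
90th percentile of in-mask intensities, which is deterministic and makes
the high/low labelling stable without any RNG.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .io import BinaryMask, IntensityVolume, check_same_grid

__all__ = [
    "FcmConfig",
    "FcmResult",
    "WmhThreshold",
    "normalize_flair",
    "fcm_membership",
    "threshold_wmh",
    "segment_wmh",
]


@dataclasses.dataclass
class FcmConfig:
    """Two-class fuzzy c-means settings.

    fuzzifier_m : float
        Membership sharpness exponent m > 1; 2.0 is the classical choice.
    tol : float
        Convergence tolerance on the maximum centroid movement.
    max_iter : int
        Iteration cap; non-convergence is reported, not raised.
    """

    n_clusters: int = 2
    fuzzifier_m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    seed: int = 0  # kept for config round-trips; percentile init uses no RNG

    def __post_init__(self) -> None:
        if self.n_clusters != 2:
            raise ValueError("this segmenter is strictly two-class")
        if self.fuzzifier_m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclasses.dataclass
class FcmResult:
    centroids: tuple[float, float]  # (low, high), high > low
    membership_high: np.ndarray  # 3-D, zeros outside the cerebral mask
    n_iter: int
    converged: bool
    objective_trace: np.ndarray


@dataclasses.dataclass
class WmhThreshold:
    value: float = 0.75
    strict: bool = True  # ">" rather than ">="

    def __post_init__(self) -> None:
        if not 0 < self.value < 1:
            raise ValueError("threshold must lie strictly between 0 and 1")


def normalize_flair(flair: IntensityVolume, cerebellar_wm: BinaryMask) -> IntensityVolume:
    """Z-score FLAIR against its cerebellar white-matter reference.

    Output voxel = (input - mu_ref) / sd_ref with mu_ref, sd_ref the mean
    and (population) SD over reference voxels, so the reference region has
    mean 0 and SD 1 afterwards.
    """
    check_same_grid(flair, cerebellar_wm)
    ref = flair.data[cerebellar_wm.data]
    if ref.size < 2:
        raise ValueError("cerebellar reference must contain at least 2 voxels")
    mu = float(ref.mean())
    sd = float(ref.std())
    if sd == 0.0:
        raise ValueError("cerebellar reference has zero intensity variance")
    return IntensityVolume((flair.data - mu) / sd, flair.affine)


def _fcm_1d(x: np.ndarray, cfg: FcmConfig) -> tuple[np.ndarray, np.ndarray, int, bool, np.ndarray]:
    """Plain two-class FCM on a 1-D sample; returns (centroids, U, iters, conv, obj)."""
    m = cfg.fuzzifier_m
    # deterministic percentile initialisation (low, high)
    c = np.percentile(x, [10.0, 90.0]).astype(float)
    if c[0] == c[1]:
        # fall back to min/max before declaring degeneracy
        c = np.array([x.min(), x.max()], dtype=float)
    if c[0] == c[1]:
        raise ValueError("all in-mask intensities identical; clustering is degenerate")

    obj_trace = []
    u = None
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        d2 = (x[:, None] - c[None, :]) ** 2  # (n, 2) squared distances
        u = _memberships(d2, m)
        um = u**m
        obj_trace.append(float((um * d2).sum()))
        c_new = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        move = float(np.abs(c_new - c).max())
        c = c_new
        if move < cfg.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"FCM did not converge in {cfg.max_iter} iterations", RuntimeWarning
        )
    # final memberships for the converged centroids
    u = _memberships((x[:, None] - c[None, :]) ** 2, m)
    return c, u, n_iter, converged, np.asarray(obj_trace)


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """FCM memberships from squared distances, with exact-hit handling."""
    exponent = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-exponent)
        u = inv / inv.sum(axis=1, keepdims=True)
    # voxels sitting exactly on a centroid: full membership there
    hits = d2 == 0.0
    rows = hits.any(axis=1)
    if rows.any():
        u[rows] = hits[rows] / hits[rows].sum(axis=1, keepdims=True)
    return u


def fcm_membership(
    normalized: IntensityVolume, cerebral_mask: BinaryMask, cfg: FcmConfig | None = None
) -> FcmResult:
    """Soft high/low-intensity memberships for every cerebral voxel.

    Minimises sum_i sum_k u_ik^m (x_i - c_k)^2 by alternating membership and
    centroid updates until the largest centroid move drops below ``cfg.tol``.
    The "high" cluster is the one with the larger converged centroid;
    voxels outside the cerebral mask get membership_high = 0.
    """
    cfg = cfg or FcmConfig()
    check_same_grid(normalized, cerebral_mask)
    if cerebral_mask.n_true == 0:
        raise ValueError("cerebral mask is empty")
    x = normalized.data[cerebral_mask.data]
    c, u, n_iter, converged, obj = _fcm_1d(x, cfg)
    hi = int(np.argmax(c))
    lo = 1 - hi
    membership_high = np.zeros(normalized.shape, dtype=float)
    membership_high[cerebral_mask.data] = u[:, hi]
    return FcmResult(
        centroids=(float(c[lo]), float(c[hi])),
        membership_high=membership_high,
        n_iter=n_iter,
        converged=converged,
        objective_trace=obj,
    )


def threshold_wmh(result: FcmResult, thr: WmhThreshold | None = None, affine=None) -> BinaryMask:
    """Binarise the high-intensity membership map (strict > by default)."""
    thr = thr or WmhThreshold()
    if thr.strict:
        data = result.membership_high > thr.value
    else:
        data = result.membership_high >= thr.value
    if affine is None:
        affine = np.eye(4)
    return BinaryMask(data, affine)


def segment_wmh(
    flair: IntensityVolume,
    cerebellar_wm: BinaryMask,
    cerebral_mask: BinaryMask,
    cfg: FcmConfig | None = None,
    thr: WmhThreshold | None = None,
) -> tuple[BinaryMask, FcmResult]:
    """Full pipeline: normalise, cluster, threshold. Returns (mask, fcm)."""
    normalized = normalize_flair(flair, cerebellar_wm)
    result = fcm_membership(normalized, cerebral_mask, cfg)
    mask = threshold_wmh(result, thr, affine=flair.affine)
    return mask, result
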