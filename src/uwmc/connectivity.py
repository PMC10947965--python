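"""Unhealthy white matter connectivity (UWMC).

A streamline counts toward an unordered region pair {a, b} only when its two
endpoints land in those two (distinct, nonzero) parcellation labels — the
end-to-end convention.  It is "unhealthy" when its path crosses at least
one lesion (WMH) voxel, decided by an exact voxel-traversal test by
default.  Pairwise UWMC is then the unhealthy/total streamline
ratio per pair; lobar and global UWMC are ratios of summed counts (sum of
unhealthy over sum of total), not means of per-pair ratios.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np

from .io import BinaryMask, LabelVolume, StreamlineSet

__all__ = [
    "PairKey",
    "ConnectivityCounts",
    "UwmcMatrix",
    "IntersectionConfig",
    "passes_through",
    "endpoint_labels",
    "count_connections",
    "pairwise_uwmc",
    "lobar_uwmc",
    "global_uwmc",
    "pathology_subset",
]


@dataclasses.dataclass(frozen=True, order=True)
class PairKey:
    """Canonical unordered region pair: a < b, a != b."""

    a: int
    b: int

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("a pair must join two distinct regions")
        if self.a > self.b:
            # canonicalise through object.__setattr__ (frozen dataclass)
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)


@dataclasses.dataclass
class ConnectivityCounts:
    """Per-pair streamline tallies: total T and unhealthy U, 0 <= U <= T."""

    counts: dict[PairKey, tuple[int, int]]

    def __post_init__(self) -> None:
        for key, (t, u) in self.counts.items():
            if not (0 <= u <= t):
                raise ValueError(f"pair {key}: need 0 <= U <= T, got T={t}, U={u}")

    def total(self) -> int:
        return sum(t for t, _ in self.counts.values())

    def unhealthy(self) -> int:
        return sum(u for _, u in self.counts.values())


@dataclasses.dataclass
class UwmcMatrix:
    """Per-pair U/T ratios; zero-denominator pairs carry 0 and are flagged."""

    values: dict[PairKey, float]
    zero_denominator: set[PairKey]
    counts: dict[PairKey, tuple[int, int]] | None = None


@dataclasses.dataclass
class IntersectionConfig:
    """Geometry settings for streamline-voxel tests.

    sampling_step : float or None
        None (default) selects the exact traversal: every voxel whose
        rounding cell a segment crosses is visited, found by walking the
        half-integer boundary crossings in index space.  A positive value
        switches to approximate point sampling with at most this spacing
        (mm) between samples along each segment.
    endpoint_dilation : int
        Chebyshev radius (voxels) searched for a majority label when an
        endpoint voxel is unlabeled; 0 = exact-voxel matching.
    """

    sampling_step: float | None = None
    endpoint_dilation: int = 0

    def __post_init__(self) -> None:
        if self.sampling_step is not None and self.sampling_step <= 0:
            raise ValueError("sampling_step must be positive")
        if self.endpoint_dilation < 0:
            raise ValueError("endpoint_dilation must be >= 0")


def _densify(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline so consecutive samples are at most `step` apart.

    Original vertices are always retained; each segment gets
    ceil(len/step) - 1 evenly spaced interior samples.
    """
    segs = np.diff(points, axis=0)
    lengths = np.linalg.norm(segs, axis=1)
    pieces = [points[:1]]
    for i, L in enumerate(lengths):
        n = max(int(np.ceil(L / step)), 1)
        t = np.arange(1, n + 1) / n
        pieces.append(points[i] + t[:, None] * segs[i])
    return np.vstack(pieces)


def _world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """World mm -> nearest integer voxel indices (0-based)."""
    inv = np.linalg.inv(affine)
    ijk = points @ inv[:3, :3].T + inv[:3, 3]
    return np.rint(ijk).astype(np.int64)


def _in_bounds(ijk: np.ndarray, shape) -> np.ndarray:
    return ((ijk >= 0) & (ijk < np.asarray(shape))).all(axis=1)


def _walk_voxels(points_ijk: np.ndarray) -> np.ndarray:
    """All integer voxel indices whose rounding cell a polyline crosses.

    Works in continuous index space where the cell of voxel k is
    [k-1/2, k+1/2): for each segment, the crossing parameters of every
    half-integer plane are collected and the voxel between consecutive
    crossings is read off at the interval midpoint.
    """
    out = [np.rint(points_ijk).astype(np.int64)]
    for p0, p1 in zip(points_ijk[:-1], points_ijk[1:]):
        d = p1 - p0
        ts = [np.array([0.0, 1.0])]
        for ax in range(3):
            if d[ax] == 0:
                continue
            lo, hi = sorted((p0[ax], p1[ax]))
            # half-integer boundaries strictly inside the segment's span
            first = np.floor(lo + 0.5) + 0.5
            bounds = np.arange(first, hi, 1.0)
            bounds = bounds[(bounds > lo) & (bounds < hi)]
            if bounds.size:
                ts.append((bounds - p0[ax]) / d[ax])
        t = np.unique(np.concatenate(ts))
        mids = (t[:-1] + t[1:]) / 2.0
        out.append(np.rint(p0 + mids[:, None] * d).astype(np.int64))
    return np.vstack(out)


def passes_through(
    streamline: np.ndarray, wmh: BinaryMask, cfg: IntersectionConfig | None = None
) -> bool:
    """Does the polyline cross any true mask voxel?

    The default is an exact traversal (every voxel cell a segment crosses
    is checked); with ``cfg.sampling_step`` set, segments are instead
    densified to that spacing and sampled pointwise.  Points outside the
    grid simply never hit; there is no minimum overlap length — touching
    one lesion voxel is enough.
    """
    cfg = cfg or IntersectionConfig()
    points = np.asarray(streamline, dtype=float)
    inv = np.linalg.inv(wmh.affine)
    ijk_cont = points @ inv[:3, :3].T + inv[:3, 3]
    if cfg.sampling_step is None:
        ijk = _walk_voxels(ijk_cont)
    else:
        # densify in world mm, then convert
        dense = _densify(points, cfg.sampling_step)
        ijk = _world_to_voxel(dense, wmh.affine)
    ok = _in_bounds(ijk, wmh.shape)
    if not ok.any():
        return False
    ijk = ijk[ok]
    return bool(wmh.data[ijk[:, 0], ijk[:, 1], ijk[:, 2]].any())


def _label_at(ijk: np.ndarray, labels: LabelVolume, dilation: int) -> int | None:
    shape = labels.shape
    if _in_bounds(ijk[None, :], shape)[0]:
        lab = int(labels.data[tuple(ijk)])
    else:
        lab = 0
    if lab != 0:
        return lab
    if dilation == 0:
        return None
    # majority nonzero label within a Chebyshev ball; ties -> None
    lo = np.maximum(ijk - dilation, 0)
    hi = np.minimum(ijk + dilation + 1, shape)
    block = labels.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    nz = block[block != 0]
    if nz.size == 0:
        return None
    counts = Counter(nz.tolist())
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return int(ranked[0][0])


def endpoint_labels(
    streamline: np.ndarray, labels: LabelVolume, cfg: IntersectionConfig | None = None
) -> tuple[int | None, int | None]:
    """Parcellation labels at the first and last streamline point."""
    cfg = cfg or IntersectionConfig()
    points = np.asarray(streamline, dtype=float)
    ends = _world_to_voxel(points[[0, -1]], labels.affine)
    return (
        _label_at(ends[0], labels, cfg.endpoint_dilation),
        _label_at(ends[1], labels, cfg.endpoint_dilation),
    )


def count_connections(
    streamlines: StreamlineSet,
    labels: LabelVolume,
    wmh: BinaryMask,
    cfg: IntersectionConfig | None = None,
) -> ConnectivityCounts:
    """Tally end-to-end connections per unordered pair.

    A streamline is counted iff its two endpoints resolve to two distinct
    nonzero labels; it increments that pair's total always and its
    unhealthy count additionally iff it passes through the lesion mask.
    Loops (both ends in one region) and streamlines with an unlabeled end
    are ignored.
    """
    cfg = cfg or IntersectionConfig()
    counts: dict[PairKey, list[int]] = {}
    for sl in streamlines:
        la, lb = endpoint_labels(sl, labels, cfg)
        if la is None or lb is None or la == lb:
            continue
        key = PairKey(la, lb)
        entry = counts.setdefault(key, [0, 0])
        entry[0] += 1
        if passes_through(sl, wmh, cfg):
            entry[1] += 1
    return ConnectivityCounts({k: (t, u) for k, (t, u) in counts.items()})


def pairwise_uwmc(counts: ConnectivityCounts) -> UwmcMatrix:
    """U/T per pair; pairs with T = 0 get 0.0 and a zero-denominator flag."""
    values: dict[PairKey, float] = {}
    flagged: set[PairKey] = set()
    for key, (t, u) in counts.counts.items():
        if t > 0:
            values[key] = u / t
        else:
            values[key] = 0.0
            flagged.add(key)
    return UwmcMatrix(values, flagged, counts=dict(counts.counts))


def lobar_uwmc(counts: ConnectivityCounts, labels: LabelVolume) -> dict[str, float]:
    """Ratio-of-sums UWMC per bilateral lobe.

    For lobe L: sum of U over pairs with BOTH regions in L divided by the
    matching sum of T.  Lobes whose pair set has no streamlines are
    reported as 0.0 (and show up in the companion zero set of
    :func:`lobar_uwmc_flagged`).
    """
    values, _ = lobar_uwmc_flagged(counts, labels)
    return values


def lobar_uwmc_flagged(
    counts: ConnectivityCounts, labels: LabelVolume
) -> tuple[dict[str, float], set[str]]:
    by_id = labels.by_id
    sums: dict[str, list[int]] = {}
    for key, (t, u) in counts.counts.items():
        try:
            lobe_a = by_id[key.a].lobe
            lobe_b = by_id[key.b].lobe
        except KeyError as exc:
            raise ValueError(f"region {exc} in counts has no label record") from exc
        if lobe_a != lobe_b:
            continue
        entry = sums.setdefault(lobe_a, [0, 0])
        entry[0] += t
        entry[1] += u
    values: dict[str, float] = {}
    flagged: set[str] = set()
    lobes_present = {rec.lobe for rec in labels.table}
    for lobe in sorted(lobes_present):
        t, u = sums.get(lobe, [0, 0])
        if t > 0:
            values[lobe] = u / t
        else:
            values[lobe] = 0.0
            flagged.add(lobe)
    return values, flagged


def global_uwmc(counts: ConnectivityCounts) -> float:
    """Whole-brain ratio: sum U / sum T over every pair (inter-lobe included)."""
    t = counts.total()
    if t == 0:
        raise ValueError("empty connectome: no end-to-end streamlines counted")
    return counts.unhealthy() / t


def pathology_subset(
    matrix: UwmcMatrix, labels: LabelVolume, which: str
) -> list[tuple[PairKey, float]]:
    """All unordered pairs of regions flagged for a pathology set.

    Returns every candidate pair (including pairs with no streamlines,
    which carry UWMC 0) in canonical (min id, max id) order, so a set of n
    flagged regions yields n(n-1)/2 entries.
    """
    ids = labels.ids_in_set(which)
    if len(ids) < 2:
        raise ValueError(f"pathology set {which!r} flags fewer than 2 regions")
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            key = PairKey(a, b)
            out.append((key, matrix.values.get(key, 0.0)))
    return out
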