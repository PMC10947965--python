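"""Synthetic phantoms and cohorts with known ground truth.

Two generators:

* :func:`make_phantom` builds an image-space phantom — spherical labeled
  ROIs, smooth streamline bundles joining them, and a lesion blob planted
  so that an exact, pre-specified fraction of each bundle passes through
  it (verified by an independent dense-sampling check).  It also
  synthesises a FLAIR-like volume (background N(0,1), lesion N(shift,1))
  and a disjoint cerebellar reference region so segmentation can run end
  to end.  The canonical ``worked_example`` preset is one pair of regions joined
  by four streamlines of which two cross the lesion (UWMC = 0.5).

* :func:`make_cohort` draws participant tables where MoCA is a linear
  function of log-UWMC on designated active pairs plus covariate effects
  and Gaussian noise, with every true parameter recorded.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import ConnectivityCounts, PairKey, UwmcMatrix, pairwise_uwmc
from .io import (
    BinaryMask,
    IntensityVolume,
    LabelRecord,
    LabelVolume,
    StreamlineSet,
    write_label_table,
    write_streamlines,
    write_volume,
)

__all__ = [
    "RegionSpec",
    "BundleSpec",
    "PhantomConfig",
    "PhantomTruth",
    "CohortConfig",
    "SyntheticCohort",
    "make_phantom",
    "make_intensity_phantom",
    "make_cohort",
    "worked_example_config",
    "multibundle_config",
]


@dataclasses.dataclass(frozen=True)
class RegionSpec:
    id: int
    lobe: str
    hemisphere: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    in_abeta_set: bool = False
    in_tau_set: bool = False


@dataclasses.dataclass(frozen=True)
class BundleSpec:
    pair: PairKey
    n_streamlines: int
    target_uwmc: float

    def __post_init__(self) -> None:
        k = self.target_uwmc * self.n_streamlines
        if abs(k - round(k)) > 1e-9:
            raise ValueError(
                "target_uwmc * n_streamlines must be an integer for exact planting"
            )

    @property
    def n_unhealthy(self) -> int:
        return int(round(self.target_uwmc * self.n_streamlines))


@dataclasses.dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (48, 24, 24)
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    regions: Sequence[RegionSpec] = ()
    bundles: Sequence[BundleSpec] = ()
    lesion_intensity_shift: float = 6.0
    seed: int = 0
    max_retries: int = 8


@dataclasses.dataclass
class PhantomTruth:
    labels: LabelVolume
    streamlines: StreamlineSet
    lesion_mask: BinaryMask
    flair: IntensityVolume
    cerebellar_mask: BinaryMask
    cerebral_mask: BinaryMask
    true_counts: ConnectivityCounts
    true_uwmc: UwmcMatrix
    #: per-streamline ground-truth lesion crossing, aligned with streamlines
    crossing: list[bool]

    def write(self, out_dir) -> dict[str, str]:
        """Write NIfTI volumes, the TCK tractogram, label table and truth."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, vol in (
            ("labels", self.labels),
            ("wmh", self.lesion_mask),
            ("flair", self.flair),
            ("cerebellar_wm", self.cerebellar_mask),
            ("cerebral_mask", self.cerebral_mask),
        ):
            p = out / f"{name}.nii.gz"
            write_volume(vol, p)
            paths[name] = str(p)
        p = out / "tractogram.tck"
        write_streamlines(self.streamlines, p)
        paths["tractogram"] = str(p)
        p = out / "labels.tsv"
        write_label_table(self.labels.table, p)
        paths["label_table"] = str(p)
        truth = {
            "pairs": {
                f"{k.a}-{k.b}": {"total": t, "unhealthy": u, "uwmc": self.true_uwmc.values[k]}
                for k, (t, u) in self.true_counts.counts.items()
            }
        }
        p = out / "truth.json"
        p.write_text(json.dumps(truth, indent=2))
        paths["truth"] = str(p)
        return paths


def _dense_voxels(points: np.ndarray, affine: np.ndarray, shape, step: float = 0.01):
    """Voxel set visited by a polyline, sampled at `step` mm (the oracle)."""
    inv = np.linalg.inv(affine)
    segs = np.diff(points, axis=0)
    lengths = np.linalg.norm(segs, axis=1)
    pieces = [points[:1]]
    for i, L in enumerate(lengths):
        n = max(int(np.ceil(L / step)), 1)
        t = np.arange(1, n + 1) / n
        pieces.append(points[i] + t[:, None] * segs[i])
    dense = np.vstack(pieces)
    ijk = np.rint(dense @ inv[:3, :3].T + inv[:3, 3]).astype(np.int64)
    ok = ((ijk >= 0) & (ijk < np.asarray(shape))).all(axis=1)
    return set(map(tuple, ijk[ok]))


def _make_streamline(
    rng: np.random.Generator,
    start: np.ndarray,
    end: np.ndarray,
    n_points: int = 33,
) -> np.ndarray:
    """A gently curved polyline from start to end (sinusoidal lateral bow)."""
    t = np.linspace(0.0, 1.0, n_points)
    base = start[None, :] + t[:, None] * (end - start)[None, :]
    direction = (end - start) / np.linalg.norm(end - start)
    # two perpendicular unit vectors
    helper = np.array([0.0, 0.0, 1.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, helper)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    amp_u, amp_v = rng.uniform(-1.5, 1.5, size=2)
    bow = np.sin(np.pi * t)
    return base + bow[:, None] * (amp_u * u + amp_v * v)[None, :]


def _sphere_mask(shape, affine, center_mm, radius_mm) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T
    world = idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    inside = np.linalg.norm(world - np.asarray(center_mm), axis=1) <= radius_mm
    return inside.reshape(shape)


def make_phantom(cfg: PhantomConfig) -> PhantomTruth:
    """Build a phantom whose per-pair UWMC equals each bundle's target.

    The lesion is assembled from voxels traversed by the designated
    unhealthy streamlines in their middle section, minus any voxel touched
    (at 0.01 mm sampling) by a healthy streamline or lying inside an ROI;
    the plant is then verified streamline-by-streamline, both with the
    dense-sampling oracle and with the pipeline's own exact intersection
    test, and retried with fresh curvature if infeasible.
    """
    if not cfg.regions or not cfg.bundles:
        raise ValueError("phantom needs at least one region pair and one bundle")
    shape = tuple(cfg.grid_shape)
    affine = np.diag(list(cfg.voxel_mm) + [1.0])
    region_by_id = {r.id: r for r in cfg.regions}
    for b in cfg.bundles:
        if b.pair.a not in region_by_id or b.pair.b not in region_by_id:
            raise ValueError(f"bundle pair {b.pair} references unknown region ids")

    # labels
    label_data = np.zeros(shape, dtype=np.int32)
    for r in cfg.regions:
        mask = _sphere_mask(shape, affine, r.center_mm, r.radius_mm)
        if (label_data[mask] != 0).any():
            raise ValueError(f"region {r.id} overlaps another region")
        if not mask.any():
            raise ValueError(f"region {r.id} covers no voxels")
        label_data[mask] = r.id
    table = [
        LabelRecord(r.id, f"region_{r.id}", r.lobe, r.hemisphere, r.in_abeta_set, r.in_tau_set)
        for r in cfg.regions
    ]
    labels = LabelVolume(label_data, affine, table)

    for attempt in range(cfg.max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, attempt]))
        streamlines: list[np.ndarray] = []
        crossing: list[bool] = []
        bundle_slices: list[tuple[BundleSpec, slice]] = []
        for b in cfg.bundles:
            ra = region_by_id[b.pair.a]
            rb = region_by_id[b.pair.b]
            i0 = len(streamlines)
            for j in range(b.n_streamlines):
                # endpoints strictly inside the spheres (within half the radius)
                sa = np.asarray(ra.center_mm) + rng.uniform(-0.4, 0.4, 3) * ra.radius_mm
                sb = np.asarray(rb.center_mm) + rng.uniform(-0.4, 0.4, 3) * rb.radius_mm
                streamlines.append(_make_streamline(rng, sa, sb))
                crossing.append(j < b.n_unhealthy)
            bundle_slices.append((b, slice(i0, len(streamlines))))

        # voxel sets visited by each streamline (dense oracle)
        visited = [_dense_voxels(sl, affine, shape) for sl in streamlines]
        healthy_voxels: set = set()
        for sl_voxels, is_cross in zip(visited, crossing):
            if not is_cross:
                healthy_voxels |= sl_voxels

        roi_voxels = set(map(tuple, np.argwhere(label_data != 0)))
        lesion: set = set()
        for sl, sl_voxels, is_cross in zip(streamlines, visited, crossing):
            if not is_cross:
                continue
            mid = _dense_voxels(sl[12:21], affine, shape)  # middle ~quarter
            lesion |= (mid & sl_voxels) - healthy_voxels - roi_voxels

        # verify the plant with the dense oracle and, independently, with
        # the exact traversal the pipeline itself uses
        from .connectivity import passes_through

        lesion_data = np.zeros(shape, dtype=bool)
        if lesion:
            arr = np.array(sorted(lesion))
            lesion_data[arr[:, 0], arr[:, 1], arr[:, 2]] = True
        candidate_mask = BinaryMask(lesion_data, affine)
        ok = bool(lesion) or not any(crossing)
        if ok:
            for sl, sl_voxels, is_cross in zip(streamlines, visited, crossing):
                dense_hit = bool(sl_voxels & lesion)
                exact_hit = passes_through(sl, candidate_mask)
                if dense_hit != is_cross or exact_hit != is_cross:
                    ok = False
                    break
        if ok:
            break
    else:
        raise RuntimeError(
            f"could not plant lesion matching targets after {cfg.max_retries} attempts"
        )

    lesion_mask = candidate_mask

    # FLAIR synthesis: N(0,1) background, lesion N(shift,1); cerebellar
    # reference = a corner box kept clear of regions and bundles
    flair_data = rng.standard_normal(shape)
    flair_data[lesion_data] += cfg.lesion_intensity_shift
    cereb = np.zeros(shape, dtype=bool)
    cereb[: max(shape[0] // 8, 2), : max(shape[1] // 4, 2), : max(shape[2] // 4, 2)] = True
    cereb &= ~lesion_data & (label_data == 0)
    cerebellar = BinaryMask(cereb, affine)
    cerebral = BinaryMask(~cereb, affine)
    flair = IntensityVolume(flair_data, affine)

    counts = ConnectivityCounts(
        {b.pair: (b.n_streamlines, b.n_unhealthy) for b, _ in bundle_slices}
    )
    truth_matrix = pairwise_uwmc(counts)
    return PhantomTruth(
        labels=labels,
        streamlines=StreamlineSet(streamlines),
        lesion_mask=lesion_mask,
        flair=flair,
        cerebellar_mask=cerebellar,
        cerebral_mask=cerebral,
        true_counts=counts,
        true_uwmc=truth_matrix,
        crossing=crossing,
    )


def make_intensity_phantom(
    shape=(32, 32, 32),
    lesion_fraction: float = 0.05,
    shift: float = 6.0,
    seed: int = 0,
):
    """Two-Gaussian segmentation phantom with known lesion labels.

    Normal tissue ~ N(0,1) on the cerebellar-normalised scale, lesion
    voxels ~ N(shift,1); a corner box acts as the cerebellar reference
    (drawn from the normal component).  Returns
    (flair, cerebellar_mask, cerebral_mask, truth_mask).
    """
    rng = np.random.default_rng(seed)
    affine = np.eye(4)
    cereb = np.zeros(shape, dtype=bool)
    cereb[: max(shape[0] // 8, 2), : max(shape[1] // 4, 2), : max(shape[2] // 4, 2)] = True
    cerebral = ~cereb
    n_cerebral = int(cerebral.sum())
    n_lesion = int(round(lesion_fraction * n_cerebral))
    truth = np.zeros(shape, dtype=bool)
    flat = np.flatnonzero(cerebral)
    lesion_idx = rng.choice(flat, size=n_lesion, replace=False)
    truth.flat[lesion_idx] = True
    data = rng.standard_normal(shape)
    # re-anchor to a realistic reference scale (mean 100, SD 10) so that
    # normalisation is actually exercised
    data = 100.0 + 10.0 * data
    data[truth] += shift * 10.0
    return (
        IntensityVolume(data, affine),
        BinaryMask(cereb, affine),
        BinaryMask(cerebral, affine),
        BinaryMask(truth, affine),
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def worked_example_config(seed: int = 0) -> PhantomConfig:
    """Two connected regions, four streamlines, two through the lesion."""
    return PhantomConfig(
        grid_shape=(48, 24, 24),
        voxel_mm=(1.0, 1.0, 1.0),
        regions=(
            RegionSpec(1, "frontal", "L", (8.0, 12.0, 12.0), 4.0),
            RegionSpec(2, "frontal", "R", (40.0, 12.0, 12.0), 4.0),
        ),
        bundles=(BundleSpec(PairKey(1, 2), 4, 0.5),),
        seed=seed,
    )


def multibundle_config(
    targets: Sequence[float] = (0.3, 0.0, 1.0),
    sizes: Sequence[int] = (10, 6, 8),
    seed: int = 0,
) -> PhantomConfig:
    """Three bundles between three region pairs, one lobe per pair."""
    lobes = ("frontal", "parietal", "temporal")
    regions = []
    bundles = []
    for k, (t, n) in enumerate(zip(targets, sizes)):
        y = 10.0 + 14.0 * k
        regions.append(RegionSpec(2 * k + 1, lobes[k], "L", (8.0, y, 12.0), 4.0))
        regions.append(RegionSpec(2 * k + 2, lobes[k], "R", (54.0, y, 12.0), 4.0))
        bundles.append(BundleSpec(PairKey(2 * k + 1, 2 * k + 2), n, t))
    return PhantomConfig(
        grid_shape=(64, 48, 24),
        voxel_mm=(1.0, 1.0, 1.0),
        regions=tuple(regions),
        bundles=tuple(bundles),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CohortConfig:
    """Synthetic participant-table settings.

    ``active_effects`` maps feature name -> beta, in MoCA points per unit
    log-UWMC, or per SD of log-UWMC when ``standardize_active`` is set.
    Covariate prevalences and ranges follow the study population the
    generator emulates: ages 50-89, roughly two-thirds female, half of the
    cohort in each racialized group, and right-skewed UWMC fractions
    (Beta-distributed with mass near zero).
    """

    n_participants: int = 300
    n_features: int = 50
    active_effects: Mapping[str, float] = dataclasses.field(default_factory=dict)
    standardize_active: bool = False
    covariate_effects: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"age": -0.05, "education": 0.15, "sex": 0.3}
    )
    noise_sd: float = 1.0
    intercept: float = 26.0
    uwmc_beta_a: float = 1.2
    uwmc_beta_b: float = 6.0
    group_uwmc_shift: float = 0.04
    clip_round: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_features < len(self.active_effects):
            raise ValueError("more active effects than features")


@dataclasses.dataclass
class SyntheticCohort:
    table: pd.DataFrame
    feature_names: list[str]
    true_effects: dict[str, float]  # per unit log-UWMC, post-standardisation
    config: CohortConfig


def feature_name(pair: PairKey) -> str:
    return f"uwmc_{pair.a}_{pair.b}"


def make_cohort(cfg: CohortConfig | None = None) -> SyntheticCohort:
    """Draw a synthetic cohort with known MoCA-generating parameters.

    MoCA = intercept + sum(active beta * ln(UWMC, 0 -> 0.05))
    + covariate effects + N(0, noise_sd), clipped to [0, 30] and rounded
    to integer points (disable with ``clip_round=False`` for exactness
    checks).
    """
    from .stats import log_transform

    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants

    covs = pd.DataFrame(
        {
            "age": rng.uniform(50.0, 89.0, n),
            "sex": rng.binomial(1, 0.667, n),
            "group": rng.binomial(1, 0.5, n),
            "education": np.clip(rng.normal(14.0, 2.5, n), 8, 20).round(0),
            "physical_activity": np.exp(rng.normal(2.23, 0.8, n)),
            "diabetes": rng.binomial(1, 0.17, n),
            "hypertension": rng.binomial(1, 0.38, n),
            "high_cholesterol": rng.binomial(1, 0.35, n),
            "apoe4": rng.binomial(1, 0.31, n),
        }
    )

    names = [f"uwmc_f{j}" for j in range(cfg.n_features)]
    for given in cfg.active_effects:
        if given not in names:
            raise ValueError(f"active feature {given!r} not among generated features")
    a, b = cfg.uwmc_beta_a, cfg.uwmc_beta_b
    mean0 = a / (a + b)
    conc = a + b
    mean1 = min(max(mean0 + cfg.group_uwmc_shift, 1e-3), 1 - 1e-3)
    X = np.empty((n, cfg.n_features))
    is_ba = covs["group"].to_numpy() == 1
    for j in range(cfg.n_features):
        m = np.where(is_ba, mean1, mean0)
        X[:, j] = rng.beta(m * conc, (1 - m) * conc)
    features = pd.DataFrame(X, columns=names)

    logX = log_transform(X)
    effects: dict[str, float] = {}
    lin = np.full(n, cfg.intercept, dtype=float)
    for feat, beta in cfg.active_effects.items():
        col = names.index(feat)
        scale = logX[:, col].std() if cfg.standardize_active else 1.0
        beta_unit = beta / scale if cfg.standardize_active else beta
        effects[feat] = beta_unit
        lin += beta_unit * logX[:, col]
    for cov, beta in cfg.covariate_effects.items():
        lin += beta * covs[cov].to_numpy(dtype=float)
    moca = lin + rng.normal(0.0, cfg.noise_sd, n)
    if cfg.clip_round:
        moca = np.clip(np.round(moca), 0, 30)

    # a simple global UWMC summary with the same group shift
    gm = np.where(is_ba, mean1, mean0)
    global_uwmc = rng.beta(gm * conc, (1 - gm) * conc)

    table = pd.concat(
        [covs, features], axis=1
    ).assign(moca=moca, global_uwmc=global_uwmc)
    return SyntheticCohort(
        table=table, feature_names=names, true_effects=effects, config=cfg
    )
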