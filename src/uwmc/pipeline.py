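"""End-to-end orchestration: segment -> count -> UWMC -> volumes -> analyze.

A run is a pure function of its config: per-subject inputs (NIfTI volumes,
a TCK/TRK tractogram, a label table) flow through WMH segmentation (skipped
when a precomputed mask is supplied), streamline classification and
counting, lobar/global aggregation and lesion volumetry; outputs are plain
CSV/JSON under one results directory together with a manifest logging
parameters, seeds and row counts.  Re-running with the same config
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    IntersectionConfig,
    count_connections,
    global_uwmc,
    lobar_uwmc_flagged,
    pairwise_uwmc,
)
from .io import read_label_table, read_streamlines, read_volume, write_pair_table, write_volume, check_same_grid
from .segmentation import FcmConfig, WmhThreshold, segment_wmh
from .volumes import lobar_wmh_volume

__all__ = ["SubjectSpec", "RunConfig", "run_pipeline", "load_run_config"]


@dataclasses.dataclass
class SubjectSpec:
    subject_id: str
    tractogram: str
    labels: str
    label_table: str
    wmh: str | None = None  # precomputed mask: skip segmentation
    flair: str | None = None
    cerebellar_wm: str | None = None
    cerebral_mask: str | None = None
    lobe_labels: str | None = None  # defaults to `labels`
    icv_mask: str | None = None

    def required_paths(self) -> list[str]:
        paths = [self.tractogram, self.labels, self.label_table]
        if self.wmh is not None:
            paths.append(self.wmh)
        else:
            if not (self.flair and self.cerebellar_wm and self.cerebral_mask):
                raise ValueError(
                    f"subject {self.subject_id}: need either a wmh mask or "
                    "flair + cerebellar_wm + cerebral_mask"
                )
            paths += [self.flair, self.cerebellar_wm, self.cerebral_mask]
        for opt in (self.lobe_labels, self.icv_mask):
            if opt is not None:
                paths.append(opt)
        return paths


@dataclasses.dataclass
class RunConfig:
    subjects: list[SubjectSpec]
    out_dir: str
    fcm: FcmConfig = dataclasses.field(default_factory=FcmConfig)
    threshold: WmhThreshold = dataclasses.field(default_factory=WmhThreshold)
    intersection: IntersectionConfig = dataclasses.field(default_factory=IntersectionConfig)
    fdr_q: float = 0.05
    wmh_display_multiplier: float = 1.0
    master_seed: int = 0

    def validate(self) -> None:
        if not self.subjects:
            raise ValueError("run config lists no subjects")
        missing = []
        for s in self.subjects:
            for p in s.required_paths():
                if not Path(p).exists():
                    missing.append((s.subject_id, p))
        if missing:
            lines = ", ".join(f"{sid}: {p}" for sid, p in missing)
            raise FileNotFoundError(f"missing input files — {lines}")


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    subjects = [SubjectSpec(**s) for s in raw.pop("subjects")]
    fcm = FcmConfig(**raw.pop("fcm", {}))
    thr = WmhThreshold(**raw.pop("threshold", {}))
    inter = IntersectionConfig(**raw.pop("intersection", {}))
    return RunConfig(subjects=subjects, fcm=fcm, threshold=thr, intersection=inter, **raw)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the per-subject pipeline; returns the manifest dict.

    Any stage failure aborts the run with the failing subject and stage
    named in the raised error.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "master_seed": config.master_seed,
        "parameters": {
            "fcm": dataclasses.asdict(config.fcm),
            "threshold": dataclasses.asdict(config.threshold),
            "intersection": dataclasses.asdict(config.intersection),
            "fdr_q": config.fdr_q,
        },
        "subjects": {},
        "warnings": [],
    }
    summary_rows = []
    for subject in config.subjects:
        stage = "load"
        try:
            table = read_label_table(subject.label_table)
            labels = read_volume(subject.labels, "label", label_table=table)
            streamlines = read_streamlines(subject.tractogram)

            if subject.wmh is not None:
                wmh = read_volume(subject.wmh, "mask")
                seg_info = {"source": "precomputed"}
            else:
                stage = "segment-wmh"
                flair = read_volume(subject.flair, "intensity")
                cereb = read_volume(subject.cerebellar_wm, "mask")
                cerebral = read_volume(subject.cerebral_mask, "mask")
                wmh, fcm_result = segment_wmh(
                    flair, cereb, cerebral, config.fcm, config.threshold
                )
                if not fcm_result.converged:
                    manifest["warnings"].append(
                        f"{subject.subject_id}: FCM did not converge"
                    )
                seg_info = {
                    "source": "fcm",
                    "centroids": list(fcm_result.centroids),
                    "n_iter": fcm_result.n_iter,
                    "lesion_voxels": wmh.n_true,
                }
                write_volume(wmh, out / f"{subject.subject_id}_wmh.nii.gz")
            check_same_grid(labels, wmh)

            stage = "compute-uwmc"
            counts = count_connections(streamlines, labels, wmh, config.intersection)
            matrix = pairwise_uwmc(counts)
            if matrix.zero_denominator:
                manifest["warnings"].append(
                    f"{subject.subject_id}: {len(matrix.zero_denominator)} zero-denominator pairs"
                )
            write_pair_table(matrix, out / f"{subject.subject_id}_pairs.csv", labels)
            lobar, empty_lobes = lobar_uwmc_flagged(counts, labels)
            pd.DataFrame(
                sorted(lobar.items()), columns=["lobe", "uwmc"]
            ).to_csv(out / f"{subject.subject_id}_lobar.csv", index=False)
            g = global_uwmc(counts)
            (out / f"{subject.subject_id}_global.txt").write_text(f"{g:.10g}\n")

            row = {
                "subject_id": subject.subject_id,
                "n_streamlines": len(streamlines),
                "n_pairs": len(counts.counts),
                "global_uwmc": g,
            }
            stage = "wmh-volume"
            if subject.icv_mask is not None:
                lobes = (
                    read_volume(subject.lobe_labels, "label", label_table=table)
                    if subject.lobe_labels
                    else labels
                )
                icv = read_volume(subject.icv_mask, "mask")
                vols = lobar_wmh_volume(wmh, lobes, icv, config.wmh_display_multiplier)
                pd.DataFrame(
                    [
                        (lobe, vols.per_lobe_mm3[lobe], vols.per_lobe_normalized[lobe])
                        for lobe in sorted(vols.per_lobe_mm3)
                    ],
                    columns=["lobe", "wmh_mm3", "wmh_normalized"],
                ).to_csv(out / f"{subject.subject_id}_wmh_volumes.csv", index=False)
                row["icv_mm3"] = vols.icv_mm3
            summary_rows.append(row)
            manifest["subjects"][subject.subject_id] = {
                "segmentation": seg_info,
                "n_streamlines": len(streamlines),
                "n_pairs": len(counts.counts),
                "empty_lobes": sorted(empty_lobes),
                "global_uwmc": g,
            }
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for subject {subject.subject_id!r} at stage {stage!r}: {exc}"
            ) from exc

    pd.DataFrame(summary_rows).to_csv(out / "subjects_summary.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
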