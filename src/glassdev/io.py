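"""File-based session layout: NIfTI runs and masks, events TSV, YAML metadata.

A study directory contains ``study.yaml`` plus one subdirectory per
session::

    study/
      study.yaml
      ses-000/
        session.yaml
        pinwheel_bold.nii      pinwheel_events.tsv
        run-00_bold.nii        run-00_events.tsv
        voi-V1_mask.nii        voi-V4_mask.nii  ...

Voxels are stored flattened along the first image axis (n_voxels, 1, 1,
n_volumes); masks are binary (n_voxels, 1, 1) images, one per VOI.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .stimgen import StimulusSchedule
from .synthbold import BoldRun, SyntheticSession

__all__ = [
    "write_run",
    "read_run",
    "write_session",
    "read_session",
    "write_study",
    "read_study",
    "session_dirs",
]

_AFFINE = np.eye(4)


def _safe_voi(label: str) -> str:
    return label.replace("/", "-")


def write_run(run: BoldRun, bold_path: Path, events_path: Path) -> None:
    img = nib.Nifti1Image(
        run.data[:, np.newaxis, np.newaxis, :].astype(np.float32), _AFFINE
    )
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr))
    nib.save(img, str(bold_path))
    run.schedule.to_tsv(events_path)


def read_run(
    bold_path: Path, events_path: Path, tr: float, voi_of_voxel: np.ndarray
) -> BoldRun:
    img = nib.load(str(bold_path))
    data = np.asarray(img.dataobj, dtype=float).reshape(img.shape[0], img.shape[-1])
    schedule = StimulusSchedule.from_tsv(events_path)
    return BoldRun(data=data, tr=tr, schedule=schedule, voi_of_voxel=voi_of_voxel)


def write_session(session: SyntheticSession, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = session.config
    meta = {
        "age_months": float(cfg.age),
        "tr": float(cfg.tr),
        "seed": int(cfg.seed),
        "n_runs": len(session.glass_runs),
        "voi_labels": list(cfg.voi_labels),
    }
    (out_dir / "session.yaml").write_text(yaml.safe_dump(meta))

    voi = session.pinwheel_run.voi_of_voxel
    for label in cfg.voi_labels:
        mask = (voi == label).astype(np.uint8)[:, np.newaxis, np.newaxis]
        nib.save(
            nib.Nifti1Image(mask, _AFFINE),
            str(out_dir / f"voi-{_safe_voi(label)}_mask.nii"),
        )
    write_run(
        session.pinwheel_run, out_dir / "pinwheel_bold.nii", out_dir / "pinwheel_events.tsv"
    )
    for i, run in enumerate(session.glass_runs):
        write_run(run, out_dir / f"run-{i:02d}_bold.nii", out_dir / f"run-{i:02d}_events.tsv")


def read_session(ses_dir: Path):
    """Load one session directory; returns (meta, pinwheel_run, glass_runs)."""
    ses_dir = Path(ses_dir)
    meta = yaml.safe_load((ses_dir / "session.yaml").read_text())
    tr = float(meta["tr"])
    labels = list(meta["voi_labels"])
    masks = {
        label: np.asarray(
            nib.load(str(ses_dir / f"voi-{_safe_voi(label)}_mask.nii")).dataobj
        ).reshape(-1)
        for label in labels
    }
    n_vox = next(iter(masks.values())).size
    voi_of_voxel = np.full(n_vox, "", dtype=object)
    for label, mask in masks.items():
        voi_of_voxel[mask.astype(bool)] = label
    pinwheel = read_run(
        ses_dir / "pinwheel_bold.nii", ses_dir / "pinwheel_events.tsv", tr, voi_of_voxel
    )
    glass_runs = []
    for i in range(int(meta["n_runs"])):
        glass_runs.append(
            read_run(
                ses_dir / f"run-{i:02d}_bold.nii",
                ses_dir / f"run-{i:02d}_events.tsv",
                tr,
                voi_of_voxel,
            )
        )
    return meta, pinwheel, glass_runs


def session_dirs(study_dir: Path) -> list[Path]:
    return sorted(Path(study_dir).glob("ses-*"))


def write_study(sessions: list[SyntheticSession], study_dir: Path, meta: dict | None = None) -> None:
    study_dir = Path(study_dir)
    study_dir.mkdir(parents=True, exist_ok=True)
    info = dict(meta or {})
    info["n_sessions"] = len(sessions)
    info["ages_months"] = [float(s.age) for s in sessions]
    (study_dir / "study.yaml").write_text(yaml.safe_dump(info))
    for i, session in enumerate(sessions):
        write_session(session, study_dir / f"ses-{i:03d}")


def read_study(study_dir: Path):
    """Yield (meta, pinwheel_run, glass_runs) for every session in age order."""
    return [read_session(d) for d in session_dirs(study_dir)]
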