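"""Plain-text persistence: TSV matrices/tables, JSON sidecars, NIfTI.

Time-series TSVs have ROIs as rows (first column = ROI name) and volumes
as columns; adjacency TSVs are square with node names as both header row
and first column.  All JSON writing goes through an encoder that accepts
numpy scalars and arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .netbuild import BrainGraph
from .signals import ROITimeSeries
from .synthdata import MotionTrace, SubjectRecord, TaskDesign

__all__ = [
    "write_timeseries", "read_timeseries",
    "write_motion", "read_motion",
    "write_design", "read_design",
    "write_adjacency", "read_adjacency",
    "write_cohort", "read_cohort",
    "write_json",
]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def write_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.values, index=ts.roi_names,
                      columns=[f"vol_{i:04d}" for i in ts.volume_index])
    df.index.name = "roi"
    df.to_csv(path, sep="\t")


def read_timeseries(path: str | Path, tr_s: float = 2.5) -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vol_index = np.array([int(c.split("_")[-1]) for c in df.columns])
    return ROITimeSeries(values=df.to_numpy(), roi_names=list(df.index),
                         tr_s=tr_s, volume_index=vol_index)


def write_motion(motion: MotionTrace, path: str | Path) -> None:
    pd.DataFrame({"mm_per_tr": motion.mm}).to_csv(path, sep="\t", index=False)


def read_motion(path: str | Path) -> MotionTrace:
    return MotionTrace(mm=pd.read_csv(path, sep="\t")["mm_per_tr"].to_numpy())


def write_design(design: TaskDesign, path: str | Path) -> None:
    write_json({
        "n_blocks": design.n_blocks, "task_s": design.task_s,
        "rest_s": design.rest_s, "tr_s": design.tr_s,
        "task_mask": design.task_mask.astype(int),
    }, path)


def read_design(path: str | Path) -> TaskDesign:
    d = json.loads(Path(path).read_text())
    return TaskDesign(
        n_blocks=d["n_blocks"], task_s=d["task_s"], rest_s=d["rest_s"],
        tr_s=d["tr_s"], task_mask=np.asarray(d["task_mask"], dtype=bool))


def write_adjacency(g: BrainGraph, path: str | Path) -> None:
    df = pd.DataFrame(g.adjacency, index=g.node_names, columns=g.node_names)
    df.index.name = "node"
    df.to_csv(path, sep="\t")


def read_adjacency(path: str | Path) -> BrainGraph:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return BrainGraph(adjacency=df.to_numpy(), node_names=list(df.index))


def write_cohort(records: list[SubjectRecord], design: TaskDesign,
                 out_dir: str | Path) -> Path:
    """One TSV pair per subject plus design JSON and a manifest TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        ts_path = out / f"{rec.subject_id}_timeseries.tsv"
        mot_path = out / f"{rec.subject_id}_motion.tsv"
        write_timeseries(rec.timeseries, ts_path)
        write_motion(rec.motion, mot_path)
        rows.append({"subject": rec.subject_id, "group": rec.group,
                     "timeseries": ts_path.name, "motion": mot_path.name})
    write_design(design, out / "design.json")
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    return out / "manifest.tsv"


def read_cohort(manifest_path: str | Path) -> tuple[list[SubjectRecord], TaskDesign]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    design = read_design(base / "design.json")
    records = []
    for _, row in pd.read_csv(manifest_path, sep="\t").iterrows():
        ts = read_timeseries(base / row["timeseries"], tr_s=design.tr_s)
        motion = read_motion(base / row["motion"])
        records.append(SubjectRecord(subject_id=row["subject"], group=row["group"],
                                     timeseries=ts, motion=motion))
    return records, design


def write_atlas_nifti(labels: np.ndarray, path: str | Path) -> None:
    """3-D integer label volume as NIfTI (identity affine)."""
    import nibabel as nib
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int32), np.eye(4)),
             str(path))


def write_timeseries_nifti(ts: ROITimeSeries, labels: np.ndarray,
                           path: str | Path) -> None:
    """Render ROI time series back into a 4-D volume via the label atlas.

    Every voxel of ROI r carries that ROI's signal; background stays 0.
    Intended for exercising the NIfTI extraction path, not for realism.
    """
    import nibabel as nib
    lab = np.asarray(labels)
    vol = np.zeros(lab.shape + (ts.n_volumes,), dtype=np.float32)
    for r in range(ts.n_rois):
        vol[lab == r + 1] = ts.values[r].astype(np.float32)
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))


def read_nifti(path: str | Path) -> np.ndarray:
    import nibabel as nib
    return np.asarray(nib.load(str(path)).dataobj)
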