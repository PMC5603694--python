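"""Standard-format I/O: NIfTI-1 volumes via nibabel, CSV/TSV tables.

Beta datasets round-trip as one 4-D NIfTI per subject (stimulus along
the 4th axis) plus a 3-D mask volume and a JSON sidecar naming the
stimulus rows; stimulus tables and result tables round-trip as CSV,
event designs as BIDS-style events TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datasets import BetaDataset, EventDesign, VolumeGeometry, validate_stimulus_frame


def write_stimulus_table(stimuli: pd.DataFrame, path: str | Path) -> None:
    validate_stimulus_frame(stimuli).to_csv(path, index=False)


def read_stimulus_table(path: str | Path) -> pd.DataFrame:
    return validate_stimulus_frame(pd.read_csv(path))


def write_events_tsv(design: EventDesign, path: str | Path) -> None:
    design.to_events_frame().to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path, tr_s: float = 2.0, n_volumes: int | None = None) -> EventDesign:
    df = pd.read_csv(path, sep="\t")
    onsets = df["onset"].to_numpy(dtype=float)
    durations = df["duration"].to_numpy(dtype=float)
    if n_volumes is None:
        n_volumes = int(np.ceil((onsets[-1] + durations[-1] + 10.0) / tr_s))
    return EventDesign(
        onsets_s=onsets,
        durations_s=durations,
        stim_ids=list(df["trial_type"].astype(str)),
        tr_s=tr_s,
        n_volumes=n_volumes,
    )


def write_volume(flat_map: np.ndarray, geometry: VolumeGeometry, path: str | Path) -> None:
    """Write a flat voxel map (or (n, voxels) stack) as a NIfTI volume."""
    arr = np.asarray(flat_map)
    if arr.ndim == 1:
        vol = geometry.unravel(arr).astype(np.float64)
    else:
        vol = np.stack([geometry.unravel(row) for row in arr], axis=-1).astype(np.float64)
    nib.save(nib.Nifti1Image(vol, geometry.affine), str(path))


def read_volume(path: str | Path, geometry: VolumeGeometry | None = None) -> tuple[np.ndarray, VolumeGeometry]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    grid = data.shape[:3]
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    geom = VolumeGeometry(grid_shape=grid, voxel_size_mm=vox)
    if geometry is not None:
        if grid != tuple(geometry.grid_shape) or not np.allclose(
            img.affine, geometry.affine
        ):
            raise ValueError(f"geometry mismatch reading {path}")
        geom = geometry
    if data.ndim == 3:
        return data.reshape(-1), geom
    return data.reshape(-1, data.shape[-1]).T.copy(), geom


def write_beta_dataset(data: BetaDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "grid_shape": list(data.geometry.grid_shape),
        "voxel_size_mm": list(data.geometry.voxel_size_mm),
        "subject_ids": data.subject_ids,
        "stim_ids": data.stim_ids,
    }
    (out / "dataset.json").write_text(json.dumps(meta, indent=2))
    for s, sid in enumerate(data.subject_ids):
        write_volume(data.betas[s], data.geometry, out / f"{sid}_betas.nii")
        write_volume(data.gm_masks[s].astype(float), data.geometry, out / f"{sid}_gmmask.nii")


def read_beta_dataset(in_dir: str | Path) -> BetaDataset:
    src = Path(in_dir)
    meta = json.loads((src / "dataset.json").read_text())
    geometry = VolumeGeometry(
        grid_shape=tuple(meta["grid_shape"]),
        voxel_size_mm=tuple(meta["voxel_size_mm"]),
    )
    betas, masks = [], []
    for sid in meta["subject_ids"]:
        b, _ = read_volume(src / f"{sid}_betas.nii", geometry)
        m, _ = read_volume(src / f"{sid}_gmmask.nii", geometry)
        betas.append(b)
        masks.append(m > 0.5)
    return BetaDataset(
        betas=betas,
        geometry=geometry,
        subject_ids=list(meta["subject_ids"]),
        stim_ids=[list(x) for x in meta["stim_ids"]],
        gm_masks=masks,
    )
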