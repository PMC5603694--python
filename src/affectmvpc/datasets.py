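"""Core in-memory containers shared across the pipeline.

Stimulus tables live in :class:`pandas.DataFrame` form (one row per
stimulus); voxel data live in dense :class:`numpy.ndarray` form indexed
``[subject, stimulus, voxel]`` together with a :class:`VolumeGeometry`
describing the 3-D grid so maps can be round-tripped through NIfTI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STIMULUS_COLUMNS = [
    "stim_id",
    "valence9",
    "arousal9",
    "valence5",
    "arousal5",
    "tier",
    "set",
]


@dataclass(frozen=True)
class VolumeGeometry:
    """A 3-D voxel grid with its voxel-to-mm affine."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        if any(int(s) < 1 for s in self.grid_shape):
            raise ValueError(f"grid_shape components must be >= 1, got {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def affine(self) -> np.ndarray:
        """Diagonal scaling affine (voxel indices -> mm), origin at voxel 0."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        return aff

    def unravel(self, flat: np.ndarray) -> np.ndarray:
        """Reshape a flat voxel vector to the 3-D grid."""
        return np.asarray(flat).reshape(self.grid_shape)

    def ravel(self, vol: np.ndarray) -> np.ndarray:
        vol = np.asarray(vol)
        if vol.shape != self.grid_shape:
            raise ValueError(f"volume shape {vol.shape} != grid {self.grid_shape}")
        return vol.reshape(-1)

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to mm coordinates through the affine."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homog = np.c_[ijk, np.ones(len(ijk))]
        return (homog @ self.affine.T)[:, :3]


@dataclass(frozen=True)
class EncodingSpec:
    """Planted linear affect encoding for the synthetic generator.

    ``w_valence`` / ``w_arousal`` are flat voxel maps; stimulus ratings
    enter the signal through ``g(r) = (r - 5) / 4`` so the class boundary
    at rating 5.0 is the natural zero of the planted signal.
    """

    w_valence: np.ndarray
    w_arousal: np.ndarray
    snr: float = 1.0
    noise_fwhm_mm: float = 6.0
    noise_sd: float = 1.0
    subject_offset_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.snr < 0 or self.noise_sd < 0:
            raise ValueError("snr and noise_sd must be nonnegative")
        if self.noise_fwhm_mm < 0:
            raise ValueError("noise_fwhm_mm must be nonnegative")
        if self.w_valence.size == 0 or self.w_arousal.size == 0:
            raise ValueError("encoding maps must be nonempty")
        if self.w_valence.shape != self.w_arousal.shape:
            raise ValueError("encoding maps must share a shape")


@dataclass
class BetaDataset:
    """Per-subject, per-stimulus voxel activation maps on a shared grid.

    ``betas[s]`` is an (n_stimuli_s, n_voxels) array for subject ``s``;
    ``stim_ids[s]`` names the rows.  ``gm_masks`` holds one boolean voxel
    map per subject.
    """

    betas: list[np.ndarray]
    geometry: VolumeGeometry
    subject_ids: list[str]
    stim_ids: list[list[str]]
    gm_masks: list[np.ndarray]
    encoding: EncodingSpec | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if not (len(self.betas) == len(self.stim_ids) == len(self.gm_masks) == n):
            raise ValueError("per-subject lists must have equal lengths")
        for b, ids, m in zip(self.betas, self.stim_ids, self.gm_masks):
            if b.shape != (len(ids), self.geometry.n_voxels):
                raise ValueError("beta array shape inconsistent with stim ids/geometry")
            if not np.all(np.isfinite(b)):
                raise ValueError("betas must be finite")
            if m.shape != (self.geometry.n_voxels,) or not m.any():
                raise ValueError("gm_masks must be nonempty flat voxel maps")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@dataclass(frozen=True)
class EventDesign:
    """Event-related design: trial onsets/durations on a fixed-TR scan."""

    onsets_s: np.ndarray
    durations_s: np.ndarray
    stim_ids: list[str]
    tr_s: float = 2.0
    n_volumes: int = 160

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_s, dtype=float)
        durations = np.asarray(self.durations_s, dtype=float)
        if onsets.ndim != 1 or len(onsets) == 0 or len(onsets) != len(durations):
            raise ValueError("onsets and durations must be matched nonempty 1-D arrays")
        if len(onsets) != len(self.stim_ids):
            raise ValueError("stim_ids must match onsets")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(onsets < 0) or np.any(durations <= 0):
            raise ValueError("onsets nonnegative, durations positive")
        if self.tr_s <= 0 or self.n_volumes < 1:
            raise ValueError("tr_s positive, n_volumes >= 1")
        if onsets[-1] + durations[-1] > self.tr_s * self.n_volumes:
            raise ValueError("events extend past scan end")

    @property
    def n_trials(self) -> int:
        return len(self.stim_ids)

    @property
    def scan_duration_s(self) -> float:
        return self.tr_s * self.n_volumes

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_s

    def to_events_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type)."""
        return pd.DataFrame(
            {
                "onset": np.asarray(self.onsets_s, dtype=float),
                "duration": np.asarray(self.durations_s, dtype=float),
                "trial_type": self.stim_ids,
            }
        )


def validate_stimulus_frame(stimuli: pd.DataFrame) -> pd.DataFrame:
    """Check bounds/columns of a stimulus table and return it unchanged."""
    missing = [c for c in ("stim_id", "valence9", "arousal9") if c not in stimuli]
    if missing:
        raise ValueError(f"stimulus table missing columns: {missing}")
    for col, lo, hi in (("valence9", 1, 9), ("arousal9", 1, 9), ("valence5", 1, 5), ("arousal5", 1, 5)):
        if col in stimuli and len(stimuli):
            vals = stimuli[col].to_numpy(dtype=float)
            if np.nanmin(vals) < lo or np.nanmax(vals) > hi:
                raise ValueError(f"{col} outside [{lo}, {hi}]")
    return stimuli
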