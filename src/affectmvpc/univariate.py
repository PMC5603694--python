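"""Univariate analyses: group gray-matter masks, condition and trial-wise
(least-squares-separate) GLMs, group t-maps, extent-corrected cluster
extraction, and mask relaxation by morphological dilation.

Cluster-extent correction follows the Monte-Carlo logic of classical
cluster-size simulation: smooth Gaussian null fields are generated inside
the analysis mask, thresholded voxelwise two-sidedly, and the distribution
of the maximum cluster size yields the minimum surviving cluster size at
the desired family-wise alpha.  Spatial smoothness is summarised by a
single Gaussian FWHM.  "NN = 1" connectivity means face adjacency
(6-neighbourhood) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .datasets import EventDesign, VolumeGeometry
from .synthetic import hrf_convolved_regressor, legendre_drift, smoothed_unit_noise

FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


# ---------------------------------------------------------------------------
# gray-matter masks


@dataclass(frozen=True)
class GroupGMMask:
    """Voting-rule group gray-matter mask."""

    include: np.ndarray
    threshold_fraction: float
    contributing_subjects: tuple[str, ...]


def build_group_gm_mask(
    subject_masks: list[np.ndarray],
    include_fraction: float = 0.5,
    subject_ids: list[str] | None = None,
) -> GroupGMMask:
    """Include a voxel iff >= ``include_fraction`` of subjects' masks do.

    The boundary is inclusive (a voxel hit by exactly half the subjects
    survives at fraction 0.5).  Pass any subject subset to build
    leave-one-out masks.
    """
    if len(subject_masks) == 0:
        raise ValueError("need at least one subject mask")
    masks = np.asarray(subject_masks, dtype=bool)
    if masks.ndim != 2:
        raise ValueError("subject masks must share one flat geometry")
    frac = masks.mean(axis=0)
    ids = tuple(subject_ids) if subject_ids is not None else tuple(
        f"sub-{i + 1:02d}" for i in range(len(masks))
    )
    return GroupGMMask(include=frac >= include_fraction, threshold_fraction=include_fraction, contributing_subjects=ids)


def leave_one_out_gm_masks(
    subject_masks: list[np.ndarray], include_fraction: float = 0.5
) -> list[np.ndarray]:
    """For each subject, the group mask built from the other n-1 masks."""
    n = len(subject_masks)
    if n < 2:
        raise ValueError("need >= 2 subjects for leave-one-out masks")
    out = []
    for s in range(n):
        others = [m for j, m in enumerate(subject_masks) if j != s]
        out.append(build_group_gm_mask(others, include_fraction).include)
    return out


def dilate_mask(
    mask: np.ndarray,
    n_voxels: int,
    geometry: VolumeGeometry,
    gm_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Morphological dilation by the face-connected structuring element,
    applied ``n_voxels`` times, optionally intersected with a group GM
    mask.  Accepts and returns flat voxel maps."""
    if n_voxels not in (1, 2):
        raise ValueError("n_voxels must be 1 or 2")
    vol = geometry.unravel(np.asarray(mask, dtype=bool))
    if vol.any():
        vol = ndimage.binary_dilation(vol, structure=FACE_STRUCTURE, iterations=n_voxels)
    out = geometry.ravel(vol)
    if gm_mask is not None:
        out = out & np.asarray(gm_mask, dtype=bool)
    return out


# ---------------------------------------------------------------------------
# GLMs


def _design_columns(
    design: EventDesign,
    groups: list[np.ndarray],
    hrf: str,
    drift_order: int | None,
) -> np.ndarray:
    """Stack HRF-convolved regressors (one per trial group) and Legendre
    drift columns (orders 0..drift_order; ``None`` fits no drift)."""
    frame_times = design.frame_times
    onsets = np.asarray(design.onsets_s, dtype=float)
    durations = np.asarray(design.durations_s, dtype=float)
    cols = []
    for idx in groups:
        amps = np.zeros(design.n_trials)
        amps[idx] = 1.0
        cols.append(hrf_convolved_regressor(onsets, durations, amps, frame_times, hrf))
    if drift_order is not None:
        for order in range(drift_order + 1):
            coefs = np.zeros(order + 1)
            coefs[order] = 1.0
            cols.append(legendre_drift(frame_times, coefs))
    return np.column_stack(cols)


def fit_condition_glm(
    timeseries: np.ndarray,
    design: EventDesign,
    condition_of: dict[str, str],
    hrf: str = "spm",
    drift_order: int = 2,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Ordinary-least-squares condition GLM with two condition regressors.

    ``condition_of`` maps stimulus ids to exactly two condition names
    (e.g. V_pos/V_neg).  Returns per-condition beta maps and the contrast
    (first condition minus second, in sorted-descending name order so
    V_pos - V_neg and A_high - A_low come out with conventional sign).
    """
    conditions = sorted({condition_of[s] for s in design.stim_ids}, reverse=True)
    if len(conditions) != 2:
        raise ValueError("condition GLM requires exactly 2 conditions in the design")
    groups = [
        np.array([i for i, s in enumerate(design.stim_ids) if condition_of[s] == c])
        for c in conditions
    ]
    if any(len(g) == 0 for g in groups):
        raise ValueError("each condition needs >= 1 trial")
    X = _design_columns(design, groups, hrf, drift_order)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    Y = np.asarray(timeseries, dtype=float)
    Y2 = Y[:, None] if Y.ndim == 1 else Y
    coef, *_ = np.linalg.lstsq(X, Y2, rcond=None)
    betas = {c: (coef[i, 0] if Y.ndim == 1 else coef[i]) for i, c in enumerate(conditions)}
    contrast = betas[conditions[0]] - betas[conditions[1]]
    return betas, contrast


def fit_lss_betas(
    timeseries: np.ndarray,
    design: EventDesign,
    hrf: str = "spm",
    drift_order: int = 2,
) -> np.ndarray:
    """Trial-wise betas by the least-squares-separate scheme.

    For each trial, fit one regressor for that trial and one summing all
    other trials (plus drift), and keep the target trial's coefficient.
    Returns (n_trials,) or (n_trials, n_voxels).
    """
    n = design.n_trials
    if n < 2:
        raise ValueError("LSS needs >= 2 trials")
    Y = np.asarray(timeseries, dtype=float)
    Y2 = Y[:, None] if Y.ndim == 1 else Y
    out = np.empty((n, Y2.shape[1]))
    all_idx = np.arange(n)
    for i in range(n):
        X = _design_columns(
            design, [np.array([i]), all_idx[all_idx != i]], hrf, drift_order
        )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"collinear LSS design at trial {i}")
        coef, *_ = np.linalg.lstsq(X, Y2, rcond=None)
        out[i] = coef[0]
    return out[:, 0] if Y.ndim == 1 else out


# ---------------------------------------------------------------------------
# group statistics


@dataclass(frozen=True)
class TMap:
    """Voxelwise one-sample t statistics with degeneracy flags."""

    t: np.ndarray
    df: int
    contrast_name: str = ""
    degenerate: np.ndarray = field(default=None)  # zero-variance voxels


def group_ttest_map(contrast_maps: np.ndarray, contrast_name: str = "") -> TMap:
    """One-sample t-test across subjects at every voxel.

    ``contrast_maps`` is (n_subjects, n_voxels).  Zero-variance voxels are
    flagged in ``degenerate`` and assigned t = 0 rather than +/-inf.
    """
    maps = np.asarray(contrast_maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2:
        raise ValueError("need (n_subjects >= 2, n_voxels) contrast maps")
    if not np.all(np.isfinite(maps)):
        raise ValueError("contrast maps contain non-finite values")
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    # zero variance up to roundoff relative to the signal magnitude
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    t = np.zeros(maps.shape[1])
    ok = ~degenerate
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    return TMap(t=t, df=n - 1, contrast_name=contrast_name, degenerate=degenerate)


def critical_t(df: int, p_two_tailed: float) -> float:
    """Two-tailed critical value: c with P(|T_df| >= c) = p."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < p_two_tailed < 1:
        raise ValueError("p must be in (0, 1)")
    return float(stats.t.ppf(1.0 - p_two_tailed / 2.0, df))


# ---------------------------------------------------------------------------
# cluster extent correction


def estimate_min_cluster_size(
    geometry: VolumeGeometry,
    noise_fwhm_mm: float,
    mask: np.ndarray,
    p_voxel: float = 0.001,
    alpha: float = 0.05,
    n_iter: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo minimum cluster size at family-wise ``alpha``.

    Simulates smooth Gaussian null fields inside the mask, thresholds
    two-sidedly at voxelwise ``p_voxel``, clusters each sign separately
    under face connectivity, records the maximum cluster size per
    iteration, and returns the (1 - alpha) quantile (linear interpolation,
    hence possibly fractional).  A cluster survives iff size >= k_min.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    rng = np.random.default_rng(seed)
    zcrit = stats.norm.ppf(1.0 - p_voxel / 2.0)
    mask_vol = geometry.unravel(mask)
    max_sizes = np.empty(n_iter)
    for it in range(n_iter):
        flat = smoothed_unit_noise((), geometry, noise_fwhm_mm, rng)
        # standardise within the mask so p_voxel is honoured exactly
        vals = flat[mask.reshape(-1)]
        flat = (flat - vals.mean()) / vals.std()
        vol = geometry.unravel(flat)
        best = 0
        for supra in (vol >= zcrit, vol <= -zcrit):
            labeled, n_comp = ndimage.label(supra & mask_vol, structure=FACE_STRUCTURE)
            if n_comp:
                best = max(best, int(np.bincount(labeled.reshape(-1))[1:].max()))
        max_sizes[it] = best
    return float(np.quantile(max_sizes, 1.0 - alpha))


@dataclass(frozen=True)
class Cluster:
    cluster_id: int
    size: int
    sign: int  # +1 or -1
    center_of_mass_mm: tuple[float, float, float]
    mean_abs_t: float


@dataclass(frozen=True)
class ClusterSet:
    """Labelled suprathreshold clusters (0 = background), sorted by size."""

    labels: np.ndarray  # flat integer voxel map
    clusters: tuple[Cluster, ...]
    geometry: VolumeGeometry

    def __len__(self) -> int:
        return len(self.clusters)

    def mask(self, cluster_id: int | None = None) -> np.ndarray:
        """Flat boolean mask of one cluster (or all clusters)."""
        return self.labels > 0 if cluster_id is None else self.labels == cluster_id

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": [c.cluster_id for c in self.clusters],
                "size": [c.size for c in self.clusters],
                "sign": ["+" if c.sign > 0 else "-" for c in self.clusters],
                "com_x": [c.center_of_mass_mm[0] for c in self.clusters],
                "com_y": [c.center_of_mass_mm[1] for c in self.clusters],
                "com_z": [c.center_of_mass_mm[2] for c in self.clusters],
                "mean_abs_t": [c.mean_abs_t for c in self.clusters],
            }
        )


def extract_clusters(
    tmap: TMap,
    t_thresh: float,
    k_min: float,
    geometry: VolumeGeometry,
    mask: np.ndarray | None = None,
) -> ClusterSet:
    """Extent-thresholded clusters of the |t| >= t_thresh voxels.

    Positive and negative suprathreshold voxels are clustered separately
    (sign-pure clusters) under face connectivity; components smaller than
    ceil(k_min) are discarded.  Centers of mass are unweighted means of
    member-voxel mm coordinates.
    """
    if t_thresh <= 0:
        raise ValueError("t_thresh must be positive")
    t = np.asarray(tmap.t, dtype=float)
    if mask is not None:
        t = np.where(np.asarray(mask, dtype=bool), t, 0.0)
    vol = geometry.unravel(t)
    k_int = int(np.ceil(k_min))

    found: list[tuple[int, np.ndarray]] = []  # (sign, member flat indices)
    for sign, supra in ((1, vol >= t_thresh), (-1, vol <= -t_thresh)):
        labeled, n_comp = ndimage.label(supra, structure=FACE_STRUCTURE)
        for comp in range(1, n_comp + 1):
            members = np.flatnonzero(labeled.reshape(-1) == comp)
            if len(members) >= k_int:
                found.append((sign, members))

    # sort descending by size; ties by mean |t| then discovery order
    found.sort(key=lambda sm: (-len(sm[1]), -np.abs(t[sm[1]]).mean()))
    labels = np.zeros(geometry.n_voxels, dtype=int)
    clusters = []
    for cid, (sign, members) in enumerate(found, start=1):
        labels[members] = cid
        ijk = np.column_stack(np.unravel_index(members, geometry.grid_shape))
        com = geometry.voxel_to_mm(ijk).mean(axis=0)
        clusters.append(
            Cluster(
                cluster_id=cid,
                size=len(members),
                sign=sign,
                center_of_mass_mm=tuple(float(x) for x in com),
                mean_abs_t=float(np.abs(t[members]).mean()),
            )
        )
    return ClusterSet(labels=labels, clusters=tuple(clusters), geometry=geometry)


# ---------------------------------------------------------------------------
# beta-series validation


def select_validation_voxels(
    tmap: TMap, t_thresh: float, loocv_gm_masks: list[np.ndarray]
) -> np.ndarray:
    """Voxels with group |t| above threshold that appear in every
    leave-one-out gray-matter mask."""
    sel = np.abs(tmap.t) > t_thresh
    for m in loocv_gm_masks:
        sel &= np.asarray(m, dtype=bool)
    return sel


def validate_betaseries(
    betaseries_contrasts: np.ndarray,
    glm_contrasts: np.ndarray,
    voxel_selection: np.ndarray,
) -> tuple[float, float]:
    """Correlate mean beta-series class contrasts with mean GLM contrasts.

    Both inputs are (n_subjects, n_voxels); maps are averaged over
    subjects and correlated (Pearson) over the selected voxels.
    Returns (r, p).
    """
    sel = np.asarray(voxel_selection, dtype=bool)
    if sel.sum() < 3:
        raise ValueError("voxel selection must keep >= 3 voxels")
    a = np.asarray(betaseries_contrasts, dtype=float).mean(axis=0)[sel]
    b = np.asarray(glm_contrasts, dtype=float).mean(axis=0)[sel]
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def betaseries_class_contrast(
    betas: np.ndarray, labels_pm1: np.ndarray
) -> np.ndarray:
    """Mean beta map of the +1 class minus the -1 class."""
    betas = np.asarray(betas, dtype=float)
    pos, neg = labels_pm1 > 0, labels_pm1 < 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    return betas[pos].mean(axis=0) - betas[neg].mean(axis=0)
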