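"""Synthetic data generation for the affect-decoding pipeline.

The generator emulates the structure of an event-related picture-viewing
experiment: a stimulus set spanning the 9-point valence/arousal plane in
positive/neutral/negative tiers, per-subject trial-wise activation maps
("brain states") carrying a planted linear affect encoding at controllable
SNR, per-subject gray-matter masks perturbed from a common template, and
optionally event-related BOLD timeseries with jittered inter-trial
intervals for validating trial-wise beta estimation.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .datasets import (
    BetaDataset,
    EncodingSpec,
    EventDesign,
    VolumeGeometry,
    validate_stimulus_frame,
)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Tier-specific valence ranges jointly spanning the full 9-point scale.
_TIER_VALENCE_RANGES = {
    "negative": (1.0, 11.0 / 3.0),
    "neutral": (11.0 / 3.0, 19.0 / 3.0),
    "positive": (19.0 / 3.0, 9.0),
}
_TIERS = ("positive", "neutral", "negative")


def _tier_counts(n_stim: int, tier_fractions: tuple[float, float, float]) -> dict[str, int]:
    fracs = np.asarray(tier_fractions, dtype=float)
    if fracs.shape != (3,) or np.any(fracs < 0) or not np.isclose(fracs.sum(), 1.0):
        raise ValueError("tier_fractions must be 3 nonnegative values summing to 1")
    raw = fracs * n_stim
    counts = np.floor(raw).astype(int)
    # largest-remainder rounding so counts sum exactly to n_stim
    remainder_order = np.argsort(-(raw - counts))
    for i in range(n_stim - counts.sum()):
        counts[remainder_order[i % 3]] += 1
    return dict(zip(_TIERS, counts))


def generate_stimulus_set(
    n_stim: int = 88,
    tier_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    rating_bias: tuple[float, float] = (1.0, 0.0),
    rating_noise_sd: float = 0.25,
    arousal_valence_corr: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a stimulus table with 9-point and derived 5-point ratings.

    Valence is sampled uniformly within tier-specific ranges (negative /
    neutral / positive thirds of [1, 9]).  Arousal is sampled on
    [2.0, 7.5] with optional correlation ``arousal_valence_corr`` to the
    centred valence.  The 5-point ratings emulate an independent small
    rater sample: the exact linear rescaling of the 9-point rating passed
    through a latent linear bias ``rating_bias = (slope, intercept)``
    plus Gaussian noise, clipped to [1, 5].

    Returns a DataFrame with columns ``stim_id, valence9, arousal9,
    valence5, arousal5, tier, set``; stimuli are split into two
    counterbalanced sets A/B with equal tier composition.
    """
    if n_stim < 2:
        raise ValueError("n_stim must be >= 2")
    rng = np.random.default_rng(seed)
    counts = _tier_counts(n_stim, tier_fractions)

    rows: list[dict] = []
    for tier in _TIERS:
        lo, hi = _TIER_VALENCE_RANGES[tier]
        v = rng.uniform(lo, hi, size=counts[tier])
        rows.extend({"tier": tier, "valence9": float(x)} for x in v)
    df = pd.DataFrame(rows)

    rho = float(np.clip(arousal_valence_corr, -1.0, 1.0))
    v_centred = (df["valence9"].to_numpy() - 5.0) / 4.0  # in [-1, 1]
    u = rng.uniform(-1.0, 1.0, size=len(df))
    df["arousal9"] = np.clip(
        4.75 + 2.75 * (rho * v_centred + np.sqrt(1.0 - rho**2) * u), 1.0, 9.0
    )

    slope, intercept = rating_bias
    for dim in ("valence", "arousal"):
        exact5 = (df[f"{dim}9"].to_numpy() + 1.0) / 2.0  # [1,9] -> [1,5]
        noise = rng.normal(0.0, rating_noise_sd, size=len(df)) if rating_noise_sd > 0 else 0.0
        df[f"{dim}5"] = np.clip(slope * exact5 + intercept + noise, 1.0, 5.0)

    # counterbalanced sets: alternate A/B within each tier
    df = df.sort_values(["tier", "valence9"], kind="stable").reset_index(drop=True)
    df["set"] = [("A", "B")[i % 2] for tier in df["tier"].unique() for i in range(int((df["tier"] == tier).sum()))]
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    df["stim_id"] = [f"stim{idx:03d}" for idx in range(len(df))]
    df = df[["stim_id", "valence9", "arousal9", "valence5", "arousal5", "tier", "set"]]
    return validate_stimulus_frame(df)


def _smoothing_sigma_vox(fwhm_mm: float, geometry: VolumeGeometry) -> np.ndarray:
    return fwhm_mm * _FWHM_TO_SIGMA / np.asarray(geometry.voxel_size_mm)


def _kernel_l2_norm(sigma_vox: np.ndarray) -> float:
    """L2 norm of the discrete Gaussian kernel (impulse response)."""
    half = np.maximum(np.ceil(4 * sigma_vox).astype(int), 1)
    shape = tuple(2 * half + 1)
    impulse = np.zeros(shape)
    impulse[tuple(half)] = 1.0
    k = ndimage.gaussian_filter(impulse, sigma=sigma_vox)
    return float(np.sqrt(np.sum(k**2)))


def smoothed_unit_noise(
    shape: tuple[int, ...],
    geometry: VolumeGeometry,
    fwhm_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """White Gaussian noise smoothed to ``fwhm_mm`` and renormalised to
    approximately unit voxelwise variance.

    ``shape`` is a leading batch shape; each batch entry is an independent
    field on the geometry's grid, returned flattened to voxels.
    """
    full = rng.standard_normal(shape + geometry.grid_shape)
    if fwhm_mm > 0:
        sigma = _smoothing_sigma_vox(fwhm_mm, geometry)
        norm = _kernel_l2_norm(sigma)
        out = np.empty_like(full)
        for idx in np.ndindex(shape):
            out[idx] = ndimage.gaussian_filter(full[idx], sigma=sigma) / norm
        full = out
    return full.reshape(shape + (geometry.n_voxels,))


def _blob_support(
    geometry: VolumeGeometry,
    n_voxels: int,
    rng: np.random.Generator,
    exclude: np.ndarray | None = None,
    n_blobs: int = 3,
) -> np.ndarray:
    """Flat boolean support of ~``n_voxels`` voxels from spherical blobs
    around random centers, avoiding ``exclude``."""
    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in geometry.grid_shape], indexing="ij"), axis=-1
    ).reshape(-1, 3).astype(float) * np.asarray(geometry.voxel_size_mm)
    support = np.zeros(geometry.n_voxels, dtype=bool)
    excluded = np.zeros(geometry.n_voxels, dtype=bool) if exclude is None else np.asarray(exclude, bool)
    vox_volume = float(np.prod(geometry.voxel_size_mm))
    radius = ((3.0 * n_voxels * vox_volume) / (4.0 * np.pi * n_blobs)) ** (1.0 / 3.0)
    free = np.flatnonzero(~excluded)
    for _ in range(n_blobs):
        center = grid[rng.choice(free)]
        ball = np.linalg.norm(grid - center, axis=1) <= radius
        support |= ball & ~excluded
    if not support.any():
        support[free[0]] = True
    return support


def random_encoding_spec(
    geometry: VolumeGeometry,
    snr: float = 1.0,
    noise_fwhm_mm: float = 6.0,
    noise_sd: float = 1.0,
    subject_offset_sd: float = 0.3,
    signal_fraction: float = 0.1,
    pattern_fwhm_mm: float = 9.0,
    seed: int = 0,
) -> EncodingSpec:
    """Draw a planted encoding: two disjoint sets of smooth signal blobs.

    Each dimension's weight map lives on its own set of spherical blobs
    covering ``signal_fraction`` of the grid (disjoint between valence
    and arousal so "signal-free" voxels exist), weighted by a smoothed
    Gaussian field and rescaled to unit maximum absolute weight.  The
    contiguous supports make the planted signal clusterable, mirroring
    focal activations.
    """
    rng = np.random.default_rng(seed)
    n_vox = geometry.n_voxels
    n_sig = max(1, int(round(signal_fraction * n_vox)))
    val_support = _blob_support(geometry, n_sig, rng, exclude=None)
    aro_support = _blob_support(geometry, n_sig, rng, exclude=val_support)
    maps = {}
    for dim, support in (("valence", val_support), ("arousal", aro_support)):
        field = smoothed_unit_noise((), geometry, pattern_fwhm_mm, rng)
        w = np.where(support, field, 0.0)
        maxabs = np.max(np.abs(w))
        maps[dim] = w / maxabs if maxabs > 0 else w
    return EncodingSpec(
        w_valence=maps["valence"],
        w_arousal=maps["arousal"],
        snr=snr,
        noise_fwhm_mm=noise_fwhm_mm,
        noise_sd=noise_sd,
        subject_offset_sd=subject_offset_sd,
    )


def generate_gm_masks(
    n_subjects: int,
    geometry: VolumeGeometry,
    template_fraction: float = 0.75,
    flip_rate: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject gray-matter masks as voxel flips of a common template.

    The template includes the ``template_fraction`` of voxels with the
    largest values of a smooth random field (a contiguous, brain-like
    blob).  Each subject's mask flips template voxels independently with
    probability ``flip_rate``.

    Returns ``(template, masks)`` with ``masks`` of shape
    (n_subjects, n_voxels), both boolean.
    """
    if not 0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    field = smoothed_unit_noise((), geometry, 3.0 * max(geometry.voxel_size_mm), rng)
    cutoff = np.quantile(field, 1.0 - template_fraction)
    template = field >= cutoff
    flips = rng.random((n_subjects, geometry.n_voxels)) < flip_rate
    masks = template[None, :] ^ flips
    # never hand a subject an empty mask
    for m in masks:
        if not m.any():
            m[int(np.argmax(field))] = True
    return template, masks


def g_center(rating: np.ndarray | float) -> np.ndarray | float:
    """Center a 9-point rating at the class threshold: (rating - 5) / 4."""
    return (np.asarray(rating, dtype=float) - 5.0) / 4.0


def generate_subject_betas(
    stimuli: pd.DataFrame,
    n_subjects: int,
    geometry: VolumeGeometry,
    encoding: EncodingSpec,
    stimuli_per_subject: int | None = None,
    gm_template_fraction: float = 0.75,
    gm_flip_rate: float = 0.05,
    seed: int = 0,
) -> BetaDataset:
    """Generate per-subject trial-wise activation maps with planted signal.

    For subject ``s`` and stimulus ``i``::

        beta[s, i] = snr * (w_valence * g(V_i) + w_arousal * g(A_i))
                     + offset[s] + noise[s, i]

    where ``g`` centres ratings at the 5.0 class threshold, ``offset[s]``
    is a smooth subject-specific map (sd ``subject_offset_sd``) constant
    over stimuli, and ``noise`` is unit-variance Gaussian noise smoothed
    to ``noise_fwhm_mm``.  Odd-numbered subjects view stimulus set A,
    even-numbered set B (counterbalanced); within the assigned set the
    first ``stimuli_per_subject`` stimuli by id are used.
    """
    validate_stimulus_frame(stimuli)
    if geometry.n_voxels == 0:
        raise ValueError("zero-size grid")
    if encoding.w_valence.shape != (geometry.n_voxels,):
        raise ValueError("encoding maps must be flat maps on the full grid")
    rng = np.random.default_rng(seed)

    _, gm_masks = generate_gm_masks(
        n_subjects,
        geometry,
        template_fraction=gm_template_fraction,
        flip_rate=gm_flip_rate,
        seed=int(rng.integers(2**31)),
    )

    betas: list[np.ndarray] = []
    stim_ids: list[list[str]] = []
    subject_ids: list[str] = []
    for s in range(n_subjects):
        subject_ids.append(f"sub-{s + 1:02d}")
        assigned = "A" if (s + 1) % 2 == 1 else "B"
        subset = stimuli[stimuli["set"] == assigned].sort_values("stim_id")
        if stimuli_per_subject is not None:
            if stimuli_per_subject > len(stimuli):
                raise ValueError("stimuli_per_subject exceeds stimulus set size")
            subset = subset.iloc[:stimuli_per_subject]
        n_s = len(subset)
        gv = g_center(subset["valence9"].to_numpy())
        ga = g_center(subset["arousal9"].to_numpy())
        signal = encoding.snr * (np.outer(gv, encoding.w_valence) + np.outer(ga, encoding.w_arousal))
        offset = encoding.subject_offset_sd * smoothed_unit_noise(
            (), geometry, encoding.noise_fwhm_mm, rng
        )
        noise = encoding.noise_sd * smoothed_unit_noise((n_s,), geometry, encoding.noise_fwhm_mm, rng)
        betas.append(signal + offset[None, :] + noise)
        stim_ids.append(list(subset["stim_id"]))

    return BetaDataset(
        betas=betas,
        geometry=geometry,
        subject_ids=subject_ids,
        stim_ids=stim_ids,
        gm_masks=list(gm_masks),
        encoding=encoding,
    )


def generate_event_design(
    stim_ids: list[str],
    duration_s: float = 2.5,
    iti_bounds_s: tuple[float, float] = (2.0, 6.0),
    tr_s: float = 2.0,
    initial_rest_s: float = 4.0,
    final_rest_s: float = 10.0,
    seed: int = 0,
) -> EventDesign:
    """Jittered event-related design: fixed-duration trials, uniform ITIs."""
    rng = np.random.default_rng(seed)
    itis = rng.uniform(*iti_bounds_s, size=len(stim_ids))
    onsets = initial_rest_s + np.concatenate(
        [[0.0], np.cumsum(duration_s + itis[:-1])]
    )
    scan_len = onsets[-1] + duration_s + final_rest_s
    n_volumes = int(np.ceil(scan_len / tr_s))
    return EventDesign(
        onsets_s=onsets,
        durations_s=np.full(len(stim_ids), duration_s),
        stim_ids=list(stim_ids),
        tr_s=tr_s,
        n_volumes=n_volumes,
    )


def hrf_convolved_regressor(
    onsets_s: np.ndarray,
    durations_s: np.ndarray,
    amplitudes: np.ndarray,
    frame_times: np.ndarray,
    hrf: str = "spm",
) -> np.ndarray:
    """Amplitude-weighted boxcar convolved with a canonical double-gamma
    HRF (6 s peak, 16 s undershoot, 1:6 undershoot ratio), sampled at the
    scan frame times."""
    from nilearn.glm.first_level import compute_regressor

    exp_condition = np.vstack([onsets_s, durations_s, amplitudes])
    reg, _ = compute_regressor(exp_condition, hrf, frame_times, oversampling=50)
    return reg[:, 0]


def legendre_drift(frame_times: np.ndarray, coefs: np.ndarray | None) -> np.ndarray:
    """Polynomial drift as a Legendre expansion on the scan interval."""
    if coefs is None or len(np.atleast_1d(coefs)) == 0:
        return np.zeros_like(frame_times, dtype=float)
    x = 2.0 * frame_times / frame_times[-1] - 1.0 if len(frame_times) > 1 else np.zeros_like(frame_times)
    return np.polynomial.legendre.legval(x, np.atleast_1d(coefs))


def generate_event_timeseries(
    design: EventDesign,
    trial_betas: np.ndarray,
    hrf: str = "spm",
    drift_coefs: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a BOLD timeseries from per-trial amplitudes.

    ``trial_betas`` may be (n_trials,) for a single series or
    (n_trials, n_voxels) for voxelwise series; the output is
    (n_volumes,) or (n_volumes, n_voxels) accordingly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    trial_betas = np.asarray(trial_betas, dtype=float)
    if trial_betas.shape[0] != design.n_trials:
        raise ValueError("trial_betas length must equal the number of trials")
    rng = np.random.default_rng(seed)
    frame_times = design.frame_times
    onsets = np.asarray(design.onsets_s, dtype=float)
    durations = np.asarray(design.durations_s, dtype=float)

    scalar = trial_betas.ndim == 1
    amps = trial_betas[:, None] if scalar else trial_betas
    out = np.empty((design.n_volumes, amps.shape[1]))
    for v in range(amps.shape[1]):
        out[:, v] = hrf_convolved_regressor(onsets, durations, amps[:, v], frame_times, hrf)
    out += legendre_drift(frame_times, drift_coefs)[:, None]
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=out.shape)
    return out[:, 0] if scalar else out
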