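"""Chance-level calibration studies on label-free synthetic data.

When the planted encoding SNR is zero the voxel features carry no label
information, so the class-balanced inter-subject LOOCV must average 0.50
accuracy and the per-stimulus joint valence-arousal classification
probability must average 0.25 (0.5 x 0.5).  These routines run that null
experiment end to end — generation, binarization, cross-validation for
both affect dimensions, joint misclassification — and are reused by the
acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import interpretation, mvpc, synthetic
from .datasets import VolumeGeometry
from .labels import binarize_labels


def null_calibration_run(
    seed: int,
    n_subjects: int = 16,
    n_stimuli: int = 88,
    stimuli_per_subject: int = 44,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    noise_fwhm_mm: float = 6.0,
) -> dict:
    """One snr = 0 simulation with whole-brain LOOCV for both dimensions.

    Returns the group mean accuracy and t-test p-value per dimension and
    the across-stimuli mean joint classification probability under both
    product conventions (error rates and correct rates).
    """
    geometry = VolumeGeometry(grid_shape)
    rng = np.random.default_rng(seed)
    stim_seed, enc_seed, beta_seed = (int(x) for x in rng.integers(2**31, size=3))
    stimuli = synthetic.generate_stimulus_set(n_stim=n_stimuli, seed=stim_seed)
    labels = binarize_labels(stimuli)
    encoding = synthetic.random_encoding_spec(
        geometry, snr=0.0, noise_fwhm_mm=noise_fwhm_mm, seed=enc_seed
    )
    data = synthetic.generate_subject_betas(
        stimuli,
        n_subjects=n_subjects,
        geometry=geometry,
        encoding=encoding,
        stimuli_per_subject=stimuli_per_subject,
        seed=beta_seed,
    )
    perf = {
        target: mvpc.intersubject_loocv(data, labels, target=target)
        for target in ("valence", "arousal")
    }
    joint_err = interpretation.joint_misclassification(
        perf["valence"].folds, perf["arousal"].folds, mode="error"
    )
    joint_cor = interpretation.joint_misclassification(
        perf["valence"].folds, perf["arousal"].folds, mode="correct"
    )
    return {
        "seed": seed,
        "mean_accuracy_valence": perf["valence"].mean_accuracy,
        "p_value_valence": perf["valence"].p_value,
        "mean_accuracy_arousal": perf["arousal"].mean_accuracy,
        "p_value_arousal": perf["arousal"].p_value,
        "mean_p_joint_error": float(joint_err["p_joint"].mean()),
        "mean_p_joint_correct": float(joint_cor["p_joint"].mean()),
    }


def null_calibration_study(
    n_seeds: int = 20,
    base_seed: int = 1,
    **run_kwargs,
) -> pd.DataFrame:
    """Repeat the null run over ``n_seeds`` derived seeds."""
    seeds = np.random.SeedSequence(base_seed).generate_state(n_seeds) % (2**31)
    return pd.DataFrame([null_calibration_run(int(s), **run_kwargs) for s in seeds])


def signal_recovery_run(
    seed: int,
    snr: float = 6.0,
    n_subjects: int = 16,
    n_stimuli: int = 88,
    stimuli_per_subject: int = 44,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
) -> dict:
    """High-SNR run probing where the decodable signal lives.

    Runs whole-brain LOOCV, then restricts features to the planted
    valence-signal voxels and to signal-free voxels (no planted valence
    or arousal weight), and correlates the group decoder's forward
    encoding pattern with the planted valence pattern.
    """
    geometry = VolumeGeometry(grid_shape)
    rng = np.random.default_rng(seed)
    stim_seed, enc_seed, beta_seed = (int(x) for x in rng.integers(2**31, size=3))
    stimuli = synthetic.generate_stimulus_set(n_stim=n_stimuli, seed=stim_seed)
    labels = binarize_labels(stimuli)
    encoding = synthetic.random_encoding_spec(geometry, snr=snr, seed=enc_seed)
    data = synthetic.generate_subject_betas(
        stimuli,
        n_subjects=n_subjects,
        geometry=geometry,
        encoding=encoding,
        stimuli_per_subject=stimuli_per_subject,
        seed=beta_seed,
    )
    signal_mask = encoding.w_valence != 0
    empty_mask = (encoding.w_valence == 0) & (encoding.w_arousal == 0)

    acc = {}
    for name, fmask in (
        ("wholebrain", None),
        ("signal_voxels", signal_mask),
        ("signal_free_voxels", empty_mask),
    ):
        acc[name] = mvpc.intersubject_loocv(
            data, labels, target="valence", feature_mask=fmask
        ).mean_accuracy

    w, _, X, gmask = mvpc.fit_group_svm(data, labels, target="valence")
    emap = interpretation.decoder_to_encoder(X, w)
    r_encoding, _ = interpretation.correlate_maps(emap.a, encoding.w_valence[gmask])
    return {
        "seed": seed,
        "snr": snr,
        "accuracy_wholebrain": acc["wholebrain"],
        "accuracy_signal_voxels": acc["signal_voxels"],
        "accuracy_signal_free_voxels": acc["signal_free_voxels"],
        "encoding_correlation_with_planted": float(r_encoding),
    }
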