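"""Model-object front end to the decoding pipeline.

:class:`AffectDecoder` bundles a :class:`~affectmvpc.datasets.BetaDataset`
with binarized affect labels and a classifier specification; ``fit()``
runs the class-balanced cross-validation and returns an
:class:`AffectDecoderResults` carrying per-subject accuracies, their
uncertainty, fold-level predictions, and interpretation helpers.
:class:`MisclassificationGP` models joint misclassification over the
valence-arousal plane and exposes the predicted surface from its results
object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import interpretation, mvpc
from .datasets import BetaDataset
from .labels import binarize_labels, label_vector
from .mvpc import ClassifierSpec, GroupPerformance


class AffectDecoder:
    """Linear-SVM decoder of a binary affect dimension from brain states.

    Parameters
    ----------
    data : BetaDataset
        Per-subject, per-stimulus activation maps with gray-matter masks.
    stimuli : DataFrame
        Stimulus table with 9-point ratings; labels are binarized at
        ``threshold`` unless class columns are already present.
    target : {"valence", "arousal", "selfreport"}
    feature_mask : flat boolean map, optional
        ROI restriction intersected with the per-fold gray-matter mask.
    """

    def __init__(
        self,
        data: BetaDataset,
        stimuli: pd.DataFrame,
        target: str = "valence",
        feature_mask: np.ndarray | None = None,
        classifier: ClassifierSpec = ClassifierSpec(),
        threshold: float = 5.0,
        gm_fraction: float = 0.5,
    ):
        self.data = data
        self.labels = (
            stimuli
            if {"valence_class", "arousal_class"} <= set(stimuli.columns)
            else binarize_labels(stimuli, threshold=threshold)
        )
        self.target = target
        self.feature_mask = feature_mask
        self.classifier = classifier
        self.gm_fraction = gm_fraction

    def fit(self, mode: str = "inter") -> "AffectDecoderResults":
        """Run leave-one-out cross-validation (``mode='inter'`` subject-
        wise, ``mode='intra'`` stimulus-wise within subjects)."""
        if mode == "inter":
            perf = mvpc.intersubject_loocv(
                self.data,
                self.labels,
                target=self.target,
                feature_mask=self.feature_mask,
                spec=self.classifier,
                gm_fraction=self.gm_fraction,
            )
        elif mode == "intra":
            from .univariate import leave_one_out_gm_masks

            loo = leave_one_out_gm_masks(self.data.gm_masks, self.gm_fraction)
            accs = []
            for s in range(self.data.n_subjects):
                order = np.argsort(np.asarray(self.data.stim_ids[s]))
                ids = [self.data.stim_ids[s][i] for i in order]
                y = label_vector(self.labels, self.target, ids)
                mask = loo[s]
                if self.feature_mask is not None:
                    mask = mask & np.asarray(self.feature_mask, dtype=bool)
                accs.append(
                    mvpc.intrasubject_loocv(
                        self.data.betas[s][order], y, mask, self.classifier
                    )
                )
            perf = mvpc.summarize_performance(np.asarray(accs), 0.5, ())
        else:
            raise ValueError("mode must be 'inter' or 'intra'")
        return AffectDecoderResults(model=self, mode=mode, performance=perf)


@dataclass
class AffectDecoderResults:
    """Cross-validated decoding results with group statistics."""

    model: AffectDecoder
    mode: str
    performance: GroupPerformance
    _group_fit: tuple | None = field(default=None, repr=False)

    @property
    def per_subject_accuracy(self) -> np.ndarray:
        return self.performance.per_subject_accuracy

    @property
    def mean_accuracy(self) -> float:
        return self.performance.mean_accuracy

    @property
    def conf_int(self) -> tuple[float, float]:
        return self.performance.ci95

    @property
    def folds(self):
        return self.performance.folds

    def _ensure_group_fit(self):
        if self._group_fit is None:
            self._group_fit = mvpc.fit_group_svm(
                self.model.data,
                self.model.labels,
                target=self.model.target,
                feature_mask=self.model.feature_mask,
                spec=self.model.classifier,
                gm_fraction=self.model.gm_fraction,
            )
        return self._group_fit

    def encoding_map(self) -> tuple[interpretation.EncodingMap, np.ndarray]:
        """Forward encoding pattern of a decoder trained on all subjects;
        returns (map, feature mask it is defined on)."""
        w, _, X, mask = self._ensure_group_fit()
        return interpretation.decoder_to_encoder(X, w, source_fold="all-subjects"), mask

    def affect_projection(self) -> interpretation.AffectProjection:
        return interpretation.hyperplane_affect_projection(
            self.folds, self.model.labels, target=self.model.target
        )

    def summary(self) -> str:
        p = self.performance
        lines = [
            f"AffectDecoder results ({self.mode}-subject LOOCV, target={self.model.target})",
            "=" * 64,
            f"subjects: {len(p.per_subject_accuracy):>4d}    classifier: linear SVM"
            f" (C={self.model.classifier.regularization})",
            f"mean accuracy: {p.mean_accuracy:.4f}   95% CI [{p.ci95[0]:.4f}, {p.ci95[1]:.4f}]",
            f"t vs {p.null_value:.2f}: {p.t_statistic:.3f}   p = {p.p_value:.4g}",
            f"mean TPR: {p.mean_tpr:.4f}   mean FPR: {p.mean_fpr:.4f}",
        ]
        if p.degenerate:
            lines.append("warning: zero variance across subjects; t-test degenerate")
        return "\n".join(lines)


class MisclassificationGP:
    """Warped Gaussian-process model of joint misclassification.

    Built from the valence and arousal fold results of two fitted
    decoders (or directly from per-stimulus probabilities).
    """

    def __init__(self, coords: np.ndarray, p_joint: np.ndarray, seed: int = 0):
        self.coords = np.asarray(coords, dtype=float)
        self.p_joint = np.asarray(p_joint, dtype=float)
        self.seed = seed

    @classmethod
    def from_results(
        cls,
        valence_results: AffectDecoderResults,
        arousal_results: AffectDecoderResults,
        mode: str = "error",
        seed: int = 0,
    ) -> tuple["MisclassificationGP", pd.DataFrame]:
        table = interpretation.joint_misclassification(
            valence_results.folds, arousal_results.folds, mode=mode
        )
        labels = valence_results.model.labels.set_index("stim_id")
        coords = labels.loc[table["stim_id"], ["valence9", "arousal9"]].to_numpy()
        return cls(coords, table["p_joint"].to_numpy(), seed=seed), table

    def fit(self) -> "MisclassificationGPResults":
        gp = interpretation.fit_misclassification_gp(self.coords, self.p_joint, seed=self.seed)
        return MisclassificationGPResults(model=self, gp=gp)


@dataclass
class MisclassificationGPResults:
    model: MisclassificationGP
    gp: object

    def predict_surface(self, **kwargs) -> interpretation.MisclassSurface:
        return interpretation.predict_misclassification_surface(self.gp, **kwargs)

    def summary(self) -> str:
        surf = self.predict_surface()
        vmax, amax = surf.argmax
        return (
            "MisclassificationGP results\n"
            "===========================\n"
            f"stimuli: {len(self.model.p_joint)}   mean p_joint: {self.model.p_joint.mean():.4f}\n"
            f"kernel: {self.gp.kernel_}\n"
            f"surface max p = {surf.p_surface.max():.4f} at (V={vmax:.2f}, A={amax:.2f})"
        )
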