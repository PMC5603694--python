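"""Affect label scaling and binarization.

Independent raters score stimuli on a 5-point Likert scale while the
normative reference ratings use a 9-point scale.  To remove a possible
latent linear bias in the small independent sample, ratings are mapped
onto the 9-point scale by robust (iteratively reweighted least squares)
regression fitted on stimuli rated on both scales.  Continuous 9-point
ratings are then binarized at the midpoint (>= 5.0) into the
classification labels used throughout: positive vs. negative valence and
high vs. low arousal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class RescaleModel:
    """Linear map from a 5-point rating to the 9-point scale."""

    slope: float
    intercept: float
    dimension: str = ""
    n_train: int = 0
    spearman_rho_train: float = float("nan")
    n_iterations: int = 0

    def predict(self, ratings5: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(ratings5, dtype=float) + self.intercept

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RescaleModel":
        return cls(**json.loads(Path(path).read_text()))


def rescale_ratings(
    train_pairs: np.ndarray,
    new_ratings5: np.ndarray | None = None,
    dimension: str = "",
) -> tuple[RescaleModel, np.ndarray, float]:
    """Fit the 5-point -> 9-point robust linear rescaling.

    Parameters
    ----------
    train_pairs : (n, 2) array
        Paired ``(rating5, rating9)`` observations, n >= 3.
    new_ratings5 : array, optional
        Ratings to map onto the 9-point scale (defaults to the training
        predictor itself).

    Returns ``(model, predicted_ratings9, spearman_rho_on_train)`` where
    the Spearman rank correlation compares fitted and observed 9-point
    ratings on the training pairs.

    The fit is IRLS with Tukey bisquare weights (tuning constant 4.685)
    and an intercept, the documented defaults of the classic ``robustfit``
    routine.
    """
    pairs = np.asarray(train_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need >= 3 (rating5, rating9) training pairs")
    if not np.all(np.isfinite(pairs)):
        raise ValueError("training pairs must be finite")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all 5-point ratings equal")

    X = sm.add_constant(x)
    fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit(
        conv="coefs", tol=1e-8, maxiter=50
    )
    intercept, slope = fit.params
    fitted = slope * x + intercept
    rho = float(stats.spearmanr(fitted, y).statistic)
    model = RescaleModel(
        slope=float(slope),
        intercept=float(intercept),
        dimension=dimension,
        n_train=len(x),
        spearman_rho_train=rho,
        n_iterations=int(getattr(fit, "fit_history", {}).get("iteration", 0) or 0),
    )
    if new_ratings5 is None:
        new_ratings5 = x
    return model, model.predict(np.asarray(new_ratings5, dtype=float)), rho


def binarize_labels(
    stimuli: pd.DataFrame,
    threshold: float = 5.0,
    selfreport: pd.Series | None = None,
) -> pd.DataFrame:
    """Binarize 9-point ratings into classification labels.

    Adds ``valence_class`` (``V_pos`` iff valence9 >= threshold, else
    ``V_neg``) and ``arousal_class`` (``A_high`` iff arousal9 >=
    threshold, else ``A_low``).  If per-stimulus ternary self-reports
    (``pos``/``neg``/``neutral``) are supplied, a ``selfreport_class``
    column is added with neutral trials left missing — the self-report
    classification contrasts positive vs. negative only.
    """
    for col in ("valence9", "arousal9"):
        if col not in stimuli:
            raise ValueError(f"missing column {col}")
        vals = stimuli[col].to_numpy(dtype=float)
        if len(vals) and (vals.min() < 1.0 or vals.max() > 9.0):
            raise ValueError(f"{col} outside the 9-point scale [1, 9]")
    out = stimuli.copy()
    out["valence_class"] = np.where(out["valence9"] >= threshold, "V_pos", "V_neg")
    out["arousal_class"] = np.where(out["arousal9"] >= threshold, "A_high", "A_low")
    if selfreport is not None:
        sr = pd.Series(selfreport, index=out.index)
        out["selfreport_class"] = sr.where(sr.isin(["pos", "neg"]))
    return out


POSITIVE_CLASS = {"valence": "V_pos", "arousal": "A_high", "selfreport": "pos"}
CLASS_COLUMN = {
    "valence": "valence_class",
    "arousal": "arousal_class",
    "selfreport": "selfreport_class",
}


def label_vector(labels: pd.DataFrame, target: str, stim_ids: list[str]) -> np.ndarray:
    """+1/-1 label vector for the given stimuli and classification target."""
    col, pos = CLASS_COLUMN[target], POSITIVE_CLASS[target]
    table = labels.set_index("stim_id")[col]
    vals = table.loc[stim_ids]
    if vals.isna().any():
        raise ValueError("stimuli without a class label for this target")
    return np.where(vals.to_numpy() == pos, 1, -1)
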