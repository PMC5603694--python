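"""Interpreting the decoder: anatomical encoding patterns, affect-space
projections of hyperplane distances, and a warped Gaussian-process model
of joint misclassification over the valence-arousal plane.

A linear decoder's weights are not directly interpretable as activation;
multiplying them by the feature covariance yields the equivalent forward
*encoding* pattern — the voxel activation pattern whose presence the
decoder detects.  Joint misclassification of the valence and arousal
classifiers is modelled per stimulus as the product of the two error
rates (chance level 0.5 x 0.5 = 0.25), warped to an unbounded scale with
``y = atanh(2p - 1)`` for Gaussian-process regression on the (V, A)
plane and back-transformed with ``p = (tanh(y) + 1) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.svm import SVC

from .mvpc import FoldResult

EPS_PROB = 1e-6
GRID_VALENCE = (1.0, 9.0)
GRID_AROUSAL = (2.0, 7.5)


# ---------------------------------------------------------------------------
# decoder -> encoder


@dataclass(frozen=True)
class EncodingMap:
    """Forward encoding pattern implied by a linear decoder."""

    a: np.ndarray  # encoding weights, unit maximum absolute value
    vi_max: float  # the scale divided out (maximum voxel intensity)
    source_fold: str = ""


def decoder_to_encoder(X_train: np.ndarray, w: np.ndarray, source_fold: str = "") -> EncodingMap:
    """Convert decoding weights to the equivalent encoding pattern.

    ``a = Cov(X_train) . w``, rescaled to unit maximum absolute value
    (voxel intensities reported as fractions of VI_max).
    """
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 training examples")
    Xc = X - X.mean(axis=0, keepdims=True)
    a = Xc.T @ (Xc @ np.asarray(w, dtype=float)) / (X.shape[0] - 1)
    vi_max = float(np.max(np.abs(a)))
    if vi_max > 0:
        a = a / vi_max
    return EncodingMap(a=a, vi_max=vi_max, source_fold=source_fold)


def correlate_maps(
    map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation between two voxel maps over a mask."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if mask is not None:
        sel = np.asarray(mask, dtype=bool)
        a, b = a[sel], b[sel]
    if len(a) < 3:
        raise ValueError("need >= 3 masked voxels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map has no defined correlation")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# affect-space projection


@dataclass(frozen=True)
class AffectProjection:
    """Per-stimulus mean hyperplane distances in (V, A) space with the
    observed 2-D separating line and its theoretical ideal."""

    per_stimulus: pd.DataFrame  # stim_id, valence9, arousal9, mean_distance, sign, saturation
    w_valence: float
    w_arousal: float
    bias: float
    ideal_axis: str  # "valence" -> V = 5 vertical; "arousal" -> A = 5 horizontal

    @property
    def line_normal(self) -> np.ndarray:
        n = np.array([self.w_valence, self.w_arousal])
        return n / np.linalg.norm(n)


def mean_stimulus_distances(folds: tuple[FoldResult, ...]) -> pd.Series:
    """Signed hyperplane distance per stimulus, averaged over every
    cross-validation fold in which the stimulus was tested."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for f in folds:
        for sid, d in zip(f.test_stim_ids, f.hyperplane_distances):
            sums[sid] = sums.get(sid, 0.0) + float(d)
            counts[sid] = counts.get(sid, 0) + 1
    return pd.Series({k: sums[k] / counts[k] for k in sums}, name="mean_distance").sort_index()


def hyperplane_affect_projection(
    fold_results: tuple[FoldResult, ...],
    labels: pd.DataFrame,
    target: str = "valence",
) -> AffectProjection:
    """Project cross-validated hyperplane distances into affect space.

    Per-stimulus mean distances are computed over folds; a linear
    maximum-margin line is fitted in (valence, arousal) coordinates to
    classify the *signs* of those mean distances, giving the observed 2-D
    separating line to compare with the ideal (V = 5 or A = 5).
    """
    dist = mean_stimulus_distances(fold_results)
    coords = labels.set_index("stim_id").loc[dist.index, ["valence9", "arousal9"]]
    signs = np.where(dist.to_numpy() >= 0, 1, -1)
    if len(np.unique(signs)) < 2:
        raise ValueError("all mean distances share one sign; no separating line")
    clf = SVC(kernel="linear", C=1e3)
    clf.fit(coords.to_numpy(), signs)
    per_stim = coords.reset_index()
    per_stim["mean_distance"] = dist.to_numpy()
    per_stim["sign"] = signs
    per_stim["saturation"] = np.minimum(np.abs(dist.to_numpy()), 1.0)
    return AffectProjection(
        per_stimulus=per_stim,
        w_valence=float(clf.coef_[0][0]),
        w_arousal=float(clf.coef_[0][1]),
        bias=float(clf.intercept_[0]),
        ideal_axis=target,
    )


# ---------------------------------------------------------------------------
# joint misclassification


def per_subject_misclassification(folds: tuple[FoldResult, ...]) -> pd.DataFrame:
    """Misclassification rate per (stimulus, subject) over that subject's
    test rotations containing the stimulus."""
    err: dict[tuple[str, str], list[float]] = {}
    for f in folds:
        wrong = f.predicted_labels != f.true_labels
        for sid, e in zip(f.test_stim_ids, wrong):
            err.setdefault((sid, f.subject_id), []).append(float(e))
    rows = [
        {"stim_id": sid, "subject_id": sub, "misclass_rate": float(np.mean(v))}
        for (sid, sub), v in err.items()
    ]
    return pd.DataFrame(rows)


def joint_misclassification(
    valence_folds: tuple[FoldResult, ...],
    arousal_folds: tuple[FoldResult, ...],
    mode: str = "error",
) -> pd.DataFrame:
    """Per-stimulus joint classification probabilities.

    Mean misclassification rates are computed across subjects
    independently for valence and arousal (subjects in whose test
    rotations the stimulus never appeared do not contribute); the joint
    probability is their product.  ``mode='error'`` multiplies error
    rates (the default); ``mode='correct'`` multiplies correct-
    classification rates.  Both share the 0.25 chance level.

    Also reports a per-stimulus one-sample t-test of the per-subject
    joint products against 0.25.
    """
    if mode not in ("error", "correct"):
        raise ValueError("mode must be 'error' or 'correct'")
    rv = per_subject_misclassification(valence_folds)
    ra = per_subject_misclassification(arousal_folds)
    stims_v, stims_a = set(rv["stim_id"]), set(ra["stim_id"])
    if stims_v != stims_a:
        raise ValueError("valence and arousal folds cover different stimuli")
    pv = rv.set_index(["stim_id", "subject_id"])["misclass_rate"]
    pa = ra.set_index(["stim_id", "subject_id"])["misclass_rate"]
    if mode == "correct":
        pv, pa = 1.0 - pv, 1.0 - pa

    rows = []
    for sid in sorted(stims_v):
        v_rates = pv.loc[sid]
        a_rates = pa.loc[sid]
        p_v, p_a = float(v_rates.mean()), float(a_rates.mean())
        # per-subject joint products over subjects with both rates
        shared = v_rates.index.intersection(a_rates.index)
        joint_subj = (v_rates.loc[shared] * a_rates.loc[shared]).to_numpy()
        if len(joint_subj) >= 2 and np.std(joint_subj, ddof=1) > 0:
            t_res = stats.ttest_1samp(joint_subj, 0.25)
            t_stat, p_val = float(t_res.statistic), float(t_res.pvalue)
        else:
            t_stat, p_val = float("nan"), float("nan")
        rows.append(
            {
                "stim_id": sid,
                "p_valence": p_v,
                "p_arousal": p_a,
                "p_joint": p_v * p_a,
                "n_subjects": int(len(shared)),
                "t_vs_chance": t_stat,
                "p_value": p_val,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probability warping and the GP surface


def warp_probability(p: np.ndarray | float) -> np.ndarray | float:
    """y = atanh(2p - 1) after clipping p to [eps, 1 - eps]."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    clipped = np.clip(p_arr, EPS_PROB, 1.0 - EPS_PROB)
    out = np.arctanh(2.0 * clipped - 1.0)
    return float(out) if np.isscalar(p) else out


def unwarp_probability(y: np.ndarray | float) -> np.ndarray | float:
    """p = (tanh(y) + 1) / 2."""
    out = (np.tanh(np.asarray(y, dtype=float)) + 1.0) / 2.0
    return float(out) if np.isscalar(y) else out


@dataclass(frozen=True)
class MisclassSurface:
    """GP-predicted joint misclassification over the affect plane."""

    valence_grid: np.ndarray  # (n_v,)
    arousal_grid: np.ndarray  # (n_a,)
    p_surface: np.ndarray  # (n_a, n_v), probabilities in [0, 1]
    per_stimulus: pd.DataFrame = field(default=None, repr=False)

    @property
    def argmax(self) -> tuple[float, float]:
        """(valence, arousal) grid location of maximum misclassification."""
        ia, iv = np.unravel_index(np.argmax(self.p_surface), self.p_surface.shape)
        return float(self.valence_grid[iv]), float(self.arousal_grid[ia])

    def to_frame(self) -> pd.DataFrame:
        vv, aa = np.meshgrid(self.valence_grid, self.arousal_grid)
        return pd.DataFrame(
            {"valence9": vv.reshape(-1), "arousal9": aa.reshape(-1), "p_pred": self.p_surface.reshape(-1)}
        )

    def plot(self, path=None, ax=None):
        """Contour heatmap of the surface over the affect plane, with
        the per-stimulus probabilities overlaid when available.  Saves a
        PNG when ``path`` is given; returns the axes."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4.5))
        im = ax.contourf(self.valence_grid, self.arousal_grid, self.p_surface, levels=20)
        if self.per_stimulus is not None and {"valence9", "arousal9", "p_joint"} <= set(
            self.per_stimulus.columns
        ):
            ax.scatter(
                self.per_stimulus["valence9"],
                self.per_stimulus["arousal9"],
                c=self.per_stimulus["p_joint"],
                edgecolors="white",
                linewidths=0.5,
                vmin=float(self.p_surface.min()),
                vmax=float(self.p_surface.max()),
            )
        ax.set_xlabel("valence (9-point)")
        ax.set_ylabel("arousal (9-point)")
        ax.set_title("joint misclassification probability")
        ax.figure.colorbar(im, ax=ax, label="p")
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def fit_misclassification_gp(
    coords: np.ndarray,
    p_joint: np.ndarray,
    seed: int = 0,
) -> GaussianProcessRegressor:
    """Gaussian-process regression of warped joint misclassification.

    ``coords`` is (n, 2) mean (valence, arousal) scores; targets are the
    warped probabilities.  Squared-exponential kernel with constant mean
    (via target normalisation); hyperparameters fitted by marginal-
    likelihood maximisation with an observation-noise floor of 1e-4.
    Duplicate coordinates are jittered by 1e-6 rating units.
    """
    X = np.array(coords, dtype=float)
    y = warp_probability(np.asarray(p_joint, dtype=float))
    if X.ndim != 2 or X.shape[1] != 2 or X.shape[0] < 5:
        raise ValueError("need >= 5 (valence, arousal) coordinates")
    uniq, inverse, counts = np.unique(X, axis=0, return_inverse=True, return_counts=True)
    if len(uniq) < 5:
        raise ValueError("need >= 5 distinct coordinates")
    if np.any(counts > 1):
        rng = np.random.default_rng(seed)
        dup = counts[inverse] > 1
        X = X + np.where(dup[:, None], rng.uniform(-1e-6, 1e-6, X.shape), 0.0)
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
        length_scale=[2.0, 2.0], length_scale_bounds=(0.1, 50.0)
    ) + WhiteKernel(noise_level=1e-2, noise_level_bounds=(1e-4, 1e1))
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True, random_state=seed)
    gp.fit(X, y)
    return gp


def predict_misclassification_surface(
    model: GaussianProcessRegressor,
    valence_range: tuple[float, float] = GRID_VALENCE,
    arousal_range: tuple[float, float] = GRID_AROUSAL,
    n_valence: int = 81,
    n_arousal: int = 56,
    per_stimulus: pd.DataFrame | None = None,
) -> MisclassSurface:
    """Predict the misclassification probability surface on a regular
    grid over the affect plane (default V in [1, 9], A in [2, 7.5]) and
    back-transform warped predictions to probabilities."""
    v = np.linspace(*valence_range, n_valence)
    a = np.linspace(*arousal_range, n_arousal)
    vv, aa = np.meshgrid(v, a)
    y_pred = model.predict(np.column_stack([vv.reshape(-1), aa.reshape(-1)]))
    p = unwarp_probability(y_pred).reshape(aa.shape)
    return MisclassSurface(valence_grid=v, arousal_grid=a, p_surface=p, per_stimulus=per_stimulus)
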