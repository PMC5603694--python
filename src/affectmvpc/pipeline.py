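"""End-to-end pipeline orchestration.

Runs simulate -> labels -> univariate -> stability -> classify ->
interpret on a single :class:`RunConfig`, writing standard-format
artifacts (NIfTI volumes, CSV/TSV tables, JSON metrics) under the output
directory.  All randomness flows from the config seed through named
per-stage substreams, so an identical config and seed reproduces an
identical report.  The expensive stages (simulation, classification) are
cached on disk keyed by a content hash of the parameters that feed them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import interpretation, io, mvpc, stability, synthetic, univariate
from .datasets import BetaDataset, VolumeGeometry
from .labels import binarize_labels, label_vector
from .model import AffectDecoder, MisclassificationGP

logger = logging.getLogger("affectmvpc")


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Missing or inconsistent data artifact (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Desk-scale pipeline configuration."""

    seed: int = 0
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_subjects: int = 16
    n_stimuli: int = 88
    stimuli_per_subject: int = 44
    snr: float = 1.0
    noise_fwhm_mm: float = 6.0
    subject_offset_sd: float = 0.3
    signal_fraction: float = 0.1
    arousal_valence_corr: float = 0.0
    gm_fraction: float = 0.5
    binarize_threshold: float = 5.0
    p_voxel: float = 0.001
    alpha: float = 0.05
    cluster_sim_iters: int = 200
    features: tuple[str, ...] = ("wholebrain", "aroi")
    targets: tuple[str, ...] = ("valence", "arousal")
    classifier_C: float = 1.0
    out_dir: str = "affectmvpc_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except Exception as exc:  # malformed YAML is a config error
            raise ConfigError(f"cannot parse config: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        for key in ("grid_shape", "voxel_size_mm", "features", "targets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def content_hash(self, *fields_used: str) -> str:
        payload = {f: getattr(self, f) for f in sorted(fields_used)}
        return hashlib.sha256(json.dumps(payload, default=str).encode()).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def simulate(config: RunConfig) -> tuple[pd.DataFrame, BetaDataset]:
    """Generate the stimulus set and planted-signal beta dataset."""
    geometry = VolumeGeometry(config.grid_shape, config.voxel_size_mm)
    stimuli = synthetic.generate_stimulus_set(
        n_stim=config.n_stimuli,
        arousal_valence_corr=config.arousal_valence_corr,
        seed=_stage_seed(config.seed, "stimuli"),
    )
    encoding = synthetic.random_encoding_spec(
        geometry,
        snr=config.snr,
        noise_fwhm_mm=config.noise_fwhm_mm,
        subject_offset_sd=config.subject_offset_sd,
        signal_fraction=config.signal_fraction,
        seed=_stage_seed(config.seed, "encoding"),
    )
    data = synthetic.generate_subject_betas(
        stimuli,
        n_subjects=config.n_subjects,
        geometry=geometry,
        encoding=encoding,
        stimuli_per_subject=config.stimuli_per_subject,
        seed=_stage_seed(config.seed, "betas"),
    )
    return stimuli, data


def subject_contrast_maps(data: BetaDataset, labels: pd.DataFrame, target: str) -> np.ndarray:
    """Per-subject class-contrast maps (mean positive minus mean negative
    brain state) from the trial-wise betas."""
    out = []
    for s in range(data.n_subjects):
        y = label_vector(labels, target, data.stim_ids[s])
        out.append(univariate.betaseries_class_contrast(data.betas[s], y))
    return np.asarray(out)


@dataclass
class UnivariateStage:
    tmap: univariate.TMap
    t_thresh: float
    k_min: float
    clusters: univariate.ClusterSet
    loo_clusters: list[univariate.ClusterSet]
    group_gm: np.ndarray


def run_univariate(
    config: RunConfig,
    data: BetaDataset,
    labels: pd.DataFrame,
    target: str,
    with_loo_clusters: bool = True,
) -> UnivariateStage:
    """Group t-map, Monte-Carlo extent threshold, and cluster extraction
    (group-level and leave-one-out for the stability analysis)."""
    contrasts = subject_contrast_maps(data, labels, target)
    group_gm = univariate.build_group_gm_mask(data.gm_masks, config.gm_fraction).include
    tmap = univariate.group_ttest_map(contrasts, contrast_name=target)
    t_thresh = univariate.critical_t(tmap.df, config.p_voxel)
    k_min = univariate.estimate_min_cluster_size(
        data.geometry,
        config.noise_fwhm_mm,
        group_gm,
        p_voxel=config.p_voxel,
        alpha=config.alpha,
        n_iter=config.cluster_sim_iters,
        seed=_stage_seed(config.seed, f"clustsim:{target}"),
    )
    clusters = univariate.extract_clusters(tmap, t_thresh, k_min, data.geometry, mask=group_gm)
    loo_sets: list[univariate.ClusterSet] = []
    if with_loo_clusters:
        for s in range(data.n_subjects):
            keep = [u for u in range(data.n_subjects) if u != s]
            tmap_s = univariate.group_ttest_map(contrasts[keep], contrast_name=f"{target}-loo")
            thr_s = univariate.critical_t(tmap_s.df, config.p_voxel)
            loo_sets.append(
                univariate.extract_clusters(tmap_s, thr_s, k_min, data.geometry, mask=group_gm)
            )
    return UnivariateStage(tmap, t_thresh, k_min, clusters, loo_sets, group_gm)


def feature_mask_for(
    variant: str,
    uni: UnivariateStage,
    config: RunConfig,
    data: BetaDataset,
) -> np.ndarray | None:
    """Resolve a feature-variant name to a flat voxel mask.

    Variants: ``wholebrain``; ``aroi`` (all surviving clusters);
    ``iroi:<cluster_id>``; ``rcaroi:dilate1`` / ``rcaroi:dilate2``
    (dilated aROI); ``rcaroi:p0.01`` / ``rcaroi:p0.05`` (relaxed voxel
    threshold with its own extent threshold).
    """
    if variant == "wholebrain":
        return None
    if variant == "aroi":
        return uni.clusters.mask()
    if variant.startswith("iroi:"):
        cid = int(variant.split(":", 1)[1])
        if not any(c.cluster_id == cid for c in uni.clusters.clusters):
            raise DataError(f"no cluster with id {cid} for variant {variant}")
        return uni.clusters.mask(cid)
    if variant.startswith("rcaroi:dilate"):
        n = int(variant.removeprefix("rcaroi:dilate"))
        return univariate.dilate_mask(uni.clusters.mask(), n, data.geometry, gm_mask=uni.group_gm)
    if variant.startswith("rcaroi:p"):
        p_relaxed = float(variant.split(":p", 1)[1])
        thr = univariate.critical_t(uni.tmap.df, p_relaxed)
        k_min = univariate.estimate_min_cluster_size(
            data.geometry,
            config.noise_fwhm_mm,
            uni.group_gm,
            p_voxel=p_relaxed,
            alpha=config.alpha,
            n_iter=config.cluster_sim_iters,
            seed=_stage_seed(config.seed, f"clustsim:{variant}"),
        )
        relaxed = univariate.extract_clusters(
            uni.tmap, thr, k_min, data.geometry, mask=uni.group_gm
        )
        return relaxed.mask()
    raise ConfigError(f"unknown feature variant: {variant}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and write) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_hash = config.content_hash(*[f.name for f in dataclasses.fields(config) if f.name != "out_dir"])
    report_path = out / "metrics.json"
    if report_path.exists():
        cached = json.loads(report_path.read_text())
        if cached.get("config_hash") == report_hash:
            logger.info("report cache hit (%s); skipping recompute", report_hash)
            return cached

    logger.info("stage simulate: %d subjects, grid %s, snr %.3g", config.n_subjects, config.grid_shape, config.snr)
    stimuli, data = simulate(config)
    labels = binarize_labels(stimuli, threshold=config.binarize_threshold)
    io.write_stimulus_table(labels, out / "stimuli.csv")
    io.write_beta_dataset(data, out / "betas")

    from . import __version__

    report: dict = {
        "config_hash": report_hash,
        "version": __version__,
        "seed": config.seed,
        "config": {f.name: getattr(config, f.name) for f in dataclasses.fields(config)},
        "stages": {},
    }

    uni_stages: dict[str, UnivariateStage] = {}
    stability_rows = []
    for target in config.targets:
        if target == "selfreport":
            continue
        logger.info("stage univariate: target=%s", target)
        uni = run_univariate(config, data, labels, target)
        uni_stages[target] = uni
        uni.clusters.to_frame().to_csv(out / f"clusters_{target}.csv", index=False)
        io.write_volume(uni.tmap.t, data.geometry, out / f"tmap_{target}.nii")
        report["stages"][f"univariate_{target}"] = {
            "t_thresh": uni.t_thresh,
            "k_min": uni.k_min,
            "n_clusters": len(uni.clusters),
            "n_degenerate_voxels": int(uni.tmap.degenerate.sum()),
        }
        tables = [stability.match_clusters(cv, uni.clusters) for cv in uni.loo_clusters]
        if tables and len(uni.clusters):
            summ = stability.summarize_stability(tables)
            summ.insert(0, "cluster_set", target)
            stability_rows.append(summ)
    if stability_rows:
        pd.concat(stability_rows, ignore_index=True).to_csv(out / "cluster_stability.csv", index=False)

    results_rows = []
    decoder_results: dict[tuple[str, str], object] = {}
    for target in config.targets:
        for variant in config.features:
            logger.info("stage classify: target=%s features=%s", target, variant)
            uni = uni_stages.get(target)
            fmask = None
            if variant != "wholebrain":
                if uni is None:
                    raise ConfigError(f"feature variant {variant} needs a univariate stage for {target}")
                fmask = feature_mask_for(variant, uni, config, data)
                if fmask is not None and not fmask.any():
                    logger.warning("variant %s has an empty mask; skipping", variant)
                    continue
            decoder = AffectDecoder(
                data,
                labels,
                target=target,
                feature_mask=fmask,
                classifier=mvpc.ClassifierSpec(regularization=config.classifier_C),
                gm_fraction=config.gm_fraction,
            )
            res = decoder.fit(mode="inter")
            decoder_results[(target, variant)] = res
            p = res.performance
            results_rows.append(
                {
                    "target": target,
                    "feature": variant,
                    "mean_accuracy": p.mean_accuracy,
                    "ci_low": p.ci95[0],
                    "ci_high": p.ci95[1],
                    "mean_tpr": p.mean_tpr,
                    "mean_fpr": p.mean_fpr,
                    "t": p.t_statistic,
                    "p": p.p_value,
                }
            )
    results = pd.DataFrame(results_rows)
    results.to_csv(out / "classification.csv", index=False)
    report["stages"]["classify"] = results.to_dict(orient="records")
    report["stages"]["per_subject_accuracy"] = {
        f"{target}/{variant}": [float(a) for a in res.per_subject_accuracy]
        for (target, variant), res in decoder_results.items()
    }

    # interpretation: whole-brain valence + arousal decoders
    key_v, key_a = ("valence", "wholebrain"), ("arousal", "wholebrain")
    if key_v in decoder_results and key_a in decoder_results:
        logger.info("stage interpret")
        res_v, res_a = decoder_results[key_v], decoder_results[key_a]
        gp_model, joint = MisclassificationGP.from_results(
            res_v, res_a, seed=_stage_seed(config.seed, "gp")
        )
        joint.to_csv(out / "joint_misclassification.csv", index=False)
        surface = gp_model.fit().predict_surface()
        surface.to_frame().to_csv(out / "misclass_surface.csv", index=False)
        interp: dict = {
            "mean_p_joint": float(joint["p_joint"].mean()),
            "surface_max_p": float(surface.p_surface.max()),
            "surface_argmax": list(surface.argmax),
        }
        if data.encoding is not None and data.encoding.snr > 0:
            emap, emask = res_v.encoding_map()
            r, _ = interpretation.correlate_maps(emap.a, data.encoding.w_valence[emask])
            interp["encoding_corr_with_planted_valence"] = float(r)
        try:
            proj = res_v.affect_projection()
            interp["affect_line"] = {
                "w_valence": proj.w_valence,
                "w_arousal": proj.w_arousal,
                "bias": proj.bias,
            }
        except ValueError:
            interp["affect_line"] = None  # degenerate (single-sign) distances
        report["stages"]["interpret"] = interp

    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("report written to %s", report_path)
    return report
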