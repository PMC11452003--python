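"""End-to-end phantom experiment: build models, corrupt, post-process, score.

Mirrors the evaluation design used for muscle-segmentation post-processing:
a training family of multi-label phantoms yields per-label mean shapes; an
independent test family is corrupted into synthetic "predictions"; the
post-processing arms (raw, 2D morphological, CRF, mean-shape) all consume
the *same* corrupted prediction per subject (paired design), and paired
Wilcoxon signed-rank tests compare arms per metric.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crf import CRFParams, crf_postprocess_volume
from .meanshape import MSModelBank, ms_postprocess_volume
from .metrics import pooled_metrics, wilcoxon_signed_rank
from .phantoms import (CorruptionSpec, PhantomSpec, corrupt_prediction,
                       generate_multilabel_phantom, synth_intensity_image,
                       unaries_from_labels)
from .slice2d import Slice2DParams, postprocess_2d_volume
from .ssm import build_shape_model, optimize_correspondences, reconstruct_mean_mask
from .volumes import LabelVolume, extract_label_mask, write_label_volume

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one phantom experiment."""

    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(
        n_labels=2, volume_shape=(64, 64, 80), base_radius=7.0,
        variability=1.2, bend_amplitude=1.5, gap=3))
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)
    n_train: int = 6
    n_test: int = 4
    particles: int = 64
    ssm_iterations: int = 60
    ns: float = 5.0
    lam: float | str = 10.0
    cleanup_radius: int = 1
    slice2d: Slice2DParams = field(default_factory=Slice2DParams)
    crf: CRFParams = field(default_factory=CRFParams)
    unary_flip_prob: float = 0.1
    intensity_noise_sd: float = 8.0
    arms: tuple[str, ...] = ("raw", "2d", "crf", "ms")
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "phantom" in kwargs:
            kwargs["phantom"] = PhantomSpec(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in kwargs["phantom"].items()})
        if "corruption" in kwargs:
            kwargs["corruption"] = CorruptionSpec(**kwargs["corruption"])
        if "slice2d" in kwargs:
            kwargs["slice2d"] = Slice2DParams(**kwargs["slice2d"])
        if "crf" in kwargs:
            kwargs["crf"] = CRFParams(**kwargs["crf"])
        if "arms" in kwargs:
            kwargs["arms"] = tuple(kwargs["arms"])
        return cls(**kwargs)


@dataclass
class ExperimentResult:
    bank: MSModelBank
    metrics: pd.DataFrame          # subject, arm, label, dsc/rve/hd/assd
    comparisons: pd.DataFrame      # arm_a, arm_b, metric, W, p
    manifest: dict


def build_bank_from_family(phantoms: list[LabelVolume], labels: list[int],
                           particles: int = 64, iterations: int = 60,
                           seed: int = 0) -> MSModelBank:
    """Per-label shape models and mean masks from a training family."""
    mean_masks, models = {}, {}
    for label in labels:
        masks = [extract_label_mask(v, label) for v in phantoms]
        if any(m.is_empty() for m in masks):
            raise StageError(f"build-ssm: label {label} empty in training set")
        ps, _ = optimize_correspondences(masks, m=particles,
                                         iterations=iterations, seed=seed)
        model = build_shape_model(ps)
        mean_masks[label] = reconstruct_mean_mask(model, ps, masks)
        models[label] = model
    return MSModelBank(mean_masks=mean_masks, models=models,
                       provenance={"n_train": len(phantoms),
                                   "particles": particles,
                                   "iterations": iterations, "seed": seed})


def _grid_hash(vol: LabelVolume) -> str:
    return hashlib.sha256(np.ascontiguousarray(vol.grid).tobytes()).hexdigest()[:16]


def run_experiment(cfg: ExperimentConfig,
                   output_dir: str | Path | None = None) -> ExperimentResult:
    """Run the full paired phantom comparison of post-processing arms."""
    rows = []
    manifest = {"config": _jsonable(cfg.to_dict()), "subjects": []}
    labels = list(range(1, cfg.phantom.n_labels + 1))

    try:
        train = [generate_multilabel_phantom(
            replace(cfg.phantom, seed=cfg.seed + 1000 + s))
            for s in range(cfg.n_train)]
    except Exception as exc:
        raise StageError(f"simulate-train: {exc}") from exc
    try:
        bank = build_bank_from_family(train, labels, particles=cfg.particles,
                                      iterations=cfg.ssm_iterations,
                                      seed=cfg.seed)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"build-ssm: {exc}") from exc

    n_classes = cfg.phantom.n_labels + 1
    class_means = {0: 20.0}
    class_means.update({l: 60.0 + 30.0 * l for l in labels})

    outdir = Path(output_dir) if output_dir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    for s in range(cfg.n_test):
        subj_seed = cfg.seed + 2000 + s
        gt = generate_multilabel_phantom(replace(cfg.phantom, seed=subj_seed))
        pred = corrupt_prediction(gt, replace(cfg.corruption, seed=subj_seed))
        entry = {"subject": s, "seed": subj_seed, "gt_hash": _grid_hash(gt),
                 "pred_hash": _grid_hash(pred), "arms": {}}
        outputs = {"raw": pred}
        if "2d" in cfg.arms:
            try:
                outputs["2d"] = postprocess_2d_volume(pred, cfg.slice2d)
            except Exception as exc:
                raise StageError(f"postprocess-2d[{s}]: {exc}") from exc
        if "crf" in cfg.arms:
            try:
                intensity = synth_intensity_image(
                    gt, class_means, noise_sd=cfg.intensity_noise_sd,
                    seed=subj_seed)
                prob = unaries_from_labels(pred, cfg.unary_flip_prob,
                                           n_classes=n_classes)
                outputs["crf"] = crf_postprocess_volume(
                    prob, intensity, cfg.crf, spacing=gt.spacing)
            except Exception as exc:
                raise StageError(f"postprocess-crf[{s}]: {exc}") from exc
        if "ms" in cfg.arms:
            try:
                outputs["ms"] = ms_postprocess_volume(
                    pred, bank, ns=cfg.ns, lam=cfg.lam,
                    cleanup_radius=cfg.cleanup_radius)
            except Exception as exc:
                raise StageError(f"postprocess-ms[{s}]: {exc}") from exc
        for arm in cfg.arms:
            if arm not in outputs:
                continue
            report = pooled_metrics(gt, outputs[arm], labels=labels)
            entry["arms"][arm] = _grid_hash(outputs[arm])
            for lab, vals in report.per_label.items():
                rows.append({"subject": s, "arm": arm, "label": lab, **vals})
            rows.append({"subject": s, "arm": arm, "label": "pooled",
                         **report.pooled})
            if outdir is not None:
                write_label_volume(outputs[arm], outdir / f"s{s}_{arm}.nii.gz")
        if outdir is not None:
            write_label_volume(gt, outdir / f"s{s}_gt.nii.gz")
        manifest["subjects"].append(entry)

    metrics = pd.DataFrame(rows)
    comparisons = compare_arms(metrics, cfg.arms)
    if outdir is not None:
        metrics.to_csv(outdir / "metrics.csv", index=False)
        comparisons.to_csv(outdir / "comparisons.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ExperimentResult(bank=bank, metrics=metrics,
                            comparisons=comparisons, manifest=manifest)


def compare_arms(metrics: pd.DataFrame, arms) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank tests between arms, per metric."""
    rows = []
    per_label = metrics[metrics["label"] != "pooled"]
    for i, a in enumerate(arms):
        for b in arms[i + 1:]:
            for metric in ("dsc", "rve", "hd", "assd"):
                if metric not in per_label.columns:
                    continue
                pa = per_label[per_label["arm"] == a].sort_values(
                    ["subject", "label"])[metric].to_numpy()
                pb = per_label[per_label["arm"] == b].sort_values(
                    ["subject", "label"])[metric].to_numpy()
                ok = np.isfinite(pa) & np.isfinite(pb)
                if ok.sum() < 5 or np.all(pa[ok] == pb[ok]):
                    continue
                w, p = wilcoxon_signed_rank(pa[ok], pb[ok])
                rows.append({"arm_a": a, "arm_b": b, "metric": metric,
                             "n": int(ok.sum()), "W": w, "p": p})
    return pd.DataFrame(rows)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
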