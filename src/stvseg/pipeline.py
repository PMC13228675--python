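"""End-to-end experiment orchestration.

One :class:`RunConfig` drives the whole study: phantom generation, a
volume-level train/test split, slice-wise training, prediction on held-out
volumes, contour-stitched reconstruction, the 2D/3D metric battery, and the
paired statistical comparison with Bland-Altman agreement. Every stage
writes its artifacts into a fixed run-directory layout:

    run_dir/
      config.json      resolved configuration
      manifest.csv     per-volume id, target kind, true volume
      split.json       train/test volume ids
      checkpoints/     model weights (+ JSON sidecar) and history.csv
      masks/           predicted label volumes (NIfTI, optional)
      meshes/          stitched surfaces (OBJ)
      reports/         metrics_2d.csv, metrics_3d.csv, comparison.csv,
                       bland_altman.csv (+ .png)
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as met
from . import nn
from .phantom import PhantomParams, RaterPerturbation, draw_params, generate_phantom
from .stats import PairedSample, bland_altman, bland_altman_plot, compare_methods_report
from .surface import masks_to_surface, save_mesh
from .volume import (
    LabelVolume,
    UltrasoundVolume,
    reslice,
    reslice_label,
    restack,
    save_label,
    save_volume,
    split_by_volume,
)

__all__ = ["RunConfig", "run_experiment", "evaluate_only", "StageError"]

log = logging.getLogger("stvseg")


class StageError(RuntimeError):
    """A pipeline stage failed; earlier artifacts are left in place."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Everything one experiment needs; nested configs validate themselves."""

    n_volumes: int = 20
    phantom: PhantomParams = field(default_factory=PhantomParams)
    n_slices: int = 10
    train_fraction: float = 0.8
    seed: int = 0
    model: nn.ModelConfig = field(default_factory=lambda: nn.ModelConfig(
        architecture="unet", depth=2, base_filters=8, input_size=(64, 64)))
    train: nn.TrainConfig = field(default_factory=lambda: nn.TrainConfig.scaled_down())
    augmentation: nn.AugmentationConfig = field(
        default_factory=nn.AugmentationConfig)
    threshold: float = 0.5
    n_contour_points: int = 64
    interpolate_gaps: bool = True
    outside_positive: bool = True
    save_nifti: bool = False
    save_meshes: bool = True

    def __post_init__(self) -> None:
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2 (train and test)")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.n_contour_points < 3:
            raise ValueError("n_contour_points must be >= 3")
        if not 1 <= self.n_slices <= self.phantom.shape[0]:
            raise ValueError("n_slices must fit the phantom depth")

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            p = dict(d["phantom"])
            for key in ("shape", "spacing", "semi_axes_mm", "center_frac"):
                if key in p:
                    p[key] = tuple(p[key])
            d["phantom"] = PhantomParams(**p)
        if "model" in d and isinstance(d["model"], dict):
            m = dict(d["model"])
            if "input_size" in m:
                m["input_size"] = tuple(m["input_size"])
            d["model"] = nn.ModelConfig(**m)
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = nn.TrainConfig(**d["train"])
        if "augmentation" in d and isinstance(d["augmentation"], dict):
            d["augmentation"] = nn.AugmentationConfig(**d["augmentation"])
        return RunConfig(**d)

    @staticmethod
    def from_yaml(path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            t0 = time.monotonic()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                log.error("stage %s: FAILED (%s)", name, exc)
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.1f s", name, time.monotonic() - t0)
            return out
        return wrapped
    return decorate


@_stage("phantom")
def _make_phantoms(cfg: RunConfig, run_dir: Path):
    rng = np.random.default_rng(cfg.seed)
    pairs, rows = [], []
    for i in range(cfg.n_volumes):
        p = draw_params(cfg.phantom, rng)
        vol, lab = generate_phantom(p)
        pairs.append((vol, lab))
        rows.append({
            "id": f"vol{i:03d}", "seed": p.seed, "target_kind": p.target_kind,
            "true_volume_mm3": lab.volume_mm3(),
        })
        if cfg.save_nifti:
            d = run_dir / "volumes"
            d.mkdir(exist_ok=True)
            save_volume(vol, str(d / f"vol{i:03d}.nii.gz"))
            save_label(lab, str(d / f"vol{i:03d}_label.nii.gz"))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(run_dir / "manifest.csv", index=False)
    return pairs, manifest


@_stage("split")
def _split(cfg: RunConfig, run_dir: Path, ids: list[str]):
    train_ids, test_ids = split_by_volume(ids, cfg.train_fraction, cfg.seed)
    with open(run_dir / "split.json", "w") as fh:
        json.dump({"train": train_ids, "test": test_ids}, fh, indent=2)
    return train_ids, test_ids


def _slice_pairs(vol: UltrasoundVolume, lab: LabelVolume, n_slices: int):
    vs = reslice(vol, n_slices)
    ls = reslice_label(lab, n_slices)
    return list(zip(vs.images, ls.images))


@_stage("train")
def _train(cfg: RunConfig, run_dir: Path, train_pairs, val_pairs):
    model = nn.build_model(cfg.model)
    log.info("model: %s", model.summary())
    model, history = nn.train(model, train_pairs, val_pairs, cfg.train,
                              cfg.augmentation)
    ckpt = run_dir / "checkpoints"
    ckpt.mkdir(exist_ok=True)
    nn.save_checkpoint(model, str(ckpt / "model.npz"))
    pd.DataFrame(history).to_csv(ckpt / "history.csv", index=False)
    return model, history


@_stage("predict")
def _predict(cfg: RunConfig, run_dir: Path, model, test_sets):
    preds = {}
    for vid, (vol, lab) in test_sets.items():
        stack = reslice(vol, cfg.n_slices)
        masks = nn.predict_stack(model, stack, cfg.threshold)
        preds[vid] = (stack, masks)
        if cfg.save_nifti:
            d = run_dir / "masks"
            d.mkdir(exist_ok=True)
            save_label(restack(stack, masks, vol.shape), str(d / f"{vid}.nii.gz"))
    return preds


@_stage("reconstruct")
def _reconstruct(cfg: RunConfig, run_dir: Path, preds, test_sets):
    surfaces = {}
    mesh_dir = run_dir / "meshes"
    for vid, (stack, masks) in preds.items():
        _, lab = test_sets[vid]
        gt_masks = reslice_label(lab, cfg.n_slices).images
        pred_s, pred_v, warn_p = masks_to_surface(
            stack, masks, cfg.interpolate_gaps, cfg.n_contour_points)
        gt_s, gt_v, warn_g = masks_to_surface(
            stack, gt_masks, cfg.interpolate_gaps, cfg.n_contour_points)
        for w in warn_p:
            log.warning("%s prediction: %s", vid, w)
        surfaces[vid] = {
            "pred": (pred_s, pred_v, masks), "gt": (gt_s, gt_v, gt_masks),
        }
        if cfg.save_meshes:
            mesh_dir.mkdir(exist_ok=True)
            save_mesh(pred_s, str(mesh_dir / f"{vid}_pred.obj"))
            save_mesh(gt_s, str(mesh_dir / f"{vid}_manual.obj"))
    return surfaces


@_stage("evaluate")
def _evaluate(cfg: RunConfig, run_dir: Path, preds, surfaces, test_sets):
    spacing = (cfg.phantom.spacing[1], cfg.phantom.spacing[2])
    rows_2d, recs_3d, rows_3d = [], [], []
    recs_2d_by_vol = {}
    for vid in sorted(preds):
        stack, masks = preds[vid]
        _, lab = test_sets[vid]
        gt_masks = reslice_label(lab, cfg.n_slices).images
        vol_recs = []
        for i, (pm, gm) in enumerate(zip(masks, gt_masks)):
            rec = met.evaluate_pair_2d(pm, gm, spacing, cfg.outside_positive)
            vol_recs.append(rec)
            rows_2d.append({"id": vid, "slice": i, **rec.to_row()})
        recs_2d_by_vol[vid] = vol_recs
        pred_s, pred_v, _ = surfaces[vid]["pred"]
        gt_s, gt_v, _ = surfaces[vid]["gt"]
        rec3 = met.evaluate_pair_3d(
            masks, gt_masks, spacing, pred_s, gt_s, pred_v, gt_v,
            gt_label=lab, outside_positive=cfg.outside_positive)
        recs_3d.append(rec3)
        rows_3d.append({
            "id": vid, **rec3.to_row(),
            "pred_volume_mm3": pred_v, "manual_volume_mm3": gt_v,
        })
    reports = run_dir / "reports"
    reports.mkdir(exist_ok=True)
    pd.DataFrame(rows_2d).to_csv(reports / "metrics_2d.csv", index=False,
                                 float_format="%.6f")
    pd.DataFrame(rows_3d).to_csv(reports / "metrics_3d.csv", index=False,
                                 float_format="%.6f")
    return recs_2d_by_vol, recs_3d, pd.DataFrame(rows_3d)


def _mean_record(recs: list) -> met.MetricsRecord:
    """Per-volume mean of per-slice records (NaN-safe)."""
    fields = [f.name for f in dataclasses.fields(met.MetricsRecord)
              if f.name != "degenerate"]
    vals = {f: float(np.nanmean([getattr(r, f) for r in recs])) for f in fields}
    return met.MetricsRecord(**vals, degenerate=any(r.degenerate for r in recs))


@_stage("compare")
def _compare(cfg: RunConfig, run_dir: Path, recs_2d_by_vol, recs_3d, table_3d):
    reports = run_dir / "reports"
    mean_2d = [_mean_record(recs_2d_by_vol[vid]) for vid in sorted(recs_2d_by_vol)]
    report = None
    if len(mean_2d) >= 3:
        report = compare_methods_report(
            mean_2d, recs_3d, ("2D slices", "3D reconstruction"))
        report.to_csv(reports / "comparison.csv", index=False,
                      float_format="%.6g")
    # volume agreement: algorithm vs manual STV
    if len(table_3d) >= 3:
        sample = PairedSample(
            table_3d["pred_volume_mm3"].to_numpy(),
            table_3d["manual_volume_mm3"].to_numpy(),
            label="synovial tissue volume", units="mm^3")
        ba = bland_altman(sample)
        pd.DataFrame({"mean_mm3": ba.means, "difference_mm3": ba.differences}) \
            .to_csv(reports / "bland_altman.csv", index=False)
        with open(reports / "bland_altman.json", "w") as fh:
            json.dump({"bias_mm3": ba.bias, "sd_mm3": ba.sd,
                       "loa_lower_mm3": ba.loa_lower,
                       "loa_upper_mm3": ba.loa_upper}, fh, indent=2)
        try:
            bland_altman_plot(ba, str(reports / "bland_altman.png"))
        except Exception as exc:  # plotting is informational only
            log.warning("Bland-Altman plot skipped: %s", exc)
    return report


def run_experiment(cfg: RunConfig, out_dir: str) -> Path:
    """Run the full phantom study; returns the populated run directory."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    with open(run_dir / "config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, default=str)

    pairs, manifest = _make_phantoms(cfg, run_dir)
    ids = list(manifest["id"])
    by_id = dict(zip(ids, pairs))
    train_ids, test_ids = _split(cfg, run_dir, ids)

    # hold out the last ~20% of training volumes for validation
    n_val = max(1, len(train_ids) // 5) if len(train_ids) >= 3 else 0
    fit_ids = train_ids[: len(train_ids) - n_val]
    val_ids = train_ids[len(train_ids) - n_val:]
    train_pairs = [p for vid in fit_ids
                   for p in _slice_pairs(*by_id[vid], cfg.n_slices)]
    val_pairs = [p for vid in val_ids
                 for p in _slice_pairs(*by_id[vid], cfg.n_slices)]

    model, _ = _train(cfg, run_dir, train_pairs, val_pairs)
    test_sets = {vid: by_id[vid] for vid in test_ids}
    preds = _predict(cfg, run_dir, model, test_sets)
    surfaces = _reconstruct(cfg, run_dir, preds, test_sets)
    recs_2d, recs_3d, table_3d = _evaluate(cfg, run_dir, preds, surfaces,
                                           test_sets)
    _compare(cfg, run_dir, recs_2d, recs_3d, table_3d)
    return run_dir


def evaluate_only(
    pred_labels: dict,
    gt_labels: dict,
    cfg: RunConfig,
    out_dir: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Metric battery for precomputed label volumes (no training).

    ``pred_labels`` and ``gt_labels`` map volume id to
    :class:`~stvseg.volume.LabelVolume`; ids must match. Used for
    rater-vs-rater and rater-vs-algorithm comparisons. Returns the
    per-volume 3D table and (for >= 3 volumes) the comparison report.
    """
    if set(pred_labels) != set(gt_labels):
        missing = set(pred_labels) ^ set(gt_labels)
        raise ValueError(f"volume ids do not match: {sorted(missing)}")
    rows, recs_pred = [], []
    for vid in sorted(pred_labels):
        pl, gl = pred_labels[vid], gt_labels[vid]
        if pl.shape != gl.shape:
            raise ValueError(f"{vid}: shapes differ {pl.shape} vs {gl.shape}")
        spacing = (gl.spacing[1], gl.spacing[2])
        n_slices = min(cfg.n_slices, gl.shape[0])
        ps = reslice_label(pl, n_slices)
        gs = reslice_label(gl, n_slices)
        pred_s, pred_v, _ = masks_to_surface(
            ps, ps.images, cfg.interpolate_gaps, cfg.n_contour_points)
        gt_s, gt_v, _ = masks_to_surface(
            gs, gs.images, cfg.interpolate_gaps, cfg.n_contour_points)
        rec = met.evaluate_pair_3d(
            ps.images, gs.images, spacing, pred_s, gt_s, pred_v, gt_v,
            gt_label=gl, outside_positive=cfg.outside_positive)
        recs_pred.append(rec)
        rows.append({"id": vid, **rec.to_row(),
                     "pred_volume_mm3": pred_v, "manual_volume_mm3": gt_v})
    table = pd.DataFrame(rows)
    report = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "metrics_3d.csv", index=False, float_format="%.6f")
    return table, report
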