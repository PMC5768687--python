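"""End-to-end pipeline driver, configuration and cutting-list export.

Runs the full isolation-planning chain on one or more slides:

    illumination -> landmark detection -> segmentation -> features
    -> classifier training/selection -> prediction -> ranking
    -> cutting contours -> cross-microscope registration -> export

In synthetic mode the slides are generated by :mod:`camikit.synthetic`
and the training annotations are derived from the planted ground
truth, so the whole chain runs with no instrument and no external
data. Every stage writes its intermediate artifact under the output
directory and appends to a structured log, giving each exported cell
a full provenance chain (seed -> segment -> features -> prediction ->
contour -> registered contour).

The export dialect (CSV manifest + per-cell JSON contour + PNG
snapshot crop) is this package's own documented format; the
downstream microdissection instrument formats are proprietary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import classify, illumination, registration, segmentation, synthetic
from .features import FEATURE_NAMES, features_table
from .synthetic import SlideSpec
from .targeting import CuttingContour, check_collisions, make_cutting_contour

__all__ = ["PipelineConfig", "load_config", "run_pipeline",
           "export_cutting_list", "read_contour_file"]

log = logging.getLogger("camikit")


@dataclass
class PipelineConfig:
    """One YAML-serialisable object holding every stage's parameters."""

    seed: int = 0
    out_dir: str = "camikit_run"
    n_slides: int = 2
    slide: SlideSpec = field(default_factory=SlideSpec)
    # illumination
    illum_degree: int = 2
    illum_enabled: bool = True
    # segmentation
    wavelet_scales: tuple[int, ...] = (2, 3)
    k_sigma: float = 3.0
    otsu_block_px: int = 128
    # classification
    annotations_per_class: int = 40
    cv_folds: int = 10
    per_class_quota: int = 200
    # targeting / registration
    ring_um: float = 3.0
    max_vertices: int = 64
    swap_axes: bool = True
    ncc_threshold: float = 0.6
    target_origin_offset_um: tuple[float, float] = (250.0, 400.0)
    crop_margin_px: int = 12


def load_config(path: str | Path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    slide_doc = doc.pop("slide", None)
    cfg = PipelineConfig(**doc)
    if slide_doc is not None:
        mix = slide_doc.pop("class_mix", None)
        if mix is not None:
            slide_doc["class_mix"] = tuple(
                synthetic.ClassSpec(**c) for c in mix
            )
        for key in ("landmark_position_um", "origin_offset_um",
                    "semi_minor_um", "aspect_range"):
            if key in slide_doc:
                slide_doc[key] = tuple(slide_doc[key])
        cfg.slide = SlideSpec(**slide_doc)
    return cfg


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _derive_annotations(
    segments: list[segmentation.NucleusSegment],
    gt: synthetic.GroundTruth,
    feats: pd.DataFrame,
    per_class: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Synthetic stand-in for interactive annotation: label segments by
    the nearest planted nucleus and sample a balanced training set."""
    centers = np.array([[n.cx, n.cy] for n in gt.nuclei])
    classes = [n.class_name for n in gt.nuclei]
    labelled: dict[str, list[int]] = {}
    for seg in segments:
        if seg.border_touching or seg.undersized:
            continue
        cx, cy = seg.centroid
        d = np.hypot(centers[:, 0] - cx, centers[:, 1] - cy)
        j = int(np.argmin(d))
        if d[j] <= 6.0:
            labelled.setdefault(classes[j], []).append(seg.label)
    chosen_rows, chosen_labels = [], []
    feat_by_label = feats.set_index("label")
    for cls, seg_labels in sorted(labelled.items()):
        order = rng.permutation(len(seg_labels))
        for idx in order[:per_class]:
            lab = seg_labels[idx]
            chosen_rows.append(feat_by_label.loc[lab, list(FEATURE_NAMES)].to_numpy(float))
            chosen_labels.append(cls)
    return (np.array(chosen_rows), np.array(chosen_labels),
            sorted(set(chosen_labels)))


def _snapshot_crop(
    channel: np.ndarray, seg: segmentation.NucleusSegment, margin: int
) -> np.ndarray:
    y0, x0, y1, x1 = seg.bbox
    h, w = channel.shape
    y0, x0 = max(y0 - margin, 0), max(x0 - margin, 0)
    y1, x1 = min(y1 + margin, h), min(x1 + margin, w)
    crop = channel[y0:y1, x0:x1]
    lo, hi = float(crop.min()), float(crop.max())
    scaled = (crop - lo) / (hi - lo) if hi > lo else np.zeros_like(crop)
    return (scaled * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# main driver
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> tuple[classify.SelectionList, dict]:
    """Execute the full chain on synthetic slides; deterministic per seed.

    Returns the final selection list (with registered contours
    attached in ``reports``) plus a reports dict of per-stage
    diagnostics. Everything is also written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    reports: dict = {"slides": {}}
    try:
        return _run(config, out, reports)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path, reports: dict):
    rng = np.random.default_rng(config.seed)

    # --- acquire slides -----------------------------------------------------
    slides, truths = [], []
    for i in range(config.n_slides):
        spec = dataclasses.replace(config.slide, rng_seed=config.seed * 1000 + i)
        slide, gt = synthetic.generate_slide(spec)
        slide.slide_id = f"slide{i:02d}"
        slides.append(slide)
        truths.append(gt)
        synthetic.write_slide(slide, gt, out / slide.slide_id)
        log.info("generated %s: %d nuclei", slide.slide_id, len(gt.nuclei))

    # --- illumination (per channel, fitted across the slide stack) ---------
    if config.illum_enabled and len(slides) >= 2:
        for ch in ("nuclear", "marker"):
            model = illumination.fit_illumination(
                [s.channels[ch] for s in slides], degree=config.illum_degree
            )
            model.save(out / f"illumination_{ch}")
            for s in slides:
                s.channels[ch] = illumination.apply_correction(s.channels[ch], model)
            log.info("illumination fit (%s): residual %.3g, %d iters",
                     ch, model.residual, model.iterations)

    # --- landmark detection: source view and target (microdissection) view -
    spec = config.slide
    size_px = max(int(round(spec.landmark_size_um / spec.pixel_size_um)), 8)
    template = synthetic.landmark_template(size_px)
    frames = {}
    registered_views = {}
    for slide, gt in zip(slides, truths):
        det_src = registration.detect_landmark(
            slide.channels["nuclear"], template, slide.pixel_size_um,
            threshold=config.ncc_threshold,
            origin_offset_um=slide.origin_offset_um,
        )
        if not det_src.accepted:
            raise RuntimeError(f"landmark not found on {slide.slide_id}; "
                               "cannot register")
        target_view, _ = synthetic.render_transposed_view(
            slide, gt, config.target_origin_offset_um
        )
        det_tgt = registration.detect_landmark(
            target_view.channels["nuclear"], template.T,
            target_view.pixel_size_um, threshold=config.ncc_threshold,
            origin_offset_um=target_view.origin_offset_um,
        )
        if not det_tgt.accepted:
            raise RuntimeError(f"landmark not found in target view of "
                               f"{slide.slide_id}")
        src_frame = registration.frame_from_detection("source", det_src)
        # orientation bookkeeping is per-instrument; the relation itself
        # requires matching orientations, which the transposed views satisfy
        tgt_frame = registration.MicroscopeFrame(
            "target", det_tgt.x_um, det_tgt.y_um, src_frame.rotation_deg
        )
        frames[slide.slide_id] = (src_frame, tgt_frame)
        registered_views[slide.slide_id] = target_view
        registration.write_manifest(
            out / slide.slide_id / "registration.json",
            {"source": det_src, "target": det_tgt},
            {"source": src_frame, "target": tgt_frame},
        )
        log.info("%s landmark: source (%.2f, %.2f) um peak %.3f; "
                 "target (%.2f, %.2f) um peak %.3f",
                 slide.slide_id, det_src.x_um, det_src.y_um, det_src.peak,
                 det_tgt.x_um, det_tgt.y_um, det_tgt.peak)

    # --- segmentation + features -------------------------------------------
    per_slide_segments: dict[str, list[segmentation.NucleusSegment]] = {}
    per_slide_features: dict[str, pd.DataFrame] = {}
    for slide in slides:
        seeds = segmentation.detect_seeds(
            slide.channels["nuclear"], scales=config.wavelet_scales,
            k_sigma=config.k_sigma,
        )
        segments, diag = segmentation.segment_nuclei(
            slide.channels["nuclear"], seeds, block_px=config.otsu_block_px
        )
        segmentation.write_segments(segments, slide.shape, out / slide.slide_id)
        feats = features_table(slide.channels, segments)
        feats.to_csv(out / slide.slide_id / "features.csv", index=False)
        per_slide_segments[slide.slide_id] = segments
        per_slide_features[slide.slide_id] = feats
        reports["slides"][slide.slide_id] = {
            "n_seeds": len(seeds), "n_segments": len(segments), **diag,
        }
        log.info("%s: %d seeds, %d segments (%s)", slide.slide_id,
                 len(seeds), len(segments), diag)

    # --- training + model selection (annotations from slide 0 truth) -------
    X, y, label_set = _derive_annotations(
        per_slide_segments[slides[0].slide_id], truths[0],
        per_slide_features[slides[0].slide_id],
        config.annotations_per_class, rng,
    )
    train = classify.TrainingSet(X, y, tuple(label_set))
    model, report = classify.train_and_select(
        train, k=min(config.cv_folds, min(pd.Series(y).value_counts())),
        seed=config.seed,
    )
    reports["model"] = {"cv_accuracy": report.cv_accuracy,
                        "chosen": report.chosen_algorithm, "k": report.k}
    (out / "model_report.json").write_text(json.dumps(reports["model"], indent=2))
    log.info("model selection: %s", reports["model"])

    # --- prediction + ranking ----------------------------------------------
    predictions: list[classify.PhenotypePrediction] = []
    for slide in slides:
        feats = per_slide_features[slide.slide_id]
        segments = per_slide_segments[slide.slide_id]
        excl = {
            s.label: ("border" if s.border_touching else "undersized")
            for s in segments if s.border_touching or s.undersized
        }
        preds = classify.predict_all(
            model, feats[list(FEATURE_NAMES)].to_numpy(float),
            feats["label"].tolist(), slide_id=slide.slide_id, exclusions=excl,
        )
        predictions.extend(preds)
        pd.DataFrame([{
            "slide_id": p.slide_id, "nucleus_label": p.nucleus_label,
            "class": p.predicted_class, "confidence": p.confidence,
            "excluded": p.excluded, "reason": p.exclusion_reason,
        } for p in preds]).to_csv(out / slide.slide_id / "predictions.csv",
                                  index=False)
    selection = classify.rank_and_pick(predictions, config.per_class_quota)
    log.info("selected %d cells (shortfalls: %s)", len(selection.cells),
             selection.shortfalls)

    # --- contours + collision check + registration -------------------------
    seg_index = {
        (sid, s.label): s
        for sid, segs in per_slide_segments.items() for s in segs
    }
    slide_index = {s.slide_id: s for s in slides}
    contours: list[CuttingContour] = []
    for row in selection.cells.itertuples():
        seg = seg_index[(row.slide_id, row.nucleus_label)]
        slide = slide_index[row.slide_id]
        w_um = slide.shape[1] * slide.pixel_size_um
        h_um = slide.shape[0] * slide.pixel_size_um
        ox, oy = slide.origin_offset_um
        contours.append(make_cutting_contour(
            seg, slide.pixel_size_um, ring_um=config.ring_um,
            max_vertices=config.max_vertices,
            origin_offset_um=slide.origin_offset_um,
            image_bounds_um=(ox, oy, ox + w_um, oy + h_um),
            slide_id=row.slide_id,
        ))
    by_slide: dict[str, list[CuttingContour]] = {}
    for c in contours:
        by_slide.setdefault(c.slide_id, []).append(c)
    for sid, group in by_slide.items():
        check_collisions(group, per_slide_segments[sid],
                         slide_index[sid].pixel_size_um,
                         slide_index[sid].origin_offset_um)
    kept, dropped = [], []
    for c in contours:
        (dropped if (c.clipped or c.collides) else kept).append(c)
    reports["contours"] = {"kept": len(kept), "dropped": len(dropped)}
    log.info("contours: %d kept, %d dropped (clipped/collision)",
             len(kept), len(dropped))

    registered: list[CuttingContour] = []
    for c in kept:
        src_frame, tgt_frame = frames[c.slide_id]
        registered.append(registration.register_contour(
            c, src_frame, tgt_frame, swap_axes=config.swap_axes,
        ))
    kept_keys = {(c.slide_id, c.nucleus_label) for c in kept}
    final_cells = selection.cells[[
        (r.slide_id, r.nucleus_label) in kept_keys
        for r in selection.cells.itertuples()
    ]].reset_index(drop=True)
    final = classify.SelectionList(cells=final_cells,
                                  shortfalls=selection.shortfalls)
    reports["registered_contours"] = registered
    reports["segments"] = per_slide_segments
    reports["slide_objects"] = slide_index
    reports["ground_truths"] = dict(zip([s.slide_id for s in slides], truths))

    export_cutting_list(final, registered, slide_index, per_slide_segments,
                        out / "export", crop_margin_px=config.crop_margin_px)
    log.info("exported %d cells", len(final.cells))
    return final, reports


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_cutting_list(
    selection: classify.SelectionList,
    contours: list[CuttingContour],
    slides: dict[str, "synthetic.Slide"],
    segments: dict[str, list[segmentation.NucleusSegment]],
    out_dir: str | Path,
    decimals: int = 6,
    crop_margin_px: int = 12,
) -> Path:
    """Write the instrument hand-off files.

    (a) ``manifest.csv`` — one row per cell: ids, class, confidence and
    the target-frame centroid; (b) ``contours/<slide>_<label>.json`` —
    the registered vertex list in target um; (c) ``crops/`` — per-cell
    PNG snapshots documenting each cell before isolation. ``decimals``
    sets the export precision of the vertex coordinates.
    """
    out = Path(out_dir)
    (out / "contours").mkdir(parents=True, exist_ok=True)
    (out / "crops").mkdir(parents=True, exist_ok=True)
    contour_index = {(c.slide_id, c.nucleus_label): c for c in contours}
    rows = []
    for cell in selection.cells.to_dict("records"):
        key = (cell["slide_id"], cell["nucleus_label"])
        c = contour_index.get(key)
        if c is None or c.frame_id is None:
            raise ValueError(f"cell {key} has no registered contour")
        verts = np.round(c.vertices_um, decimals)
        name = f"{cell['slide_id']}_{cell['nucleus_label']:05d}"
        (out / "contours" / f"{name}.json").write_text(json.dumps({
            "slide_id": cell["slide_id"],
            "nucleus_label": int(cell["nucleus_label"]),
            "frame_id": c.frame_id, "ring_um": c.ring_um,
            "vertices_um": verts.tolist(),
        }))
        seg = next(s for s in segments[cell["slide_id"]]
                   if s.label == cell["nucleus_label"])
        crop = _snapshot_crop(slides[cell["slide_id"]].channels["nuclear"],
                              seg, crop_margin_px)
        iio.imwrite(out / "crops" / f"{name}.png", crop)
        cx, cy = verts[:-1, 0].mean(), verts[:-1, 1].mean()
        rows.append({
            "slide_id": cell["slide_id"],
            "nucleus_label": cell["nucleus_label"],
            "class": cell["class"],
            "confidence": round(float(cell["confidence"]), decimals),
            "target_x_um": round(float(cx), decimals),
            "target_y_um": round(float(cy), decimals),
        })
    manifest = pd.DataFrame(rows, columns=[
        "slide_id", "nucleus_label", "class", "confidence",
        "target_x_um", "target_y_um",
    ])
    manifest.to_csv(out / "manifest.csv", index=False)
    return out


def read_contour_file(path: str | Path) -> CuttingContour:
    doc = json.loads(Path(path).read_text())
    return CuttingContour(
        nucleus_label=doc["nucleus_label"], slide_id=doc["slide_id"],
        vertices_um=np.asarray(doc["vertices_um"], dtype=float),
        ring_um=doc["ring_um"], frame_id=doc["frame_id"],
    )
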