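"""Shared fixtures: small synthetic slides and matching utilities.

Slide generation is the expensive part of the suite, so the canonical
fixtures are session-scoped and sized to exercise every code path
(overlapping pairs, both phenotype classes, gain field, landmark)
without the full-survey image sizes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import camikit as ck


@pytest.fixture(scope="session")
def canonical_slide():
    """The default study-condition slide: 200 nuclei, 20% overlapping."""
    slide, gt = ck.generate_slide(ck.SlideSpec(rng_seed=1))
    return slide, gt


@pytest.fixture(scope="session")
def slide_stack():
    """Three default slides (different seeds) for illumination fitting."""
    specs = [dataclasses.replace(ck.SlideSpec(), rng_seed=s) for s in (1, 2, 3)]
    return [ck.generate_slide(sp) for sp in specs]


@pytest.fixture(scope="session")
def corrected_canonical(slide_stack):
    """Canonical slide with the stack-fitted gain removed from both channels."""
    models = {
        ch: ck.fit_illumination([sl.channels[ch] for sl, _ in slide_stack])
        for ch in ("nuclear", "marker")
    }
    slide, gt = slide_stack[0]
    channels = {
        ch: ck.apply_correction(slide.channels[ch], models[ch])
        for ch in ("nuclear", "marker")
    }
    corrected = ck.Slide(channels=channels, pixel_size_um=slide.pixel_size_um,
                         origin_offset_um=slide.origin_offset_um,
                         slide_id=slide.slide_id)
    return corrected, gt


@pytest.fixture(scope="session")
def segmented_canonical(corrected_canonical):
    slide, gt = corrected_canonical
    seeds = ck.detect_seeds(slide.channels["nuclear"])
    segments, diag = ck.segment_nuclei(slide.channels["nuclear"], seeds)
    return slide, gt, seeds, segments, diag


def iou_match(segments, gt, shape):
    """Greedy one-to-one matching of segments to planted nuclei by IoU.

    Returns (n_matched_at_iou_0.5, n_spurious_segments).
    """
    label_img = np.zeros(shape, np.int32)
    areas = {}
    for s in segments:
        y0, x0, y1, x1 = s.bbox
        label_img[y0:y1, x0:x1][s.mask] = s.label
        areas[s.label] = s.area_px
    candidates = []
    for gi, rec in enumerate(gt.nuclei):
        tm = gt.nucleus_mask(rec, shape)
        ts = tm.sum()
        vals, cnts = np.unique(label_img[tm], return_counts=True)
        for v, c in zip(vals, cnts):
            if v == 0:
                continue
            candidates.append((c / (ts + areas[v] - c), gi, int(v)))
    candidates.sort(reverse=True)
    used_gt, used_seg = set(), set()
    for iou, gi, lab in candidates:
        if iou >= 0.5 and gi not in used_gt and lab not in used_seg:
            used_gt.add(gi)
            used_seg.add(lab)
    return len(used_gt), len(segments) - len(used_seg)


@pytest.fixture(scope="session")
def canonical_features(segmented_canonical):
    slide, gt, seeds, segments, _ = segmented_canonical
    from camikit.features import features_table

    return features_table(slide.channels, segments)
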