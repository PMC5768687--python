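# camikit

Planning single-cell laser microdissection from fluorescence images.

Isolating *specific* single cells out of fixed tissue — chosen by their
phenotype, not just their position — requires closing the loop between a
high-throughput screening microscope and a laser microdissection (LCM)
instrument. `camikit` implements the computational core of that loop
(computer-assisted microscopy isolation, CAMI):

1. **Illumination correction** — a smooth multiplicative gain field is
   estimated retrospectively from an image collection (low-order polynomial
   surface, robust Huber fit by quasi-Newton optimisation) and removed.
2. **Nucleus segmentation** — nucleus centers are detected as local maxima
   of a B3-spline *à trous* wavelet decomposition of the nuclear channel;
   a seed-based adaptive Otsu threshold delineates the foreground, and
   merged components holding several seeds are partitioned by seeded
   watershed so touching/overlapping nuclei are recovered one-to-one.
3. **Feature extraction** — every nucleus gets a frozen registry of
   **92 measurements** of intensity, texture (13 Haralick co-occurrence
   statistics × mean/range over 4 directions) and shape.
4. **Classification and ranking** — user annotations train several
   candidate classifiers (random forest, logistic regression, k-NN, SVM);
   stratified 10-fold cross-validation picks the best, every cell is
   scored, and the **200 highest-confidence cells per phenotype class**
   become isolation candidates.
5. **Cutting contours** — each selected nucleus receives a polygon
   approximation of a **3 µm ring** around its boundary, so the laser
   never ablates nuclear material.
6. **Registration** — an orientation-asymmetric fiducial etched into the
   slide (50 × 50 µm) is located in both instruments by normalized 2-D
   cross-correlation, and contours are mapped from screening-microscope
   coordinates (x¹, y¹) to microdissection coordinates (x², y²) via

   ```
   (x², y²)ᵀ = (y¹, x¹)ᵀ − (y_off¹, x_off¹)ᵀ + (x_off², y_off²)ᵀ
   ```

   an axis swap plus translation — an exact isometry.
7. **Molecular QC** — the downstream numeric rules: digital-PCR reactions
   with CT < 23 (primer dimers) or CT > 33 (background) are excluded, and
   replicate expression profiles are compared by Pearson correlation and
   top-100 expressed-gene overlap.

A ground-truthed **synthetic slide generator** (dark slide, etched
landmark, hundreds of elliptical nuclei with overlapping pairs, two
marker phenotypes — punctate "foci" vs homogeneous signal — smooth gain
field, additive noise) makes the entire chain testable with no
instrument and no external data.

## Worked example

```python
import camikit as ck

# a synthetic screen: two slides, 200 nuclei each, 20% overlapping pairs
cfg = ck.PipelineConfig(seed=11, out_dir="camikit_run")
selection, reports = ck.run_pipeline(cfg)

print(reports["model"])
# {'cv_accuracy': {'random_forest': 0.975, 'logistic_regression': 1.0,
#   'knn': 1.0, 'svm': 0.9875}, 'chosen': 'logistic_regression', 'k': 10}
print(len(selection.cells))   # 161
print(selection.cells.head())
#   slide_id  nucleus_label class  confidence
# 0  slide01            249  foci    0.999897
# 1  slide00             55  foci    0.999798
# ...
```

The run directory contains, per slide, the corrected channels, the label
image, the segment table, the 92-column feature CSV and the per-cell
predictions; `export/` holds the instrument hand-off: a manifest CSV (one
row per selected cell with its target-frame centroid), per-cell cutting
contours as JSON vertex lists in target-microscope µm, and a PNG snapshot
of each cell before isolation. Cells whose ring would cross a neighbour
(collision) or leave the imaged area (clipped) are excluded from the
export and kept in diagnostics — here 161 of the 400 ranked candidates
survive those physical checks.

The same stages are available as a CLI (`camikit simulate`, `illum`,
`segment`, `features`, `register`, `run`).

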