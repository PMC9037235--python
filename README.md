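# pitcount

Automated counting of **pitted red blood cells** (%PIT) from differential
interference contrast (DIC) microscopy.

Pits are membrane-bound vacuoles that give erythrocytes a crater-like
surface appearance under DIC optics. A healthy spleen removes them from
circulating cells, so the percentage of RBCs carrying at least one pit —
the PIT count, or %PIT — is a well-validated surrogate biomarker of
splenic filtration function, used in particular in sickle cell anaemia,
where splenic function is lost early in life. Manual counting (at least
500 consecutive RBCs per sample under the microscope) is laborious and
user-dependent; this package implements the automated alternative as a
tested, fully synthetic-data-driven pipeline:

1. **simulate** — synthetic DIC scenes of biconcave RBCs with
   hemispherical pit craters and the real-world confounders (platelets
   adjoining cells, fused platelet aggregates, white blood cells,
   wrinkled cells, debris), with exhaustive ground truth.
2. **segment** — a trainable pixel classifier (multi-scale filter bank +
   random forest) labelling every pixel background / cell / pit.
3. **postprocess** — the macro stage: split channels, fill holes,
   separate adjoining cells with a distance-transform watershed, measure
   each cell, and exclude cells by size, edge contact, or low
   **solidity** (area / convex area — the workhorse filter against
   platelet aggregates and debris-attached cells).
4. **metrics** — %PIT and pit morphometrics per sample:

   ```
   %PIT = 100 × (# included cells with ≥ 1 pit) / (# included cells)
   ```

   plus the published splenic-function rules, applied exactly as
   printed: Rogers — %PIT ≥ 3.5 ⇒ loss of splenic function;
   El Hoss — %PIT < 1.2 ⇒ normal, %PIT > 4.5 ⇒ absent, otherwise
   indeterminate.
5. **agreement** — Bland–Altman method comparison (bias, limits of
   agreement bias ± 1.96·SD with t-based confidence intervals, LOA CIs
   via the classical sd·√(3/n) approximation), the stratified LOA
   acceptance rule (±5 %PIT overall, ±1.5 for samples with manual
   %PIT < 5%), observer-consensus maps, paired t-test and Pearson
   correlation.

## Worked example

Run the full seeded pipeline (simulate → train → segment → count) from
Python:

```python
from pitcount.config import run_config_from_dict
from pitcount.workflow import run_pipeline

cfg = run_config_from_dict({
    "seed": 5, "n_train_images": 3, "n_test_images": 3,
    "scene": {"image_height_px": 512, "image_width_px": 512,
              "pixel_size_um": 0.15, "n_cells": 30,
              "pitted_fraction": 0.3, "touching_fraction": 0.1},
    "metrics": {"min_cells": 25},
})
out = run_pipeline(cfg, "demo_out")
```

`demo_out/results.csv` then contains one row per held-out image
(abridged):

```
sample_id  n_cells_counted  n_pitted  percent_pit  mean_pits_per_pitted_cell  spleen_status
 test_000               28         6    21.428571                   1.666667         absent
 test_001               29         7    24.137931                   2.000000         absent
 test_002               30        14    46.666667                   1.642857         absent
```

and `pooled.csv` vs `truth_stats.csv` compare the automated count with
the simulator's ground truth: pooled automated %PIT **31.03** over 87
included cells against a true pooled %PIT of **31.11** — the classifier
plus macro recovers the pitted fraction to well under one percentage
point here. `n_cells_counted` is slightly below the 30 true cells per
scene because cells touching the image edge or failing the solidity
gate are excluded, exactly as the macro prescribes; the large
`excluded_size` tallies are mostly sub-RBC noise specks rejected by the
20–80 µm² size gate. Per-cell measurements (area, solidity, pit count,
pit areas, inclusion status) are in `test_*_cells.csv`.

The same stages are available as CLI subcommands:

```bash
pitcount simulate --config run.json --n-images 4 --out-dir scenes/
pitcount train    --config run.json --model-out model.joblib
pitcount segment  --model model.joblib --pixel-size 0.15 --out-dir seg/ scenes/*_image.tif
pitcount count    --pixel-size 0.15 --out-dir counts/ seg/*_labels.tif
pitcount agree    --pairs pairs.csv --out-dir ba/
pitcount pipeline --config run.json --seed 5 --out-dir full_run/
```

Reruns at a fixed seed are byte-identical.

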