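"""Workflow orchestration: simulate → train → segment → count.

The functions here are the programmatic face of the CLI subcommands;
everything is driven by one :class:`~pitcount.config.RunConfig` and a
single global seed, so reruns at a fixed seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np

from . import io
from .config import RunConfig, save_run_config
from .metrics import summarize_sample
from .postprocess import run_macro
from .segment import PixelClassifier, save_classifier
from .simulate import GroundTruthScene, SceneConfig, render_dic, sample_scene, scene_truth_stats
from .types import DICImage, LabelMap

log = logging.getLogger("pitcount")

__all__ = [
    "derive_seed",
    "scene_for_index",
    "simulate_batch",
    "train_from_scenes",
    "count_labels",
    "run_pipeline",
]


def derive_seed(global_seed: int, *stream: int) -> int:
    """A reproducible child seed (< 2^31) from the global seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(global_seed), *map(int, stream)]))
    return int(rng.integers(2**31))


def scene_for_index(scene_cfg: SceneConfig, global_seed: int, split: int, index: int) -> SceneConfig:
    return dataclasses.replace(scene_cfg, seed=derive_seed(global_seed, split, index))


def simulate_batch(
    scene_cfg: SceneConfig, global_seed: int, n_images: int, split: int = 0
) -> list[tuple[GroundTruthScene, DICImage]]:
    """Sample and render ``n_images`` scenes on independent seed streams."""
    out = []
    for i in range(n_images):
        cfg = scene_for_index(scene_cfg, global_seed, split, i)
        scene = sample_scene(cfg)
        out.append((scene, render_dic(scene)))
    return out


def train_from_scenes(batch, run_cfg: RunConfig) -> PixelClassifier:
    images = [img for _, img in batch]
    labels = [scene.truth_label_map for scene, _ in batch]
    clf = PixelClassifier(
        n_trees=run_cfg.forest.n_trees,
        max_depth=run_cfg.forest.max_depth,
        max_pixels_per_class=run_cfg.forest.max_pixels_per_class,
        feature_config=run_cfg.features,
        random_state=derive_seed(run_cfg.seed, 99),
    ).fit(images, labels)
    log.info("trained forest; held-out per-class accuracy: %s", clf.holdout_accuracy_)
    return clf


def count_labels(labels: LabelMap, pixel_size_um: float, run_cfg: RunConfig, image_id: str = ""):
    """Macro + metrics for one label map → (ObjectTable, SampleResult)."""
    table = run_macro(labels, pixel_size_um, run_cfg.postprocess, image_id)
    result = summarize_sample(
        table,
        min_cells=run_cfg.metrics.min_cells,
        rule=run_cfg.metrics.rule,
        pit_size_average=run_cfg.metrics.pit_size_average,
    )
    log.info(
        "%s: %d instances, included %d, excluded %s, pitted %d",
        image_id or "image",
        len(table),
        result.n_cells_counted,
        result.exclusions,
        result.n_pitted,
    )
    return table, result


def run_pipeline(run_cfg: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Simulate training and test scenes, train, segment the test scenes,
    run the macro and metrics, and write all artefacts under ``out_dir``.

    Writes per-image TIFFs (rendered image, truth and predicted label
    maps), per-image object tables, ``results.csv`` with one SampleResult
    row per test image, a pooled row, truth statistics for comparison,
    the fitted model, and the resolved config.
    """
    out = Path(out_dir if out_dir is not None else run_cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_run_config(run_cfg, out / "run_config.json")

    train_batch = simulate_batch(run_cfg.scene, run_cfg.seed, run_cfg.n_train_images, split=0)
    test_batch = simulate_batch(run_cfg.scene, run_cfg.seed, run_cfg.n_test_images, split=1)
    clf = train_from_scenes(train_batch, run_cfg)
    save_classifier(clf, out / "model.joblib")

    rows = []
    pooled_included = 0
    pooled_pitted = 0
    truth_rows = []
    for i, (scene, image) in enumerate(test_batch):
        image_id = f"test_{i:03d}"
        io.write_image(image, out / f"{image_id}_image.tif")
        io.write_labels(scene.truth_label_map, out / f"{image_id}_truth.tif")
        predicted = clf.predict(image)
        io.write_labels(predicted, out / f"{image_id}_pred.tif")
        table, result = count_labels(predicted, image.pixel_size_um, run_cfg, image_id)
        io.write_table(table, out / f"{image_id}_cells.csv")
        rows.append(io.sample_result_row(image_id, result))
        pooled_included += result.n_cells_counted
        pooled_pitted += result.n_pitted
        truth = scene_truth_stats(scene)
        truth_rows.append(
            {
                "sample_id": image_id,
                "true_n_rbc": truth.n_rbc,
                "true_n_pitted": truth.n_pitted,
                "true_percent_pit": truth.percent_pit,
            }
        )
    io.write_sample_results(rows, out / "results.csv")

    import pandas as pd

    pd.DataFrame(truth_rows).to_csv(out / "truth_stats.csv", index=False)
    pooled_pct = 100.0 * pooled_pitted / pooled_included if pooled_included else float("nan")
    pd.DataFrame(
        [
            {
                "n_cells_counted": pooled_included,
                "n_pitted": pooled_pitted,
                "percent_pit": pooled_pct,
            }
        ]
    ).to_csv(out / "pooled.csv", index=False)
    log.info("pooled automated %%PIT over %d cells: %.3f", pooled_included, pooled_pct)
    return out
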