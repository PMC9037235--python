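import numpy as np
import pytest

from pitcount.segment import PixelClassifier
from pitcount.simulate import SceneConfig, render_dic, sample_scene
from pitcount.workflow import simulate_batch

# Desk-scale study conditions shared across tests: a coarser 0.15 µm/px
# sampling keeps 12-50 cell scenes on small grids.
SMALL_PX = 0.15


def small_scene_config(**overrides) -> SceneConfig:
    base = dict(
        image_height_px=400,
        image_width_px=400,
        pixel_size_um=SMALL_PX,
        n_cells=12,
        pitted_fraction=0.4,
        touching_fraction=0.0,
        seed=7,
    )
    base.update(overrides)
    return SceneConfig(**base)


@pytest.fixture(scope="session")
def small_scene():
    cfg = small_scene_config()
    return sample_scene(cfg)


@pytest.fixture(scope="session")
def noiseless_clf():
    """Classifier trained on one noiseless, defocus-free scene (plus the
    scene itself) — for self-consistency and determinism checks."""
    cfg = small_scene_config(
        image_height_px=320, image_width_px=320, n_cells=8,
        pitted_fraction=0.5, noise_sigma=0.0, defocus_sigma_px=0.0, seed=21,
    )
    scene = sample_scene(cfg)
    image = render_dic(scene)
    clf = PixelClassifier(n_trees=30, random_state=3).fit([image], [scene.truth_label_map])
    return clf, scene, image


@pytest.fixture(scope="session")
def artefact_clf():
    """Classifier trained at default noise/defocus on scenes containing
    pits and all artefact classes; shared by the heavier segmentation and
    artefact-suppression tests."""
    cfg = small_scene_config(
        image_height_px=512,
        image_width_px=512,
        n_cells=25,
        pitted_fraction=0.4,
        touching_fraction=0.1,
        artefact_rates={
            "platelet_on_cell": 2.0,
            "platelet_aggregate": 1.0,
            "wbc": 1.0,
            "wrinkled_cell": 1.0,
            "debris": 1.0,
        },
    )
    batch = simulate_batch(cfg, 11, 3, split=0)
    clf = PixelClassifier(n_trees=50, random_state=11).fit(
        [img for _, img in batch], [s.truth_label_map for s, _ in batch]
    )
    return clf, cfg
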