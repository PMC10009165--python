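import logging

import numpy as np
import pytest

import filamorph as fm
from filamorph import segmentation as seg

logging.getLogger("filamorph").setLevel(logging.ERROR)


SMALL_COUNTS = {"dot": 12, "fragment": 6, "filament": 3, "ring": 4,
                "aggregate": 2}


@pytest.fixture(scope="session")
def small_scene():
    """One modest synthetic scene shared by read-only tests."""
    params = fm.SceneParams(image_size=(320, 320), counts=SMALL_COUNTS)
    return fm.gen_structure_scene(params, seed=11)


@pytest.fixture(scope="session")
def segmented_scene(small_scene):
    """The small scene run through cell/structure segmentation."""
    frame = seg.ImageFrame(small_scene.image, pixel_size=0.1)
    mask = seg.segment_cell(frame, small_scene.suggested_cell_threshold)
    bgsub = seg.subtract_background(frame)
    objects = seg.segment_structures(bgsub, mask, 2000.0)
    return small_scene, frame, mask, bgsub, objects


def truth_class_of(scene, obj):
    """Majority ground-truth class under a segmented object."""
    labs = scene.truth_labels[obj.pixels[:, 0], obj.pixels[:, 1]]
    labs = labs[labs > 0]
    if labs.size == 0:
        return "none"
    return scene.truth_classes.get(int(np.bincount(labs).argmax()), "none")


def disk_mask(radius, pad=2):
    n = int(np.ceil(radius)) + pad
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    return (yy ** 2 + xx ** 2) <= radius ** 2
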