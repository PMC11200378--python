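import numpy as np
import pytest

from mcpose import (
    BoundingBox,
    Keypoint,
    PoseInstance,
    SceneAnnotation,
    ScenePrediction,
    default_chicken_schema,
)


@pytest.fixture(scope="session")
def schema():
    return default_chicken_schema()


def make_instance(xy, visible=None, box=None, score=1.0):
    """Build a PoseInstance from an (N, 2) coordinate array."""
    xy = np.asarray(xy, dtype=float)
    if visible is None:
        visible = [1] * len(xy)
    if box is None:
        x0, y0 = xy.min(axis=0)
        x1, y1 = xy.max(axis=0)
        box = BoundingBox(float(x0) - 5, float(y0) - 5,
                          float(x1 - x0) + 10, float(y1 - y0) + 10)
    kps = tuple(Keypoint(float(x), float(y), int(v))
                for (x, y), v in zip(xy, visible))
    return PoseInstance(box=box, keypoints=kps, score=score)


def random_instance(rng, schema, width=640, height=480, score=1.0):
    """A random instance with all keypoints inside the image."""
    xy = rng.uniform([40, 40], [width - 40, height - 40], size=(1, 2)) \
        + rng.uniform(-30, 30, size=(schema.n_keypoints, 2))
    xy = np.clip(xy, 0, [width - 1, height - 1])
    return make_instance(xy, score=score)


def random_scene(rng, schema, image_id, n_gt, n_pred, width=640, height=480):
    """One random image: n_gt GT instances and n_pred scored predictions."""
    gt = tuple(random_instance(rng, schema, width, height)
               for _ in range(n_gt))
    pred = tuple(
        random_instance(rng, schema, width, height,
                        score=float(rng.uniform(0.05, 1.0)))
        for _ in range(n_pred)
    )
    return (SceneAnnotation(image_id=image_id, width=width, height=height,
                            instances=gt),
            ScenePrediction(image_id=image_id, instances=pred))
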