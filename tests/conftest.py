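from dataclasses import replace

import numpy as np
import pytest

from planktodetect import PipelineConfig
from planktodetect.candidates import detect_candidates
from planktodetect.merging import merge_colonies
from planktodetect.synthetic import SceneSpec, generate_dataset, generate_scene


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def scene():
    """One default synthetic scene with exact ground truth."""
    return generate_scene(SceneSpec(seed=3))


@pytest.fixture(scope="session")
def dataset30():
    """The default seeded 30-image synthetic study dataset (train, test)."""
    return generate_dataset(30, seed=7)


@pytest.fixture(scope="session")
def pipeline_outputs(dataset30, config):
    """Merged candidates (and pre-merge candidates) for every scene."""
    out = []
    for scene in dataset30[0] + dataset30[1]:
        cands = detect_candidates(scene.image, config)
        merged = merge_colonies(cands, scene.image, config)
        out.append((scene, cands, merged))
    return out


def candidate_object_ids(cand, scene) -> set[int]:
    """Planted object ids overlapped by a candidate's mask."""
    ys, xs = np.nonzero(cand.mask)
    labs = scene.label_map[ys + cand.bbox.y_min, xs + cand.bbox.x_min]
    return set(labs.tolist()) - {0}
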