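import warnings

import numpy as np
import pytest

from bmlpipe.phantom import demo_phantom_spec, generate_annotation, \
    generate_knee_phantom
from bmlpipe.segmentation import detect_hyperintensities, \
    extract_candidates, refine_bone_boundary

warnings.filterwarnings(
    "ignore", message=".*Maximum Likelihood optimization failed.*")
warnings.filterwarnings("ignore", message=".*covariance of constraints.*")
warnings.filterwarnings("ignore", message=".*Perfect separation.*")


@pytest.fixture(scope="session")
def demo_phantom():
    """Noisy two-lesion demo phantom (1.0 + 0.5 cm^3) with ground truth."""
    return generate_knee_phantom(demo_phantom_spec(seed=0))


@pytest.fixture(scope="session")
def segmented_demo(demo_phantom):
    """Full segmentation of the demo phantom under 1 mm annotation jitter."""
    vol, truth = demo_phantom
    ann = generate_annotation(truth, jitter_mm=1.0, seed=1)
    bones = refine_bone_boundary(vol, ann)
    cmask = detect_hyperintensities(vol, bones)
    cands = extract_candidates(cmask, vol, bones)
    return bones, cmask, cands


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
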