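import numpy as np
import pytest
from hypothesis import settings

import grainct as g

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


#: compact phantom used by unit tests; small enough to keep the suite quick
SMALL_SPEC = dict(shape=(112, 112, 112), semi_axes=(46.0, 38.0, 30.0),
                  shell_thickness=10.0)


@pytest.fixture(scope="session")
def phantom_bundle():
    """Default-size porous phantom pushed through the full analysis chain."""
    spec = g.PhantomSpec(void_fraction=0.3, seed=1)
    vol, truth = g.generate_phantom(spec)
    mask = g.segment_caryopsis(vol)
    trace = g.detect_crease_tips(mask, 5.0)
    transform = g.compute_alignment(mask, trace)
    masked = g.apply_mask(vol, mask)
    aligned_mask = g.apply_transform(mask, transform)
    aligned = g.apply_transform(masked, transform)
    return {
        "spec": spec, "vol": vol, "truth": truth, "mask": mask,
        "trace": trace, "transform": transform,
        "aligned": aligned, "aligned_mask": aligned_mask,
    }


@pytest.fixture(scope="session")
def solid_phantom():
    """Void-free default-size phantom (porosity degenerate case)."""
    spec = g.PhantomSpec(void_fraction=0.0, seed=2)
    vol, truth = g.generate_phantom(spec)
    return vol, truth


@pytest.fixture(scope="session")
def small_phantom():
    """Compact solid phantom for geometry-level unit tests."""
    spec = g.PhantomSpec(**SMALL_SPEC, void_fraction=0.0, seed=7)
    vol, truth = g.generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
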