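import numpy as np
import pytest

from camseg.phantoms import PhantomSpec, generate_phantom
from camseg.preprocess import PreprocessConfig, preprocess_case

# study-scale phantom: 32^3 at 3 mm so a case spans ~10 cm with nodules
# of 9-21 mm (>= 3 voxels across)
DESK_SPEC = PhantomSpec(
    shape=(32, 32, 32),
    spacing=(3.0, 3.0, 3.0),
    nodule_diameter_mm=(9.0, 21.0),
    nodules_per_case=(1, 2),
    noise_sigma_hu=20.0,
)


@pytest.fixture(scope="session")
def desk_spec():
    return DESK_SPEC


@pytest.fixture(scope="session")
def phantom_case():
    return generate_phantom(DESK_SPEC, seed=7)


def preprocessed_phantoms(n, seed, spec=DESK_SPEC):
    """n preprocessed (volume, mask) training pairs at the phantom's own grid."""
    cfg = PreprocessConfig(target_shape=spec.shape)
    out = []
    rng = np.random.default_rng(seed)
    for case_seed in rng.integers(0, 2 ** 31 - 1, size=n):
        case = generate_phantom(spec, int(case_seed))
        vol, mask = preprocess_case(case.volume, case.mask, cfg)
        out.append((vol.data.astype(np.float32), mask.data))
    return out


@pytest.fixture(scope="session")
def tiny_dataset():
    return preprocessed_phantoms(3, seed=100)
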