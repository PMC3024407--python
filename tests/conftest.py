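import numpy as np
import pytest

from ktblast_tpm.phantom import MotionModel, PhantomGeometry, build_phantom, encode_velocity
from ktblast_tpm.protocol import ProtocolParams


@pytest.fixture
def protocol() -> ProtocolParams:
    return ProtocolParams()


@pytest.fixture
def motion() -> MotionModel:
    return MotionModel()


@pytest.fixture
def small_phantom(motion):
    """48x48, 12-phase phantom covering most of the cycle."""
    return build_phantom(
        motion=motion, n_phases=12, matrix=(48, 48),
        times_frac=np.arange(12) / 12.0, rr_ms=1000.0,
    )


@pytest.fixture
def small_encoded(small_phantom):
    return encode_velocity(small_phantom, venc_cm_s=30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
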