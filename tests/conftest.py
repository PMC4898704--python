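import numpy as np
import pytest

from titinsim import (
    Isoform,
    MechanicalParams,
    build_force_curves,
    default_cluster_model,
    default_length_grid,
    make_ramp,
)
from titinsim.mechanics import ForceCurveFamily
from titinsim.protocols import LengthProtocol


@pytest.fixture(scope="session")
def params():
    return MechanicalParams()


@pytest.fixture(scope="session")
def isoform():
    return Isoform()


@pytest.fixture(scope="session")
def family(params, isoform):
    """Force-curve family of the default rabbit-psoas model, 1 nm grid."""
    return build_force_curves(default_length_grid(), params, isoform)


@pytest.fixture(scope="session")
def ramp():
    """Canonical 1 -> 2 um half-sarcomere ramp at 1 um/s."""
    return make_ramp(1e-6, 2e-6, 1e-6)


@pytest.fixture(scope="session")
def default_model():
    """Five stability clusters of ten domains, geometric rate spacing."""
    return default_cluster_model()


def flat_family(forces_by_level) -> ForceCurveFamily:
    """Length-independent force curves (frozen-force toy models)."""
    f = np.asarray(forces_by_level, dtype=float)
    return ForceCurveFamily(np.array([0.0, 1.0]), np.tile(f[:, None], (1, 2)))


def hold(duration: float, length: float = 0.5) -> LengthProtocol:
    """Constant-length protocol."""
    return LengthProtocol(np.array([0.0, duration]),
                          np.array([length, length]))


@pytest.fixture
def make_flat_family():
    return flat_family


@pytest.fixture
def make_hold():
    return hold
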