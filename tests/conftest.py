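import numpy as np
import pytest

from nanosip.isotope_quant import SubstrateSpec
from nanosip.synthetic_data import GeneratorConfig, IonYields


@pytest.fixture
def dom_substrate() -> SubstrateSpec:
    """Dual-labeled algal-exudate addition: 18% 13C / 45% 15N, diluted 50%."""
    return SubstrateSpec(
        f_s_C_labeled=0.18,
        f_s_N_labeled=0.45,
        dilution_unlabeled=0.5,
        duration_days=1.0,
    )


@pytest.fixture
def undiluted_substrate() -> SubstrateSpec:
    """Glycolate/nitrate-style design: undiluted labels, 48 h."""
    return SubstrateSpec(
        f_s_C_labeled=0.99,
        f_s_N_labeled=0.45,
        dilution_unlabeled=0.0,
        duration_days=2.0,
    )


@pytest.fixture
def small_config() -> GeneratorConfig:
    """Small, fast acquisition geometry for imaging tests."""
    return GeneratorConfig(
        raster_um=20.0,
        pixels=128,
        cycles=6,
        dwell_ms=1.0,
        ion_yields=IonYields(c2_cell=80.0, c2_background=0.5, cn_cell=200.0, cn_background=0.5),
        seed=42,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
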