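import numpy as np
import pytest

from tailscope.sd_detect import TailSequence
from tailscope.synthetic import BSU_TAIL, ECO_TAIL, synthetic_tail3_reference


@pytest.fixture(scope="session")
def bsu_tail() -> TailSequence:
    """15-nt B. subtilis-like mature tail, CCUCC at sites 6-10."""
    return TailSequence(BSU_TAIL, species="bsu")


@pytest.fixture(scope="session")
def eco_tail() -> TailSequence:
    """13-nt E. coli-like mature tail."""
    return TailSequence(ECO_TAIL, species="eco")


@pytest.fixture(scope="session")
def bsu_ref():
    """Synthetic 85-nt rDNA 3' region ending ...GATCACCTCCTTTCT + extension."""
    return synthetic_tail3_reference("bsu", seed=0)


@pytest.fixture(scope="session")
def eco_ref():
    return synthetic_tail3_reference("eco", seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
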