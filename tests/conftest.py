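import pytest

from kselect.selectors import MethodSpec


@pytest.fixture
def open_syncmer_15_11_3() -> MethodSpec:
    return MethodSpec("open_syncmer", k=15, s=11, t=3, order_seed=7)


@pytest.fixture
def closed_syncmer_15_11() -> MethodSpec:
    return MethodSpec("closed_syncmer", k=15, s=11, order_seed=7)


@pytest.fixture
def minimizer_9_15() -> MethodSpec:
    return MethodSpec("minimizer", k=15, w=9, order_seed=7)
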