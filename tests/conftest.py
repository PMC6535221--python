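import pytest

from lncforge.simulate import SimConfig, simulate_study


@pytest.fixture()
def default_cfg():
    return SimConfig.default(seed=7)


@pytest.fixture()
def study(default_cfg):
    """A freshly generated default synthetic study (function-scoped because
    downstream stages annotate the transcript objects in place)."""
    return simulate_study(default_cfg)
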