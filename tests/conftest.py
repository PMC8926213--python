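import pytest

import ssiweight as sw
from ssiweight.design import with_participants


@pytest.fixture(scope="session")
def default_design():
    return sw.build_default_design()


@pytest.fixture(scope="session")
def small_table(default_design):
    """Six perceptual participants, full factorial (fast, deterministic)."""
    design = with_participants(default_design, 6)
    models = sw.make_cohort(6, master_seed=123)
    return design, sw.simulate_study(design, models, master_seed=123)


@pytest.fixture(scope="session")
def random_table(default_design):
    """Sixty random-responder participants, both conditions."""
    design = with_participants(default_design, 60)
    models = sw.make_cohort(60, master_seed=321, mode="random")
    return design, sw.simulate_study(design, models, master_seed=321)
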