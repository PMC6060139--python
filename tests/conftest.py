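import pytest
from hypothesis import settings

import angiosched as ang
from angiosched._fast import warm_up
from angiosched.params import (FIG2_CONTINUOUS, FIG3_THRESHOLD,
                               FIG4_BEST_FIT, params_from_dict)

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session", autouse=True)
def _jit_warmup():
    """Compile the numba kernels once for the whole session."""
    warm_up()


def _paramset(d):
    g, ch, pb, pf = params_from_dict(d)
    return g, ch, {ang.Drug.BVZ: pb, ang.Drug.FOLFOX: pf}


@pytest.fixture(scope="session")
def fig2():
    """Published continuous-model example parameter set."""
    return _paramset(FIG2_CONTINUOUS)


@pytest.fixture(scope="session")
def fig3():
    """Published threshold-model example parameter set."""
    return _paramset(FIG3_THRESHOLD)


@pytest.fixture(scope="session")
def fig4():
    """Published threshold-model best-fit parameter set."""
    return _paramset(FIG4_BEST_FIT)


@pytest.fixture(scope="session")
def pk_true():
    return dict(ang.studies.PK_TRUE)


@pytest.fixture(scope="session")
def recovery_study():
    """Small synthetic three-arm study with known ground truth."""
    return ang.studies.make_recovery_study(seed=11)
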