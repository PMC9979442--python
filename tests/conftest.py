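import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from _helpers import make_fit  # noqa: E402

from btccea.config import base_case_config  # noqa: E402


@pytest.fixture
def config():
    return base_case_config()


@pytest.fixture
def chemo_fits(config):
    pfs, os_ = config.survival.fits("chemo")
    return make_fit(pfs.lam, pfs.gam), make_fit(os_.lam, os_.gam)


@pytest.fixture
def combo_fits(config):
    pfs, os_ = config.survival.fits("combo")
    return make_fit(pfs.lam, pfs.gam), make_fit(os_.lam, os_.gam)
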