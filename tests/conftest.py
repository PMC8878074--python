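import warnings

import pytest


@pytest.fixture(autouse=True)
def _quiet_packing_warnings():
    # dense synthetic scenes legitimately place fewer nuclei than requested;
    # the flag is asserted where it matters, elsewhere it is just noise
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="placed .*nuclei")
        yield
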