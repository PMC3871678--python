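import numpy as np
import pytest

from neuroscale import HeadModel, build_cortical_surface, build_montage


@pytest.fixture(scope="session")
def surf4():
    """Folded ico4 surface (5124 nodes), area-calibrated."""
    return build_cortical_surface(mesh_level=4, seed=1)


@pytest.fixture(scope="session")
def surf4_smooth():
    """Unfolded ico4 sphere pair."""
    return build_cortical_surface(mesh_level=4, fold_amplitude=0.0, seed=1)


@pytest.fixture(scope="session")
def head(surf4):
    return HeadModel(fold_amplitude=surf4.fold_amplitude)


@pytest.fixture(scope="session")
def montages(head):
    return {m: build_montage(m, head) for m in ("eeg", "meg_mag", "meg_grad", "dot")}
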