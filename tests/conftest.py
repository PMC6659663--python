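import numpy as np
import pytest

from glrlmtex import DIRECTIONS, ROISpec
from glrlmtex.fixtures import table1_fixture


@pytest.fixture(scope="session")
def worked():
    """The embedded 5x5 worked ROI with its four known GLRLMs."""
    return table1_fixture()


@pytest.fixture(scope="session")
def spec55():
    return ROISpec(roi_width=5, roi_height=5)


@pytest.fixture(params=list(DIRECTIONS))
def direction(request):
    """Parametrize over the four principal directions."""
    return DIRECTIONS[request.param]


def dense_from_entries(entries):
    """Dense GLRLM matrix from a sparse {(gray, run): count} mapping."""
    max_g = max(g for g, _ in entries) + 1
    max_r = max(r for _, r in entries) + 1
    dense = np.zeros((max_g, max_r), dtype=np.int64)
    for (g, r), c in entries.items():
        dense[g, r] = c
    return dense
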