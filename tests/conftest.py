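import numpy as np
import pytest

from bspm import PriorSpec, q_values
from bspm.ppm import PosteriorProbabilityMap


def make_map_from_pp(pp_h1, prior=None, design="paired", null_type="interval"):
    """Assemble a PosteriorProbabilityMap directly from a pp_h1 array
    (bypassing the Bayes factor machinery) for cluster-logic tests."""
    pp_h1 = np.asarray(pp_h1, dtype=float)
    pp_h0 = 1.0 - pp_h1
    bf10 = pp_h1 / np.maximum(pp_h0, 1e-300)
    return PosteriorProbabilityMap(
        bf10=bf10, pp_h1=pp_h1, pp_h0=pp_h0,
        pep_h1=pp_h0, pep_h0=pp_h1,
        q_h1=q_values(pp_h0), q_h0=q_values(pp_h1),
        prior=prior or PriorSpec(c=0.2), design=design, null_type=null_type,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
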