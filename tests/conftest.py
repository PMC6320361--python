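import numpy as np
import pytest

from floranet import InputSignals, MotifParams, ParameterSet

#: Published positive equilibrium of the full model (nM), order
#: AP1, LFY, SOC1, FD, AGL24, FT.
PUBLISHED_STEADY_STATE = np.array(
    [121.567, 452.395, 827.835, 1113.882, 86881.258, 2.037])

#: Post-germination expression levels (nM), same ordering.
GERMINATION_STATE = np.array([0.00056, 0.68, 33.3, 0.431, 27.69, 0.00056])

#: FT / FT-FD action constants that best match the full model's equilibrium.
BEST_MATCH_F1 = 1.3445
BEST_MATCH_F2 = 1.0476


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet.default()


@pytest.fixture(scope="session")
def inputs() -> InputSignals:
    return InputSignals.default()


@pytest.fixture(scope="session")
def motif_best(params) -> MotifParams:
    return MotifParams.from_parameters(params, F1=BEST_MATCH_F1, F2=BEST_MATCH_F2)
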