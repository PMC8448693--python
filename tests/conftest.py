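import numpy as np
import pandas as pd
import pytest

from mixtk import schemas as S
from mixtk.dose_response import ExponentialModelParams
from mixtk.synthetic import generate_dose_response


@pytest.fixture
def known_params() -> ExponentialModelParams:
    return ExponentialModelParams(a=100.0, b=0.01, c=0.2, d=1.0)


@pytest.fixture
def grid() -> np.ndarray:
    return np.array([0.0, 5.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0])


@pytest.fixture
def noise_free_data(known_params, grid) -> pd.DataFrame:
    return generate_dose_response(known_params, grid, residual_sd=0.0,
                                  bio_intercept_sd=0.0, seed=0)
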